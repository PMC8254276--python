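"""Exception hierarchy for isomergen.

All package-specific errors derive from :class:`IsomergenError` so callers can
catch everything the library raises with a single ``except`` clause.
"""


class IsomergenError(Exception):
    """Base class for all isomergen errors."""


class ParseError(IsomergenError, ValueError):
    """A molecular formula string could not be tokenised."""


class UnsupportedElement(ParseError):
    """The formula names an element outside the supported valence table."""


class InvalidInput(IsomergenError, ValueError):
    """An argument violates a documented precondition (wrong length, empty, ...)."""


class GraphNonexistent(IsomergenError):
    """No graph can realise the degree sequence implied by the formula."""


class CapacityError(IsomergenError):
    """A brute-force enumeration would exceed its configured size bound."""


class StateError(IsomergenError):
    """An operation was called on an object in the wrong state
    (e.g. a connectivity back-jump requested for a connected matrix)."""
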