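"""Structure output: MDL SDF (V2000 molfiles) and optional SMILES.

Hydrogens, removed for generation, are re-attached on output: they are
appended after the heavy atoms and bonded, order 1, to their heavy atom in
heavy-atom index order, so every record round-trips to the input molecular
formula.  Counts-line integers use the 3-wide right-justified fields the
V2000 format requires.  No SDF property fields are emitted.

SMILES output converts each molfile record through RDKit and therefore
requires the optional ``rdkit`` dependency at run time.
"""

from __future__ import annotations

import os
from typing import IO, Iterable, Iterator

from .errors import InvalidInput
from .generator import Molecule

__all__ = ["molblock", "write_sdf", "write_smiles"]


def molblock(mol: Molecule, title: str = "") -> str:
    """Render one structure as a V2000 molfile block (without ``$$$$``)."""
    symbols = mol.atom_symbols()
    bonds = mol.all_bonds()
    lines = [
        title,
        "  isomergen          2D",
        "",
        f"{len(symbols):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for sym in symbols:
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {sym:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for a, b, order in bonds:
        if not 1 <= order <= 3:
            raise InvalidInput(f"bond order {order} outside 1..3")
        lines.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines)


def _open_sink(path_or_file: "str | os.PathLike | IO[str]"):
    if hasattr(path_or_file, "write"):
        return path_or_file, False
    try:
        return open(path_or_file, "w"), True
    except OSError as exc:
        raise OSError(f"cannot write SDF to {path_or_file!r}: {exc}") from exc


def write_sdf(
    structures: Iterable[Molecule],
    path_or_file: "str | os.PathLike | IO[str]",
    *,
    title: str = "",
) -> int:
    """Write structures as an SDF file; returns the number of records."""
    sink, owned = _open_sink(path_or_file)
    n = 0
    try:
        for mol in structures:
            sink.write(molblock(mol, title=title))
            sink.write("\n$$$$\n")
            n += 1
    finally:
        if owned:
            sink.close()
    return n


def to_smiles(mol: Molecule) -> str:
    """Canonical SMILES of one structure (requires rdkit)."""
    from rdkit import Chem  # deferred: optional dependency

    rd = Chem.MolFromMolBlock(molblock(mol), sanitize=False)
    if rd is None:
        raise InvalidInput("structure could not be interpreted as a molblock")
    Chem.SanitizeMol(
        rd,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
    )
    return Chem.MolToSmiles(rd)


def write_smiles(
    structures: Iterable[Molecule], path_or_file: "str | os.PathLike | IO[str]"
) -> int:
    """Write one SMILES per line; returns the number of records."""
    sink, owned = _open_sink(path_or_file)
    n = 0
    try:
        for mol in structures:
            sink.write(to_smiles(mol))
            sink.write("\n")
            n += 1
    finally:
        if owned:
            sink.close()
    return n


def iter_molblocks(structures: Iterable[Molecule], title: str = "") -> Iterator[str]:
    """Lazily render molfile blocks (``$$$$`` separator not included)."""
    for mol in structures:
        yield molblock(mol, title=title)
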