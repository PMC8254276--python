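# isomergen

Exhaustive, duplicate-free generation of **constitutional isomers** from a
molecular formula, in pure Python.

Given a formula such as `C10H16O`, the package enumerates every connected
molecular multigraph that realises the formula at the elements' lowest
valences (C=4, N=3, P=3, O=2, S=2, halogens=1, H=1), exactly once per
isomorphism class — the kind of enumeration used to chart chemical spaces
and to drive hypothesis generation in computer-assisted structure
elucidation.

The method is *orderly generation*: molecules are bond-order adjacency
matrices `A`, interchangeable atoms form the blocks of an ordered partition
λ, and only the canonical — lexicographically maximal — matrix of each
Young-subgroup orbit is ever completed,

```
A canonical  ⇔  A ≥ Aπ  for all π ∈ S_λ ,
```

so duplicates are excluded *during* construction rather than filtered
afterwards.  Hydrogens are distributed onto the heavy atoms first (they are
always pendant), the matrix is filled block-wise with maximality tested as
soon as each block completes, and rejected or disconnected candidates
teach the search where to resume (witness and first-component back-jumps).
See `docs/methods.md` for the full account.

## Usage

From the shell:

```
$ isomergen -f C2OH4
C2H4O: 3 structures (0.00 s)

$ isomergen -f C4H10 -o /tmp --format sdf   # writes /tmp/C4H10.sdf
```

The three isomers of C2H4O are acetaldehyde, oxirane and vinyl alcohol;
with `-v` the tool also logs the per-hydrogen-distribution breakdown
(C6H6, for instance, has 7 hydrogen distributions contributing
7+46+16+34+76+32+6 = 217 structures).

From Python:

```python
>>> from isomergen import generate, generate_structures
>>> generate("C6H6").count
217
>>> mol = next(generate_structures("C2H6O"))
>>> mol.elements, mol.hydrogens, mol.bonds
(('C', 'C', 'O'), (3, 2, 1), ((0, 1, 1), (1, 2, 1)))
```

`generate` counts; `generate_structures` streams `Molecule` objects
(heavy-atom skeleton, per-atom hydrogen counts, bond list) that
`isomergen.sdf.write_sdf` renders as V2000 molfiles with hydrogens
re-attached.  A brute-force oracle (`isomergen.brute_force_count`) provides
independent ground truth for small formulae and backs the test suite.

## Testing

```
python -m pytest -q tests/
```

The suite validates the generator against the brute-force oracle on a
35-formula panel, checks the canonical engine against naive orbit
enumeration, cross-checks isomorphism keys with networkx and the SDF
writer with RDKit, and reproduces the worked partition/cycle examples.

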