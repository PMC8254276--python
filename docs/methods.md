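# Methods

`isomergen` enumerates the constitutional isomers of a molecular formula:
all connected multigraphs whose nodes are the formula's atoms at their
lowest valences and whose edge multiplicities (bond orders 1–3) exactly
consume every atom's valence, counted once per isomorphism class.
Stereochemistry, charges, radicals, isotopes and higher oxidation states of
N, P and S are out of scope.

## Model

A molecule is a coloured multigraph represented by a symmetric p×p
bond-order matrix `A` over the heavy atoms (zero diagonal, entries 0–3,
row sums equal to the residual degrees).  Interchangeable atoms — same
element, same residual degree — are grouped into the contiguous blocks of
an ordered partition λ, and the symmetry group respected by the colouring
is the Young subgroup S_λ (the direct product of symmetric groups on the
blocks).  Two matrices describe the same isomer exactly when one is the
image of the other under S_λ; the *canonical* representative of each orbit
is defined as the row-lexicographically maximal matrix, `A ≥ Aπ` for all
π ∈ S_λ.

The generator is *orderly*: it constructs only canonical matrices in the
first place, so duplicate elimination needs no memory of previously
generated structures, and the set of emissions is exhaustive and
duplicate-free by construction.

## Pipeline

1. **Existence check.**  A degree sequence is realisable as a connected
   graph only if its sum is even and at least `2(p−1)`.  The check is
   applied to the full formula (hydrogens included) before anything else,
   and again to every heavy-atom degree sequence produced by step 2.
   The second application is a conservative pruning: it discards hydrogen
   distributions that could not possibly yield a connected heavy graph.

2. **Hydrogen distribution.**  Hydrogens have valence 1 and are always
   pendant, so they are distributed onto the heavy atoms up front and
   removed from the matrix problem.  Within each element block the per-atom
   hydrogen counts are enumerated as non-decreasing sequences, which makes
   the enumeration duplicate-free; the per-atom cap is valence−1 when p ≥ 2
   (a hydrogen-saturated atom could never connect to the rest) and the full
   valence when p = 1.  Each surviving assignment yields a degree state:
   residual degrees sorted non-increasingly inside every element block, and
   the partition refined so each block has constant (element, degree).

3. **Orderly fill ("build-and-forget").**  The upper triangle is filled
   row-major, each entry set to the largest feasible value
   `min(rem_i, rem_j, 3)`.  One working matrix is mutated through the whole
   search: after an emission or a rejection the last relevant entry is
   decremented and the fill resumes after it.  A row whose residual degree
   cannot fit into its remaining columns is abandoned immediately.

4. **Canonical test.**  Performed whenever all rows of an initial-partition
   block are complete, row by row within the block.  For row `i` the
   refined partition (earlier indices singleton, later blocks grouping
   columns identical in all earlier rows) is maintained together with the
   automorphism list F⁽ⁱ⁾ — permutations fixing the partial matrix through
   row `i`.  Row `i` is compared against every candidate τ·ς (τ ∈ F⁽ⁱ⁻¹⁾,
   ς a cycle transposition of the block at `i` — the coset representatives
   linking S of the previous partition to S of the refined one).  The
   permuted row may be re-sorted descending inside each refined block
   (the adversary can always adjust later rows accordingly): a strictly
   larger sorted row rejects the matrix, an equal one contributes the
   composite τ·ς·σ to F⁽ⁱ⁾, where σ is the deterministic block-wise
   matching of equal entries.  After the row passes, the partition is
   subdivided at every value change of the row.

5. **Witness back-jump.**  A rejected matrix yields a *witness*: the
   latest-filled entry among those that certify the violation — the
   original row prefix up to the failing position, the source entries of
   the permuted row realising the sorted prefix (ties resolved toward
   smaller columns), and, when the automorphism τ maps an earlier row onto
   a row m ≥ i, the whole of row m (the entries that certify τ's
   automorphism property).  Every continuation keeping the prefix up to the
   witness unchanged retains the certificate — added or altered entries
   beyond it can only raise the adversary's sorted prefix — so the fill may
   resume directly at the witness.  The row-m extension is essential: an
   automorphism certified partly by entries *beyond* the witness can break
   in a skipped continuation, and without the extension the generator
   undercounts (dropping it loses 4 of the 217 isomers of C6H6).  Setting
   `learning=False` reverts to plain backward steps; the test suite checks
   both paths produce identical counts.

6. **Connectivity test.**  Completed canonical matrices are screened by
   label propagation: every node starts with its own index, each node's
   closed neighbourhood is collapsed to its minimum label, and sweeps
   repeat until stable (a single sweep is not always sufficient; the
   fixpoint provably equals traversal reachability, which the suite
   asserts).  For a disconnected matrix the component containing node 0
   (the *first component*) is located; entries after the last entry of its
   maximum-index row can only produce further disconnected graphs, so the
   fill back-jumps there.  The generator's hot loop uses an equivalent
   stack traversal; the label-propagation implementation is the public API
   and the property tests pin their agreement.

## Numerical and design choices

* **Bond-order bound.**  Each entry is bounded by
  `min(rem_i, rem_j, 3)`.  A per-bond cap of valence−1 may look natural
  (carbon's largest bond order is 3) but generalises wrongly: it would
  forbid the terminal triple bond of a nitrile-like trivalent atom and
  demonstrably undercounts (the brute-force oracle gives 5 isomers for
  C2H3N, including acetonitrile; the capped variant finds 4).  The ≤3 cap
  is what excludes quadruple bonds (C2 admits no structure).
* **Atom order.**  Heavy atoms sorted by descending valence, ties broken
  alphabetically (C, N, P, O, S, then halogens).  Any fixed order is
  correct; a deterministic one makes matrices and output reproducible.
* **Indexing.**  All public interfaces are 0-based (rows, columns,
  permutations).  Group-theory literature conventionally writes 1-based
  cycles; `permutation_from_cycles(..., one_based=True)` bridges the two
  so documented worked examples can be written verbatim.
* **Partition invariant.**  Refinement always preserves Σλᵢ = p; the
  refinement chain of C3O2 (p = 5) ends in {1,1,1,1,1}.
* **Emission order.**  Within a degree state, matrices appear in descending
  lexicographic order (a consequence of always filling maximal values
  first); degree states appear in ascending hydrogen-profile order.  Counts
  are order-independent; the order itself is part of the determinism
  contract.
* **Degenerate inputs.**  p = 1 emits a single structure when hydrogens
  exactly consume the valence; the formula H2 is handled as the single
  two-atom graph; formulae failing the existence check raise
  `GraphNonexistent`.

## Validation strategy

The brute-force oracle (`isomergen.oracle`) is the ground truth at small
sizes: it enumerates every hydrogen assignment and every bond matrix with
exact row sums outright, filters connected graphs, and deduplicates with an
exhaustive canonical key (minimum of the flattened upper triangle over all
colour-class-preserving permutations, colours = element plus hydrogen
count).  It shares nothing with the orderly machinery except the formula
parser.  The suite pins:

* generator count = oracle count on a fixed panel of 35 formulae with ≤ 6
  heavy atoms, and key-set equality on representatives;
* block-test verdict = naive `A ≥ Aπ` enumeration on random matrices and
  random partitions;
* canonical keys = networkx coloured-multigraph isomorphism on random pairs;
* connectivity fixpoint = breadth-first reachability on random graphs;
* learning on/off count equality, determinism, valence-swap parity
  (N↔P, O↔S, halogen↔halogen leave degree sequences unchanged);
* SDF records reparse (RDKit) to the input formula as single fragments.

Problem sizes in the default suite stay at desk scale (≤ 6 heavy atoms for
oracle-backed checks, plus the full C10H16O = 452,458 run); larger spaces
from the multi-million-isomer regime are reachable through the CLI but are
not part of the default suite.

## Known limitations

* Lowest valences only; no user-defined valence table.
* The oracle is deliberately naive and refuses > 7 heavy atoms.
* Automorphism lists are kept exact (no group-structure compression); for
  highly symmetric degree states with large identical blocks the lists can
  grow, which costs time, not correctness.
* SDF output writes V2000 molfiles with zeroed coordinates and no property
  fields; SMILES output requires the optional rdkit dependency.
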