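# Methods

## The packing model

`ksdesign` treats a protein–protein interface as a set of knob-socket
motifs. A *socket* is a triangle of three mutually contacting residues,
written `XY:H`, where X and Y are the pair closest in sequence (X before
Y) and H is the remaining residue. A *knob* B is a fourth residue, from a
different chain or secondary-structure element, that contacts all three —
so a filled knob-socket motif is a 4-clique in the residue contact graph.
Mapping every filled socket on a target molecule whose knob comes from the
binding partner yields a discrete, residue-level description of the
epitope: which surface triangles are engaged and by what. Peptide design
then reduces to (a) choosing an amino acid per engaged socket and (b)
connecting the chosen knobs into one linear chain.

## Pipeline stages and their parameters

**Structure model.** PDB text is parsed with gemmi; the package keeps the
first model only, heavy atoms only, and one conformer per atom (highest
occupancy; ties go to the lexicographically first altloc id). Waters and
HETATM ligands are dropped; selenomethionine is retained and mapped to M
by default (`mse_to_met=False` gives X). Crystal structures carry no
reliable hydrogens, so contact geometry is heavy-atom only throughout.
Residues are identified externally by (chain, author number, insertion
code) and internally by a 0-based chain index.

**Secondary structure.** A self-contained 3-state assignment from
backbone dihedrals, with pinned windows: helix requires
φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°] over ≥ 4 consecutive residues;
strand requires φ ∈ [−170°, −50°] and ψ ∈ [80°, 180°] ∪ [−180°, −170°]
over ≥ 3; everything else — including termini, which lack one dihedral —
is coil. The windows comfortably contain the ideal helix (−57°, −47°) and
extended strand (−120°, 130°) used by the fixture generators, and the
assignment depends only on internal coordinates (rigid-motion invariant,
verified by test). No DSSP dependency, no hydrogen-bond geometry: for
packing-clique classification the coarse 3-state labels are sufficient.

**Contacts.** Two atoms are in contact when they are Delaunay neighbours
of the atom set (equivalently, their Voronoi cells share a facet) *and*
within a distance cap, default 6.0 Å. Raw Voronoi adjacency connects
arbitrarily distant surface atoms through unbounded cells; the cap is the
simplest defensible correction and is exposed as
`contact.cap_angstrom`. No bounding-box ghost points are added. Positions
receive a deterministic jitter of at most 1e−9 Å (seed 0) so exactly
co-spherical inputs resolve reproducibly. Inputs with fewer than five
atoms or degenerate geometry cannot define a 3-D tessellation; the
explicit `brute_force` mode (all pairs within the cap) covers them. A
residue–residue edge needs ≥ 1 supporting atomic contact (configurable);
sequence-adjacent pairs are kept but flagged `bonded`.

**Cliques and sockets.** All 3- and 4-vertex complete subgraphs are
enumerated (networkx `enumerate_all_cliques`, truncated at size 4);
cliques that are a single contiguous backbone run (i, i+1, i+2[, i+3])
are discarded as trivially forced by bonding. Socket classification uses
the contact-order signature — the sorted sequence separations among the
three residues, with `x` marking cross-chain pairs: *helix* when all
three residues are helix-labelled, in one element, with separations
within {1, 2, 3, 4}; *sheet* when all are strand-labelled and span at
least two strand elements; otherwise *coil/mixed*. The signature is kept
verbatim in every output so users can re-bin under a different
convention. Two residues are in the same secondary-structure element when
they share a chain and no coil-labelled residue lies strictly between
them; a knob must come from a different element or chain than all three
socket residues, which blocks intra-helix false knobs. 4-cliques with
several plausible knobs produce one pair per knob, flagged `ambiguous`,
rather than a silent choice. X/Y role assignment takes the
smallest-separation pair (ties: lower sequence index), cross-chain pairs
ranking last.

**Interface restriction.** `interface_filter(target_group,
partner_group)` keeps pairs whose socket residues all lie in the target
chain group and whose knob lies in the partner group; the two directions
of a complex partition the cross-group pairs exactly (tested). Free
sockets survive only when entirely on the target and sharing a residue
with a kept filled socket — they are the substitutable margin of the
epitope. Chain-group selection is an explicit user input because reduced
crystallographic assemblies differ between depositions.

**Propensities.** Training counts every filled socket (intra- and
inter-chain) over a corpus, keyed by the ordered composition (X, Y, H)
plus ss_class — ordered roles preserve the XY:H geometry distinction.
Probabilities use additive smoothing (pseudocount 1.0 by default) over
the 20-letter knob alphabet, and the propensity is
`log2(P(knob | socket) / P(knob))` with the marginal taken over all
sockets; positive means enriched. Queries fall back from the exact key to
(composition, any ss_class), then the unordered composition, then the
global marginal, and report the level used. At the marginal level the
log-odds against the marginal itself would be identically zero, so that
level scores enrichment over the uniform background instead, which
reproduces the marginal frequency ordering. Tables serialize to TSV
(`socket_X socket_Y socket_H ss_class knob_aa count propensity`), so an
externally published propensity table can be dropped in unchanged.

**Design.** Each interface socket becomes a knob site anchored at the
native knob's Cα (socket-Cα centroid for free sockets, which are only
targeted with `include_free`). Sites are ordered by the shortest open
path through the anchors — exact enumeration up to 9 sites, nearest
neighbour from the most peripheral anchor beyond that, canonicalised to
start at the lower author number. Consecutive anchors d Å apart get
`max(0, round_half_up(d / 3.8) − 1)` bridging residues; 3.8 Å is the
average Cα–Cα virtual bond of a random coil, and round-half-up is stated
because round-half-even would change d = 5.7 Å. Bridges default to
glycine (maximally coil-compatible; configurable, e.g. Gly/Pro mixtures).
The Cartesian product of the top-k candidates per site is scored by
summed propensity and truncated to `max_designs` (ties: lexicographic
sequence). Controls: `reverse_control` is exact string reversal;
`scramble_control` draws seeded uniform permutations until the result
differs from both the input and its reverse, preserving composition and
failing loudly on homopolymers.

## Synthetic fixtures

The generators build ideal fragments from canonical bond geometry by
natural-extension (NeRF) placement: helix (φ = −57°, ψ = −47°, ω = 180°;
measured rise 1.50 Å/residue, Cα–Cα 3.80 Å), extended strand
(φ = −120°, ψ = 130°), and a two-chain toy complex that packs one or two
single-residue knobs against `(i, i+1, i+4)` faces of a helix. Knob
placement (radial offset 2.2 Å from the socket's Cβ centroid, nudged
1.5 Å toward the C-terminus) was chosen so the knob contacts exactly the
three socket residues — without the axial nudge it also touches the i−3
neighbour one turn back, creating a second triangle. The builder re-runs
the whole contact/clique pipeline on every generated complex and raises
unless the recovered interface equals the construction, so fixture ground
truth is verified rather than asserted. The packaged training corpus is
twelve such complexes with varied socket sequences; it is purely
geometric and non-biological. Passing tests on these fixtures
demonstrates the machinery (geometry, enumeration, bookkeeping,
determinism), not the biological validity of any propensity value — real
design work needs a real corpus or a published table.

Note on helix Cα distances: in this canonical geometry d(i, i+3) ≈ 5.2 Å
< d(i, i+2) ≈ 5.5 Å < d(i, i+4) ≈ 6.4 Å; the periodicity test pins
d(i, i+3) < d(i, i+2).

## Numerical and scale choices

Verification problem sizes: the geometry oracle uses 100 random clouds of
8–50 atoms against an O(n⁴) vectorised empty-circumsphere check; the
clique oracle uses 100 random graphs of 5–20 nodes against exhaustive
subset enumeration. Both finish in seconds and are exact set
comparisons. Exact path enumeration in site ordering is capped at 9 sites
(≤ 9!/2 paths); candidate products are capped at 10⁶ combinations with a
clear error. All randomness (jitter, scrambles, oracle clouds) is seeded;
two pipeline runs with the same config and seed are byte-identical,
which the acceptance script re-measures.

## Known limitations

- The distance cap, support threshold and dihedral windows are sensible
  defaults, not fitted values; published knob-socket statistics may bin
  sockets differently (e.g. facet-area weighting, strict i/i+1 XY
  adjacency), which is why signatures are exported verbatim.
- No docking, binding-energy estimation or pose prediction: propensity
  score ranks candidates, it does not predict affinity.
- No structure repair, protonation, D-amino acids or cyclization.
- The sheet classification requires strand labels from the dihedral
  windows; irregular β-bulges may land in coil/mixed.
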