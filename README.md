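# ksdesign

Rational design of linear peptides that mimic how one protein packs
against another, using the knob-socket model of protein packing.

Antibodies bind their antigens through a modest number of side-chain
packing interactions: single residues ("knobs", B) from the antibody
insert into triangles of three mutually contacting residues ("sockets",
written XY:H) on the antigen surface. Given a two-molecule co-crystal
structure — the worked case in the field is a Fab–receptor complex such as
Cetuximab bound to EGFR — `ksdesign`:

1. parses the structure and assigns 3-state secondary structure from
   backbone dihedrals;
2. computes atomic contacts as Voronoi-facet neighbours (equivalently,
   Delaunay-tessellation edges) within a distance cap, and lifts them to a
   residue contact graph;
3. enumerates 3- and 4-residue packing cliques of that graph and
   classifies them by contact order into helix / sheet / coil-mixed
   sockets, identifying filled sockets where a knob from a different chain
   or secondary-structure element packs into the triangle;
4. restricts knobs and sockets to the binding interface (knobs from the
   partner chain group projected onto sockets of the target group) and
   emits a 2-D topology map of the epitope socket surface;
5. ranks candidate knob amino acids per socket by packing propensity —
   `log2(P(knob | socket) / P(knob))`, trained by counting filled cliques
   over any structure corpus — and assembles linear peptides by walking
   the shortest path through the knob anchor points, inserting one
   bridging residue per 3.8 Å of Cα–Cα gap beyond the first (random-coil
   assumption);
6. generates scrambled and reversed control sequences with the same
   composition, the standard specificity controls for such peptides.

## Worked example

The package ships generators for synthetic structures with hand-verifiable
ground truth. A toy complex places a tryptophan knob (chain B) against the
`(i, i+1, i+4)` face of an ideal poly-Ala helix (chain A):

```sh
$ ksdesign fixtures --kind toy_complex --out toy.pdb
wrote toy_complex (13 residues) to toy.pdb

$ ksdesign sockets --pdb toy.pdb --target A --partner B --out map.tsv
```

The filled row of the topology map names the socket `AA:A` at residues
4/5/8 of the helix, in helix contact order, occupied by the chain-B Trp
knob:

```
socket chain  res_x  res_y  res_h ss_class status knob_aa knob_chain
  AA:A     A      4      5      8    helix filled       W          B
```

Running the full pipeline on a two-knob variant designs peptides that
carry one chosen knob per interface socket, bridged across the measured
13.8 Å anchor gap by three glycines (`round(13.8/3.8) − 1 = 3`):

```sh
$ ksdesign run --config config.json --outdir out
$ head -4 out/designs.fasta
>design01 score=0.9529 sites=AA:A=C,AA:A=C
CGGGC
>design02 score=0.9529 sites=AA:A=C,AA:A=D
CGGGD
```

Each FASTA header records the summed knob propensity (in bits) and the
socket→knob provenance of every position; `out/designs.tsv` adds lengths,
bridge geometry and the propensity-fallback level used per site, and
`out/controls.tsv` holds the scrambled and reversed controls of the top
design. Candidate ranking here comes from the packaged synthetic fixture
table, which is deliberately non-biological — for real design work train
on a structure corpus (`ksdesign propensity --pdb ...`) or load a
published table (`--propensity table.tsv`).

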