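"""Atomic contacts from Voronoi/Delaunay geometry, lifted to residues.

Two heavy atoms are in contact when their Voronoi cells share a facet —
equivalently, when they are neighbours in the Delaunay tessellation of the
atom positions — and they lie within a distance cap.  The cap (default
6.0 Å) removes the spurious long edges that unbounded surface cells would
otherwise contribute.  Residue-residue contacts aggregate the atomic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .structure import Residue, Structure

DEFAULT_CAP = 6.0
JITTER_SCALE = 1e-9  # Å; deterministic tie-break for co-spherical inputs
JITTER_SEED = 0


class ContactError(ValueError):
    """Raised when the Voronoi tessellation is not well defined."""


@dataclass(frozen=True)
class ResidueRef:
    """Hashable residue identity carried on contacts and graph nodes."""

    chain_id: str
    number: int
    icode: str
    seq_index: int
    aa: str
    ss: str

    @classmethod
    def of(cls, r: Residue) -> "ResidueRef":
        return cls(r.chain_id, r.number, r.icode, r.seq_index, r.aa, r.ss)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def __str__(self) -> str:
        return f"{self.aa}{self.chain_id}{self.number}{self.icode}"


@dataclass(frozen=True)
class AtomicContact:
    """Unordered atom pair in Voronoi contact, with residue provenance."""

    res_a: ResidueRef
    atom_a: str
    res_b: ResidueRef
    atom_b: str
    distance: float


@dataclass
class ContactGraph:
    """Residue contact graph.  Nodes are ResidueRef; each edge records its
    supporting atomic-contact count and whether the pair is a bonded
    (sequence-adjacent, same-chain) pair."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def to_records(self) -> list[dict]:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b), key=lambda r: (r.chain_id, r.seq_index))
            rows.append({
                "chain_a": a.chain_id, "resnum_a": a.number, "aa_a": a.aa,
                "chain_b": b.chain_id, "resnum_b": b.number, "aa_b": b.aa,
                "support": data["support"], "bonded": data["bonded"],
            })
        rows.sort(key=lambda r: (r["chain_a"], r["resnum_a"], r["chain_b"], r["resnum_b"]))
        return rows


def _gather_atoms(structure: Structure):
    refs: list[ResidueRef] = []
    atom_res: list[int] = []
    atom_names: list[str] = []
    coords: list[np.ndarray] = []
    for chain in structure.chains.values():
        for r in chain:
            ref = ResidueRef.of(r)
            idx = len(refs)
            refs.append(ref)
            for a in r.atoms:
                atom_res.append(idx)
                atom_names.append(a.name)
                coords.append(a.coords)
    return refs, np.array(atom_res), atom_names, np.asarray(coords, dtype=float)


def delaunay_adjacency(coords: np.ndarray) -> set[tuple[int, int]]:
    """Index pairs that are Delaunay neighbours (share a Voronoi facet).

    Positions get a deterministic jitter of at most 1e-9 Å (seed 0) so that
    exactly co-spherical inputs resolve reproducibly.
    """
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(JITTER_SEED)
    jitter = rng.uniform(-JITTER_SCALE, JITTER_SCALE, size=coords.shape)
    try:
        tri = Delaunay(coords + jitter)
    except QhullError as exc:
        raise ContactError(
            "Delaunay tessellation failed (degenerate/coplanar positions); "
            "use mode='brute_force' for an all-pairs distance fallback"
        ) from exc
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i in range(len(simplex)):
            for j in range(i + 1, len(simplex)):
                a, b = int(simplex[i]), int(simplex[j])
                pairs.add((min(a, b), max(a, b)))
    return pairs


def atomic_contacts(structure: Structure, cap: float = DEFAULT_CAP,
                    mode: str = "voronoi") -> list[AtomicContact]:
    """Compute atomic contacts for all heavy atoms of a structure.

    mode='voronoi' requires >=5 non-degenerate positions; 'brute_force'
    takes every pair within the cap and is the documented fallback for
    tiny or degenerate inputs.
    """
    if cap <= 0:
        raise ValueError("distance cap must be positive")
    refs, atom_res, atom_names, coords = _gather_atoms(structure)
    n = len(coords)
    if mode == "voronoi":
        if n < 5:
            raise ContactError(
                f"only {n} atoms; Voronoi contacts need >=5 non-degenerate "
                "positions — use mode='brute_force'"
            )
        pairs = delaunay_adjacency(coords)
    elif mode == "brute_force":
        pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        raise ValueError(f"unknown contact mode {mode!r}")

    contacts = []
    for i, j in sorted(pairs):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if 0.0 < d <= cap:
            contacts.append(AtomicContact(
                res_a=refs[atom_res[i]], atom_a=atom_names[i],
                res_b=refs[atom_res[j]], atom_b=atom_names[j],
                distance=d,
            ))
    return contacts


def residue_contact_graph(contacts: list[AtomicContact],
                          min_support: int = 1) -> ContactGraph:
    """Lift atomic contacts to a residue graph.

    An edge joins residues r != s when at least ``min_support`` atomic
    contacts connect them.  Sequence-adjacent same-chain pairs are kept but
    flagged ``bonded`` so downstream clique filters can discard cliques
    that are nothing but a backbone run.
    """
    g = nx.Graph()
    for c in contacts:
        g.add_node(c.res_a)
        g.add_node(c.res_b)
        if c.res_a == c.res_b:
            continue
        a, b = c.res_a, c.res_b
        if g.has_edge(a, b):
            g[a][b]["support"] += 1
        else:
            bonded = (a.chain_id == b.chain_id
                      and abs(a.seq_index - b.seq_index) == 1)
            g.add_edge(a, b, support=1, bonded=bonded)
    if min_support > 1:
        drop = [(a, b) for a, b, d in g.edges(data=True) if d["support"] < min_support]
        g.remove_edges_from(drop)
    return ContactGraph(graph=g)
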