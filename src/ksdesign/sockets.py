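"""Knob-socket motif identification on a residue contact graph.

A socket is a triangle of mutually contacting residues, written XY:H where
X and Y are the closest pair in sequence.  A knob-socket pair is a
four-residue clique where one residue (the knob, B) comes from a different
chain or secondary-structure element and packs into the socket formed by
the other three.  Restricting knobs to one chain group and sockets to the
other maps a binding interface, e.g. antibody paratope knobs projected
onto antigen epitope sockets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .contacts import ContactGraph, ResidueRef
from .structure import Structure

#: sequence separations allowed inside a single-helix socket
HELIX_SEPARATIONS = {1, 2, 3, 4}


@dataclass(frozen=True)
class Socket:
    """Three mutually contacting residues; X, Y are the closest pair."""

    x: ResidueRef
    y: ResidueRef
    h: ResidueRef
    ss_class: str  # helix | sheet | coil/mixed
    signature: tuple  # sorted separations; "x" marks cross-chain pairs
    filled: bool = False

    @property
    def residues(self) -> tuple[ResidueRef, ResidueRef, ResidueRef]:
        return (self.x, self.y, self.h)

    @property
    def residue_set(self) -> frozenset:
        return frozenset(self.residues)

    @property
    def label(self) -> str:
        return f"{self.x.aa}{self.y.aa}:{self.h.aa}"

    @property
    def composition(self) -> tuple[str, str, str]:
        return (self.x.aa, self.y.aa, self.h.aa)

    def describe(self) -> str:
        return (f"{self.label} [{self.x.chain_id}{self.x.number}"
                f",{self.y.chain_id}{self.y.number},{self.h.chain_id}{self.h.number}]")


@dataclass(frozen=True)
class KnobSocketPair:
    """A filled socket: knob residue B packing into socket XY:H."""

    socket: Socket
    knob: ResidueRef
    ambiguous: bool = False

    @property
    def label(self) -> str:
        return f"{self.socket.label}<-{self.knob.aa}"


@dataclass
class InterfaceMap:
    """Sockets on the target molecule with knobs from the partner."""

    target_group: frozenset
    partner_group: frozenset
    pairs: list[KnobSocketPair] = field(default_factory=list)
    free_sockets: list[Socket] = field(default_factory=list)

    @property
    def sockets(self) -> list[Socket]:
        return [p.socket for p in self.pairs] + list(self.free_sockets)

    def adjacency(self) -> dict[int, list[int]]:
        """Indices (into .sockets order) of sockets sharing >=1 residue."""
        socks = self.sockets
        adj: dict[int, list[int]] = {i: [] for i in range(len(socks))}
        for i, j in itertools.combinations(range(len(socks)), 2):
            if socks[i].residue_set & socks[j].residue_set:
                adj[i].append(j)
                adj[j].append(i)
        return adj


def _is_bonded_run(residues) -> bool:
    """True when the clique is a single contiguous backbone run i..i+k."""
    chains = {r.chain_id for r in residues}
    if len(chains) != 1:
        return False
    idx = sorted(r.seq_index for r in residues)
    return all(b - a == 1 for a, b in zip(idx, idx[1:]))


def enumerate_packing_cliques(graph: ContactGraph):
    """All 3- and 4-vertex complete subgraphs of the contact graph,
    excluding cliques that are nothing but one contiguous bonded run."""
    cliques3: list[frozenset] = []
    cliques4: list[frozenset] = []
    for clique in nx.enumerate_all_cliques(graph.graph):
        if len(clique) == 3:
            if not _is_bonded_run(clique):
                cliques3.append(frozenset(clique))
        elif len(clique) == 4:
            if not _is_bonded_run(clique):
                cliques4.append(frozenset(clique))
        elif len(clique) > 4:
            break  # enumerate_all_cliques yields by increasing size
    # non-maximal 3-subsets of larger cliques are produced by
    # enumerate_all_cliques already; dedupe defensively
    return sorted(set(cliques3), key=_clique_sort_key), sorted(set(cliques4), key=_clique_sort_key)


def _clique_sort_key(clique: frozenset):
    return tuple(sorted((r.chain_id, r.seq_index) for r in clique))


def _separation(a: ResidueRef, b: ResidueRef):
    if a.chain_id != b.chain_id:
        return "x"
    return abs(a.seq_index - b.seq_index)


def same_element(a: ResidueRef, b: ResidueRef, structure: Structure) -> bool:
    """Same secondary-structure element: same chain and no coil-labelled
    residue strictly between the two positions."""
    if a.chain_id != b.chain_id:
        return False
    chain = structure.chains[a.chain_id]
    lo, hi = sorted((a.seq_index, b.seq_index))
    return not any(chain[i].ss == "C" for i in range(lo + 1, hi))


def classify_socket(clique, structure: Structure, filled: bool = False) -> Socket:
    """Assign XY:H roles and a contact-order class to a residue triangle.

    X, Y are the pair with the smallest sequence separation (cross-chain
    pairs rank last; ties go to the lower seq_index pair), with X before Y.
    The class is helix when all three residues sit in one helix with
    separations within {1,2,3,4}; sheet when all are strand residues
    spanning at least two strand elements; otherwise coil/mixed.
    """
    residues = sorted(clique, key=lambda r: (r.chain_id, r.seq_index))
    pairs = list(itertools.combinations(residues, 2))

    def pair_rank(pair):
        sep = _separation(*pair)
        sep_val = float("inf") if sep == "x" else sep
        return (sep_val, pair[0].chain_id, pair[0].seq_index, pair[1].seq_index)

    x, y = min(pairs, key=pair_rank)
    (h,) = [r for r in residues if r not in (x, y)]

    seps = tuple(sorted((_separation(a, b) for a, b in pairs),
                        key=lambda s: (isinstance(s, str), s)))

    ss_set = {r.ss for r in residues}
    one_chain = len({r.chain_id for r in residues}) == 1
    ss_class = "coil/mixed"
    if ss_set == {"H"} and one_chain and all(
            same_element(a, b, structure) for a, b in pairs):
        if all(isinstance(s, int) and s in HELIX_SEPARATIONS for s in seps):
            ss_class = "helix"
    elif ss_set == {"E"}:
        n_elements = _count_strand_elements(residues, structure)
        if n_elements >= 2:
            ss_class = "sheet"
    return Socket(x=x, y=y, h=h, ss_class=ss_class, signature=seps, filled=filled)


def _count_strand_elements(residues, structure: Structure) -> int:
    groups = []
    for r in residues:
        placed = False
        for g in groups:
            if any(same_element(r, s, structure) for s in g):
                g.append(r)
                placed = True
                break
        if not placed:
            groups.append([r])
    return len(groups)


def _different_element(a: ResidueRef, b: ResidueRef, structure: Structure) -> bool:
    return not same_element(a, b, structure)


def identify_knob_sockets(cliques3, cliques4, structure: Structure):
    """Split packing cliques into filled knob-socket pairs and free sockets.

    In a 4-clique, a residue is a plausible knob when it comes from a
    different chain or secondary-structure element than each of the other
    three.  Exactly one plausible knob gives a filled socket; several give
    one pair per knob, flagged ambiguous.  3-cliques that underlie no
    filled pair are free sockets.
    """
    pairs: list[KnobSocketPair] = []
    filled_triangles: set[frozenset] = set()
    for clique in cliques4:
        residues = list(clique)
        knobs = [
            r for r in residues
            if all(_different_element(r, s, structure) for s in residues if s is not r)
        ]
        for knob in knobs:
            triangle = frozenset(r for r in residues if r is not knob)
            if _is_bonded_run(triangle):
                continue
            socket = classify_socket(triangle, structure, filled=True)
            pairs.append(KnobSocketPair(socket=socket, knob=knob,
                                        ambiguous=len(knobs) > 1))
            filled_triangles.add(triangle)
    free = [
        classify_socket(c, structure, filled=False)
        for c in cliques3 if frozenset(c) not in filled_triangles
    ]
    pairs.sort(key=lambda p: (_clique_sort_key(p.socket.residue_set),
                              p.knob.chain_id, p.knob.seq_index))
    free.sort(key=lambda s: _clique_sort_key(s.residue_set))
    return pairs, free


def interface_filter(pairs, free_sockets, target_group, partner_group) -> InterfaceMap:
    """Restrict to the binding interface: socket residues all in the target
    chain group, knob in the partner group.  Free sockets are kept when
    entirely on the target and adjacent to a kept filled socket."""
    target = frozenset(target_group)
    partner = frozenset(partner_group)
    if not target or not partner:
        raise ValueError("chain groups must be non-empty")
    if target & partner:
        raise ValueError(f"chain groups overlap: {sorted(target & partner)}")

    kept_pairs = [
        p for p in pairs
        if all(r.chain_id in target for r in p.socket.residues)
        and p.knob.chain_id in partner
    ]
    kept_residues = set()
    for p in kept_pairs:
        kept_residues |= p.socket.residue_set
    kept_free = [
        s for s in free_sockets
        if all(r.chain_id in target for r in s.residues)
        and (s.residue_set & kept_residues)
    ]
    return InterfaceMap(target_group=target, partner_group=partner,
                        pairs=kept_pairs, free_sockets=kept_free)


def topology_map(interface: InterfaceMap) -> pd.DataFrame:
    """Tabular 2-D topology map: one row per interface socket with its
    XY:H label, author numbering, fill state, knob provenance and the
    labels of adjacent sockets (sharing >=1 residue)."""
    if not interface.pairs and not interface.free_sockets:
        raise ValueError("interface map is empty")
    socks = interface.sockets
    knob_for = {id(p.socket): p for p in interface.pairs}
    adj = interface.adjacency()
    rows = []
    for i, s in enumerate(socks):
        pair = knob_for.get(id(s))
        rows.append({
            "socket": s.label,
            "chain": s.x.chain_id,
            "res_x": s.x.number, "res_y": s.y.number, "res_h": s.h.number,
            "ss_class": s.ss_class,
            "signature": ",".join(str(v) for v in s.signature),
            "status": "filled" if pair else "free",
            "knob_aa": pair.knob.aa if pair else "",
            "knob_chain": pair.knob.chain_id if pair else "",
            "knob_resnum": pair.knob.number if pair else "",
            "ambiguous": bool(pair.ambiguous) if pair else False,
            "adjacent": ";".join(socks[j].describe() for j in adj[i]),
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["chain", "res_x", "res_y", "res_h", "socket"],
                        kind="mergesort").reset_index(drop=True)
    return df
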