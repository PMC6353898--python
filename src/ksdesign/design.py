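"""Peptide-mimetic design from an interface map and a propensity table.

Each interface socket becomes a knob site anchored at the Cα of its native
knob (or the socket Cα centroid for free sockets).  Sites are ordered along
the shortest path through their anchors, consecutive gaps are bridged with
coil-compatible residues assuming a 3.8 Å Cα–Cα spacing, and the top
propensity-ranked knob candidates per site are combined into ranked linear
peptide sequences, plus scrambled and reversed controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .propensity import PropensityTable
from .sockets import InterfaceMap, KnobSocketPair, Socket
from .structure import Structure

CA_SPACING = 3.8  # Å, average Cα-Cα distance in a random coil


@dataclass
class KnobSite:
    """A designable position: a target socket plus its anchor point."""

    socket: Socket
    anchor_point: np.ndarray
    native_knob_aa: str | None
    candidates: list[tuple[str, float]]  # (aa, propensity), ranked

    def __post_init__(self) -> None:
        self.anchor_point = np.asarray(self.anchor_point, dtype=float)
        if self.anchor_point.shape != (3,) or not np.all(np.isfinite(self.anchor_point)):
            raise ValueError("anchor point must be a finite 3-vector")
        if not self.candidates:
            raise ValueError("knob site has no candidate amino acids")

    @property
    def sort_key(self):
        s = self.socket
        return (s.x.chain_id, s.x.number, s.y.number, s.h.number)


@dataclass
class PeptideDesign:
    """One designed peptide with provenance and propensity score."""

    site_sockets: list[str]  # socket labels in peptide order
    chosen_knobs: list[str]
    bridges: list[tuple[float, int, str]]  # (gap Å, length, bridge aa string)
    sequence: str
    score: float
    fallbacks: list[str] = field(default_factory=list)

    def fasta_header(self, design_id: str) -> str:
        prov = ",".join(f"{s}={k}" for s, k in zip(self.site_sockets, self.chosen_knobs))
        return f">{design_id} score={self.score:.4f} sites={prov}"


def make_knob_sites(interface: InterfaceMap, structure: Structure,
                    table: PropensityTable, k_candidates: int = 5,
                    include_free: bool = False) -> list[KnobSite]:
    """Build knob sites from an interface map.  Filled sockets anchor at
    the native knob Cα; free sockets (optional) at the socket Cα centroid."""
    ca_by_key = {r.key: (r.ca.coords if r.ca else None)
                 for r in structure.residues()}
    sites: list[KnobSite] = []
    for pair in interface.pairs:
        anchor = ca_by_key.get(pair.knob.key)
        if anchor is None:
            anchor = _socket_centroid(pair.socket, ca_by_key)
        sites.append(_site_for(pair.socket, anchor, pair, table, k_candidates))
    if include_free:
        for socket in interface.free_sockets:
            anchor = _socket_centroid(socket, ca_by_key)
            sites.append(_site_for(socket, anchor, None, table, k_candidates))
    return sites


def _socket_centroid(socket: Socket, ca_by_key) -> np.ndarray:
    cas = [ca_by_key[r.key] for r in socket.residues if ca_by_key.get(r.key) is not None]
    if not cas:
        raise ValueError(f"socket {socket.label} has no Cα coordinates")
    return np.mean(cas, axis=0)


def _site_for(socket: Socket, anchor, pair: KnobSocketPair | None,
              table: PropensityTable, k: int) -> KnobSite:
    ranking, level = table.top_knobs(socket.composition, socket.ss_class, k=k)
    site = KnobSite(
        socket=socket,
        anchor_point=anchor,
        native_knob_aa=pair.knob.aa if pair else None,
        candidates=ranking,
    )
    site.fallback_level = level  # recorded for provenance output
    return site


# ---------------------------------------------------------------------------
# ordering and linking

EXACT_ENUMERATION_LIMIT = 9


def order_knob_sites(sites: list[KnobSite]) -> list[KnobSite]:
    """Order sites to minimise total consecutive anchor distance.

    Exact path enumeration up to 9 sites; nearest-neighbour from the most
    peripheral anchor beyond that.  The optimal open path is canonicalised
    to start at the endpoint with the lower author residue number (then
    chain id) so equal-length reversals resolve deterministically.
    """
    if len(sites) <= 1:
        return list(sites)
    anchors = np.array([s.anchor_point for s in sites])
    dist = np.linalg.norm(anchors[:, None, :] - anchors[None, :, :], axis=-1)
    n = len(sites)
    if n <= EXACT_ENUMERATION_LIMIT:
        best_len = np.inf
        best_orders: list[tuple[int, ...]] = []
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:
                continue  # a path and its reverse have equal length
            length = sum(dist[perm[i], perm[i + 1]] for i in range(n - 1))
            if length < best_len - 1e-12:
                best_len = length
                best_orders = [perm]
            elif abs(length - best_len) <= 1e-12:
                best_orders.append(perm)
        order = min(best_orders,
                    key=lambda p: tuple(sites[i].sort_key for i in p))
    else:
        centroid = anchors.mean(axis=0)
        start = int(np.argmax(np.linalg.norm(anchors - centroid, axis=1)))
        order = [start]
        remaining = set(range(n)) - {start}
        while remaining:
            cur = order[-1]
            nxt = min(remaining, key=lambda j: (dist[cur, j], sites[j].sort_key))
            order.append(nxt)
            remaining.remove(nxt)
        order = tuple(order)
    ordered = [sites[i] for i in order]
    if ordered[-1].sort_key < ordered[0].sort_key:
        ordered.reverse()
    return ordered


def bridge_length(d: float) -> int:
    """Number of bridging residues spanning a Cα–Cα gap of d Å, assuming
    3.8 Å per residue in a random coil: max(0, round_half_up(d/3.8) - 1)."""
    if d < 0:
        raise ValueError("gap distance must be non-negative")
    import math
    return max(0, math.floor(d / CA_SPACING + 0.5) - 1)


MAX_COMBINATIONS = 1_000_000


def assemble_peptides(ordered_sites: list[KnobSite], table: PropensityTable | None = None,
                      k_per_site: int = 3, bridge_aa: str = "G",
                      max_designs: int = 24) -> list[PeptideDesign]:
    """Combine top-k knob candidates per site into ranked peptides.

    The full Cartesian product of candidates is scored by summed knob
    propensity and truncated to ``max_designs`` (ties broken by sequence).
    Gaps between consecutive anchors are filled with ``bridge_aa``.
    """
    if not ordered_sites:
        raise ValueError("no knob sites to assemble")
    if not 1 <= k_per_site <= 20:
        raise ValueError("k_per_site must be in [1, 20]")
    if max_designs < 1:
        raise ValueError("max_designs must be >= 1")
    per_site = [s.candidates[:k_per_site] for s in ordered_sites]
    n_combo = 1
    for c in per_site:
        n_combo *= len(c)
    if n_combo > MAX_COMBINATIONS:
        raise ValueError(
            f"{n_combo} candidate combinations exceed the enumeration limit; "
            "reduce k_per_site or the number of sites"
        )

    bridges: list[tuple[float, int, str]] = []
    for a, b in zip(ordered_sites, ordered_sites[1:]):
        gap = float(np.linalg.norm(a.anchor_point - b.anchor_point))
        blen = bridge_length(gap)
        bridges.append((gap, blen, bridge_aa * blen))

    labels = [s.socket.label for s in ordered_sites]
    fallbacks = [getattr(s, "fallback_level", "exact") for s in ordered_sites]
    designs = []
    for combo in itertools.product(*per_site):
        knobs = [aa for aa, _ in combo]
        score = float(sum(p for _, p in combo))
        parts = [knobs[0]]
        for (_, _, seg), aa in zip(bridges, knobs[1:]):
            parts.append(seg)
            parts.append(aa)
        designs.append(PeptideDesign(
            site_sockets=labels, chosen_knobs=knobs, bridges=bridges,
            sequence="".join(parts), score=score, fallbacks=fallbacks,
        ))
    designs.sort(key=lambda d: (-d.score, d.sequence))
    return designs[:max_designs]


# ---------------------------------------------------------------------------
# controls

MAX_SCRAMBLE_ATTEMPTS = 10_000


def scramble_control(sequence: str, seed: int = 0) -> str:
    """Uniform random permutation of the sequence, resampled until it
    differs from both the input and its reverse; composition is preserved.
    A fixed seed makes the control reproducible."""
    if len(sequence) < 2 or len(set(sequence)) < 2:
        raise ValueError("scramble needs length >= 2 with >= 2 distinct letters")
    rng = np.random.default_rng(seed)
    letters = list(sequence)
    for _ in range(MAX_SCRAMBLE_ATTEMPTS):
        perm = "".join(rng.permutation(letters))
        if perm != sequence and perm != sequence[::-1]:
            return perm
    raise ValueError(f"no scramble of {sequence!r} distinct from it and its reverse")


def reverse_control(sequence: str) -> str:
    """Exact string reversal (e.g. a reversed-sequence control peptide)."""
    if not sequence:
        raise ValueError("cannot reverse an empty sequence")
    return sequence[::-1]


# ---------------------------------------------------------------------------
# output

def designs_to_fasta(designs: list[PeptideDesign], prefix: str = "design") -> str:
    lines = []
    for i, d in enumerate(designs, start=1):
        lines.append(d.fasta_header(f"{prefix}{i:02d}"))
        lines.append(d.sequence)
    return "\n".join(lines) + "\n"


def designs_to_records(designs: list[PeptideDesign]) -> list[dict]:
    rows = []
    for i, d in enumerate(designs, start=1):
        rows.append({
            "design_id": f"design{i:02d}",
            "sequence": d.sequence,
            "length": len(d.sequence),
            "score": round(d.score, 6),
            "knobs": ",".join(d.chosen_knobs),
            "sockets": ",".join(d.site_sockets),
            "bridges": ",".join(f"{g:.2f}:{n}" for g, n, _ in d.bridges),
            "fallbacks": ",".join(d.fallbacks),
        })
    return rows
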