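"""Knob-socket packing propensities.

Counts how often each amino acid appears as the knob packing into a socket
of a given composition, over a training corpus of structures, and converts
the counts to log-odds: propensity = log2(P(knob|socket) / P(knob)), with
P(knob) the marginal over all sockets.  Positive values mean the knob is
enriched in that socket.  Queries fall back from the exact ordered
(X, Y, H, ss_class) key to coarser keys so a ranking is always available.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

#: socket key: (X, Y, H, ss_class)
SocketKey = tuple[str, str, str, str]

FALLBACK_EXACT = "exact"
FALLBACK_ANY_SS = "any_ss"
FALLBACK_COMPOSITION = "composition"
FALLBACK_MARGINAL = "marginal"


@dataclass
class PropensityTable:
    counts: dict[SocketKey, dict[str, int]]
    pseudocount: float = 1.0
    training_meta: dict = field(default_factory=dict)
    propensity: dict[SocketKey, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not self.propensity:
            self._compute()

    # -- probabilities -----------------------------------------------------
    def _marginal_counts(self) -> dict[str, float]:
        tot: dict[str, float] = defaultdict(float)
        for knobs in self.counts.values():
            for aa, c in knobs.items():
                tot[aa] += c
        return tot

    def marginal(self) -> dict[str, float]:
        """Smoothed marginal knob distribution P(knob) over all sockets."""
        return _smooth(self._marginal_counts(), self.pseudocount)

    def conditional(self, key: SocketKey) -> dict[str, float]:
        """Smoothed P(knob | socket key); sums to 1 over the 20 aa."""
        return _smooth(self.counts.get(key, {}), self.pseudocount)

    def _compute(self) -> None:
        from math import log2
        marg = self.marginal()
        self.propensity = {}
        for key in self.counts:
            cond = self.conditional(key)
            self.propensity[key] = {aa: log2(cond[aa] / marg[aa]) for aa in AA20}

    # -- queries -----------------------------------------------------------
    def top_knobs(self, socket: tuple[str, str, str], ss_class: str = "coil/mixed",
                  k: int = 5) -> tuple[list[tuple[str, float]], str]:
        """Top-k knob amino acids for a socket, descending propensity, ties
        broken alphabetically.  Returns (ranking, fallback_level); the
        fallback cascade is exact key -> any ss_class -> unordered
        composition -> global marginal."""
        if not 1 <= k <= 20:
            raise ValueError("k must be in [1, 20]")
        x, y, h = socket
        level, counts = self._lookup(x, y, h, ss_class)
        from math import log2
        marg = self.marginal()
        cond = _smooth(counts, self.pseudocount)
        if level == FALLBACK_MARGINAL:
            # scoring the marginal against itself is identically zero;
            # rank by enrichment over the uniform background instead so the
            # fallback reproduces the global marginal ordering
            scored = [(aa, log2(cond[aa] * 20.0)) for aa in AA20]
        else:
            scored = [(aa, log2(cond[aa] / marg[aa])) for aa in AA20]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored[:k], level

    def _lookup(self, x: str, y: str, h: str, ss_class: str):
        key = (x, y, h, ss_class)
        if key in self.counts:
            return FALLBACK_EXACT, self.counts[key]
        pooled: dict[str, int] = defaultdict(int)
        for (kx, ky, kh, _), knobs in self.counts.items():
            if (kx, ky, kh) == (x, y, h):
                for aa, c in knobs.items():
                    pooled[aa] += c
        if pooled:
            return FALLBACK_ANY_SS, dict(pooled)
        want = tuple(sorted((x, y, h)))
        pooled = defaultdict(int)
        for (kx, ky, kh, _), knobs in self.counts.items():
            if tuple(sorted((kx, ky, kh))) == want:
                for aa, c in knobs.items():
                    pooled[aa] += c
        if pooled:
            return FALLBACK_COMPOSITION, dict(pooled)
        return FALLBACK_MARGINAL, dict(self._marginal_counts())

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (x, y, h, ss), knobs in sorted(self.counts.items()):
            for aa in AA20:
                c = knobs.get(aa, 0)
                rows.append({
                    "socket_X": x, "socket_Y": y, "socket_H": h,
                    "ss_class": ss, "knob_aa": aa, "count": c,
                    "propensity": self.propensity[(x, y, h, ss)][aa],
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, pseudocount: float = 1.0) -> "PropensityTable":
        df = pd.read_csv(path, sep="\t")
        counts: dict[SocketKey, dict[str, int]] = {}
        for row in df.itertuples(index=False):
            key = (row.socket_X, row.socket_Y, row.socket_H, row.ss_class)
            if int(row.count) > 0:
                counts.setdefault(key, {})[row.knob_aa] = int(row.count)
            else:
                counts.setdefault(key, {})
        return cls(counts=counts, pseudocount=pseudocount,
                   training_meta={"source": str(path)})


def _smooth(counts: dict[str, float], pseudocount: float) -> dict[str, float]:
    total = sum(counts.get(aa, 0) for aa in AA20) + 20 * pseudocount
    return {aa: (counts.get(aa, 0) + pseudocount) / total for aa in AA20}


# ---------------------------------------------------------------------------
# training

def count_knob_sockets(structures, cap: float | None = None,
                       mode: str = "voronoi") -> dict[SocketKey, dict[str, int]]:
    """Count filled knob-socket cliques (intra- and inter-chain) over a
    corpus.  Structures that fail contact computation are skipped with a
    warning.  Counts are independent of corpus order."""
    from .contacts import DEFAULT_CAP, ContactError, atomic_contacts, residue_contact_graph
    from .sockets import enumerate_packing_cliques, identify_knob_sockets
    from .structure import assign_all_secondary_structure

    cap = DEFAULT_CAP if cap is None else cap
    counts: dict[SocketKey, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for st in structures:
        try:
            assign_all_secondary_structure(st)
            contacts = atomic_contacts(st, cap=cap, mode=mode)
            graph = residue_contact_graph(contacts)
            c3, c4 = enumerate_packing_cliques(graph)
            pairs, _ = identify_knob_sockets(c3, c4, st)
        except ContactError as exc:
            logger.warning("skipping structure %s: %s", st.source_id or "<unnamed>", exc)
            continue
        for p in pairs:
            key = (*p.socket.composition, p.socket.ss_class)
            counts[key][p.knob.aa] += 1
    return {k: dict(v) for k, v in sorted(counts.items())}


def build_table(counts, pseudocount: float = 1.0,
                training_meta: dict | None = None) -> PropensityTable:
    """Additive smoothing over the 20-letter knob alphabet per socket key,
    then log2 odds against the global knob marginal."""
    canonical = {k: dict(sorted(v.items())) for k, v in sorted(counts.items())}
    total = sum(c for knobs in canonical.values() for c in knobs.values())
    meta = dict(training_meta or {})
    meta.setdefault("n_cliques", total)
    return PropensityTable(counts=canonical, pseudocount=pseudocount,
                           training_meta=meta)


def top_knobs(table: PropensityTable, socket: tuple[str, str, str],
              ss_class: str = "coil/mixed", k: int = 5):
    """Module-level convenience wrapper over PropensityTable.top_knobs."""
    return table.top_knobs(socket, ss_class=ss_class, k=k)
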