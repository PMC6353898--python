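"""Synthetic test structures with known knob-socket ground truth.

Builds ideal secondary-structure fragments from canonical backbone
dihedrals and bond geometry, and small two-chain toy complexes whose
knob-socket assignment is verifiable by hand.  These emulate the geometry
of real folds (helical lattice, extended strands, a knob packing against a
helix face) without any biological sequence signal; they exist so the
pipeline can be tested end to end without structure downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import ONE_TO_THREE, Atom, Residue, Structure

# canonical backbone geometry (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4
TORSION_CB = -122.6  # C(i)-N(i)-CA(i)-CB(i): L-amino-acid branch

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 130.0
OMEGA = 180.0


class FixtureError(RuntimeError):
    """A generated fixture failed its own ground-truth self-check."""


@dataclass
class FixtureSpec:
    kind: str  # ideal_helix | ideal_strand | toy_complex
    n_residues: int = 15
    sequence: str | None = None
    phi: float | None = None
    psi: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("fixtures need at least 3 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O/CB coordinates for an ideal (phi, psi) repeat."""
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[i - 1]
        n_i = _extend(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _extend(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _extend(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(coords):
        psi_i = psi  # uniform repeat; also used for the final carbonyl
        res["O"] = _extend(res["N"], res["CA"], res["C"], BOND_C_O,
                           ANGLE_CA_C_O, psi_i + 180.0)
        res["CB"] = _extend(res["C"], res["N"], res["CA"], BOND_CA_CB,
                            ANGLE_N_CA_CB, TORSION_CB)
    return coords


def _make_residues(coords, sequence: str, chain_id: str,
                   first_number: int = 1, serial_start: int = 1) -> list[Residue]:
    residues = []
    serial = serial_start
    for i, (res_coords, aa) in enumerate(zip(coords, sequence)):
        atoms = []
        names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
        for name in names:
            atoms.append(Atom(
                serial=serial, name=name,
                element="N" if name == "N" else ("O" if name == "O" else "C"),
                coords=res_coords[name],
            ))
            serial += 1
        residues.append(Residue(
            chain_id=chain_id, number=first_number + i, icode="",
            seq_index=i, aa=aa, name3=ONE_TO_THREE.get(aa, "UNK"), atoms=atoms,
        ))
    return residues


def build_ideal_helix(spec: FixtureSpec | None = None, n_residues: int = 15,
                      sequence: str | None = None) -> Structure:
    """Ideal α-helix (φ=-57°, ψ=-47°, ω=180°), poly-Ala by default.

    The generated lattice has ~1.5 Å rise per residue and ~3.6 residues
    per turn, so consecutive Cα atoms sit 3.8 Å apart and the i/i+4 face
    contacts that form canonical helix sockets are present by construction.
    """
    if spec is not None:
        n_residues, sequence = spec.n_residues, spec.sequence
    seq = sequence or "A" * n_residues
    coords = _build_backbone(len(seq), HELIX_PHI, HELIX_PSI)
    chain = _make_residues(coords, seq, "A")
    return Structure(chains={"A": chain}, source_id="ideal_helix")


def build_ideal_strand(spec: FixtureSpec | None = None, n_residues: int = 10,
                       sequence: str | None = None) -> Structure:
    """Ideal extended β-strand (φ=-120°, ψ=130°), poly-Ala by default."""
    if spec is not None:
        n_residues, sequence = spec.n_residues, spec.sequence
    seq = sequence or "A" * n_residues
    coords = _build_backbone(len(seq), STRAND_PHI, STRAND_PSI)
    chain = _make_residues(coords, seq, "A")
    return Structure(chains={"A": chain}, source_id="ideal_strand")


# ---------------------------------------------------------------------------
# toy complex

@dataclass
class ToyComplexTruth:
    """Recomputable ground truth for a generated toy complex."""

    socket_numbers: list[tuple[int, int, int]]  # author numbers (X, Y, H) on chain A
    knob_numbers: list[int]  # author numbers of the chain-B knobs
    knob_chain: str = "B"
    target_chain: str = "A"
    params: dict = field(default_factory=dict)


@dataclass
class ToyComplex:
    structure: Structure
    truth: ToyComplexTruth


def _helix_axis(chain) -> tuple[np.ndarray, np.ndarray]:
    cas = np.array([r.ca.coords for r in chain])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    return centroid, vt[0]


def _place_knob_residue(chain_a, socket_idx: tuple[int, int, int],
                        offset: float, aa: str, number: int,
                        serial_start: int, axial_shift: float = 1.5) -> Residue:
    """Build a single knob residue whose Cβ points into the chosen socket.

    The anchor sits over the Cβ centroid of the socket triple, nudged
    ``axial_shift`` Å toward the C-terminus so the knob clears the i-3
    neighbour one turn back and touches exactly the three socket residues.
    """
    triple = [chain_a[i] for i in socket_idx]
    cb = [(r.atom("CB") or r.ca).coords for r in triple]
    centroid, axis = _helix_axis(chain_a)
    cas = np.array([r.ca.coords for r in chain_a])
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis  # orient toward the C-terminus
    center = np.mean(cb, axis=0) + axial_shift * axis
    radial = center - (centroid + np.dot(center - centroid, axis) * axis)
    e1 = radial / np.linalg.norm(radial)  # outward from the helix surface
    e2 = np.cross(axis, e1)
    e2 /= np.linalg.norm(e2)

    cb_b = center + offset * e1
    ca_b = cb_b + BOND_CA_CB * e1
    n_b = ca_b + BOND_N_CA * (0.55 * e1 + 0.835 * e2)
    c_b = ca_b + BOND_CA_C * (0.55 * e1 - 0.835 * e2)
    o_b = c_b + BOND_C_O * e1
    names = {"N": n_b, "CA": ca_b, "C": c_b, "O": o_b}
    if aa != "G":
        names["CB"] = cb_b
    atoms = []
    serial = serial_start
    for name, pos in names.items():
        atoms.append(Atom(serial=serial, name=name,
                          element="N" if name == "N" else ("O" if name == "O" else "C"),
                          coords=pos))
        serial += 1
    return Residue(chain_id="B", number=number, icode="", seq_index=0,
                   aa=aa, name3=ONE_TO_THREE.get(aa, "UNK"), atoms=atoms)


def build_toy_complex(n_helix: int = 12, socket_start: int = 3,
                      knob_aa: str = "W", offset: float = 2.2,
                      n_knobs: int = 1, second_socket_start: int = 7,
                      second_knob_aa: str = "F",
                      helix_sequence: str | None = None,
                      displacement: float = 0.0,
                      self_check: bool = True) -> ToyComplex:
    """Two-chain toy complex: chain A is an ideal helix, chain B holds one
    or two knob residues packed against chain-A (i, i+1, i+4) sockets.

    ``displacement`` shifts chain B radially outward (e.g. +20 Å removes
    all cross-chain contacts).  With ``self_check`` the generator reruns
    the contact/clique pipeline and errors out unless the recovered filled
    interface sockets are exactly the constructed ones.
    """
    if n_knobs not in (1, 2):
        raise ValueError("toy complex supports 1 or 2 knobs")
    helix = build_ideal_helix(n_residues=n_helix, sequence=helix_sequence)
    chain_a = helix.chains["A"]
    socket_specs = [(socket_start, knob_aa)]
    if n_knobs == 2:
        socket_specs.append((second_socket_start, second_knob_aa))
    chain_b: list[Residue] = []
    truth_sockets = []
    truth_knobs = []
    serial = sum(len(r.atoms) for r in chain_a) + 1
    for j, (start, aa) in enumerate(socket_specs):
        idx = (start, start + 1, start + 4)
        if idx[-1] >= n_helix:
            raise ValueError("socket start too close to the helix C-terminus")
        res = _place_knob_residue(chain_a, idx, offset, aa,
                                  number=1 + 4 * j, serial_start=serial)
        serial += len(res.atoms)
        if displacement:
            centroid, axis = _helix_axis(chain_a)
            for a in res.atoms:
                radial = a.coords - (centroid + np.dot(a.coords - centroid, axis) * axis)
                a.coords = a.coords + displacement * radial / np.linalg.norm(radial)
        res.seq_index = j
        chain_b.append(res)
        truth_sockets.append(tuple(chain_a[i].number for i in idx))
        truth_knobs.append(res.number)

    structure = Structure(chains={"A": chain_a, "B": chain_b},
                          source_id="toy_complex")
    truth = ToyComplexTruth(
        socket_numbers=truth_sockets, knob_numbers=truth_knobs,
        params={"n_helix": n_helix, "socket_start": socket_start,
                "offset": offset, "n_knobs": n_knobs,
                "displacement": displacement},
    )
    toy = ToyComplex(structure=structure, truth=truth)
    if self_check and not displacement:
        _self_check(toy)
    return toy


# (helix_sequence, knob_aa) pairs for the packaged synthetic training corpus
_FIXTURE_CORPUS = [
    ("AAAAAAAAAAAA", "W"), ("AAAAAAAAAAAA", "F"), ("AAAAAAAAAAAA", "Y"),
    ("AAALAAAQAAAA", "W"), ("AAALAAAQAAAA", "L"),
    ("AAAVSAASAAAA", "F"), ("AAAVSAASAAAA", "Y"),
    ("AAASIAAIAAAA", "I"), ("AAAGAAAPAAAA", "A"),
    ("AAAQAAAPAAAA", "A"), ("AAAQAAAPAAAA", "W"),
    ("AAALPAAQAAAA", "Q"),
]


def fixture_corpus() -> list[Structure]:
    """Synthetic training corpus: toy helix/knob complexes with varied
    socket sequences.  Purely geometric and non-biological — it exercises
    the counting machinery, it does not approximate real packing
    statistics."""
    corpus = []
    for i, (seq, knob) in enumerate(_FIXTURE_CORPUS):
        toy = build_toy_complex(helix_sequence=seq, knob_aa=knob)
        toy.structure.source_id = f"synthetic_{i:02d}"
        corpus.append(toy.structure)
    return corpus


def fixture_propensity_table(pseudocount: float = 1.0):
    """Propensity table trained on the packaged synthetic corpus.
    Clearly non-biological; intended for tests and worked examples."""
    from .propensity import build_table, count_knob_sockets
    counts = count_knob_sockets(fixture_corpus())
    return build_table(counts, pseudocount=pseudocount,
                       training_meta={"sources": "ksdesign synthetic fixture corpus"})


def _self_check(toy: ToyComplex) -> None:
    from .contacts import atomic_contacts, residue_contact_graph
    from .sockets import enumerate_packing_cliques, identify_knob_sockets, interface_filter
    from .structure import assign_all_secondary_structure

    st = toy.structure
    assign_all_secondary_structure(st)
    graph = residue_contact_graph(atomic_contacts(st))
    c3, c4 = enumerate_packing_cliques(graph)
    pairs, free = identify_knob_sockets(c3, c4, st)
    interface = interface_filter(pairs, free, {toy.truth.target_chain},
                                 {toy.truth.knob_chain})
    found = {
        (tuple(sorted(r.number for r in p.socket.residues)), p.knob.number)
        for p in interface.pairs
    }
    expected = {
        (tuple(sorted(nums)), knob)
        for nums, knob in zip(toy.truth.socket_numbers, toy.truth.knob_numbers)
    }
    if found != expected:
        raise FixtureError(
            f"toy complex self-check failed: expected {sorted(expected)}, "
            f"pipeline recovered {sorted(found)}"
        )
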