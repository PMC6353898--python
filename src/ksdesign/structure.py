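"""Structure model and PDB input/output.

Reads PDB text into a minimal coordinate model suited to packing analysis:
first model only, heavy atoms only, one conformer per atom.  Secondary
structure is assigned internally from backbone dihedral windows so that the
package needs no external DSSP-style dependency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical 3-letter -> 1-letter amino-acid mapping.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be turned into a Structure."""


@dataclass
class Atom:
    """A heavy atom with coordinates in Å."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    """One residue: author numbering, 0-based chain index, atoms, SS label."""

    chain_id: str
    number: int
    icode: str
    seq_index: int
    aa: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    ss: str = "C"  # one of H / E / C

    @property
    def key(self) -> tuple[str, int, str]:
        """Author identity: (chain_id, author_number, insertion code)."""
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def backbone_complete(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class Structure:
    """An ordered set of chains, each an ordered list of residues."""

    chains: dict[str, list[Residue]]
    source_id: str = ""

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def __getitem__(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def parse_structure(pdb_text: str, altloc_policy: str = "occupancy",
                    source_id: str = "", mse_to_met: bool = True) -> Structure:
    """Parse PDB text into a Structure.

    Keeps the first model only; drops hydrogens, waters and HETATM ligands
    (selenomethionine is retained as methionine when ``mse_to_met``).  For
    alternate locations the highest-occupancy conformer is kept; occupancy
    ties go to the lexicographically first altloc identifier.

    Parameters
    ----------
    pdb_text:
        Text of a PDB file (ATOM/HETATM/MODEL/TER records).
    altloc_policy:
        Only ``"occupancy"`` is defined; the argument names the rule so the
        choice is explicit at every call site.
    """
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    if "ATOM" not in pdb_text:
        first = next((ln for ln in pdb_text.splitlines() if ln.strip()), "<empty input>")
        raise PDBParseError(f"no ATOM records found; first line: {first!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise PDBParseError(f"unparsable PDB text: {exc}") from exc
    if len(st) == 0:
        first = next((ln for ln in pdb_text.splitlines() if ln.strip()), "<empty input>")
        raise PDBParseError(f"no models parsed; first line: {first!r}")

    model = st[0]  # first model only
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            name3 = res.name.strip()
            if name3 in WATER_NAMES:
                continue
            if res.het_flag == "H" and not (mse_to_met and name3 == "MSE"):
                continue  # ligand / modified hetero group
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            aa = THREE_TO_ONE.get(name3, "M" if (name3 == "MSE" and mse_to_met) else "X")
            residues.append(Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
                seq_index=0,  # assigned after ordering
                aa=aa,
                name3=name3,
                atoms=atoms,
            ))
        residues = [r for r in residues if r.atom("CA") or r.atoms]
        if not any(any(a.is_backbone for a in r.atoms) for r in residues):
            if residues:
                logger.warning("chain %s has no standard residues; dropped", chain.name)
            continue
        residues.sort(key=lambda r: (r.number, r.icode))
        for i, r in enumerate(residues):
            r.seq_index = i
        if chain.name in chains:
            raise PDBParseError(f"duplicate chain id {chain.name!r} in first model")
        chains[chain.name] = residues

    if not chains:
        raise PDBParseError("no chains with standard residues after filtering")
    return Structure(chains=chains, source_id=source_id or st.name or "")


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to the
    lexicographically first altloc id.  Hydrogens are discarded."""
    by_name: dict[str, Atom] = {}
    for a in res:
        if a.element.is_hydrogen:
            continue
        alt = a.altloc if a.altloc and a.altloc != "\x00" else ""
        cand = Atom(
            serial=a.serial,
            name=a.name.strip(),
            element=a.element.name,
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=min(max(a.occ, 0.0), 1.0),
            altloc=alt,
        )
        held = by_name.get(cand.name)
        if held is None or (cand.occupancy, _alt_rank(cand.altloc)) > (
                held.occupancy, _alt_rank(held.altloc)):
            by_name[cand.name] = cand
    return list(by_name.values())


def _alt_rank(altloc: str) -> float:
    # higher is better; blank beats any letter, then A beats B, etc.
    if not altloc:
        return 0.0
    return -ord(altloc)


# ---------------------------------------------------------------------------
# secondary structure

# Dihedral windows (degrees) for the 3-state assignment.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-170.0, -50.0)
STRAND_PSI = ((80.0, 180.0), (-180.0, -170.0))
HELIX_MIN_RUN = 4
STRAND_MIN_RUN = 3


def backbone_dihedrals(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where the flanking residue or an atom
    is missing (chain termini, broken backbone)."""
    out: list[tuple[float | None, float | None]] = []
    for i, r in enumerate(chain):
        phi = psi = None
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        if n and ca and c:
            if i > 0:
                prev_c = chain[i - 1].atom("C")
                if prev_c is not None:
                    phi = _dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
            if i < len(chain) - 1:
                next_n = chain[i + 1].atom("N")
                if next_n is not None:
                    psi = _dihedral(n.coords, ca.coords, c.coords, next_n.coords)
        else:
            logger.warning("residue %s%s missing backbone atoms; labelled C",
                           r.chain_id, r.number)
        out.append((phi, psi))
    return out


def _in_window(x: float | None, lo: float, hi: float) -> bool:
    return x is not None and lo <= x <= hi


def assign_secondary_structure(chain: list[Residue]) -> list[str]:
    """3-state secondary structure from backbone dihedrals.

    Helix: phi in [-100, -30] and psi in [-80, -5] over >=4 consecutive
    residues.  Strand: phi in [-170, -50] and psi in [80, 180] or
    [-180, -170] over >=3 consecutive residues.  Everything else, and
    termini that lack a dihedral, is coil.  Labels are written back onto
    the residues and also returned.
    """
    if len(chain) < 3:
        labels = ["C"] * len(chain)
        for r, s in zip(chain, labels):
            r.ss = s
        return labels
    dihedrals = backbone_dihedrals(chain)
    helix_ok = [
        _in_window(phi, *HELIX_PHI) and _in_window(psi, *HELIX_PSI)
        for phi, psi in dihedrals
    ]
    strand_ok = [
        _in_window(phi, *STRAND_PHI)
        and (psi is not None and any(lo <= psi <= hi for lo, hi in STRAND_PSI))
        for phi, psi in dihedrals
    ]
    labels = ["C"] * len(chain)
    _mark_runs(labels, helix_ok, HELIX_MIN_RUN, "H")
    _mark_runs(labels, strand_ok, STRAND_MIN_RUN, "E")
    for r, s in zip(chain, labels):
        r.ss = s
    return labels


def _mark_runs(labels: list[str], ok: list[bool], min_run: int, code: str) -> None:
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    if labels[k] == "C":  # helix assignment wins on overlap
                        labels[k] = code
            i = j
        else:
            i += 1


def assign_all_secondary_structure(structure: Structure) -> None:
    for chain in structure.chains.values():
        assign_secondary_structure(chain)


def extract_sequence(chain: list[Residue]) -> str:
    """One-letter sequence in seq_index order; nonstandard residues are X
    (selenomethionine maps to M by default at parse time)."""
    if not chain:
        raise ValueError("cannot extract a sequence from an empty chain")
    return "".join(r.aa for r in sorted(chain, key=lambda r: r.seq_index))


# ---------------------------------------------------------------------------
# serialization

def to_pdb_string(structure: Structure) -> str:
    """Serialize the retained model back to PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "KSDESIGN"
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for r in residues:
            gres = gemmi.Residue()
            gres.name = r.name3
            gres.seqid = gemmi.SeqId(r.number, r.icode or " ")
            gres.het_flag = "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.serial = a.serial
                ga.altloc = "\x00"
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
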