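"""Contact geometry in crystal structures (mmCIF/PDB via gemmi).

Distances, heavy-atom hydrogen bonds, glycosidic torsions (syn/anti calls)
and least-squares superposition RMSDs, as used to characterise active-site
contacts and nucleotide conformations in enzyme-RNA complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["StructureModel", "HBond", "read_structure", "measure_distance",
           "detect_hbonds", "glycosidic_chi", "kabsch_rmsd"]


@dataclass
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    pos: np.ndarray       # (3,) Angstrom
    occupancy: float
    b_factor: float
    altloc: str


class StructureModel:
    """Flat atom table parsed from a gemmi structure (first model).

    Alternate locations are resolved per (chain, residue, atom name) to the
    highest occupancy; ties go to altloc 'A' (blank beats lettered only at
    equal occupancy through lexicographic order).
    """

    def __init__(self, atoms: list[AtomRecord], source_id: str = ""):
        self.atoms = atoms
        self.source_id = source_id
        self._index: dict[tuple[str, int, str], AtomRecord] = {}
        grouped: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in atoms:
            grouped.setdefault((a.chain, a.resnum, a.name), []).append(a)
        for key, group in grouped.items():
            group.sort(key=lambda a: (-a.occupancy, a.altloc))
            self._index[key] = group[0]

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "StructureModel":
        atoms = []
        model = st[0]
        for chain in model:
            for res in chain:
                for at in res:
                    pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                    if not np.all(np.isfinite(pos)):
                        raise ValueError(f"non-finite coordinates on {at.name}")
                    atoms.append(AtomRecord(
                        chain.name, res.seqid.num, res.name, at.name,
                        at.element.name, pos, at.occ, at.b_iso,
                        "" if at.altloc in ("", "\0") else at.altloc))
        return cls(atoms, st.name)

    def atom(self, atom_id: str) -> AtomRecord:
        """Resolve a ``chain:resnum:atomname`` selection."""
        try:
            chain, resnum, name = atom_id.split(":")
            key = (chain, int(resnum), name)
        except ValueError as e:
            raise ValueError(f"bad atom id {atom_id!r}; "
                             "expected chain:resnum:atomname") from e
        if key not in self._index:
            raise KeyError(f"atom {atom_id!r} not found in {self.source_id or 'structure'}")
        return self._index[key]

    def residue_atoms(self, chain: str, resnum: int) -> list[AtomRecord]:
        return [a for (c, r, _), a in self._index.items()
                if c == chain and r == resnum]


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a flat atom table."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ValueError(f"no atoms parsed from {path}")
    st.name = Path(path).stem
    return StructureModel.from_gemmi(st)


def measure_distance(structure: StructureModel, atom_id_a: str,
                     atom_id_b: str) -> float:
    """Euclidean distance (A) between two ``chain:resnum:atomname`` atoms."""
    a = structure.atom(atom_id_a)
    b = structure.atom(atom_id_b)
    return float(np.linalg.norm(a.pos - b.pos))


@dataclass
class HBond:
    donor: str
    acceptor: str
    distance: float
    angle: float | None
    weak: bool


def detect_hbonds(structure: StructureModel, distance_cutoff: float = 3.5,
                  weak_threshold: float = 3.3,
                  angle_cutoff: float = 120.0) -> list[HBond]:
    """Heavy-atom (N/O) hydrogen bonds between different residues.

    Pairs within ``distance_cutoff`` are reported, flagged weak in the
    [weak_threshold, distance_cutoff] band.  When a hydrogen is bonded
    (< 1.25 A) to one partner, the D-H...A angle is required to exceed
    ``angle_cutoff``; without hydrogens the angle test is skipped.
    """
    heavies = [a for a in structure._index.values() if a.element in ("N", "O")]
    hydrogens = [a for a in structure._index.values() if a.element == "H"]
    out = []
    for i, a in enumerate(heavies):
        for b in heavies[i + 1:]:
            if (a.chain, a.resnum) == (b.chain, b.resnum):
                continue
            d = float(np.linalg.norm(a.pos - b.pos))
            if d > distance_cutoff:
                continue
            angle = None
            ok = True
            for donor, acceptor in ((a, b), (b, a)):
                hs = [h for h in hydrogens
                      if np.linalg.norm(h.pos - donor.pos) < 1.25]
                for h in hs:
                    v1 = donor.pos - h.pos
                    v2 = acceptor.pos - h.pos
                    ang = math.degrees(math.acos(np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1.0, 1.0)))
                    angle = ang if angle is None else max(angle, ang)
            if angle is not None:
                ok = angle >= angle_cutoff
            if ok:
                aid = f"{a.chain}:{a.resnum}:{a.name}"
                bid = f"{b.chain}:{b.resnum}:{b.name}"
                out.append(HBond(aid, bid, d, angle, d >= weak_threshold))
    out.sort(key=lambda hb: hb.distance)
    return out


_PURINES = {"A", "G", "DA", "DG", "AMP", "ADE", "GMP", "GUA"}


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.degrees(math.atan2(y, x))


def glycosidic_chi(structure: StructureModel, chain: str,
                   resnum: int) -> tuple[float, str]:
    """Glycosidic torsion chi and its syn/anti call for one nucleotide.

    chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines,
    reported in (-180, 180].  syn is the (-30, 90] window (standard
    nucleic-acid convention); everything else is anti.
    """
    atoms = {a.name: a for a in structure.residue_atoms(chain, resnum)}
    if not atoms:
        raise KeyError(f"no residue {chain}:{resnum}")
    resname = next(iter(atoms.values())).resname.strip()
    purine = resname in _PURINES or (resname not in _PURINES and "N9" in atoms)
    names = ("O4'", "C1'", "N9", "C4") if purine else ("O4'", "C1'", "N1", "C2")
    missing = [n for n in names if n not in atoms]
    if missing:
        raise KeyError(f"residue {chain}:{resnum} is missing atoms {missing}")
    chi = _dihedral(*(atoms[n].pos.astype(float) for n in names))
    if chi <= -180.0:
        chi += 360.0
    conf = "syn" if -30.0 < chi <= 90.0 else "anti"
    return chi, conf


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (Kabsch).

    Inputs are paired coordinate sets of identical shape (n >= 3, 3).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need two equal (n >= 3, 3) coordinate sets")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.ones(3)
    d[-1] = sign
    rot = u @ np.diag(d) @ vt
    diff = bc @ rot - ac
    return float(np.sqrt((diff**2).sum() / a.shape[0]))
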