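"""Protein-peptide and dimer interface characterization from PDB coordinates.

Provides the geometric toolkit used to describe how a FIR/LIR peptide docks
onto the FIP200 Claw domain:

* Shrake-Rupley numerical solvent-accessible surface area (SASA) with a
  deterministic sphere point set;
* buried surface area (BSA) of an A/B interface, reported both as the
  summed convention ``SASA(A) + SASA(B) - SASA(AB)`` and as the PISA-style
  half of that sum, with a per-residue decomposition;
* hydrogen bonds from heavy-atom donor/acceptor geometry (deposited models
  carry no hydrogens, so the criterion is donor-acceptor distance plus the
  angle at the donor subtended by its covalent antecedent);
* salt bridges between side-chain cation and anion atoms, including the
  phosphate oxygens of phospho-Ser/Thr/Tyr (SEP/TPO/PTR);
* Kabsch least-squares superposition;
* contacts of peptide residues with the Claw's large hydrophobic pocket
  (LHP: C1565, A1567, F1574, V1576, F1582) and small hydrophobic groove
  (SHG: Y1564, K1581).

Coordinate input is parsed with gemmi; model 1 is used, alternate locations
are resolved to the highest-occupancy conformer (ties to altloc 'A'), and
waters are dropped by default.  Phospho residues SEP/TPO/PTR are kept as
polymer residues with their phosphate atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

# Van der Waals radii (Angstrom) used for SASA.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}

PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
PHOSPHO_RESNAMES = {"SEP", "TPO", "PTR"}
PHOSPHATE_OXYGENS = {"O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}

LHP_RESIDUES = {1565: "CYS", 1567: "ALA", 1574: "PHE", 1576: "VAL", 1582: "PHE"}
SHG_RESIDUES = {1564: "TYR", 1581: "LYS"}

# Side-chain donor (H-bearing) and acceptor heavy atoms per residue type.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "SEP": PHOSPHATE_OXYGENS,
    "TPO": PHOSPHATE_OXYGENS,
    "PTR": PHOSPHATE_OXYGENS,
}
_CATION_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
_ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "SEP": PHOSPHATE_OXYGENS,
    "TPO": PHOSPHATE_OXYGENS,
    "PTR": PHOSPHATE_OXYGENS,
}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


class StructureModel:
    """A flat atom list with index-based selections."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        self._coords = np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)
        if self._coords.size and not np.isfinite(self._coords).all():
            raise ValueError("non-finite atom coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select(
        self,
        chain: str | None = None,
        res_range: tuple[int, int] | None = None,
        resnums: Iterable[int] | None = None,
        backbone_only: bool = False,
        heavy_only: bool = True,
    ) -> np.ndarray:
        """Atom indices matching the predicates (all optional, ANDed)."""
        resnums = set(resnums) if resnums is not None else None
        idx = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if res_range is not None and not res_range[0] <= a.resnum <= res_range[1]:
                continue
            if resnums is not None and a.resnum not in resnums:
                continue
            if backbone_only and not a.is_backbone:
                continue
            if heavy_only and a.element == "H":
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        new_coords = self._coords @ rotation.T + translation
        atoms = [
            Atom(a.chain, a.resnum, a.icode, a.resname, a.name, a.element,
                 tuple(c), a.occupancy, a.bfactor)
            for a, c in zip(self.atoms, new_coords)
        ]
        return StructureModel(atoms)


def _from_gemmi(st: gemmi.Structure, keep_waters: bool) -> StructureModel:
    st.setup_entities()
    model = st[0]  # model 1 of multi-model files
    picked: dict[tuple, tuple[Atom, str]] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            if not keep_waters and res.name in ("HOH", "WAT", "DOD"):
                continue
            for at in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), at.name)
                altloc = at.altloc.strip("\x00 ") or "A"
                cand = Atom(
                    chain.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                    res.name,
                    at.name,
                    at.element.name.upper(),
                    (at.pos.x, at.pos.y, at.pos.z),
                    at.occ,
                    at.b_iso,
                )
                prev = picked.get(key)
                # highest occupancy wins; occupancy ties go to altloc 'A'
                if prev is None or (-at.occ, altloc) < (-prev[0].occupancy, prev[1]):
                    if prev is None:
                        order.append(key)
                    picked[key] = (cand, altloc)
    return StructureModel([picked[k][0] for k in order])


def read_structure(source: str, keep_waters: bool = False) -> StructureModel:
    """Read PDB text or a PDB/mmCIF file path into a :class:`StructureModel`.

    Uses model 1, drops waters unless *keep_waters*, and resolves alternate
    locations to the highest-occupancy conformer (occupancy ties keep the
    first-listed conformer, conventionally altloc 'A').
    """
    if "\n" in source:
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_structure(source)
    if len(st) == 0:
        raise ValueError("no models in structure")
    return _from_gemmi(st, keep_waters)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(model: StructureModel, indices: np.ndarray) -> np.ndarray:
    radii = np.empty(indices.size)
    for j, i in enumerate(indices):
        el = model.atoms[i].element
        try:
            radii[j] = VDW_RADII[el]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {el!r}") from None
    return radii


def sasa(
    model: StructureModel,
    selection: np.ndarray | None = None,
    probe: float = PROBE_RADIUS,
    points_per_atom: int = DEFAULT_SASA_POINTS,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley SASA of the selection treated as an isolated object.

    Returns (per-atom areas aligned with *selection*, total area) in A^2.
    Only atoms inside the selection occlude each other, so BSA arithmetic
    on group selections is exact by construction.
    """
    if selection is None:
        selection = np.arange(len(model))
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        return np.zeros(0), 0.0

    coords = model.coords[selection]
    radii = _atom_radii(model, selection) + probe
    unit = _sphere_points(points_per_atom)

    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(selection.size)
    for i in range(selection.size):
        pts = coords[i] + radii[i] * unit
        neighbors = tree.query_ball_point(coords[i], radii[i] + rmax)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(points_per_atom, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = accessible.mean() * 4.0 * math.pi * radii[i] ** 2
    return areas, float(areas.sum())


@dataclass(frozen=True)
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    angle: float | None  # antecedent-donor-acceptor, degrees; None if no antecedent
    hbond_class: str  # "backbone-backbone" | "side-chain-involved"


@dataclass(frozen=True)
class SaltBridge:
    cation: Atom
    anion: Atom
    distance: float


@dataclass
class InterfaceReport:
    bsa_sum: float
    bsa_half: float
    per_residue: dict[tuple[str, int, str], float]
    hbonds: list[HBond] = field(default_factory=list)
    salt_bridges: list[SaltBridge] = field(default_factory=list)
    pocket_contacts: dict = field(default_factory=dict)

    def n_backbone_hbonds(self) -> int:
        return sum(1 for h in self.hbonds if h.hbond_class == "backbone-backbone")


def buried_surface(
    model: StructureModel,
    groupA: np.ndarray,
    groupB: np.ndarray,
    probe: float = PROBE_RADIUS,
    points_per_atom: int = DEFAULT_SASA_POINTS,
) -> InterfaceReport:
    """Buried surface area of the A/B interface.

    ``bsa_sum = SASA(A) + SASA(B) - SASA(A u B)`` (the "total buried"
    convention); ``bsa_half`` is half of that (the per-complex interface
    area PISA reports).  The per-residue decomposition sums to ``bsa_sum``.
    """
    groupA = np.asarray(groupA, dtype=int)
    groupB = np.asarray(groupB, dtype=int)
    if groupA.size == 0 or groupB.size == 0:
        raise ValueError("both selections must be non-empty")
    if np.intersect1d(groupA, groupB).size:
        raise ValueError("selections overlap")

    both = np.concatenate([groupA, groupB])
    areas_a, tot_a = sasa(model, groupA, probe, points_per_atom)
    areas_b, tot_b = sasa(model, groupB, probe, points_per_atom)
    areas_ab, tot_ab = sasa(model, both, probe, points_per_atom)

    alone = np.concatenate([areas_a, areas_b])
    buried = alone - areas_ab
    per_residue: dict[tuple[str, int, str], float] = {}
    for idx, db in zip(both, buried):
        key = model.atoms[idx].residue_key
        per_residue[key] = per_residue.get(key, 0.0) + float(db)

    bsa = tot_a + tot_b - tot_ab
    return InterfaceReport(bsa_sum=float(bsa), bsa_half=float(bsa) / 2.0,
                           per_residue=per_residue)


def _is_donor(a: Atom) -> bool:
    if a.name == "N" and a.resname != "PRO":
        return True
    return a.name in _SIDECHAIN_DONORS.get(a.resname, ())


def _is_acceptor(a: Atom) -> bool:
    if a.name in ("O", "OXT"):
        return True
    return a.name in _SIDECHAIN_ACCEPTORS.get(a.resname, ())


def _antecedent(model: StructureModel, i: int) -> int | None:
    """Nearest covalently bonded heavy atom (within 1.8 A) of atom i."""
    d = np.linalg.norm(model.coords - model.coords[i], axis=1)
    d[i] = np.inf
    for j, a in enumerate(model.atoms):
        if a.element == "H":
            d[j] = np.inf
    j = int(np.argmin(d))
    return j if d[j] <= 1.8 else None


def hydrogen_bonds(
    model: StructureModel,
    selA: np.ndarray,
    selB: np.ndarray,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Hydrogen bonds across two selections from heavy-atom geometry.

    A donor N/O (amide N except proline, or an H-bearing side-chain N/O) and
    an acceptor N/O within *d_max* form a bond when the angle at the donor
    between its covalent antecedent and the acceptor is at least
    *angle_min* (skipped when the donor has no antecedent, as in minimal
    synthetic fixtures).  Each unordered atom pair is reported once.
    """
    selA = np.asarray(selA, dtype=int)
    selB = np.asarray(selB, dtype=int)
    if selA.size == 0 or selB.size == 0:
        raise ValueError("selections must be non-empty")

    bonds: list[HBond] = []
    seen: set[frozenset[int]] = set()
    for donors, acceptors in ((selA, selB), (selB, selA)):
        for di in donors:
            da = model.atoms[di]
            if da.element not in ("N", "O") or not _is_donor(da):
                continue
            for ai in acceptors:
                aa = model.atoms[ai]
                if aa.element not in ("N", "O") or not _is_acceptor(aa):
                    continue
                dist = float(np.linalg.norm(model.coords[di] - model.coords[ai]))
                if dist > d_max or frozenset((int(di), int(ai))) in seen:
                    continue
                angle = None
                ante = _antecedent(model, int(di))
                if ante is not None:
                    v1 = model.coords[ante] - model.coords[di]
                    v2 = model.coords[ai] - model.coords[di]
                    cosang = float(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle < angle_min:
                        continue
                cls = (
                    "backbone-backbone"
                    if da.is_backbone and aa.is_backbone
                    else "side-chain-involved"
                )
                seen.add(frozenset((int(di), int(ai))))
                bonds.append(HBond(da, aa, dist, angle, cls))
    bonds.sort(key=lambda h: (h.donor.chain, h.donor.resnum, h.donor.name, h.distance))
    return bonds


def salt_bridges(
    model: StructureModel,
    selA: np.ndarray,
    selB: np.ndarray,
    d_max: float = 4.0,
) -> list[SaltBridge]:
    """Cation-anion side-chain contacts across two selections within d_max.

    Cations: Lys NZ, Arg NE/NH1/NH2, His ND1/NE2.  Anions: Asp OD1/OD2,
    Glu OE1/OE2, and the phosphate oxygens of SEP/TPO/PTR.
    """
    selA = np.asarray(selA, dtype=int)
    selB = np.asarray(selB, dtype=int)
    if selA.size == 0 or selB.size == 0:
        raise ValueError("selections must be non-empty")

    def classify(idx: np.ndarray) -> tuple[list[int], list[int]]:
        cats, ans = [], []
        for i in idx:
            a = model.atoms[i]
            if a.name in _CATION_ATOMS.get(a.resname, ()):
                cats.append(int(i))
            if a.name in _ANION_ATOMS.get(a.resname, ()):
                ans.append(int(i))
        return cats, ans

    catsA, ansA = classify(selA)
    catsB, ansB = classify(selB)
    bridges = []
    for cats, ans in ((catsA, ansB), (catsB, ansA)):
        for ci in cats:
            for ai in ans:
                dist = float(np.linalg.norm(model.coords[ci] - model.coords[ai]))
                if dist <= d_max:
                    bridges.append(SaltBridge(model.atoms[ci], model.atoms[ai], dist))
    bridges.sort(key=lambda b: b.distance)
    return bridges


def superpose(
    coordsA: np.ndarray, coordsB: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Kabsch least-squares superposition of B onto A.

    Returns (RMSD, rotation, translation) so that
    ``coordsB @ rotation.T + translation`` best matches ``coordsA``.
    Raises on fewer than 3 pairs or (near-)collinear point sets, where the
    rotation is not uniquely determined.
    """
    P = np.asarray(coordsA, dtype=float)
    Q = np.asarray(coordsB, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs")

    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(P0), np.linalg.norm(Q0), 1.0)
    if S[1] < 1e-8 * scale:
        raise ValueError("degenerate (collinear or coincident) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Pc - R @ Qc
    diff = Q0 @ R.T - P0
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return rmsd, R, t


def pocket_contacts(
    model: StructureModel,
    peptide_sel: np.ndarray,
    claw_chain: str | None = None,
    d_max: float = 4.5,
    warn_stream=None,
) -> dict[tuple[str, int, str], list[tuple[str, int]]]:
    """Contacts of peptide residues with the Claw LHP/SHG pockets.

    Pocket membership uses the deposited Claw numbering (LHP 1565, 1567,
    1574, 1576, 1582; SHG 1564, 1581).  The Claw chain is auto-detected as
    the chain containing the most pocket residue numbers unless given.
    Returns {peptide residue key: [(pocket name, claw resnum), ...]} for
    residues with any heavy-atom pair within *d_max*.
    """
    peptide_sel = np.asarray(peptide_sel, dtype=int)
    pocket_nums = set(LHP_RESIDUES) | set(SHG_RESIDUES)

    if claw_chain is None:
        counts: dict[str, set[int]] = {}
        for a in model.atoms:
            if a.resnum in pocket_nums:
                counts.setdefault(a.chain, set()).add(a.resnum)
        if not counts:
            if warn_stream:
                print("warning: no pocket residues found in model", file=warn_stream)
            return {}
        claw_chain = max(counts, key=lambda c: len(counts[c]))

    present = {a.resnum for a in model.atoms if a.chain == claw_chain and a.resnum in pocket_nums}
    missing = pocket_nums - present
    if missing and warn_stream:
        print(f"warning: pocket residues missing from model: {sorted(missing)}", file=warn_stream)

    pocket_idx: dict[int, list[int]] = {}
    for i, a in enumerate(model.atoms):
        if a.chain == claw_chain and a.resnum in pocket_nums and a.element != "H":
            pocket_idx.setdefault(a.resnum, []).append(i)

    contacts: dict[tuple[str, int, str], list[tuple[str, int]]] = {}
    for pi in peptide_sel:
        pa = model.atoms[pi]
        if pa.element == "H":
            continue
        for resnum, idxs in pocket_idx.items():
            d = np.linalg.norm(model.coords[idxs] - model.coords[pi], axis=1).min()
            if d <= d_max:
                pocket = "LHP" if resnum in LHP_RESIDUES else "SHG"
                entry = (pocket, resnum)
                lst = contacts.setdefault(pa.residue_key, [])
                if entry not in lst:
                    lst.append(entry)
    for lst in contacts.values():
        lst.sort()
    return contacts


__all__ = [
    "Atom",
    "StructureModel",
    "HBond",
    "SaltBridge",
    "InterfaceReport",
    "read_structure",
    "sasa",
    "buried_surface",
    "hydrogen_bonds",
    "salt_bridges",
    "superpose",
    "pocket_contacts",
    "VDW_RADII",
    "LHP_RESIDUES",
    "SHG_RESIDUES",
]
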