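"""Structure models and native/variant comparison metrics.

Covers rigid-body superposition (Kabsch), full and TM-restricted CA RMSD,
a CA-geometry secondary-structure heuristic and the helical ratio R_H,
the polar-plot datum summarizing an RMSD/secondary-structure change, and
Shrake-Rupley solvent-accessible surface area with YRB atom classes for
hydrophobic-patch quantification.

Residue pairing between a native model and its QTY-variant model is by
sequential order: the substitution code preserves length and register, so
no alignment is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .props import KYTE_DOOLITTLE
from .records import Topology

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70

#: Chain-break threshold for sequential CA-CA distances (Angstrom).
CA_BREAK = 4.5

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int  # 0-based index into StructureModel.residues
    xyz: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class Residue:
    resnum: int
    aa: str  # one-letter code, 'X' if unknown
    ca_xyz: tuple[float, float, float]


@dataclass(frozen=True)
class StructureModel:
    """An ordered CA trace with optional full-atom list and SS string."""

    id: str
    residues: tuple[Residue, ...]
    atoms: tuple[Atom, ...] = ()
    ss: str | None = None

    def __post_init__(self) -> None:
        nums = [r.resnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"{self.id}: residue numbers must increase")
        if not np.all(np.isfinite(self.ca_coords())):
            raise ValueError(f"{self.id}: non-finite CA coordinates")
        for atom in self.atoms:
            if not 0 <= atom.residue_index < len(self.residues):
                raise ValueError(
                    f"{self.id}: atom {atom.serial} maps to no residue"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def atom_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def is_reduced(self) -> bool:
        """True when side chains beyond CB are absent (CB-proxy models)."""
        return bool(self.atoms) and all(
            a.name in BACKBONE_ATOMS or a.name == "CB" for a in self.atoms
        )


# ------------------------------------------------------------ PDB input ----

def _three_to_one() -> dict[str, str]:
    from Bio.Data.IUPACData import protein_letters_3to1

    return {k.upper(): v for k, v in protein_letters_3to1.items()}


_3TO1 = _three_to_one()


def read_pdb(path, chain: str | None = None, model_id: str | None = None
             ) -> StructureModel:
    """Read model 1 of a PDB file into a :class:`StructureModel`.

    Only altloc ``''`` or ``'A'`` atoms are kept. Elements map to vdW
    radii (C 1.70, N 1.55, O 1.52, S 1.80); unknown elements default to
    1.70 with a warning. A file without CA atoms is an error.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quiet PDBConstructionWarnings
        pdb_structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(iter(pdb_structure))  # model 1 only
    residues: list[Residue] = []
    atoms: list[Atom] = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.id[0].strip():  # skip heteroatoms/waters
                continue
            picked = [
                a
                for a in res.get_unpacked_list()
                if a.get_altloc() in (" ", "", "A")
            ]
            ca = next((a for a in picked if a.get_name() == "CA"), None)
            if ca is None:
                continue
            residues.append(
                Residue(
                    resnum=res.id[1],
                    aa=_3TO1.get(res.get_resname().upper(), "X"),
                    ca_xyz=tuple(map(float, ca.coord)),
                )
            )
            ridx = len(residues) - 1
            for a in picked:
                element = (a.element or "").upper()
                radius = VDW_RADII.get(element)
                if radius is None:
                    warnings.warn(
                        f"{path}: unknown element {element!r} for atom "
                        f"{a.get_serial_number()}; vdW radius "
                        f"{DEFAULT_VDW} assumed",
                        stacklevel=2,
                    )
                    radius = DEFAULT_VDW
                atoms.append(
                    Atom(
                        serial=int(a.get_serial_number() or 0),
                        name=a.get_name(),
                        element=element,
                        residue_index=ridx,
                        xyz=tuple(map(float, a.coord)),
                        radius=radius,
                    )
                )
    if not residues:
        raise ValueError(f"{path}: no CA atoms found")
    return StructureModel(
        id=model_id or str(path), residues=tuple(residues), atoms=tuple(atoms)
    )


# -------------------------------------------------------------- Kabsch ----

def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A (least-squares, Kabsch).

    Returns ``(rotation, translation, rmsd)`` with
    ``A ~ B @ rotation.T + translation``. The rotation is proper
    (det = +1); a reflection in the SVD solution is corrected by sign
    flip of the smallest singular vector. Degenerate (collinear) sets are
    computed with a warning.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired points are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0 = a - cen_a
    b0 = b - cen_b
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1.0):
        warnings.warn(
            "degenerate (collinear) coordinate set; superposition is not "
            "unique",
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cen_a - rot @ cen_b
    fitted = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_full(native: StructureModel, variant: StructureModel) -> float:
    """All-CA RMSD after Kabsch superposition (order pairing)."""
    if len(native) != len(variant):
        raise ValueError("models must have the same number of residues")
    return kabsch_superpose(native.ca_coords(), variant.ca_coords())[2]


def rmsd_tm(
    native: StructureModel, variant: StructureModel, topo: Topology
) -> float:
    """CA RMSD restricted to TM-segment residues (fit on TM CAs only).

    Residues are paired by order; TM membership uses the 1-based chain
    position (QTY preserves indexing). Fewer than 3 TM residues is an
    error.
    """
    if len(native) != len(variant):
        raise ValueError("models must have the same number of residues")
    mask = topo.tm_mask(len(native))
    if mask.sum() < 3:
        raise ValueError("fewer than 3 TM residues")
    a = native.ca_coords()[mask]
    b = variant.ca_coords()[mask]
    return kabsch_superpose(a, b)[2]


# --------------------------------------------- secondary structure / R_H ----

# P-SEA-style CA-distance windows (Angstrom).
HELIX_D13 = (4.5, 6.0)
HELIX_D14 = (5.7, 6.7)
STRAND_D12 = (6.6, 7.7)


def assign_ss(model: StructureModel) -> str:
    """Assign per-residue H/E/C from CA geometry.

    A helix window at residue i requires CA(i)-CA(i+3) within 4.5-6.0 A
    and CA(i)-CA(i+4) within 5.7-6.7 A; all five window residues are
    labeled H. An extended window requires CA(i)-CA(i+2) within
    6.6-7.7 A and labels its three residues E where not already H.
    Sequential CA-CA distances above 4.5 A are chain breaks: windows do
    not span them, and a warning is emitted.
    """
    if len(model) < 5:
        raise ValueError("at least 5 residues are required")
    xyz = model.ca_coords()
    n = len(xyz)
    gap = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    breaks = set(np.nonzero(gap > CA_BREAK)[0])  # break between i and i+1
    if breaks:
        warnings.warn(
            f"{model.id}: {len(breaks)} chain break(s) split SS windows",
            stacklevel=2,
        )

    def contiguous(i: int, j: int) -> bool:
        return not any(k in breaks for k in range(i, j))

    dist = lambda i, j: float(np.linalg.norm(xyz[i] - xyz[j]))
    ss = ["C"] * n
    for i in range(n - 4):
        if not contiguous(i, i + 4):
            continue
        d13 = dist(i, i + 3)
        d14 = dist(i, i + 4)
        if HELIX_D13[0] <= d13 <= HELIX_D13[1] and (
            HELIX_D14[0] <= d14 <= HELIX_D14[1]
        ):
            for k in range(i, i + 5):
                ss[k] = "H"
    for i in range(n - 2):
        if not contiguous(i, i + 2):
            continue
        d12 = dist(i, i + 2)
        if STRAND_D12[0] <= d12 <= STRAND_D12[1]:
            for k in range(i, i + 3):
                if ss[k] != "H":
                    ss[k] = "E"
    return "".join(ss)


def helical_ratio(ss: str) -> float:
    """Fraction of residues labeled H."""
    if not ss:
        raise ValueError("empty secondary-structure string")
    return ss.count("H") / len(ss)


def read_dssp_ss(path) -> str:
    """Read a per-residue SS string from a DSSP-style file.

    Accepts either a plain one-line H/E/C string or a DSSP output file,
    whose 3-state reduction maps H/G/I to H, E/B to E, else C. When
    supplied, this overrides the CA-geometry heuristic.
    """
    text = open(path).read()
    lines = text.splitlines()
    if len(lines) == 1 and set(lines[0]) <= set("HEC"):
        return lines[0]
    started = False
    ss = []
    for line in lines:
        if line.startswith("  #  RESIDUE"):
            started = True
            continue
        if started and len(line) > 16:
            if line[13] == "!":  # chain break record
                continue
            code = line[16]
            if code in "HGI":
                ss.append("H")
            elif code in "EB":
                ss.append("E")
            else:
                ss.append("C")
    if not ss:
        raise ValueError(f"{path}: no SS records found")
    return "".join(ss)


def polar_point(
    rmsd: float, rh_native: float, rh_variant: float, pi_native: float
) -> tuple[float, float, str]:
    """Polar-plot datum for one native/variant pair.

    Radius is the full-CA RMSD; the angle maps |delta R_H| linearly onto
    the 180-degree scale (capped); the hemisphere is upper for basic
    proteins (pI > 7; tie at exactly 7 goes upper).
    """
    angle = min(180.0, abs(rh_variant - rh_native) * 180.0)
    hemisphere = "upper" if pi_native >= 7.0 else "lower"
    return float(rmsd), float(angle), hemisphere


@dataclass(frozen=True)
class ComparisonMetrics:
    """Full comparison of a native/variant model pair."""

    pair_id: str
    rmsd_full: float
    rmsd_tm: float
    rh_native: float
    rh_variant: float
    pi_native: float
    radius: float
    polar_angle_deg: float
    hemisphere: str

    @property
    def delta_rh(self) -> float:
        return self.rh_variant - self.rh_native


def compare_models(
    native: StructureModel,
    variant: StructureModel,
    topo: Topology,
    pi_native: float,
) -> ComparisonMetrics:
    """Compute the full metric set for one pair."""
    ss_n = native.ss or assign_ss(native)
    ss_v = variant.ss or assign_ss(variant)
    rh_n = helical_ratio(ss_n)
    rh_v = helical_ratio(ss_v)
    r_full = rmsd_full(native, variant)
    r_tm = rmsd_tm(native, variant, topo) if topo.tm_length >= 3 else r_full
    radius, angle, hemisphere = polar_point(r_full, rh_n, rh_v, pi_native)
    return ComparisonMetrics(
        pair_id=native.id,
        rmsd_full=r_full,
        rmsd_tm=r_tm,
        rh_native=rh_n,
        rh_variant=rh_v,
        pi_native=pi_native,
        radius=radius,
        polar_angle_deg=angle,
        hemisphere=hemisphere,
    )


def thread_sequence(model: StructureModel, sequence: str,
                    model_id: str | None = None) -> StructureModel:
    """Thread a same-length sequence onto a model's coordinates.

    Residue identities change, coordinates do not: this is how a QTY
    variant is represented on its native backbone for the reduced
    (CB-proxy) hydrophobic-patch comparison when no modeled variant
    structure is available.
    """
    if len(sequence) != len(model):
        raise ValueError("sequence length must match the model")
    residues = tuple(
        Residue(r.resnum, aa, r.ca_xyz)
        for r, aa in zip(model.residues, sequence.upper())
    )
    return StructureModel(
        id=model_id or f"{model.id}_threaded",
        residues=residues,
        atoms=model.atoms,
        ss=model.ss,
    )


# ----------------------------------------------------------------- SASA ----

def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points via the golden-section spiral.

    Deterministic; no randomness.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa_shrake_rupley(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), in A^2.

    For each atom, test points on a sphere of radius r + probe; the
    accessible fraction (points inside no neighbor's expanded sphere)
    times 4*pi*(r+probe)^2 is its SASA. ``radii`` overrides the stored
    per-atom vdW radii (used by reduced-representation models).
    """
    if n_points < 50:
        raise ValueError("n_points must be at least 50")
    if not model.atoms:
        raise ValueError(f"{model.id}: no atoms present")
    xyz = model.atom_coords()
    if radii is None:
        radii = np.array([a.radius for a in model.atoms], dtype=float)
    else:
        radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    out = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + expanded[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(xyz[i], max_reach) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


# ------------------------------------------------------------------ YRB ----

# Side-chain carbons not covalently adjacent to N or O, per residue
# (aliphatic/aromatic surface in the YRB scheme). Backbone CA and C are
# N/O-adjacent and never yellow.
YELLOW_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "CYS": {"CB"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLY": set(),
    "HIS": {"CB"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "SER": set(),
    "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}
_1TO3 = {v: k for k, v in _3TO1.items()}

RED_OXYGENS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
BLUE_NITROGENS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}

#: CB-proxy classes for reduced (backbone + CB) models: a residue's CB
#: stands for its whole side chain and is yellow when the side chain is
#: hydrophobic on the Kyte-Doolittle scale.
CB_PROXY_YELLOW = {aa for aa, v in KYTE_DOOLITTLE.items() if v > 0}
CB_PROXY_BLUE = {"K", "R"}
CB_PROXY_RED = {"D", "E"}

#: Residue-typed CB radii for reduced models: the CB sphere approximates
#: the side-chain envelope, scaled with side-chain size.
CB_PROXY_RADII = {
    "A": 1.9, "C": 2.2, "D": 2.3, "E": 2.5, "F": 2.9, "G": 0.0,
    "H": 2.6, "I": 2.6, "K": 2.7, "L": 2.6, "M": 2.6, "N": 2.3,
    "P": 2.2, "Q": 2.5, "R": 2.9, "S": 2.0, "T": 2.2, "V": 2.3,
    "W": 3.1, "Y": 2.9,
}
CA_PROXY_RADIUS = 2.3  # backbone envelope around each CA in reduced models


def yrb_classify(
    model: StructureModel, reduced: bool | None = None
) -> list[str]:
    """Per-atom YRB class: yellow / red / blue / none.

    Yellow marks carbons with no covalent N/O neighbor (hydrophobic
    surface), red the Asp/Glu carboxylate and C-terminal oxygens, blue
    the Lys/Arg side-chain nitrogens. Reduced (backbone+CB) models use
    the CB-proxy table: each CB carries the class of its side chain.
    ``reduced=None`` auto-detects.
    """
    if not model.atoms:
        raise ValueError(f"{model.id}: no atoms present")
    if reduced is None:
        reduced = model.is_reduced()
    classes: list[str] = []
    last_ridx = len(model.residues) - 1
    for atom in model.atoms:
        aa1 = model.residues[atom.residue_index].aa
        res3 = _1TO3.get(aa1, "UNK")
        name = atom.name
        if reduced:
            if name == "CB":
                if aa1 in CB_PROXY_YELLOW:
                    classes.append("yellow")
                elif aa1 in CB_PROXY_RED:
                    classes.append("red")
                elif aa1 in CB_PROXY_BLUE:
                    classes.append("blue")
                else:
                    classes.append("none")
            else:
                classes.append("none")
            continue
        if name in YELLOW_CARBONS.get(res3, set()):
            classes.append("yellow")
        elif name in RED_OXYGENS.get(res3, set()):
            classes.append("red")
        elif name == "OXT" or (
            name == "O" and atom.residue_index == last_ridx
        ):
            classes.append("red")
        elif name in BLUE_NITROGENS.get(res3, set()):
            classes.append("blue")
        elif res3 == "UNK" or (
            name not in BACKBONE_ATOMS
            and not _known_atom(res3, name)
        ):
            warnings.warn(
                f"{model.id}: unknown atom {res3}:{name}; class 'none'",
                stacklevel=2,
            )
            classes.append("none")
        else:
            classes.append("none")
    return classes


_SIDECHAIN_ATOMS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
    "ASN": {"CB", "CG", "OD1", "ND2"},
    "ASP": {"CB", "CG", "OD1", "OD2"},
    "CYS": {"CB", "SG"},
    "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "GLY": set(),
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "SER": {"CB", "OG"},
    "THR": {"CB", "OG1", "CG2"},
    "TRP": {
        "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2",
    },
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "VAL": {"CB", "CG1", "CG2"},
}


def _known_atom(res3: str, name: str) -> bool:
    return name in _SIDECHAIN_ATOMS.get(res3, set())


def hydrophobic_patch_fraction(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """SASA-weighted fraction of yellow (hydrophobic) surface, in [0, 1].

    For reduced backbone+CB models the CB-proxy classes and
    residue-typed CB radii are used; full-atom models use their own
    radii and the full rule table.
    """
    reduced = model.is_reduced()
    classes = yrb_classify(model, reduced=reduced)
    radii = None
    if reduced:
        radii = np.array(
            [
                CB_PROXY_RADII.get(model.residues[a.residue_index].aa, 2.3)
                if a.name == "CB"
                else (CA_PROXY_RADIUS if a.name == "CA" else a.radius)
                for a in model.atoms
            ]
        )
    areas = sasa_shrake_rupley(model, probe=probe, n_points=n_points,
                               radii=radii)
    total = float(areas.sum())
    if total <= 0.0:
        raise ValueError(f"{model.id}: total SASA is zero")
    yellow = float(areas[[c == "yellow" for c in classes]].sum())
    return yellow / total
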