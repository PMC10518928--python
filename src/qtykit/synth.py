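"""Synthetic fixtures: membrane proteins, helix-bundle models, corpora.

Everything any other module consumes can be generated here offline and
deterministically: sequences with hydrophobic-biased TM helices inside
polar loops and an exactly known topology, ideal helix-bundle CA/CB
coordinate models realizing those topologies, Gaussian structure
perturbations, and keyword-structured function corpora with planted
category/cancer clusters for recovery tests.

All generators are pure functions of (spec, seed): a single named
numpy Generator is created from the seed and passed explicitly; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ProteinRecord, TMSegment, Topology, validate_topology
from .structure import Atom, Residue, StructureModel

# Hydrophobic-biased TM composition over the membrane-favored residues.
TM_ALPHABET = {
    "L": 0.22, "I": 0.15, "V": 0.15, "F": 0.12,
    "A": 0.18, "M": 0.09, "G": 0.06, "W": 0.03,
}
# Polar-biased loop composition over all 20 residues.
LOOP_ALPHABET = {
    "S": 0.09, "T": 0.07, "N": 0.07, "Q": 0.06, "D": 0.07, "E": 0.08,
    "K": 0.08, "R": 0.07, "G": 0.08, "P": 0.06, "H": 0.03, "A": 0.06,
    "L": 0.04, "I": 0.03, "V": 0.03, "F": 0.02, "Y": 0.03, "W": 0.01,
    "M": 0.01, "C": 0.01,
}

# Canonical alpha-helix CA geometry.
HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_CA_RADIUS = 2.3     # A from the helix axis
CA_CB_BOND = 1.53         # A


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic membrane-protein generator.

    TM helices are 18-25 residues (typical single-span lengths); loops
    default to 4-20 residues, long enough that bundle connectors stay
    below the chain-break threshold at the default bundle radius.
    """

    n_proteins: int = 50
    n_tm: tuple[int, int] = (2, 7)
    tm_length: tuple[int, int] = (18, 25)
    loop_length: tuple[int, int] = (4, 20)
    tm_alphabet: dict = field(default_factory=lambda: dict(TM_ALPHABET))
    loop_alphabet: dict = field(default_factory=lambda: dict(LOOP_ALPHABET))

    def __post_init__(self) -> None:
        for lo, hi in (self.n_tm, self.tm_length, self.loop_length):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


def _sample(rng: np.random.Generator, alphabet: dict, n: int) -> str:
    letters = sorted(alphabet)
    probs = np.array([alphabet[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def make_membrane_protein(
    spec: SynthSpec, seed: int, protein_id: str = "SYN1"
) -> tuple[ProteinRecord, Topology]:
    """One synthetic membrane protein with exactly recorded topology.

    Architecture: loop, then alternating TM helix / loop, ending in a
    loop. Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(seed)
    n_tm = int(rng.integers(spec.n_tm[0], spec.n_tm[1] + 1))
    parts: list[str] = []
    segments: list[TMSegment] = []
    pos = 0
    for k in range(n_tm + 1):
        loop_len = int(
            rng.integers(spec.loop_length[0], spec.loop_length[1] + 1)
        )
        parts.append(_sample(rng, spec.loop_alphabet, loop_len))
        pos += loop_len
        if k < n_tm:
            tm_len = int(
                rng.integers(spec.tm_length[0], spec.tm_length[1] + 1)
            )
            parts.append(_sample(rng, spec.tm_alphabet, tm_len))
            segments.append(TMSegment(pos + 1, pos + tm_len))
            pos += tm_len
    record = ProteinRecord(id=protein_id, sequence="".join(parts))
    topo = Topology(protein_id, tuple(segments))
    return record, validate_topology(record, topo)


def make_proteome(
    spec: SynthSpec, seed: int
) -> tuple[list[ProteinRecord], list[Topology]]:
    """``spec.n_proteins`` independent proteins, seeds derived from seed."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_proteins)
    records, topologies = [], []
    for i, s in enumerate(child_seeds):
        rec, topo = make_membrane_protein(spec, int(s), f"SYN{i + 1}")
        records.append(rec)
        topologies.append(topo)
    return records, topologies


# ------------------------------------------------------- structure side ----

def make_helix_bundle_model(
    record: ProteinRecord,
    topo: Topology,
    bundle_radius: float = 8.0,
) -> StructureModel:
    """Ideal CA/CB helix-bundle coordinates for a validated topology.

    Each TM segment is an ideal alpha-helix (1.5 A rise, 100 deg twist,
    2.3 A CA radius) on a vertical axis placed on a circle of
    ``bundle_radius``; helix direction alternates (antiparallel bundle)
    so loops connect nearby ends. Loops and tails are straight
    connectors with sub-break spacing. CB atoms sit 1.53 A from each CA,
    pointing away from the local axis (Gly has none). Deterministic.
    """
    validate_topology(record, topo)
    n = record.length
    ca = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    cb_dir = np.zeros((n, 3))
    n_tm = topo.n_tm
    max_len = max((len(s) for s in topo.segments), default=0)

    for k, seg in enumerate(topo.segments):
        phi = 2.0 * np.pi * k / max(n_tm, 1)
        axis_xy = bundle_radius * np.array([np.cos(phi), np.sin(phi)])
        up = k % 2 == 0
        m = len(seg)
        for j in range(m):
            # phase starts pointing at the bundle center to keep
            # inter-helix connector gaps short
            ang = phi + np.pi + np.deg2rad(HELIX_TWIST) * j
            z = HELIX_RISE * (j if up else (m - 1 - j))
            # center tall bundles on a shared mid-plane
            z += HELIX_RISE * 0.5 * (max_len - m)
            xy = axis_xy + HELIX_CA_RADIUS * np.array(
                [np.cos(ang), np.sin(ang)]
            )
            idx = seg.start - 1 + j
            ca[idx] = [xy[0], xy[1], z]
            radial = np.array([np.cos(ang), np.sin(ang), 0.0])
            cb_dir[idx] = radial
            placed[idx] = True

    # connectors: straight interpolation between flanking placed residues
    def fill_gap(lo: int, hi: int) -> None:
        # fill unplaced indices in (lo, hi) between placed anchors
        start = ca[lo] if lo >= 0 else None
        end = ca[hi] if hi < n else None
        idxs = list(range(lo + 1, hi))
        if not idxs:
            return
        if start is None and end is None:
            raise ValueError("topology has no TM segments to anchor loops")
        if start is None:  # N-terminal tail, walk outward from first helix
            d = end / (np.linalg.norm(end[:2]) + 1e-9)
            out = np.array([d[0], d[1], 0.0])
            out = out / (np.linalg.norm(out) + 1e-9)
            for r, idx in enumerate(reversed(idxs), start=1):
                ca[idx] = end + out * 3.5 * r
                cb_dir[idx] = out
        elif end is None:  # C-terminal tail
            d = start / (np.linalg.norm(start[:2]) + 1e-9)
            out = np.array([d[0], d[1], 0.0])
            out = out / (np.linalg.norm(out) + 1e-9)
            for r, idx in enumerate(idxs, start=1):
                ca[idx] = start + out * 3.5 * r
                cb_dir[idx] = out
        else:
            m = len(idxs)
            chord = end - start
            # bulge perpendicular to the chord keeps connectors off the
            # helix ends without stretching the spacing past the break
            perp = np.cross(chord, [0.0, 0.0, 1.0])
            norm = np.linalg.norm(perp)
            perp = perp / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            for r, idx in enumerate(idxs, start=1):
                f = r / (m + 1)
                bulge = 1.5 * np.sin(np.pi * f)
                ca[idx] = start + chord * f + perp * bulge
                cb_dir[idx] = perp

    anchors = [-1] + [i for i in range(n) if placed[i]] + [n]
    i = 0
    while i < len(anchors) - 1:
        lo, hi = anchors[i], anchors[i + 1]
        if hi - lo > 1:
            fill_gap(lo, hi)
        i += 1

    residues = tuple(
        Residue(resnum=i + 1, aa=record.sequence[i], ca_xyz=tuple(ca[i]))
        for i in range(n)
    )
    atoms: list[Atom] = []
    serial = 1
    for i in range(n):
        atoms.append(
            Atom(serial, "CA", "C", i, tuple(ca[i]), 1.70)
        )
        serial += 1
        if record.sequence[i] != "G":
            cb = ca[i] + CA_CB_BOND * cb_dir[i]
            atoms.append(Atom(serial, "CB", "C", i, tuple(cb), 1.70))
            serial += 1
    return StructureModel(
        id=record.id, residues=residues, atoms=tuple(atoms)
    )


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal standard PDB file."""
    from Bio.Data.IUPACData import protein_letters_1to3

    with open(path, "w") as fh:
        for atom in model.atoms:
            res = model.residues[atom.residue_index]
            res3 = protein_letters_1to3.get(res.aa, "Unk").upper()
            x, y, z = atom.xyz
            # names shorter than 4 chars start in column 14
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"ATOM  {atom.serial:5d} {name} {res3:>3s} A"
                f"{res.resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
            )
        fh.write("END\n")


def make_helix_bundle_pdb(
    record: ProteinRecord,
    topo: Topology,
    path,
    bundle_radius: float = 8.0,
) -> StructureModel:
    """Generate the bundle model and write it to ``path`` as PDB."""
    model = make_helix_bundle_model(record, topo, bundle_radius)
    write_pdb(model, path)
    return model


def perturb_structure(
    model: StructureModel,
    sigma: float,
    region: str = "all",
    seed: int = 0,
    topo: Topology | None = None,
) -> StructureModel:
    """Isotropic Gaussian displacement of selected residues.

    ``region`` is ``all``, ``tm`` or ``loops``; the latter two need a
    topology. Every atom of a displaced residue moves by the residue's
    displacement vector, so CB geometry is preserved. sigma=0 returns an
    identical model; deterministic per seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if region not in ("all", "tm", "loops"):
        raise ValueError(f"unknown region {region!r}")
    n = len(model)
    if region == "all":
        mask = np.ones(n, dtype=bool)
    else:
        if topo is None:
            raise ValueError("region-restricted perturbation needs a topology")
        tm = topo.tm_mask(n)
        mask = tm if region == "tm" else ~tm
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, sigma, size=(n, 3))
    shifts[~mask] = 0.0
    residues = tuple(
        Residue(r.resnum, r.aa, tuple(np.asarray(r.ca_xyz) + shifts[i]))
        for i, r in enumerate(model.residues)
    )
    atoms = tuple(
        Atom(
            a.serial, a.name, a.element, a.residue_index,
            tuple(np.asarray(a.xyz) + shifts[a.residue_index]), a.radius,
        )
        for a in model.atoms
    )
    return StructureModel(id=model.id, residues=residues, atoms=atoms,
                          ss=model.ss)


# ----------------------------------------------------------- corpus side ----

#: Planted classes: (category, cancer, keyword pool). Pools are disjoint.
DEFAULT_CLASSES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    (
        "receptor", "glioma",
        ("receptor", "ligand", "signaling", "transduction", "agonist",
         "cascade", "activation", "coupled"),
    ),
    (
        "transporter", "liver cancer",
        ("transporter", "solute", "uptake", "efflux", "gradient",
         "symport", "translocation", "carrier"),
    ),
    (
        "enzyme", "stomach cancer",
        ("enzyme", "catalyzes", "hydrolysis", "phosphorylation", "kinase",
         "acyl", "reaction", "catalytic"),
    ),
    (
        "channel", "melanoma",
        ("channel", "ion", "conductance", "gating", "voltage", "pore",
         "selectivity", "permeation"),
    ),
)

BACKGROUND_WORDS = (
    "protein", "cell", "plasma", "human", "tissue", "expression",
    "role", "involved", "process", "localized",
)


def make_function_corpus(
    n_per_class: int = 50,
    classes=DEFAULT_CLASSES,
    cancer_assignment_prob: float = 0.9,
    seed: int = 0,
):
    """Keyword-structured corpus with planted category/cancer clusters.

    Each text samples 6 keywords from its class pool plus 4 shared
    background words and a fake ``PubMed:NNNNNNN`` reference (to exercise
    cleaning). The class's cancer label is attached with probability
    ``cancer_assignment_prob``; the unlabeled remainder are the natural
    hold-outs for association-recovery tests.

    Returns ``(annotations, truth)`` where ``truth`` has ``class_labels``
    (per-protein class index), ``class_cancer`` and ``class_category``
    maps, and ``labeled`` (per-protein bool: cancer label attached).
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 planted classes")
    from .records import AnnotationRecord

    rng = np.random.default_rng(seed)
    annotations: list[AnnotationRecord] = []
    class_labels: list[int] = []
    labeled: list[bool] = []
    for ci, (category, cancer, pool) in enumerate(classes):
        for j in range(n_per_class):
            words = list(rng.choice(pool, size=6, replace=True))
            words += list(rng.choice(BACKGROUND_WORDS, size=4, replace=True))
            rng.shuffle(words)
            pmid = rng.integers(1_000_000, 9_999_999)
            text = " ".join(words) + f" (PubMed:{pmid})."
            has_label = bool(rng.random() < cancer_assignment_prob)
            annotations.append(
                AnnotationRecord(
                    protein_id=f"{category[:3].upper()}{j + 1}",
                    category=category,
                    cancers=frozenset({cancer} if has_label else set()),
                    function_text=text,
                )
            )
            class_labels.append(ci)
            labeled.append(has_label)
    truth = {
        "class_labels": class_labels,
        "class_cancer": {ci: c for ci, (_, c, _) in enumerate(classes)},
        "class_category": {ci: cat for ci, (cat, _, _) in enumerate(classes)},
        "labeled": labeled,
    }
    return annotations, truth
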