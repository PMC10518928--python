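"""Per-sequence physicochemical properties: MW, pI, GRAVY, charge census.

The isoelectric point is the pH at which the Henderson-Hasselbalch net
charge of the chain is zero. With per-group pKa values the net charge at
pH ``p`` is

    Z(p) =   sum over positive groups  n_g / (1 + 10^(p - pKa_g))
           - sum over negative groups  n_g / (1 + 10^(pKa_g - p))

which is strictly decreasing in p, so the root is unique and found by
bisection on [0, 14]. The pKa set is the Bjellqvist table used by the
ExPASy Compute pI/MW tool (Cys reduced, no disulfides); it ships as an
editable JSON constants file.

Molecular weight is the sum of average residue masses plus one water.
Hydropathy is the Kyte-Doolittle mean (GRAVY); the scale is pluggable.
Non-standard residues (B, J, O, U, X, Z) are excluded from pI and GRAVY
sums and contribute a configurable average mass (default 110 Da) to MW
with a warning.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .qty import QTYDesign, CHARGED_RESIDUES
from .records import NONSTANDARD_AA, ProteinRecord


def _load_json(name: str) -> dict:
    with resources.files("qtykit.data").joinpath(name).open() as fh:
        return json.load(fh)


_MASS = _load_json("residue_masses.json")
RESIDUE_MASSES: dict[str, float] = _MASS["residues"]
WATER_DA: float = _MASS["water_da"]
UNKNOWN_RESIDUE_DA: float = _MASS["unknown_residue_da"]

_PKA = _load_json("pka_bjellqvist.json")
PKA_POSITIVE: dict[str, float] = _PKA["positive"]
PKA_NEGATIVE: dict[str, float] = _PKA["negative"]
PKA_NTERM_BY_RESIDUE: dict[str, float] = _PKA["nterm_by_residue"]
PKA_CTERM_BY_RESIDUE: dict[str, float] = _PKA["cterm_by_residue"]

KYTE_DOOLITTLE: dict[str, float] = _load_json("kyte_doolittle.json")["scale"]


@dataclass(frozen=True)
class PropertyProfile:
    """Physicochemical summary of one sequence."""

    id: str
    mw_da: float
    pi: float
    gravy: float
    charged_counts: dict[str, int]
    length: int

    @property
    def mw_kda(self) -> float:
        """MW in kDa at 2 decimals (reporting convention)."""
        return round(self.mw_da / 1000.0, 2)


def molecular_weight(
    sequence: str, unknown_mass: float = UNKNOWN_RESIDUE_DA
) -> float:
    """Average molecular mass in Daltons (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    mw = WATER_DA
    n_unknown = 0
    for aa in sequence:
        mass = RESIDUE_MASSES.get(aa)
        if mass is None:
            if aa not in NONSTANDARD_AA:
                raise ValueError(f"invalid residue {aa!r}")
            mw += unknown_mass
            n_unknown += 1
        else:
            mw += mass
    if n_unknown:
        warnings.warn(
            f"{n_unknown} non-standard residues counted at "
            f"{unknown_mass} Da each",
            stacklevel=2,
        )
    return mw


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the chain at ``ph``.

    Terminal pKa values follow Bjellqvist's residue-specific
    refinements when the chain starts/ends with a listed residue.
    """
    sequence = sequence.upper()
    counts = Counter(sequence)
    pka_nterm = PKA_NTERM_BY_RESIDUE.get(
        sequence[0], PKA_POSITIVE["Nterm"]
    )
    pka_cterm = PKA_CTERM_BY_RESIDUE.get(
        sequence[-1], PKA_NEGATIVE["Cterm"]
    )
    pos = sum(
        counts.get(aa, 0) / (1.0 + 10.0 ** (ph - pka))
        for aa, pka in PKA_POSITIVE.items()
        if aa != "Nterm"
    )
    pos += 1.0 / (1.0 + 10.0 ** (ph - pka_nterm))
    neg = sum(
        counts.get(aa, 0) / (1.0 + 10.0 ** (pka - ph))
        for aa, pka in PKA_NEGATIVE.items()
        if aa != "Cterm"
    )
    neg += 1.0 / (1.0 + 10.0 ** (pka_cterm - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root exists
    and is unique in the interval.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str, scale: dict[str, float] | None = None) -> float:
    """Mean hydropathy over standard residues (GRAVY, Kyte-Doolittle)."""
    if not sequence:
        raise ValueError("empty sequence")
    scale = KYTE_DOOLITTLE if scale is None else scale
    values = [scale[aa] for aa in sequence.upper() if aa in scale]
    if not values:
        raise ValueError("sequence contains no standard residues")
    return sum(values) / len(values)


def charged_counts(sequence: str) -> dict[str, int]:
    """Counts of the charged residues D, E, K, R, H."""
    counts = Counter(sequence.upper())
    return {aa: counts.get(aa, 0) for aa in CHARGED_RESIDUES}


def property_profile(record: ProteinRecord) -> PropertyProfile:
    return PropertyProfile(
        id=record.id,
        mw_da=molecular_weight(record.sequence),
        pi=isoelectric_point(record.sequence),
        gravy=gravy(record.sequence),
        charged_counts=charged_counts(record.sequence),
        length=record.length,
    )


def property_table(record: ProteinRecord, design: QTYDesign) -> dict:
    """One native/variant comparison row (summary-table schema).

    Columns: id, pI and MW (kDa) for native and variant, TM/total
    variation percentages, GRAVY for both, and a flag asserting the
    charged-residue census is unchanged (QTY touches no charged residue).
    """
    if design.native_id != record.id:
        raise ValueError(
            f"design is for {design.native_id!r}, record is {record.id!r}"
        )
    native = property_profile(record)
    variant = property_profile(design.variant_record())
    return {
        "id": record.id,
        "pI_native": round(native.pi, 2),
        "pI_qty": round(variant.pi, 2),
        "MW_native_kDa": native.mw_kda,
        "MW_qty_kDa": variant.mw_kda,
        "tm_variation_pct": design.tm_variation_pct,
        "total_variation_pct": design.total_variation_pct,
        "gravy_native": round(native.gravy, 3),
        "gravy_qty": round(variant.gravy, 3),
        "charged_counts_equal": native.charged_counts
        == variant.charged_counts,
    }
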