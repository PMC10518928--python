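"""The QTY substitution code.

Inside annotated transmembrane segments the four hydrophobic residues
Leu, Val, Ile and Phe are replaced pairwise by the structurally analogous
hydrophilic residues Gln, Thr, Thr and Tyr:

    L -> Q    V -> T    I -> T    F -> Y

Each pair conserves side-chain shape and carries no charge, so the design
preserves length, register and the charged-residue census while removing
hydrophobic surface from the helix faces. Residues outside TM segments
are never touched; the mapping is closed (Trp, Met, Ala stay), and the
code is idempotent because Q, T and Y are outside its domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .records import ProteinRecord, Topology, validate_topology

#: The fixed pairwise substitution map. Not user-mutable by default.
SUBSTITUTION_MAP: dict[str, str] = {"L": "Q", "V": "T", "I": "T", "F": "Y"}

CHARGED_RESIDUES = "DEKRH"


def round2(x: Fraction | float) -> float:
    """Round half-up to 2 decimals (reporting convention for percentages)."""
    return float(
        Decimal(str(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class Substitution:
    """One applied substitution at a 1-based position."""

    position: int
    from_aa: str
    to_aa: str
    segment_index: int


@dataclass(frozen=True)
class QTYDesign:
    """A designed variant plus its variation metrics.

    ``tm_variation`` and ``total_variation`` are exact rationals
    (#substitutions over TM length and full length); the ``*_pct``
    properties report them as percentages rounded half-up to 2 decimals.
    """

    native_id: str
    native_sequence: str
    variant_sequence: str
    substitutions: tuple[Substitution, ...]
    tm_variation: Fraction
    total_variation: Fraction

    @property
    def variant_id(self) -> str:
        return f"{self.native_id}_QTY"

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def tm_variation_pct(self) -> float:
        return round2(self.tm_variation * 100)

    @property
    def total_variation_pct(self) -> float:
        return round2(self.total_variation * 100)

    def variant_record(self, suffix: str = "_QTY") -> ProteinRecord:
        return ProteinRecord(
            id=f"{self.native_id}{suffix}", sequence=self.variant_sequence
        )


def apply_qty(record: ProteinRecord, topo: Topology) -> QTYDesign:
    """Apply the QTY code to ``record`` within the TM segments of ``topo``.

    The topology is validated against the record first. With no TM
    segments the design is the identity and both variation metrics are 0
    by convention.
    """
    validate_topology(record, topo)
    seq = list(record.sequence)
    subs: list[Substitution] = []
    for seg in topo.segments:
        for pos in range(seg.start, seg.end + 1):
            aa = seq[pos - 1]
            to = SUBSTITUTION_MAP.get(aa)
            if to is not None:
                seq[pos - 1] = to
                subs.append(Substitution(pos, aa, to, seg.index))
    n = len(subs)
    tm_len = topo.tm_length
    return QTYDesign(
        native_id=record.id,
        native_sequence=record.sequence,
        variant_sequence="".join(seq),
        substitutions=tuple(subs),
        tm_variation=Fraction(n, tm_len) if tm_len else Fraction(0),
        total_variation=Fraction(n, record.length),
    )


def render_alignment(
    record: ProteinRecord,
    design: QTYDesign,
    topo: Topology,
    width: int = 60,
) -> str:
    """Render a native/variant alignment as text.

    Four lines per block, wrapped at ``width`` columns: a TM annotation
    line (``H`` under helix positions), the native sequence, a match line
    with ``|`` for unchanged and ``*`` for substituted positions, and the
    variant sequence.
    """
    if width < 10:
        raise ValueError("alignment width must be at least 10")
    native = record.sequence
    variant = design.variant_sequence
    if len(native) != len(variant):
        raise ValueError("native and variant lengths differ")
    match = "".join(
        "|" if a == b else "*" for a, b in zip(native, variant)
    )
    tm_line = "".join(
        "H" if topo.contains(i + 1) else " " for i in range(len(native))
    )
    blocks = []
    for i in range(0, len(native), width):
        j = min(i + width, len(native))
        blocks.append(
            "\n".join(
                [
                    f"TM      {tm_line[i:j]}",
                    f"{record.id:<7.7} {native[i:j]}  {j}",
                    f"        {match[i:j]}",
                    f"{design.variant_id:<7.7} {variant[i:j]}  {j}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"


def batch_design(
    records: list[ProteinRecord],
    topologies: dict[str, Topology] | list[Topology],
) -> tuple[list[QTYDesign], list[str]]:
    """Design every record that has a topology.

    Returns the designs plus a skipped-report of ids that lack a
    topology entry (missing ids are reported, never a crash). A record
    whose topology has zero segments gets an identity design with 0 %
    variation.
    """
    if not isinstance(topologies, dict):
        topologies = {t.protein_id: t for t in topologies}
    designs: list[QTYDesign] = []
    skipped: list[str] = []
    for rec in records:
        topo = topologies.get(rec.id)
        if topo is None:
            skipped.append(rec.id)
            continue
        designs.append(apply_qty(rec, topo))
    return designs, skipped
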