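"""Core domain types: protein records, transmembrane topologies, annotations.

Residue coordinates are 1-based inclusive throughout the public surface,
matching the UniProt feature-table convention; internal arithmetic converts
to 0-based half-open slices at module boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Accepted non-standard/ambiguity codes: never QTY-substituted, excluded
#: from pI/GRAVY sums, and counted at a configurable average mass in MW.
NONSTANDARD_AA = set("BJOUXZ")


class TopologyError(ValueError):
    """A transmembrane topology violates its invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by a unique id.

    ``name`` carries the FASTA description (text after the first whitespace
    in the header), if any.
    """

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper().replace("\n", "").replace(" ", "")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(seq) - STANDARD_AA - NONSTANDARD_AA
        if bad:
            raise ValueError(
                f"{self.id}: invalid sequence characters {sorted(bad)}"
            )
        nonstd = set(seq) & NONSTANDARD_AA
        if nonstd:
            warnings.warn(
                f"{self.id}: non-standard residues {sorted(nonstd)} present; "
                "they are never substituted and are excluded from pI/GRAVY",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TMSegment:
    """One transmembrane span, 1-based inclusive, with its helix ordinal."""

    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise TopologyError("segment bounds must be integers")
        if not 1 <= self.start <= self.end:
            raise TopologyError(
                f"invalid segment bounds {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open slice of the segment."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class Topology:
    """Ordered, non-overlapping TM segments of one protein.

    An empty segment list is valid and denotes a soluble protein.
    """

    protein_id: str
    segments: tuple[TMSegment, ...] = ()

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise TopologyError(
                    f"{self.protein_id}: overlapping TM segments "
                    f"{prev.start}..{prev.end} and {cur.start}..{cur.end}"
                )
        segs = tuple(
            TMSegment(s.start, s.end, i + 1) for i, s in enumerate(segs)
        )
        object.__setattr__(self, "segments", segs)

    @property
    def n_tm(self) -> int:
        return len(self.segments)

    @property
    def tm_length(self) -> int:
        """Total number of residues inside TM segments."""
        return sum(len(s) for s in self.segments)

    def contains(self, pos: int) -> bool:
        """True when 1-based position ``pos`` lies inside a TM segment."""
        return any(s.start <= pos <= s.end for s in self.segments)

    def segment_of(self, pos: int) -> int | None:
        """Helix ordinal covering 1-based ``pos``, or None."""
        for s in self.segments:
            if s.start <= pos <= s.end:
                return s.index
        return None

    def tm_mask(self, length: int):
        """Boolean array of shape (length,), True inside TM segments."""
        import numpy as np

        mask = np.zeros(length, dtype=bool)
        for s in self.segments:
            mask[s.slice] = True
        return mask


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional category, cancer-type labels, and free-text description."""

    protein_id: str
    category: str
    cancers: frozenset[str] = frozenset()
    function_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cancers", frozenset(self.cancers))


def validate_topology(record: ProteinRecord, topo: Topology) -> Topology:
    """Check a topology against the sequence it annotates.

    Returns the topology unchanged when every segment lies within
    ``[1, record.length]``; raises :class:`TopologyError` otherwise.
    """
    if topo.protein_id != record.id:
        raise TopologyError(
            f"topology is for {topo.protein_id!r}, record is {record.id!r}"
        )
    for seg in topo.segments:
        if seg.end > record.length:
            raise TopologyError(
                f"{record.id}: TM segment {seg.index} "
                f"({seg.start}..{seg.end}) extends beyond sequence "
                f"length {record.length}"
            )
    return topo
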