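"""Readers and writers for sequences, TM topologies, and annotation tables.

Three topology dialects are understood:

``tsv``
    Columns ``protein_id``, ``start``, ``end``; one segment per row.
``json``
    ``{"<protein_id>": [[start, end], ...], ...}``.
``uniprot_ft``
    UniProt flat-file feature-table lines, e.g.
    ``FT   TRANSMEM        34..54``. An ``ID``/``AC`` line or a
    ``FT``-preceding accession establishes the current protein; a bare
    feature file for a single protein may supply the id externally.

All readers take explicit paths and perform no network access.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from importlib import resources
from pathlib import Path

from .records import AnnotationRecord, ProteinRecord, TMSegment, Topology


def _load_vocab() -> dict:
    with resources.files("qtykit.data").joinpath("vocab.json").open() as fh:
        return json.load(fh)


_VOCAB = _load_vocab()
CATEGORIES: tuple[str, ...] = tuple(_VOCAB["categories"])
CANCER_TYPES: tuple[str, ...] = tuple(_VOCAB["cancers"])


# ---------------------------------------------------------------- FASTA ----

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; the rest
    of the header line is kept as ``name``. Sequences are uppercased and
    joined across lines. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        pid = parts[0]
        if pid in seen:
            raise ValueError(f"{path}: duplicate FASTA id {pid!r}")
        seen.add(pid)
        records.append(
            ProteinRecord(
                id=pid,
                sequence="".join(chunks),
                name=parts[1].strip() if len(parts) > 1 else "",
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before header")
                chunks.append(line)
    _flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: list[ProteinRecord], path: str | Path, width: int = 60
) -> None:
    """Write records to FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.name:
                head += f" {rec.name}"
            fh.write(head + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ------------------------------------------------------------- topology ----

_FT_TRANSMEM = re.compile(
    r"^FT\s+TRANSMEM\s+(\d+)\.\.(\d+)"
)
_FT_ID = re.compile(r"^(?:ID\s+(\S+)|AC\s+(\w+);?)")


def _segments_to_topology(pid: str, raw: list[tuple[int, int]]) -> Topology:
    return Topology(pid, tuple(TMSegment(s, e) for s, e in raw))


def _parse_bound(token: str, path: Path) -> int:
    token = token.strip()
    if not re.fullmatch(r"\d+", token):
        raise ValueError(f"{path}: non-integer segment bound {token!r}")
    return int(token)


def read_topology(
    path: str | Path,
    dialect: str = "tsv",
    protein_id: str | None = None,
) -> list[Topology]:
    """Read TM topologies in one of the three supported dialects.

    ``protein_id`` supplies the id for a ``uniprot_ft`` fragment that has
    no ID/AC line of its own.
    """
    path = Path(path)
    per_protein: dict[str, list[tuple[int, int]]] = {}

    if dialect == "tsv":
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "protein_id":  # optional header
                    continue
                if len(row) < 3:
                    raise ValueError(f"{path}: malformed row {row!r}")
                pid = row[0].strip()
                start = _parse_bound(row[1], path)
                end = _parse_bound(row[2], path)
                per_protein.setdefault(pid, []).append((start, end))
    elif dialect == "json":
        data = json.loads(Path(path).read_text())
        for pid, segs in data.items():
            for pair in segs:
                if len(pair) != 2:
                    raise ValueError(f"{path}: malformed segment {pair!r}")
                s, e = pair
                if not (isinstance(s, int) and isinstance(e, int)):
                    raise ValueError(
                        f"{path}: non-integer segment bounds {pair!r}"
                    )
                per_protein.setdefault(pid, []).append((s, e))
            per_protein.setdefault(pid, [])
    elif dialect == "uniprot_ft":
        current = protein_id
        with open(path) as fh:
            for line in fh:
                m = _FT_ID.match(line)
                if m:
                    current = m.group(1) or m.group(2)
                    per_protein.setdefault(current, [])
                    continue
                m = _FT_TRANSMEM.match(line)
                if m:
                    if current is None:
                        raise ValueError(
                            f"{path}: TRANSMEM line before any ID/AC line "
                            "and no protein_id given"
                        )
                    per_protein.setdefault(current, []).append(
                        (int(m.group(1)), int(m.group(2)))
                    )
    else:
        raise ValueError(f"unknown topology dialect {dialect!r}")

    return [
        _segments_to_topology(pid, raw)
        for pid, raw in per_protein.items()
    ]


def write_topology(
    topologies: list[Topology], path: str | Path
) -> None:
    """Write topologies as the TSV dialect (one segment per row)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "start", "end"])
        for topo in topologies:
            for seg in topo.segments:
                w.writerow([topo.protein_id, seg.start, seg.end])


# ---------------------------------------------------------- annotations ----

def read_annotations(
    path: str | Path,
    cancer_vocabulary: tuple[str, ...] = CANCER_TYPES,
    category_vocabulary: tuple[str, ...] = CATEGORIES,
) -> list[AnnotationRecord]:
    """Read a CSV annotation table (id, category, cancers, function_text).

    ``cancers`` is semicolon-separated. Unknown categories are mapped to
    ``"other"`` with a warning (entries lacking an apparent functional
    class); an unknown cancer label is an error because the cancer
    vocabulary is closed.
    """
    path = Path(path)
    out: list[AnnotationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "category", "cancers", "function_text"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: annotation CSV must have columns {sorted(required)}"
            )
        for row in reader:
            category = row["category"].strip().lower()
            if category not in category_vocabulary:
                warnings.warn(
                    f"{path}: unknown category {category!r} for "
                    f"{row['id']!r}; mapped to 'other'",
                    stacklevel=2,
                )
                category = "other"
            cancers = set()
            for token in row["cancers"].split(";"):
                token = token.strip().lower()
                if not token:
                    continue
                if token not in cancer_vocabulary:
                    raise ValueError(
                        f"{path}: unknown cancer label {token!r} for "
                        f"{row['id']!r}"
                    )
                cancers.add(token)
            out.append(
                AnnotationRecord(
                    protein_id=row["id"].strip(),
                    category=category,
                    cancers=frozenset(cancers),
                    function_text=row["function_text"],
                )
            )
    return out


def write_annotations(
    records: list[AnnotationRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "category", "cancers", "function_text"])
        for rec in records:
            w.writerow(
                [
                    rec.protein_id,
                    rec.category,
                    ";".join(sorted(rec.cancers)),
                    rec.function_text,
                ]
            )
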