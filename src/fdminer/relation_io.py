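"""Loading delimited tabular files into the :class:`Relation` model.

A relation is a header row of attribute names followed by rows of opaque
value tokens.  Values are never interpreted numerically: functional
dependency theory only needs equality, and coercing ``"0"`` and ``"0.0"``
to the same number would silently merge partition groups.  Empty cells are
normalized to a single reserved token (the empty string) that equals
itself, so the theory stays two-valued.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .errors import MalformedFileError, SchemaError

#: Separator candidates, in precedence order.
SEPARATORS: tuple[str, ...] = (",", "|", ";", ":", "~")

#: Reserved token for empty / missing cells.  It equals itself, so rows
#: missing the same field fall into the same partition group.
MISSING_TOKEN = ""

#: Number of leading non-empty lines inspected by :func:`detect_separator`.
SEPARATOR_SAMPLE_LINES = 20

#: File suffixes accepted by :func:`read_relation`.
TEXT_SUFFIXES = {".csv", ".txt"}
PICKLE_SUFFIX = ".pkl"


@dataclass(frozen=True)
class Relation:
    """An ordered attribute schema plus row tuples of opaque values.

    Parameters
    ----------
    name:
        Text label, conventionally derived from the source file name.
    attributes:
        Ordered sequence of unique, non-empty attribute names (the set U).
    rows:
        Sequence of value tuples; every tuple has the same arity as the
        schema, and values are compared only for equality.
    """

    name: str
    attributes: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.attributes)) != len(self.attributes):
            raise SchemaError(f"duplicate attribute names in {list(self.attributes)}")
        if any(not a for a in self.attributes):
            raise SchemaError("attribute names must be non-empty")
        arity = len(self.attributes)
        for i, row in enumerate(self.rows):
            if len(row) != arity:
                raise SchemaError(
                    f"row {i} has {len(row)} values, schema has {arity} attributes"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def detect_separator(sample_lines: Sequence[str]) -> Optional[str]:
    """Choose the field separator used by a delimited text sample.

    A candidate qualifies when it splits every sampled non-empty line into
    the same field count greater than one.  Ties are broken by the
    precedence order comma, bar, semicolon, colon, tilde.  When no
    candidate qualifies the file is treated as single-column and ``None``
    is returned.

    Raises
    ------
    MalformedFileError
        If no candidate qualifies although the header line contains at
        least one candidate character — the field counts are then
        inconsistent and the file is not rectangular.
    """
    lines = [ln for ln in sample_lines if ln.strip() != ""]
    if not lines:
        raise MalformedFileError("no non-empty lines to inspect")
    lines = lines[:SEPARATOR_SAMPLE_LINES]
    for sep in SEPARATORS:
        counts = {len(next(csv.reader([ln], delimiter=sep))) for ln in lines}
        if len(counts) == 1 and counts.pop() > 1:
            return sep
    header = lines[0]
    if any(sep in header for sep in SEPARATORS):
        raise MalformedFileError(
            "inconsistent field counts for every candidate separator"
        )
    return None


def _relation_from_rows(
    name: str, parsed: list[tuple[int, list[str]]]
) -> Relation:
    """Build a Relation from (line_number, fields) pairs, header first."""
    if not parsed:
        raise MalformedFileError("file is empty")
    _, header = parsed[0]
    attributes = tuple(h.strip() for h in header)
    if any(not a for a in attributes):
        raise MalformedFileError("empty attribute name in header")
    if len(set(attributes)) != len(attributes):
        raise MalformedFileError(f"duplicate attribute names in {attributes}")
    rows = []
    for line_num, fields in parsed[1:]:
        if len(fields) != len(attributes):
            raise MalformedFileError(
                f"line {line_num}: expected {len(attributes)} fields, "
                f"got {len(fields)}"
            )
        rows.append(tuple(MISSING_TOKEN if f.strip() == "" else f.strip() for f in fields))
    return Relation(name=name, attributes=attributes, rows=tuple(rows))


def read_relation(
    path: str | Path,
    separator: Optional[str] = None,
    *,
    allow_pickle: bool = False,
) -> Relation:
    """Read a delimited text file (or, optionally, a pickled DataFrame).

    The first row becomes the attribute schema and the remaining rows the
    tuples.  Leading/trailing whitespace is stripped from every cell and
    empty cells become :data:`MISSING_TOKEN`.  When ``separator`` is not
    given it is auto-detected from the first sampled lines.

    The ``.pkl`` input is feature-gated behind ``allow_pickle=True``; the
    text formats are canonical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == PICKLE_SUFFIX:
        if not allow_pickle:
            raise MalformedFileError(
                "pickled input is disabled; pass allow_pickle=True to enable it"
            )
        return _read_pickled(path)
    if suffix not in TEXT_SUFFIXES:
        raise MalformedFileError(
            f"unsupported extension {suffix!r}: expected .csv, .txt or .pkl"
        )
    text = path.read_text(encoding="utf-8")
    if text.strip() == "":
        raise MalformedFileError(f"{path}: file is empty")
    if separator is None:
        separator = detect_separator(text.splitlines())
    parsed: list[tuple[int, list[str]]] = []
    if separator is None:
        for i, line in enumerate(text.splitlines(), start=1):
            if line.strip() == "":
                continue
            parsed.append((i, [line]))
    else:
        reader = csv.reader(io.StringIO(text), delimiter=separator)
        for fields in reader:
            if not fields:
                continue
            parsed.append((reader.line_num, fields))
    return _relation_from_rows(path.stem, parsed)


def _read_pickled(path: Path) -> Relation:
    import pandas as pd

    frame = pd.read_pickle(path)
    attributes = tuple(str(c).strip() for c in frame.columns)
    rows = tuple(
        tuple(
            MISSING_TOKEN if pd.isna(v) else str(v).strip() for v in record
        )
        for record in frame.itertuples(index=False, name=None)
    )
    return _relation_from_rows(path.stem, [(0, list(attributes))] + [
        (i + 1, list(r)) for i, r in enumerate(rows)
    ])


def write_relation(
    relation: Relation, path: str | Path, separator: str = ","
) -> None:
    """Serialize a relation as delimited text (header row first).

    Writing and re-reading yields an identical schema and identical rows.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=separator, lineterminator="\n")
        writer.writerow(relation.attributes)
        writer.writerows(relation.rows)


def relation_to_csv(relation: Relation, separator: str = ",") -> str:
    """Render a relation as a delimited text string."""
    buffer = io.StringIO()
    writer = csv.writer(buffer, delimiter=separator, lineterminator="\n")
    writer.writerow(relation.attributes)
    writer.writerows(relation.rows)
    return buffer.getvalue()
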