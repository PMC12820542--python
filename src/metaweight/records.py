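"""Study-level path records: data model, CSV I/O, harmonization, grouping.

A *path record* is one examined predictor→outcome relationship from one
primary study dataset: its standardized coefficient (β, optional), sample
size, binary significance label as reported by the primary study, and a
country label. Different primary studies name the same construct
differently ("perceived usefulness" vs "performance expectancy"); a
:class:`MergeMap` harmonizes names before records are grouped per path.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import (
    ConfigurationError,
    DuplicateRecordError,
    RowParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Reserved country label for datasets pooled over several countries.
MULTI_COUNTRY = "multiple"

#: Largest |β| accepted without a transcription warning. Standardized
#: coefficients can legitimately exceed 1 (suppression effects), but values
#: beyond this bound almost always indicate a transcription slip.
BETA_FLAG_THRESHOLD = 1.2

# logical field -> default CSV column name
DEFAULT_COLUMNS: Mapping[str, str] = {
    "dataset_id": "dataset_id",
    "paper_id": "paper_id",
    "predictor": "predictor",
    "outcome": "outcome",
    "beta": "beta",
    "n": "n",
    "significant": "significant",
    "country": "country",
    "theory_tags": "theory_tags",
}

MANDATORY_FIELDS = ("dataset_id", "predictor", "outcome", "n", "significant")

_TRUE_LABELS = {"significant", "1", "true", "yes"}
_FALSE_LABELS = {"nonsignificant", "non-significant", "0", "false", "no"}


@dataclass(frozen=True)
class PathRecord:
    """One examined predictor→outcome relationship from one dataset."""

    dataset_id: str
    predictor: str
    outcome: str
    n: int
    significant: bool
    beta: float | None = None
    country: str | None = None
    paper_id: str | None = None
    theory_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n < 1:
            raise RowParseError(
                f"sample size must be a positive integer, got {self.n!r}"
            )
        if self.beta is not None:
            if not math.isfinite(self.beta):
                raise RowParseError(f"beta must be finite, got {self.beta!r}")
            if abs(self.beta) > BETA_FLAG_THRESHOLD:
                warnings.warn(
                    f"|beta|={abs(self.beta):.3f} exceeds "
                    f"{BETA_FLAG_THRESHOLD}; possible transcription error "
                    f"in dataset {self.dataset_id!r}",
                    stacklevel=2,
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dataset_id, self.predictor, self.outcome)


@dataclass(frozen=True)
class MergeMap:
    """Many-to-one mapping from construct aliases to canonical names."""

    mapping: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MergeMap":
        mapping: dict[str, str] = {}
        for alias, canonical in pairs:
            alias = alias.strip()
            canonical = canonical.strip()
            if alias in mapping and mapping[alias] != canonical:
                raise ConfigurationError(
                    f"alias {alias!r} maps to both {mapping[alias]!r} "
                    f"and {canonical!r}"
                )
            mapping[alias] = canonical
        for alias, canonical in mapping.items():
            if alias == canonical:
                raise ConfigurationError(
                    f"alias {alias!r} maps to itself; drop the row"
                )
        return cls(mapping=dict(mapping))

    def resolve(self, name: str) -> str:
        """Single-step lookup: no transitive closure."""
        return self.mapping.get(name, name)


@dataclass(frozen=True)
class PathGroup:
    """All records for one (predictor, outcome) path, with S/E counts."""

    predictor: str
    outcome: str
    records: tuple[PathRecord, ...]

    @property
    def S(self) -> int:
        """Number of records whose primary study reported significance."""
        return sum(1 for r in self.records if r.significant)

    @property
    def E(self) -> int:
        """Total number of examinations of this path."""
        return len(self.records)


def _parse_significance(raw: str, row: int) -> bool:
    label = raw.strip().lower()
    if label in _TRUE_LABELS:
        return True
    if label in _FALSE_LABELS:
        return False
    raise RowParseError(
        f"row {row}: unrecognised significance label {raw!r} "
        "(expected significant/nonsignificant or 1/0)",
        row=row,
    )


def read_path_records(
    source: str | Path | TextIO,
    columns: Mapping[str, str] | None = None,
) -> list[PathRecord]:
    """Read path records from a comma-separated UTF-8 table.

    Parameters
    ----------
    source
        Path or open text stream. A header row is mandatory.
    columns
        Optional overrides of the default column names, keyed by logical
        field name (see ``DEFAULT_COLUMNS``).

    Raises
    ------
    SchemaError
        if a mandatory column is absent from the header.
    RowParseError
        if a sample size or beta fails to parse; carries the row number.
    DuplicateRecordError
        if (dataset_id, predictor, outcome) repeats.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, newline="", encoding="utf-8")
        close = True
    else:
        stream, close = source, False
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return []
        header = set(reader.fieldnames)
        for fieldname in MANDATORY_FIELDS:
            if colmap[fieldname] not in header:
                raise SchemaError(
                    f"mandatory column {colmap[fieldname]!r} missing from header"
                )
        records: list[PathRecord] = []
        seen: set[tuple[str, str, str]] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw_n = (row.get(colmap["n"]) or "").strip()
            try:
                n = int(raw_n)
            except ValueError:
                raise RowParseError(
                    f"row {i}: non-numeric sample size {raw_n!r}", row=i
                ) from None
            raw_beta = (row.get(colmap["beta"]) or "").strip()
            if raw_beta == "":
                beta = None
            else:
                try:
                    beta = float(raw_beta)
                except ValueError:
                    raise RowParseError(
                        f"row {i}: non-numeric beta {raw_beta!r}", row=i
                    ) from None
            raw_tags = (row.get(colmap["theory_tags"]) or "").strip()
            tags = frozenset(t.strip() for t in raw_tags.split(";") if t.strip())
            record = PathRecord(
                dataset_id=(row[colmap["dataset_id"]] or "").strip(),
                predictor=(row[colmap["predictor"]] or "").strip(),
                outcome=(row[colmap["outcome"]] or "").strip(),
                n=n,
                significant=_parse_significance(row[colmap["significant"]], i),
                beta=beta,
                country=(row.get(colmap["country"]) or "").strip() or None,
                paper_id=(row.get(colmap["paper_id"]) or "").strip() or None,
                theory_tags=tags,
            )
            if record.key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for {record.key}"
                )
            seen.add(record.key)
            records.append(record)
        return records
    finally:
        if close:
            stream.close()


def write_path_records(
    records: Sequence[PathRecord], dest: str | Path | TextIO
) -> None:
    """Write records as CSV with the default column names (round-trips
    with :func:`read_path_records`)."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", newline="", encoding="utf-8")
        close = True
    else:
        stream, close = dest, False
    try:
        writer = csv.writer(stream)
        writer.writerow(DEFAULT_COLUMNS.values())
        for r in records:
            writer.writerow(
                [
                    r.dataset_id,
                    r.paper_id or "",
                    r.predictor,
                    r.outcome,
                    "" if r.beta is None else repr(r.beta),
                    r.n,
                    "significant" if r.significant else "nonsignificant",
                    r.country or "",
                    ";".join(sorted(r.theory_tags)),
                ]
            )
    finally:
        if close:
            stream.close()


def read_merge_map(source: str | Path | TextIO) -> MergeMap:
    """Read an alias→canonical merge map from a two-column CSV
    (columns ``alias``, ``canonical``)."""
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, newline="", encoding="utf-8")
        close = True
    else:
        stream, close = source, False
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None or not {"alias", "canonical"} <= set(
            reader.fieldnames
        ):
            raise SchemaError("merge map needs columns 'alias' and 'canonical'")
        return MergeMap.from_pairs(
            (row["alias"], row["canonical"]) for row in reader
        )
    finally:
        if close:
            stream.close()


def canonicalize(
    records: Sequence[PathRecord], merge_map: MergeMap
) -> list[PathRecord]:
    """Replace predictor/outcome aliases by canonical construct names.

    Single-pass: an alias is replaced by its mapped canonical name exactly
    once; chains are not followed. Unmatched names pass through unchanged.
    Record count is preserved.
    """
    out: list[PathRecord] = []
    unmatched: set[str] = set()
    for r in records:
        pred = merge_map.resolve(r.predictor)
        outc = merge_map.resolve(r.outcome)
        for name in (r.predictor, r.outcome):
            if name not in merge_map.mapping:
                unmatched.add(name)
        if pred != r.predictor or outc != r.outcome:
            r = replace(r, predictor=pred, outcome=outc)
        out.append(r)
    if unmatched:
        logger.debug("constructs passed through unmerged: %s", sorted(unmatched))
    return out


def group_paths(
    records: Sequence[PathRecord], min_examinations: int = 3
) -> list[PathGroup]:
    """Group records per (predictor, outcome) path and keep paths examined
    at least ``min_examinations`` times (default 3, the inclusion rule for
    both the weight analysis and the meta-analysis).

    Excluded paths are logged with their counts. Output is deterministically
    ordered by (outcome, predictor).
    """
    if min_examinations < 1:
        raise ConfigurationError("min_examinations must be >= 1")
    buckets: dict[tuple[str, str], list[PathRecord]] = {}
    for r in records:
        buckets.setdefault((r.predictor, r.outcome), []).append(r)
    groups: list[PathGroup] = []
    for (pred, outc), recs in sorted(
        buckets.items(), key=lambda kv: (kv[0][1], kv[0][0])
    ):
        group = PathGroup(predictor=pred, outcome=outc, records=tuple(recs))
        if group.E >= min_examinations:
            groups.append(group)
        else:
            logger.info(
                "excluding path %s -> %s: examined %d time(s), below %d",
                pred,
                outc,
                group.E,
                min_examinations,
            )
    return groups


def records_to_csv_text(records: Sequence[PathRecord]) -> str:
    """Serialize records to a CSV string (convenience for manifests/tests)."""
    buf = io.StringIO()
    write_path_records(records, buf)
    return buf.getvalue()
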