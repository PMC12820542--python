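"""Packaged fixtures and corpus-reconstruction helpers.

Two small tables ship with the package:

* ``table5_pe_bi.csv`` — the 77 study-level effects for the performance
  expectancy → behavioral intention path, on the Fisher-z scale, with the
  reported standard error, sample size, significance label and country.
* ``table3_counts.csv`` — the significant/nonsignificant/total counts for
  the 67 paths examined at least 3 times, across the six outcome
  constructs.

Effect points derive their standard error from the sample size
(SE = 1/√(n−3)) rather than from the table's 3-decimal SE column: the
full-precision SE reproduces the published Egger regression and subgroup
results, the rounded column does not.
"""

from __future__ import annotations

import csv
from importlib import resources
from math import sqrt

from .records import PathRecord
from .transforms import EffectPoint


def _read_packaged(name: str) -> list[dict]:
    text = resources.files("metaweight.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def load_pe_bi_effects(se_from_n: bool = True) -> list[EffectPoint]:
    """The 77 Fisher-z effects for performance expectancy → behavioral
    intention (32 from China, 45 from other countries).

    ``se_from_n=False`` uses the printed 3-decimal SE column instead of
    recomputing 1/√(n−3); pooled results then shift in the third decimal.
    """
    effects = []
    for i, row in enumerate(_read_packaged("table5_pe_bi.csv"), start=1):
        n = int(row["n"])
        se = 1.0 / sqrt(n - 3) if se_from_n else float(row["se_z"])
        effects.append(
            EffectPoint(
                dataset_id=f"T5-{i:02d}",
                z=float(row["effect_z"]),
                se_z=se,
                n=n,
                significant=row["significance"] == "significant",
                country=row["country"],
            )
        )
    return effects


def load_path_counts() -> list[dict]:
    """Path-level S/E counts: one dict per path with keys outcome,
    predictor, significant, nonsignificant, total (ints parsed)."""
    rows = []
    for row in _read_packaged("table3_counts.csv"):
        rows.append(
            {
                "outcome": row["outcome"],
                "predictor": row["predictor"],
                "significant": int(row["significant"]),
                "nonsignificant": int(row["nonsignificant"]),
                "total": int(row["total"]),
            }
        )
    return rows


def records_from_counts(
    counts: list[dict] | None = None, n: int = 200
) -> list[PathRecord]:
    """Reconstruct a corpus of path records from S/E counts.

    For each path, emits S significant and E − S nonsignificant records
    (β absent, placeholder sample size): enough structure for the weight
    analysis, which depends only on the labels.
    """
    counts = counts if counts is not None else load_path_counts()
    records: list[PathRecord] = []
    for row in counts:
        for j in range(row["total"]):
            records.append(
                PathRecord(
                    dataset_id=(
                        f"{row['predictor']}->{row['outcome']}#{j:03d}"
                    ),
                    predictor=row["predictor"],
                    outcome=row["outcome"],
                    n=n,
                    significant=j < row["significant"],
                )
            )
    return records
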