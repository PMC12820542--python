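"""Synthetic study corpora with the random-effects structure the analysis
assumes.

Each simulated study i draws a true Fisher-z effect
z_i ~ Normal(atanh(true_r), τ²), a sample size n_i uniform on n_range, and
an observed effect z_obs ~ Normal(z_i, 1/(n_i − 3)). The study's reported
standardized coefficient inverts the Peterson–Brown conversion
(β = tanh(z_obs) − 0.05), so a round trip through the pipeline's β → r → z
path is exact. Significance labels come from the two-tailed Fisher-z test
at α = .05 — a deliberate stand-in for the heterogeneous tests of real
primary studies that makes statistical power analytically checkable.
Selective publication is a one-parameter censoring model: each
nonsignificant study is suppressed with probability ``bias_prob``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .records import PathRecord

Z_CRIT = 1.959964  # two-tailed 5% normal critical value


@dataclass(frozen=True)
class CorpusSpec:
    """Data-generating conditions for one synthetic corpus.

    Defaults mirror the observed corpus for the most-examined path:
    mean effect 0.34 on the correlation scale, between-study SD 0.25 on
    the Fisher-z scale, 77 studies with sample sizes spanning 67–1292.
    """

    true_r: float = 0.34
    tau: float = 0.25
    n_studies: int = 77
    n_range: tuple[int, int] = (67, 1292)
    bias_prob: float = 0.0
    group_specs: tuple[tuple[str, float, int], ...] | None = None
    predictor: str = "performance expectancy"
    outcome: str = "behavioral intention"
    seed: int = 0

    def __post_init__(self):
        if not abs(self.true_r) < 1:
            raise ConfigurationError(f"|true_r| must be < 1, got {self.true_r}")
        if self.tau < 0:
            raise ConfigurationError(f"tau must be >= 0, got {self.tau}")
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        lo, hi = self.n_range
        if lo < 10 or hi < lo:
            raise ConfigurationError(
                f"n_range must satisfy 10 <= min <= max, got {self.n_range}"
            )
        if not 0 <= self.bias_prob <= 1:
            raise ConfigurationError(
                f"bias_prob must be in [0, 1], got {self.bias_prob}"
            )
        if self.group_specs is not None:
            for label, r, k in self.group_specs:
                if not abs(r) < 1 or k < 1:
                    raise ConfigurationError(
                        f"bad group spec ({label!r}, {r}, {k})"
                    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _simulate_batch(
    rng: np.random.Generator,
    true_r: float,
    spec: CorpusSpec,
    n_studies: int,
    country: str | None,
    id_prefix: str,
) -> list[PathRecord]:
    mu = math.atanh(true_r)
    records: list[PathRecord] = []
    for i in range(n_studies):
        z_true = rng.normal(mu, spec.tau)
        n_i = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        se = 1.0 / math.sqrt(n_i - 3)
        z_obs = rng.normal(z_true, se)
        significant = abs(z_obs) / se > Z_CRIT
        if not significant and rng.random() < spec.bias_prob:
            continue  # suppressed: never enters the corpus
        records.append(
            PathRecord(
                dataset_id=f"{id_prefix}{i:04d}",
                predictor=spec.predictor,
                outcome=spec.outcome,
                n=n_i,
                significant=bool(significant),
                beta=math.tanh(z_obs) - 0.05,
                country=country,
            )
        )
    return records


def generate_corpus(spec: CorpusSpec) -> list[PathRecord]:
    """Generate one corpus of path records; bit-reproducible given the seed.

    With ``group_specs`` present, each (label, true_r, n_studies) group is
    generated with its own mean effect and carries ``label`` as country.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.group_specs is None:
        return _simulate_batch(
            rng, spec.true_r, spec, spec.n_studies, None, "sim-"
        )
    records: list[PathRecord] = []
    for label, true_r, n_studies in spec.group_specs:
        records.extend(
            _simulate_batch(
                rng, true_r, spec, n_studies, label, f"sim-{label}-"
            )
        )
    return records


def generate_theory_corpus(
    edge_specs: Sequence[tuple[str, str, float, int]],
    defaults: CorpusSpec | None = None,
) -> list[PathRecord]:
    """Concatenate per-edge corpora for a list of theory paths.

    Each edge spec is (predictor, outcome, true_r, n_studies) with
    n_studies ≥ 3 so every edge survives the inclusion rule. Edge streams
    draw from seeds spawned deterministically from ``defaults.seed``.
    """
    defaults = defaults or CorpusSpec()
    seen: set[tuple[str, str]] = set()
    for pred, outc, _r, k in edge_specs:
        if (pred, outc) in seen:
            raise ConfigurationError(f"duplicate edge spec {pred!r} -> {outc!r}")
        if k < 3:
            raise ConfigurationError(
                f"edge {pred!r} -> {outc!r} needs n_studies >= 3, got {k}"
            )
        seen.add((pred, outc))
    records: list[PathRecord] = []
    children = np.random.SeedSequence(defaults.seed).spawn(len(edge_specs))
    for child, (pred, outc, true_r, k) in zip(children, edge_specs):
        rng = np.random.default_rng(child)
        edge_spec = replace(
            defaults,
            true_r=true_r,
            n_studies=k,
            predictor=pred,
            outcome=outc,
            group_specs=None,
        )
        records.extend(
            _simulate_batch(
                rng, true_r, edge_spec, k, None, f"sim-{pred[:12]}-{outc[:12]}-"
            )
        )
    return records
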