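"""Fixed- and random-effects pooling of Fisher-z effects.

Fixed-effect pooling weights each study by its inverse variance
w_i = 1/SE_i²; heterogeneity is measured by Cochran's
Q = Σ w_i (z_i − ẑ)² and expressed as I² = max(0, (Q − (k−1))/Q) × 100.
Between-study variance τ² is estimated by the one-step DerSimonian–Laird
moment estimator

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),

and the random-effects estimate re-weights by w*_i = 1/(SE_i² + τ²).
Confidence intervals and two-tailed p-values use the standard normal
distribution; pooled effects are reported back-transformed to the
correlation metric via tanh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .transforms import EffectPoint


@dataclass(frozen=True)
class StudyContribution:
    """Per-study weights and Q component under the fixed-effect model."""

    dataset_id: str
    w_fixed: float
    w_random: float
    q_component: float


@dataclass(frozen=True)
class FixedResult:
    z_fixed: float
    Q: float
    contributions: tuple[StudyContribution, ...]


@dataclass(frozen=True)
class PoolResult:
    """Random-effects pooling summary for one path."""

    k: int
    z_fixed: float
    Q: float
    tau2: float
    z_random: float
    se_random: float
    ci_z: tuple[float, float]
    zscore: float
    p: float
    i2: float
    contributions: tuple[StudyContribution, ...]

    @property
    def r(self) -> float:
        """Pooled effect back-transformed to the correlation metric."""
        return math.tanh(self.z_random)

    @property
    def ci_r(self) -> tuple[float, float]:
        return (math.tanh(self.ci_z[0]), math.tanh(self.ci_z[1]))


def _arrays(effects: Sequence[EffectPoint]) -> tuple[np.ndarray, np.ndarray]:
    z = np.array([e.z for e in effects], dtype=float)
    se = np.array([e.se_z for e in effects], dtype=float)
    return z, se


def pool_fixed(effects: Sequence[EffectPoint]) -> FixedResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q.

    Requires k ≥ 2 effects with positive standard errors. The per-study
    Q components in the result sum to Q exactly.
    """
    if len(effects) < 2:
        raise InsufficientDataError(
            f"fixed-effect pooling needs k >= 2 effects, got {len(effects)}"
        )
    z, se = _arrays(effects)
    w = 1.0 / se**2
    z_fixed = float(np.sum(w * z) / np.sum(w))
    q_components = w * (z - z_fixed) ** 2
    contributions = tuple(
        StudyContribution(
            dataset_id=e.dataset_id,
            w_fixed=float(wi),
            w_random=float("nan"),  # filled by pool_random
            q_component=float(qi),
        )
        for e, wi, qi in zip(effects, w, q_components)
    )
    return FixedResult(
        z_fixed=z_fixed, Q=float(np.sum(q_components)), contributions=contributions
    )


def dl_tau2(effects: Sequence[EffectPoint], Q: float | None = None) -> float:
    """One-step DerSimonian–Laird moment estimate of τ², truncated at 0.

    ``Q`` may be supplied from a previous :func:`pool_fixed` on the same
    effects; otherwise it is recomputed.
    """
    if Q is None:
        Q = pool_fixed(effects).Q
    z, se = _arrays(effects)
    k = len(effects)
    w = 1.0 / se**2
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        raise DomainError(
            "degenerate DerSimonian-Laird denominator: all weight is "
            "concentrated in one study"
        )
    return max(0.0, (Q - (k - 1)) / denom)


def i_squared(Q: float, k: int) -> float:
    """I² heterogeneity percentage, max(0, (Q − (k−1))/Q) × 100."""
    if Q < 0:
        raise DomainError(f"Q must be >= 0, got {Q}")
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / Q) * 100.0


def pool_random(
    effects: Sequence[EffectPoint], conf_level: float = 0.95
) -> PoolResult:
    """DerSimonian–Laird random-effects pooling with CI, p, and I².

    The ``conf_level`` CI uses normal quantiles (1.959964 at 95%), matching
    z-score/two-tailed-P reporting rather than t quantiles.
    """
    if not 0 < conf_level < 1:
        raise DomainError(f"conf_level must be in (0, 1), got {conf_level}")
    fixed = pool_fixed(effects)
    tau2 = dl_tau2(effects, Q=fixed.Q)
    z, se = _arrays(effects)
    k = len(effects)
    w_star = 1.0 / (se**2 + tau2)
    z_random = float(np.sum(w_star * z) / np.sum(w_star))
    se_random = float(1.0 / math.sqrt(np.sum(w_star)))
    crit = float(stats.norm.ppf(0.5 + conf_level / 2.0))
    ci_z = (z_random - crit * se_random, z_random + crit * se_random)
    zscore = z_random / se_random
    p = float(2.0 * stats.norm.sf(abs(zscore)))
    contributions = tuple(
        StudyContribution(
            dataset_id=c.dataset_id,
            w_fixed=c.w_fixed,
            w_random=float(wi),
            q_component=c.q_component,
        )
        for c, wi in zip(fixed.contributions, w_star)
    )
    return PoolResult(
        k=k,
        z_fixed=fixed.z_fixed,
        Q=fixed.Q,
        tau2=tau2,
        z_random=z_random,
        se_random=se_random,
        ci_z=ci_z,
        zscore=zscore,
        p=p,
        i2=i_squared(fixed.Q, k),
        contributions=contributions,
    )


def china_vs_rest(effect: EffectPoint) -> str:
    """Default subgroup rule: studies conducted in China versus all others."""
    return "China" if effect.country == "China" else "Other countries"


def pool_subgroups(
    effects: Sequence[EffectPoint],
    grouping: Callable[[EffectPoint], str] = china_vs_rest,
    conf_level: float = 0.95,
) -> list[tuple[str, PoolResult]]:
    """Independent random-effects pooling per subgroup.

    τ² is estimated separately within each group (each group carries its
    own heterogeneity model). Groups are returned in sorted label order.
    """
    buckets: dict[str, list[EffectPoint]] = {}
    for e in effects:
        buckets.setdefault(grouping(e), []).append(e)
    out: list[tuple[str, PoolResult]] = []
    for label in sorted(buckets):
        members = buckets[label]
        if len(members) < 2:
            raise InsufficientDataError(
                f"subgroup {label!r} has only {len(members)} effect(s); "
                "k >= 2 required"
            )
        out.append((label, pool_random(members, conf_level=conf_level)))
    return out
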