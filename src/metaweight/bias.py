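"""Small-study / publication-bias diagnostics.

Three complementary diagnostics for a set of Fisher-z effects:

* **Egger regression** — unweighted OLS of the standard normal deviate
  z_i/SE_i on precision 1/SE_i. A nonzero intercept signals funnel
  asymmetry; by convention an intercept with p < .10 flags possible bias.
* **Funnel data** — the (effect, SE) scatter about the pooled estimate
  with pseudo-confidence contours (half-width = normal quantile × SE).
* **Trim-and-fill** — the Duval–Tweedie rank-based procedure estimating
  the number k0 of studies missing from one flank of the funnel, imputing
  their mirror images, and re-pooling for a bias-adjusted estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    ConvergenceError,
    InsufficientDataError,
    SingularDesignError,
)
from .pooling import PoolResult, pool_fixed, pool_random
from .transforms import EffectPoint

EGGER_ALPHA = 0.10  # significance threshold flagging funnel asymmetry


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    t_intercept: float
    t_slope: float
    df: int
    p_intercept: float
    p_slope: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]

    @property
    def asymmetric(self) -> bool:
        """True when the intercept is significant at the p < .10 rule."""
        return self.p_intercept < EGGER_ALPHA


@dataclass(frozen=True)
class FunnelData:
    points: tuple[tuple[float, float], ...]  # (effect z, se)
    center: float
    levels: tuple[float, ...]
    criticals: tuple[float, ...]

    def half_width(self, level: float, se: float) -> float:
        """Contour half-width at a given SE: critical value × SE."""
        try:
            crit = self.criticals[self.levels.index(level)]
        except ValueError:
            raise ConfigurationError(f"no contour at level {level}") from None
        return crit * se


@dataclass(frozen=True)
class TrimFillResult:
    k0: int
    side: str
    adjusted: PoolResult
    imputed: tuple[EffectPoint, ...]


def egger_test(effects: Sequence[EffectPoint]) -> EggerResult:
    """Egger regression: OLS of z_i/SE_i on 1/SE_i, with intercept.

    Coefficient standard errors are classical OLS; p-values and the 95%
    CIs use the t distribution with k − 2 degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientDataError(f"Egger test needs k >= 3, got {k}")
    z = np.array([e.z for e in effects])
    se = np.array([e.se_z for e in effects])
    snd = z / se
    precision = 1.0 / se
    if np.ptp(precision) == 0:
        raise SingularDesignError(
            "all precisions identical: Egger design matrix is singular"
        )
    model = sm.OLS(snd, sm.add_constant(precision)).fit()
    df = int(model.df_resid)
    ci = model.conf_int(alpha=0.05)
    return EggerResult(
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        t_intercept=float(model.tvalues[0]),
        t_slope=float(model.tvalues[1]),
        df=df,
        p_intercept=float(model.pvalues[0]),
        p_slope=float(model.pvalues[1]),
        ci_intercept=(float(ci[0][0]), float(ci[0][1])),
        ci_slope=(float(ci[1][0]), float(ci[1][1])),
    )


def funnel_data(
    effects: Sequence[EffectPoint],
    pooled: PoolResult,
    levels: Sequence[float] = (0.90, 0.95, 0.99),
) -> FunnelData:
    """Funnel-plot data: study points, pooled center, contour quantiles.

    Points are emitted in input order; plotting with SE increasing
    downward is a report-layer convention only.
    """
    criticals = tuple(float(stats.norm.ppf(0.5 + lv / 2.0)) for lv in levels)
    return FunnelData(
        points=tuple((e.z, e.se_z) for e in effects),
        center=pooled.z_random,
        levels=tuple(levels),
        criticals=criticals,
    )


def _estimate_k0(
    z: np.ndarray, center: float, estimator: str
) -> int:
    """Rank-based estimators of the number of missing studies.

    Works on the convention that the *right* flank holds the excess;
    callers mirror the data for left-flank trimming.
    """
    k = len(z)
    d = z - center
    ranks = stats.rankdata(np.abs(d))
    if estimator == "L0":
        t_n = float(np.sum(ranks[d > 0]))
        l0 = (4.0 * t_n - k * (k + 1)) / (2.0 * k - 1.0)
        return max(0, int(math.floor(l0 + 0.5)))
    if estimator == "R0":
        # length of the run of largest |deviations| that all lie right
        order = np.argsort(-ranks)
        gamma = 0
        for idx in order:
            if d[idx] > 0:
                gamma += 1
            else:
                break
        return max(0, gamma - 1)
    raise ConfigurationError(f"unknown trim-and-fill estimator {estimator!r}")


def _pick_side(effects: Sequence[EffectPoint]) -> str:
    """Choose the flank with excess studies by the sign of the rank
    correlation between centered effects and their standard errors."""
    z = np.array([e.z for e in effects])
    se = np.array([e.se_z for e in effects])
    center = pool_fixed(effects).z_fixed
    tau, _ = stats.kendalltau(z - center, se)
    return "right" if (tau is None or math.isnan(tau) or tau >= 0) else "left"


def trim_and_fill(
    effects: Sequence[EffectPoint],
    side: str = "auto",
    estimator: str = "L0",
    max_iter: int = 50,
    conf_level: float = 0.95,
) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill with a random-effects adjusted estimate.

    Iteratively: pool the untrimmed studies (fixed effect), rank all
    studies about that center, re-estimate k0, trim the k0 most extreme
    effects on the excess flank, and repeat until k0 stabilises. The k0
    trimmed effects are then mirrored about the final center
    (z → 2·center − z, same SE) and the augmented set is pooled with
    random effects (τ² re-estimated on the augmented set).
    """
    if len(effects) < 3:
        raise InsufficientDataError(
            f"trim-and-fill needs k >= 3, got {len(effects)}"
        )
    if side == "auto":
        side = _pick_side(effects)
    if side not in ("left", "right"):
        raise ConfigurationError(f"side must be left/right/auto, got {side!r}")
    sign = 1.0 if side == "right" else -1.0

    z = sign * np.array([e.z for e in effects])
    se = np.array([e.se_z for e in effects])
    k = len(z)
    order = np.argsort(z)  # ascending; extremes of the excess flank are last

    k0 = 0
    for _ in range(max_iter):
        keep = order[: k - k0] if k0 else order
        w = 1.0 / se[keep] ** 2
        center = float(np.sum(w * z[keep]) / np.sum(w))
        new_k0 = min(_estimate_k0(z, center, estimator), k - 1)
        if new_k0 == k0:
            break
        k0 = new_k0
    else:
        raise ConvergenceError(
            f"trim-and-fill did not stabilise in {max_iter} iterations",
            last_iterate=k0,
        )

    imputed: list[EffectPoint] = []
    if k0 > 0:
        donors = order[k - k0 :]
        for j, idx in enumerate(donors):
            imputed.append(
                EffectPoint(
                    dataset_id=f"imputed-{j:03d}",
                    z=sign * (2.0 * center - z[idx]),
                    se_z=float(se[idx]),
                    n=effects[idx].n,
                    significant=False,
                    country=None,
                )
            )
    adjusted = pool_random(list(effects) + imputed, conf_level=conf_level)
    return TrimFillResult(
        k0=k0, side=side, adjusted=adjusted, imputed=tuple(imputed)
    )
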