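"""Effect-size transforms: β → r, Fisher z, and standard errors.

Standardized regression coefficients are converted to approximate
correlations with the Peterson–Brown rule r = β + 0.05λ, then Fisher
z-transformed (z = atanh r) so that study effects are approximately normal
with standard error 1/√(n−3). All transforms are pure functions in double
precision; rounding happens only at the report layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConversionError, DomainError
from .records import PathRecord

#: Conversions landing outside this open interval are rejected rather than
#: clamped; at |r| ≥ 0.95 the β→r approximation is no longer credible.
R_LIMIT = 0.95


@dataclass(frozen=True)
class EffectPoint:
    """One study's effect on the Fisher-z scale with its standard error."""

    dataset_id: str
    z: float
    se_z: float
    n: int
    significant: bool
    country: str | None = None

    def __post_init__(self):
        if self.n < 4:
            raise DomainError(f"n must be >= 4 for a Fisher-z SE, got {self.n}")
        if not self.se_z > 0:
            raise DomainError(f"se_z must be positive, got {self.se_z}")

    @property
    def r(self) -> float:
        return math.tanh(self.z)


def beta_to_r(beta: float, lam: int = 1) -> float:
    """Peterson–Brown conversion r = β + 0.05·λ.

    λ=1 (the default) adds the 0.05 offset to every β; λ=0 is the identity,
    used under the original convention for negative coefficients.
    """
    if not math.isfinite(beta):
        raise DomainError(f"beta must be finite, got {beta!r}")
    if lam not in (0, 1):
        raise DomainError(f"lambda must be 0 or 1, got {lam!r}")
    r = beta + 0.05 * lam
    if abs(r) >= R_LIMIT:
        raise ConversionError(
            f"beta={beta} converts to r={r:.3f}, outside (-{R_LIMIT}, "
            f"{R_LIMIT}); no silent clamping is applied — correct the input "
            "or treat the value as already correlation/z scale"
        )
    return r


def r_to_z(r: float) -> float:
    """Fisher z transform, z = atanh(r) = ½·ln((1+r)/(1−r))."""
    if not abs(r) < 1:
        raise DomainError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def z_to_r(z: float) -> float:
    """Back-transform from Fisher z to the correlation metric, r = tanh(z)."""
    if not math.isfinite(z):
        raise DomainError(f"z must be finite, got {z!r}")
    return math.tanh(z)


def se_of_z(n: int) -> float:
    """Standard error of a Fisher-z effect, 1/√(n−3)."""
    if n <= 3:
        raise DomainError(f"n must be > 3, got {n}")
    return 1.0 / math.sqrt(n - 3)


def effect_from_record(record: PathRecord, lam: int = 1) -> EffectPoint:
    """Build a Fisher-z effect point from a path record carrying a β."""
    if record.beta is None:
        raise DomainError(
            f"record {record.dataset_id!r} has no beta; it can contribute to "
            "the weight analysis but not the meta-analysis"
        )
    z = r_to_z(beta_to_r(record.beta, lam=lam))
    return EffectPoint(
        dataset_id=record.dataset_id,
        z=z,
        se_z=se_of_z(record.n),
        n=record.n,
        significant=record.significant,
        country=record.country,
    )


def effects_from_records(
    records: Iterable[PathRecord], lam: int = 1
) -> list[EffectPoint]:
    """Convert every record with a usable β; records lacking β are skipped
    (they stay in the weight analysis only)."""
    return [
        effect_from_record(r, lam=lam) for r in records if r.beta is not None
    ]
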