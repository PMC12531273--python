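"""Minimum sample size for developing a binary clinical prediction model.

Implements the Pate & Riley style criterion based on the expected Cox–Snell
R², the number of candidate predictors, outcome prevalence, and a target
shrinkage factor:

    N = K / ( p (1 - p) · S · ln(1 - R²) )

The log term is negative, so the magnitude of the quotient is taken and
rounded up to the next whole patient.  A train/validation split of the
resulting minimum is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SampleSizeSpec", "SampleSizeResult", "riley_min_n"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the minimum-sample-size formula.

    Parameters
    ----------
    k_predictors:
        Number of candidate predictor parameters the model may use.
    prevalence:
        Expected outcome prevalence in the target population, in (0, 1).
    shrinkage:
        Desired global shrinkage factor S, in (0, 1); values close to 1
        demand larger samples (less shrinkage of coefficients).
    r2_cox_snell:
        Anticipated Cox–Snell R² of the model, in (0, 1).
    val_fraction:
        Fraction of the minimum sample held out for validation.
    """

    k_predictors: int
    prevalence: float
    shrinkage: float = 0.9
    r2_cox_snell: float = 0.05
    val_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.k_predictors < 1:
            raise ValueError("k_predictors must be a positive integer")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie strictly in (0, 1), got {self.prevalence}")
        if not 0.0 < self.shrinkage < 1.0:
            raise ValueError(f"shrinkage must lie strictly in (0, 1), got {self.shrinkage}")
        if not 0.0 < self.r2_cox_snell < 1.0:
            raise ValueError(
                f"r2_cox_snell must lie strictly in (0, 1), got {self.r2_cox_snell}"
            )
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_min: int
    n_validation: int
    n_training: int

    def __post_init__(self) -> None:
        assert self.n_validation + self.n_training == self.n_min


def riley_min_n(spec: SampleSizeSpec) -> SampleSizeResult:
    """Minimum total, validation, and training sample sizes for ``spec``.

    The raw quotient K / (p(1-p) S ln(1-R²)) is negative because
    ln(1-R²) < 0; its magnitude is rounded up (ceiling).  The validation
    size is the ceiling of ``val_fraction`` of the minimum, the training
    size the remainder.
    """
    p = spec.prevalence
    denom = p * (1.0 - p) * spec.shrinkage * math.log(1.0 - spec.r2_cox_snell)
    n_raw = abs(spec.k_predictors / denom)
    n_min = math.ceil(n_raw)
    n_validation = math.ceil(spec.val_fraction * n_min)
    return SampleSizeResult(
        n_min=n_min,
        n_validation=n_validation,
        n_training=n_min - n_validation,
    )
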