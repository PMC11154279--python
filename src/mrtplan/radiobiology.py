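"""Protracted-exposure corrections in the linear-quadratic (LQ) model.

At the low dose rates of a compact microbeam source, irradiations stretch to
many minutes and sublethal-damage repair during the exposure reduces the
biological effect of the quadratic dose term.  The Lea-Catcheside factor

    G(lambda, T) = 2/(lambda T) * [1 - (1 - exp(-lambda T)) / (lambda T)]

(for a constant dose rate over time T with mono-exponential repair at rate
lambda) discounts the beta term: BED = D (1 + G D / (alpha/beta)).  The
equivalent short-exposure dose is the acute dose with the same BED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_SERIES_THRESHOLD = 1e-4


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic model parameters for protraction corrections."""

    alpha_beta_gy: float = 2.0  # alpha/beta ratio of the tissue
    repair_rate_per_h: float = 0.5  # mono-exponential repair rate lambda
    exposure_time_h: float = 0.0

    def __post_init__(self):
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha/beta must be positive")
        if self.repair_rate_per_h < 0 or self.exposure_time_h < 0:
            raise ValueError("repair rate and exposure time must be >= 0")

    @property
    def g_factor(self) -> float:
        return lea_catcheside_g(self.repair_rate_per_h, self.exposure_time_h)


def lea_catcheside_g(repair_rate_per_h: float, exposure_time_h: float) -> float:
    """Lea-Catcheside protraction factor for a constant-dose-rate exposure.

    Returns exactly 1 in the instantaneous limit (series expansion below
    lambda*T = 1e-4 for numerical stability) and falls toward 2/(lambda*T)
    for long exposures.
    """
    if repair_rate_per_h < 0 or exposure_time_h < 0:
        raise ValueError("repair rate and exposure time must be >= 0")
    x = repair_rate_per_h * exposure_time_h
    if x < _SERIES_THRESHOLD:
        # G = 1 - x/3 + x^2/12 - ...
        return 1.0 - x / 3.0 + x * x / 12.0
    return (2.0 / x) * (1.0 - (1.0 - math.exp(-x)) / x)


def equivalent_short_dose(
    d_protracted_gy: float, g: float, alpha_beta_gy: float
) -> float:
    """Acute single-fraction dose with the same LQ biological effect.

    Solves  D_s^2 + (a/b) D_s - [(a/b) D_p + G D_p^2] = 0  for the positive
    root, i.e. the dose satisfying the BED equality
    ``D_s (1 + D_s/(a/b)) = D_p (1 + G D_p/(a/b))``.  At G = 1 (no repair)
    the result equals the protracted dose exactly.
    """
    if d_protracted_gy < 0:
        raise ValueError("dose must be non-negative")
    if not 0.0 <= g <= 1.0:
        raise ValueError("G must lie in [0, 1]")
    if alpha_beta_gy <= 0:
        raise ValueError("alpha/beta must be positive")
    ab = alpha_beta_gy
    disc = 0.25 * ab * ab + ab * d_protracted_gy + g * d_protracted_gy**2
    if disc < 0:  # impossible for valid inputs; guarded regardless
        raise ArithmeticError("negative discriminant in LQ root")
    return -0.5 * ab + math.sqrt(disc)
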