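"""Allometric scaling of the homeostatic time constant.

If somnogen production is proportional to total brain metabolic power and
clearance to a working surface area (glial, vascular, or otherwise), then
with brain mass scaling as body mass ``M_b^b`` and the surface as brain
mass to the power ``k`` (2/3 for simple-solid geometry, 1 for fully
convoluted/fractal surfaces), the clearance rate per unit volume scales as
``M_br^(k-1)`` and the homeostatic time constant as its inverse:

    chi ∝ M_br^(1-k) ∝ M_b^(b(1-k))

The production constant mu then scales as the metabolic power per unit
volume times chi, i.e. with exponent ``metabolic_volume_exponent + b(1-k)``
— close to zero under the defaults, which justifies holding mu fixed while
chi varies across species.

The module also provides log-log power-law fitting with a species-level
bootstrap for uncertainty, operating on per-species chi *intervals* (the
inversion of sleep metrics yields regions, not points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalingParams",
    "theoretical_chi_exponent",
    "mu_scaling_exponent",
    "fit_power_law",
]


@dataclass(frozen=True)
class ScalingParams:
    """Exponents and rate constants of the production/clearance derivation.

    b : brain mass ∝ (body mass)^b.
    metabolic_volume_exponent : brain metabolic power per unit volume
        ∝ (body mass)^this (negative: specific metabolic rate falls with size).
    k : working surface area ∝ (brain mass)^k, 2/3 <= k <= 1.
    clearance_coefficient : proportionality constant of clearance (1/h per
        unit surface ratio); scale only, does not affect exponents.
    state_production_factor : arousal-state multiplier on production
        (production is higher in wake than in sleep).
    """

    b: float = 0.7
    metabolic_volume_exponent: float = -0.14
    k: float = 2.0 / 3.0
    clearance_coefficient: float = 1.0
    state_production_factor: dict = field(
        default_factory=lambda: {"WAKE": 1.0, "SLEEP": 0.0}
    )

    def __post_init__(self) -> None:
        if not (2.0 / 3.0 <= self.k <= 1.0):
            raise ValueError("k must lie in [2/3, 1]")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.clearance_coefficient <= 0:
            raise ValueError("clearance_coefficient must be positive")
        if any(v < 0 for v in self.state_production_factor.values()):
            raise ValueError("state production factors must be >= 0")


def theoretical_chi_exponent(s: ScalingParams) -> float:
    """Body-mass exponent of the homeostatic time constant: b*(1-k).

    k = 2/3 (simple-solid surfaces) with b = 0.7 gives 0.23; k = 1
    (fractal surfaces) makes chi mass-independent.
    """
    return s.b * (1.0 - s.k)


def mu_scaling_exponent(s: ScalingParams) -> float:
    """Body-mass exponent of the production constant mu.

    mu ∝ (power per volume) * chi, so the exponent is
    ``metabolic_volume_exponent + b(1-k)``; near zero under the defaults,
    justifying the approximation of holding mu constant across species.
    """
    return s.metabolic_volume_exponent + theoretical_chi_exponent(s)


def fit_power_law(masses, chi_intervals, n_boot: int = 10_000,
                  seed: int | None = None) -> tuple[float, float]:
    """Power-law fit of chi vs body mass with bootstrap uncertainty.

    Point estimate: least-squares slope of log10(chi midpoint) on
    log10(mass), the chi midpoint taken in log space (geometric mean of the
    interval endpoints).  Uncertainty: ``n_boot`` bootstrap replicates, each
    resampling species with replacement and drawing one chi value per
    species uniformly in log space within its interval; returns
    ``(exponent, sd_of_exponent)``.
    """
    masses = np.asarray(masses, dtype=float)
    lo = np.asarray([c[0] for c in chi_intervals], dtype=float)
    hi = np.asarray([c[1] for c in chi_intervals], dtype=float)
    n = masses.size
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.any(masses <= 0) or np.any(lo <= 0) or np.any(hi < lo):
        raise ValueError("masses and chi intervals must be positive with lo <= hi")
    lx = np.log10(masses)
    if np.ptp(lx) <= 0:
        raise ValueError("degenerate mass spread: all masses equal")
    llo, lhi = np.log10(lo), np.log10(hi)
    lmid = 0.5 * (llo + lhi)

    slope = float(np.polyfit(lx, lmid, 1)[0])

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(lx[idx]) > 0:
                break
        ly = llo[idx] + rng.random(n) * (lhi[idx] - llo[idx])
        boots[i] = np.polyfit(lx[idx], ly, 1)[0]
    return slope, float(boots.std(ddof=1))
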