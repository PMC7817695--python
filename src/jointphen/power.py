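"""Group-size and minimum-detectable-effect calculations for the screen.

The per-group animal count N needed to detect an effect d with dispersion
sigma (SD for normal parameters, MAD for non-normal ones) at two-sided
level alpha and target power follows

    N = 2 * (z_{1-alpha/2} + z_{1-beta})^2 * sigma^2 / d^2

where the squared z-sum is the *power index* (7.85 at alpha = 0.05 and
80% power).  At an effect of two dispersions, four animals per group
suffice at 80% power, which is the screen's design point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerSpec", "power_index", "required_n", "minimum_detectable_effect"]


@dataclass
class PowerSpec:
    alpha: float = 0.05  # two-sided level
    power: float = 0.80  # target power (1 - beta)
    dispersion: float = 1.0  # sigma, or MAD for non-normal parameters
    effect: float = 2.0  # same units as dispersion

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def power_index(alpha: float = 0.05, power: float = 0.80) -> float:
    """(z_{1-alpha/2} + z_{1-beta})^2; 7.85 at alpha = 0.05, power = 0.80."""
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    return float((norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)) ** 2)


def required_n(spec: PowerSpec) -> int:
    """Animals per group: ceil(2 * index * sigma^2 / d^2)."""
    if spec.effect <= 0:
        raise ValueError("effect must be positive")
    idx = power_index(spec.alpha, spec.power)
    return int(math.ceil(2.0 * idx * spec.dispersion**2 / spec.effect**2))


def minimum_detectable_effect(
    n: int, alpha: float = 0.05, power: float = 0.80, dispersion: float = 1.0
) -> float:
    """Smallest detectable effect at n per group: sigma * sqrt(2 * index / n)."""
    if n < 2:
        raise ValueError("need at least 2 animals per group")
    return float(dispersion * math.sqrt(2.0 * power_index(alpha, power) / n))
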