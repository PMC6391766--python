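"""Molecular-clock calibration and divergence/duplication dating.

The substitution rate ``k`` (per synonymous site per year) is fitted from
anchor pairs of known divergence time as ``k = mean(Ks) / (2 t)``, and Ks
values are converted to times with ``t = Ks / (2 k)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError

YEARS_PER_MY = 1e6


@dataclass(frozen=True)
class ClockCalibration:
    """A fitted substitution rate together with its calibration inputs."""

    ks_values: tuple[float, ...]
    t_cal_years: float
    k: float

    @property
    def mean_ks(self) -> float:
        return sum(self.ks_values) / len(self.ks_values)


@dataclass(frozen=True)
class DivergenceEstimate:
    ks: float
    t_years: float

    @property
    def t_mya(self) -> float:
        return self.t_years / YEARS_PER_MY


def calibrate_rate(ks_values: Sequence[float], t_cal_years: float) -> ClockCalibration:
    """Fit the clock rate from calibration Ks values and a known time (years).

    The mean Ks is divided by ``2 * t_cal``; an all-zero calibration yields
    ``k = 0`` with a warning (times are then undefined).
    """
    ks_values = tuple(float(x) for x in ks_values)
    if not ks_values:
        raise ConfigurationError("calibration requires at least one Ks value")
    if any(x < 0 for x in ks_values):
        raise ConfigurationError("calibration Ks values must be non-negative")
    if t_cal_years <= 0:
        raise ConfigurationError("calibration time must be positive")
    mean_ks = sum(ks_values) / len(ks_values)
    k = mean_ks / (2.0 * t_cal_years)
    if k == 0:
        warnings.warn(
            "degenerate calibration: mean Ks is zero, rate k = 0", stacklevel=2
        )
    return ClockCalibration(ks_values=ks_values, t_cal_years=float(t_cal_years), k=k)


def divergence_time(ks: float, calib: ClockCalibration) -> DivergenceEstimate:
    """Convert a Ks value to a divergence time ``t = Ks / (2 k)``."""
    if ks < 0:
        raise ConfigurationError("Ks must be non-negative")
    if calib.k <= 0:
        raise ConfigurationError("divergence time undefined for rate k = 0")
    return DivergenceEstimate(ks=float(ks), t_years=ks / (2.0 * calib.k))


def divergence_range(
    cross_group_ks: Iterable[float],
    calib: ClockCalibration,
    decimals: int = 1,
) -> tuple[float, float]:
    """(min, max) divergence time in MYA over a set of cross-group Ks values."""
    estimates = [divergence_time(ks, calib) for ks in cross_group_ks]
    if not estimates:
        raise ConfigurationError("divergence range requires at least one Ks value")
    times = sorted(e.t_mya for e in estimates)
    return (round(times[0], decimals), round(times[-1], decimals))
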