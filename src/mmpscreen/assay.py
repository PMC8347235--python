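"""Percent inhibition and one-parameter IC50 dose-response fitting.

The kinetic model is competitive-style fractional velocity,

    vi/vo = 1 / (1 + [I]/IC50),

where vo is the uninhibited initial velocity and vi the velocity at
inhibitor concentration [I].  IC50 is the only free parameter; there is no
Hill slope and no baseline.  A fit requires at least five distinct
concentrations whose measured inhibition lies between 10% and 90% — points
near 0% or 100% carry almost no information about IC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "InhibitionMeasurement",
    "IC50Fit",
    "percent_inhibition",
    "predict_velocity_ratio",
    "fit_ic50",
]


@dataclass(frozen=True)
class InhibitionMeasurement:
    """One dose point: concentration (uM) and measured vi/vo."""

    concentration: float
    velocity_ratio: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.velocity_ratio < 0:
            raise ValueError("velocity ratio must be >= 0")

    @property
    def inhibition_percent(self) -> float:
        return 100.0 * (1.0 - self.velocity_ratio)


@dataclass(frozen=True)
class IC50Fit:
    ic50: float  # uM
    sd: float  # uM, from the fit's curvature at the optimum
    n_points: int
    converged: bool


def percent_inhibition(vi: float, vo: float) -> float:
    """Percent inhibition 100*(1 - vi/vo) relative to the uninhibited control."""
    if vo <= 0:
        raise ValueError(f"control velocity vo must be > 0, got {vo}")
    return 100.0 * (1.0 - vi / vo)


def predict_velocity_ratio(ic50: float, concentration: float) -> float:
    """Model fractional velocity vi/vo = 1/(1 + [I]/IC50)."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return 1.0 / (1.0 + concentration / ic50)


def fit_ic50(measurements: Sequence[InhibitionMeasurement]) -> IC50Fit:
    """Least-squares fit of IC50 to vi/vo = 1/(1 + [I]/IC50).

    Only measurements whose inhibition lies in [10%, 90%] qualify, and at
    least five distinct qualifying concentrations are required.  The
    initial guess is the concentration whose inhibition is nearest 50%
    (where [I] = IC50 exactly).  The reported SD is the one-parameter fit
    uncertainty from the curvature at the optimum — not an
    inter-experiment SD.
    """
    qualifying = [
        m
        for m in measurements
        if 10.0 <= m.inhibition_percent <= 90.0
    ]
    distinct = sorted({m.concentration for m in qualifying})
    if len(distinct) < 5:
        raise ValueError(
            "IC50 determination requires at least five distinct "
            "concentrations with inhibition between 10% and 90%; got "
            f"{len(distinct)}"
        )
    conc = np.array([m.concentration for m in qualifying])
    ratio = np.array([m.velocity_ratio for m in qualifying])
    # initial guess: concentration closest to half-inhibition
    guess = conc[int(np.argmin(np.abs(ratio - 0.5)))]
    if guess <= 0:
        guess = float(np.median(conc[conc > 0]))

    def model(x, ic50):
        return 1.0 / (1.0 + x / ic50)

    converged = True
    try:
        popt, pcov = curve_fit(
            model, conc, ratio, p0=[guess], bounds=(1e-12, np.inf),
            maxfev=10000,
        )
    except RuntimeError:
        return IC50Fit(ic50=float("nan"), sd=float("nan"),
                       n_points=len(qualifying), converged=False)
    ic50 = float(popt[0])
    var = float(pcov[0, 0])
    sd = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else float("nan")
    return IC50Fit(ic50=ic50, sd=sd, n_points=len(qualifying),
                   converged=converged)
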