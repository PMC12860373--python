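"""Franz-diffusion permeation bookkeeping and CCK-8 viability math.

Two small formulas with exacting bookkeeping.

**Cumulative permeation.** In a Franz diffusion cell an aliquot of volume
``S`` is withdrawn from the receiver chamber at each sampling time and
replaced with fresh buffer, so the analyte measured later is diluted and
the raw concentrations understate the true permeated mass. The cumulative
amount permeated per unit diffusion area up to the n-th sampling is

    Q_s(n) = C_sn * V_s / A_s  +  sum_{i=1}^{n-1} C_si * S / A_s

with ``C_si`` the receiver concentration at sampling i, ``V_s`` the
receiver volume, ``A_s`` the effective diffusion area and ``S`` the aliquot
volume (1 mL per sampling by default). The correction sum restores the
analyte removed with earlier aliquots.

**Viability.** CCK-8 optical densities at 450 nm give

    viability % = 100 * (A_sample - A_blank) / (A_control - A_blank)

and IC10/IC50 are the concentrations producing 10 %/50 % inhibition,
obtained from a dose-response table by exact hit or log-linear
interpolation between the bracketing doses (dose series are geometric, so
interpolation is linear in log10 concentration; a linear mode is exposed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PermeationExperiment",
    "cumulative_permeation",
    "ViabilityInput",
    "viability",
    "DoseResponse",
    "estimate_ic",
    "ICNotEstimableError",
]

#: Default aliquot withdrawn (and replaced) per sampling, mL.
DEFAULT_ALIQUOT_ML = 1.0


@dataclass(frozen=True)
class PermeationExperiment:
    """One Franz-cell sampling series.

    times_h are the sampling times (strictly increasing, hours);
    concentrations_ug_ml the receiver concentrations at each sampling;
    receiver_volume_ml (V_s), area_cm2 (A_s) and aliquot_ml (S) complete
    the geometry.
    """

    times_h: tuple[float, ...]
    concentrations_ug_ml: tuple[float, ...]
    receiver_volume_ml: float
    area_cm2: float
    aliquot_ml: float = DEFAULT_ALIQUOT_ML

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.concentrations_ug_ml):
            raise ValueError("times and concentrations must have equal length")
        t = np.asarray(self.times_h, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing")
        c = np.asarray(self.concentrations_ug_ml, dtype=float)
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations_ug_ml must be finite and >= 0")
        if not self.receiver_volume_ml > 0:
            raise ValueError("receiver_volume_ml must be > 0")
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be > 0")
        if not 0 <= self.aliquot_ml <= self.receiver_volume_ml:
            raise ValueError("aliquot_ml must lie in [0, receiver_volume_ml]")


def cumulative_permeation(exp: PermeationExperiment) -> np.ndarray:
    """Cumulative permeated amount per unit area (µg/cm²) at each sampling.

    Applies the aliquot-replacement correction: the n-th value is the
    receiver content at sampling n plus everything carried away in the
    n-1 earlier aliquots, divided by the diffusion area.
    """
    c = np.asarray(exp.concentrations_ug_ml, dtype=float)
    removed = np.concatenate(([0.0], np.cumsum(c)[:-1])) * exp.aliquot_ml
    return (c * exp.receiver_volume_ml + removed) / exp.area_cm2


@dataclass(frozen=True)
class ViabilityInput:
    """CCK-8 optical densities at 450 nm: blank, untreated control, sample."""

    a_blank: float
    a_control: float
    a_sample: float

    def __post_init__(self) -> None:
        if self.a_control == self.a_blank:
            raise ValueError("degenerate assay: A_control equals A_blank")


def viability(v: ViabilityInput) -> float:
    """Cell viability in percent.

    Values outside [0, 100] are reported as-is (a warning flags them);
    clipping would hide assay problems such as proliferation above control
    or absorbance below blank.
    """
    pct = 100.0 * (v.a_sample - v.a_blank) / (v.a_control - v.a_blank)
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"viability {pct:.1f}% outside [0, 100]", stacklevel=2)
    return pct


class ICNotEstimableError(ValueError):
    """The target viability is never bracketed by the dose-response data."""


@dataclass(frozen=True)
class DoseResponse:
    """Ordered (concentration, mean viability %) pairs, one unit throughout."""

    concentrations: tuple[float, ...]
    viabilities_pct: tuple[float, ...]
    units: str = "mg/mL"

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.viabilities_pct):
            raise ValueError("concentrations and viabilities must have equal length")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def estimate_ic(dr: DoseResponse, level: float, log_scale: bool = True) -> float:
    """Concentration producing ``level`` percent inhibition (IC10, IC50...).

    The target viability is ``100 - level``. An exactly-hit tested
    concentration is returned as-is (first hit in dose order); otherwise
    the estimate interpolates between the first adjacent pair crossing the
    target from above, linearly in log10 concentration by default.
    """
    if not 0 < level < 100:
        raise ValueError("level must lie in (0, 100)")
    target = 100.0 - level
    conc = np.asarray(dr.concentrations, dtype=float)
    viab = np.asarray(dr.viabilities_pct, dtype=float)

    hits = np.flatnonzero(viab == target)
    if hits.size:
        return float(conc[hits[0]])

    for i in range(len(conc) - 1):
        v0, v1 = viab[i], viab[i + 1]
        if v0 > target > v1:  # first crossing from above
            frac = (v0 - target) / (v0 - v1)
            if log_scale:
                lc = np.log10(conc[i]) + frac * (np.log10(conc[i + 1]) - np.log10(conc[i]))
                return float(10.0**lc)
            return float(conc[i] + frac * (conc[i + 1] - conc[i]))
    raise ICNotEstimableError(
        f"target viability {target}% is never bracketed by the dose-response data"
    )
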