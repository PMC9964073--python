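"""Closed-form in-vitro / in-vivo evaluation metrics.

MTT viability percentage, apparent permeability across a cell monolayer,
withdrawal-corrected intrinsic dissolution rate, fold-change reporting at
printed precision, and non-compartmental PK analysis (linear trapezoid,
log-linear terminal slope) with relative bioavailability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ViabilityPlate",
    "PermeabilityAssay",
    "DissolutionProfile",
    "PKProfile",
    "PKParams",
    "cell_viability_percent",
    "apparent_permeability",
    "withdrawal_corrected_cumulative",
    "intrinsic_dissolution_rate",
    "fold_change",
    "nca",
    "auc_trapezoid",
    "relative_bioavailability",
]


@dataclass(frozen=True)
class ViabilityPlate:
    """Mean 570 nm absorbances of a treated group, blank, and negative control."""

    group_absorbance: float
    blank_absorbance: float
    negative_control_absorbance: float


def cell_viability_percent(plate: ViabilityPlate) -> float:
    """100 * (group - blank) / (negative control - blank)."""
    denom = plate.negative_control_absorbance - plate.blank_absorbance
    if denom <= 0:
        raise ValueError("invalid assay: negative control must exceed blank absorbance")
    return 100.0 * (plate.group_absorbance - plate.blank_absorbance) / denom


@dataclass(frozen=True)
class PermeabilityAssay:
    """Transport-assay quantities: flux in amount/time, area cm^2, donor conc."""

    flux: float
    area: float
    initial_conc: float


def apparent_permeability(assay: PermeabilityAssay, seconds_per_time_unit: float = 1.0) -> float:
    """Papp = flux / (area * C0), returned in cm/s.

    ``flux`` must be pre-converted to amount per time unit with the donor
    concentration in matching amount/volume units; when the flux time unit is
    not seconds, pass ``seconds_per_time_unit`` (e.g. 60 for per-minute flux).
    """
    if assay.area <= 0 or assay.initial_conc <= 0:
        raise ValueError("area and initial_conc must be > 0")
    if assay.flux < 0:
        raise ValueError("flux must be >= 0")
    return assay.flux / (assay.area * assay.initial_conc) / seconds_per_time_unit


@dataclass(frozen=True)
class DissolutionProfile:
    """Sampled dissolution concentrations from a constant-area disc assay."""

    times: tuple  # min, strictly increasing
    concentrations: tuple  # ug/mL as measured
    medium_volume: float = 500.0  # mL
    sample_volume: float = 5.0  # mL withdrawn and replaced per sample
    disc_area: float = 0.5  # cm^2

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) != len(c):
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or self.medium_volume <= 0 or self.disc_area <= 0:
            raise ValueError("concentrations, medium_volume and disc_area must be non-negative")
        if self.sample_volume < 0 or self.sample_volume >= self.medium_volume:
            raise ValueError("sample_volume must be in [0, medium_volume)")


def withdrawal_corrected_cumulative(profile: DissolutionProfile) -> np.ndarray:
    """Correct measured concentrations for sampled-and-replaced medium.

    C_corr[n] = C[n] + (Vs/V) * sum_{i<n} C[i], using the raw measured
    concentrations in the running sum.  Identity when sample_volume is 0.
    """
    c = np.asarray(profile.concentrations, dtype=float)
    ratio = profile.sample_volume / profile.medium_volume
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c + ratio * prior


def intrinsic_dissolution_rate(
    profile: DissolutionProfile, window: tuple[float, float] | None = None
) -> float:
    """OLS slope of withdrawal-corrected dissolved mass per disc area vs time.

    Returns mg/min/cm^2 for ug/mL concentrations, mL volume and minute times.
    """
    t = np.asarray(profile.times, dtype=float)
    c_corr = withdrawal_corrected_cumulative(profile)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, c_corr = t[mask], c_corr[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 points in the window for a regression slope")
    mass_mg = c_corr * profile.medium_volume / 1000.0  # ug -> mg
    per_area = mass_mg / profile.disc_area
    slope = np.polyfit(t, per_area, 1)[0]
    return float(slope)


def fold_change(a: float, b: float, decimals: int = 1) -> float:
    """a/b rounded half-up at the reported precision."""
    if b <= 0:
        raise ValueError("denominator must be > 0")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(a / b).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PKProfile:
    times: tuple  # h, strictly increasing
    concentrations: tuple
    dose: float = 1.0  # mg/kg
    subject_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) != len(c) or len(t) < 2:
            raise ValueError("need at least two aligned (time, concentration) samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start >= 0 and be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class PKParams:
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float | None
    ke: float | None
    t_half: float | None
    mrt: float | None


def auc_trapezoid(times, concentrations, t_start: float | None = None, t_end: float | None = None) -> float:
    """Linear trapezoidal AUC over [t_start, t_end] (defaults: full range)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t_start is None:
        t_start = t[0]
    if t_end is None:
        t_end = t[-1]
    mask = (t >= t_start) & (t <= t_end)
    return float(np.trapezoid(c[mask], t[mask]))


def nca(profile: PKProfile, terminal_points: int = 3) -> PKParams:
    """Non-compartmental summary of a concentration-time profile.

    Cmax/tmax by direct lookup; AUC0-t by linear trapezoid; ke as the
    negative OLS slope of ln C over the last ``terminal_points`` positive
    samples; AUC0-inf adds C_last/ke; AUMC gets the matching tail
    C_last*t_last/ke + C_last/ke^2 and MRT = AUMC0-inf/AUC0-inf.  A
    non-positive terminal slope leaves the extrapolated quantities as None.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = float(np.trapezoid(c, t))

    pos = np.flatnonzero(c > 0)
    if len(pos) < terminal_points or terminal_points < 2:
        raise ValueError(f"need >= {max(terminal_points, 2)} positive terminal samples")
    tail = pos[-terminal_points:]
    slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
    ke = -float(slope)
    if ke <= 0:
        return PKParams(cmax, tmax, auc_t, None, None, None, None)

    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])
    auc_inf = auc_t + c_last / ke
    aumc_t = float(np.trapezoid(t * c, t))
    aumc_inf = aumc_t + c_last * t_last / ke + c_last / ke**2
    return PKParams(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        ke=ke,
        t_half=math.log(2) / ke,
        mrt=aumc_inf / auc_inf,
    )


def relative_bioavailability(
    auc_test: float, auc_ref: float, dose_test: float = 1.0, dose_ref: float = 1.0
) -> float:
    """100 * (AUC_test/dose_test) / (AUC_ref/dose_ref), in percent."""
    if min(auc_test, auc_ref, dose_test, dose_ref) <= 0:
        raise ValueError("AUCs and doses must be > 0")
    return 100.0 * (auc_test / dose_test) / (auc_ref / dose_ref)
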