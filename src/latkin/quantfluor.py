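"""Quantitative fluorescence: intensities to molecule counts, detection
limits, FRAP and NFAT trace analytics.

Condensate copy numbers come from dividing a background-corrected cluster
intensity by the single-fluorophore intensity, after normalizing both by their
acquisition conditions (gain, laser power, exposure -- assumed linear in
intensity, a precondition that must be verified on the instrument):

    N_fl = (C_I / (C_gain C_power C_exposure)) / (S_I / (S_gain S_power S_exposure))

and scaling up by the unlabeled endogenous pool, N = (1 + alpha) N_fl, with
alpha the endogenous/exogenous expression ratio.  Because the fraction of
background protein participating in a cluster is unknown, the cluster
intensity is taken as the midpoint of the annulus-corrected net intensity and
the total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CalibrationModel",
    "ClusterMeasurement",
    "Grb2DetectionLimit",
    "cluster_intensity",
    "fluorescent_copy_number",
    "total_copy_number",
    "relative_size",
    "rescale_physiological",
    "expression_slope",
    "grb2_detection_limit",
    "FrapModel",
    "FrapFit",
    "fit_frap",
    "nfat_translocation_time",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Single-fluorophore intensity with its acquisition conditions.

    ``alpha`` is the endogenous/exogenous expression ratio (0.60 for the
    LAT-eGFP calibration line used throughout).
    """

    S_I: float
    S_gain: float = 1.0
    S_power: float = 1.0
    S_exposure: float = 1.0
    alpha: float = 0.60

    def __post_init__(self) -> None:
        if self.S_I <= 0:
            raise ValueError("single-fluorophore intensity must be positive")
        if min(self.S_gain, self.S_power, self.S_exposure) <= 0:
            raise ValueError("acquisition factors must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class ClusterMeasurement:
    """Annulus-background-corrected cluster intensities and conditions."""

    C_total: float
    C_net: float
    C_gain: float = 1.0
    C_power: float = 1.0
    C_exposure: float = 1.0
    background_per_um2: float | None = None

    def __post_init__(self) -> None:
        if self.C_net < 0 or self.C_total < self.C_net:
            raise ValueError("need C_total >= C_net >= 0")
        if min(self.C_gain, self.C_power, self.C_exposure) <= 0:
            raise ValueError("acquisition factors must be positive")


def cluster_intensity(m: ClusterMeasurement) -> float:
    """Midpoint of net and total intensity: C_I = (C_total + C_net) / 2.

    The net intensity is right if the cluster displaces no background protein,
    the total if it displaces all of it; the midpoint splits the unknown.
    """
    return 0.5 * (m.C_total + m.C_net)


def fluorescent_copy_number(m: ClusterMeasurement, cal: CalibrationModel) -> float:
    """Fluorescent molecules in a cluster, condition-normalized."""
    c_norm = cluster_intensity(m) / (m.C_gain * m.C_power * m.C_exposure)
    s_norm = cal.S_I / (cal.S_gain * cal.S_power * cal.S_exposure)
    return c_norm / s_norm


def total_copy_number(n_fluorescent: float, alpha: float) -> float:
    """Total molecules including the unlabeled pool: (1 + alpha) * N_fl."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return (1.0 + alpha) * n_fluorescent


def relative_size(total: float, net: float, background_per_um2: float) -> float:
    """Cluster size in um^2-equivalents of the local background density.

    RS = (total + net) / (2 * background intensity of 1 um^2); a value of 1
    means the cluster holds as many molecules as one square micron of
    background membrane.
    """
    if background_per_um2 <= 0:
        raise ValueError("background intensity must be positive")
    if net < 0 or total < net:
        raise ValueError("need total >= net >= 0")
    return (total + net) / (2.0 * background_per_um2)


def rescale_physiological(rs: float, density: float = 601.0) -> float:
    """Molecule count at a physiological membrane density (default 601 um^-2)."""
    if density <= 0:
        raise ValueError("density must be positive")
    return rs * density


def expression_slope(expression, condensate_size) -> tuple[float, float]:
    """Zero-intercept least-squares slope of condensate size vs expression.

    Returns (slope, se).  The zero intercept encodes that a cell expressing no
    LAT builds no condensate; the slope is the fraction of a cell's total LAT
    density recruited into a condensate-sized region.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(condensate_size, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate expression values (all zero)")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return slope, se


@dataclass(frozen=True)
class Grb2DetectionLimit:
    """Detection-limit arithmetic for a diffusive background of adapter protein."""

    background_equivalents: float
    detectable_excess: float
    fluorescent_bound: float
    total_bound: float

    def summary(self) -> str:
        return "\n".join([
            "Grb2 detection limit",
            "-" * 40,
            f"{'background equivalents':<26}{self.background_equivalents:>8.1f}",
            f"{'detectable excess':<26}{self.detectable_excess:>8.1f}",
            f"{'fluorescent bound (max)':<26}{self.fluorescent_bound:>8.1f}",
            f"{'total bound (max)':<26}{self.total_bound:>8.1f}",
        ])


def grb2_detection_limit(snr_threshold: float, bg_density: float,
                         window_area: float, endo_exo_ratio: float = 1.0
                         ) -> Grb2DetectionLimit:
    """How many adapter molecules can hide below the spot-detection limit.

    With SNR defined as (I_in - I_out)/I_out over an annulus, a detection
    window of ``window_area`` holds ``bg_density * window_area`` background
    "equivalents"; a spot at the SNR threshold corresponds to
    ``snr_threshold`` times that many excess molecules.  A *failure* to detect
    therefore bounds the fluorescent molecules present by equivalents +
    excess, and the total (labeled + unlabeled) by (1 + endo/exo ratio) times
    that.
    """
    if min(snr_threshold, bg_density, window_area) <= 0 or endo_exo_ratio < 0:
        raise ValueError("inputs must be positive (ratio >= 0)")
    equivalents = bg_density * window_area
    excess = snr_threshold * equivalents
    fluorescent = equivalents + excess
    total = fluorescent * (1.0 + endo_exo_ratio)
    return Grb2DetectionLimit(equivalents, excess, fluorescent, total)


# ---------------------------------------------------------------------------
# FRAP recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapFit:
    """Single-exponential FRAP recovery fit.

    Under the reaction-limited assumption the recovery rate equals the
    molecular off-rate within the structure -- a lower bound, since any
    diffusion limitation slows apparent recovery.
    """

    rate: float
    rate_se: float
    plateau: float
    plateau_se: float

    def summary(self) -> str:
        return "\n".join([
            "FRAP recovery fit (reaction-limited; rate is a lower-bound k_off)",
            "-" * 60,
            f"{'rate (1/s)':<14}{self.rate:>10.4f}  +/- {self.rate_se:.4f}",
            f"{'plateau':<14}{self.plateau:>10.4f}  +/- {self.plateau_se:.4f}",
        ])


class FrapModel:
    """Fit I(t) = plateau * (1 - exp(-k t)) to a post-bleach recovery trace."""

    def __init__(self, t, intensity):
        t = np.asarray(t, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if t.size != intensity.size or t.size < 5:
            raise ValueError("need matched traces with >= 5 points")
        self.t = t
        self.intensity = intensity

    def fit(self) -> FrapFit:
        span = self.intensity.max() - self.intensity.min()
        if span <= 0 or self.intensity[-5:].mean() <= self.intensity[:2].mean():
            raise ValueError("trace shows no recovery; cannot fit an off-rate")
        half_idx = np.argmax(self.intensity >= 0.5 * self.intensity[-5:].mean())
        k0 = np.log(2.0) / max(self.t[half_idx], self.t[1] - self.t[0])
        popt, pcov = optimize.curve_fit(
            lambda tt, k, a: a * (1.0 - np.exp(-k * tt)),
            self.t, self.intensity, p0=[k0, float(self.intensity[-5:].mean())],
            maxfev=10000,
        )
        if self.t.max() * popt[0] < 3.0 * np.log(2.0):
            raise ValueError("trace spans fewer than 3 recovery half-lives")
        perr = np.sqrt(np.diag(pcov))
        return FrapFit(float(popt[0]), float(perr[0]), float(popt[1]), float(perr[1]))


def fit_frap(trace: pd.DataFrame) -> FrapFit:
    """Fit a FRAP recovery table with columns ``t`` and ``intensity``."""
    return FrapModel(trace["t"].to_numpy(), trace["intensity"].to_numpy()).fit()


def nfat_translocation_time(nuclear, cytosolic, t=None) -> float | None:
    """First time the mean nuclear NFAT intensity exceeds the cytosolic one.

    Returns the crossing time (or frame index when no timebase is given), or
    None if the nuclear signal never rises above the cytosolic signal.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    cytosolic = np.asarray(cytosolic, dtype=float)
    if nuclear.shape != cytosolic.shape:
        raise ValueError("nuclear and cytosolic traces must share a timebase")
    above = np.nonzero(nuclear > cytosolic)[0]
    if above.size == 0:
        return None
    idx = int(above[0])
    if t is None:
        return float(idx)
    t = np.asarray(t, dtype=float)
    if t.shape != nuclear.shape:
        raise ValueError("timebase length mismatch")
    return float(t[idx])
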