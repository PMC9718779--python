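"""Photobleach-corrected binding kinetics from single-molecule event tables.

An observed single-molecule dwell ends either because the complex unbinds
(rate k_off) or because the dye bleaches (rate k_bleach); the observed dwell
marginal is exponential with rate k_obs = k_off + k_bleach.  The bleach rate is
measured independently from immobilized-spot survival series, the observed
rate from the event table, and the true binding kinetics follow by
subtraction: k_off = k_obs - k_bleach.

The per-cell pseudo on-rate k_on_cell absorbs receptor density and contact
area; with visible ligand density decaying by bleaching at k_b, the N binding
events accumulated over time t give

    k_on_cell = N / (sigma_L * (1/k_b) * (1 - e^{-k_b t})),

which reduces continuously to N / (sigma_L * t) as k_b -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpFit",
    "BleachModel",
    "OnRateEstimate",
    "BleachDecayModel",
    "ExponentialDwellModel",
    "estimate_bleach_rate",
    "fit_observed_dwell",
    "correct_dwell",
    "bleach_loss_fraction",
    "estimate_on_rate",
    "expected_events",
]


@dataclass(frozen=True)
class ExpFit:
    """Exponential dwell fit: rate (1/s), its SE, the mean dwell and n."""

    rate: float
    rate_se: float
    mean_dwell: float
    n: int
    n_censored: int = 0

    def summary(self) -> str:
        return "\n".join([
            "Exponential dwell fit",
            "-" * 40,
            f"{'events':<16}{self.n:>10d}  ({self.n_censored} right-censored)",
            f"{'rate (1/s)':<16}{self.rate:>10.5f}  +/- {self.rate_se:.5f}",
            f"{'mean dwell (s)':<16}{self.mean_dwell:>10.2f}"
            f"  +/- {self.mean_dwell * self.rate_se / self.rate:.2f}",
        ])


@dataclass(frozen=True)
class BleachModel:
    """Fitted photobleaching decay rate (1/s) and the frames used."""

    k_bleach: float
    frames_used: int
    k_bleach_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_bleach < 0:
            raise ValueError("k_bleach must be >= 0")


@dataclass(frozen=True)
class OnRateEstimate:
    """Per-cell pseudo on-rate estimate (um^2/s) with the cell ensemble."""

    k_on_cell: float
    per_cell_values: np.ndarray
    sd: float


# ---------------------------------------------------------------------------
# Bleach-rate estimation
# ---------------------------------------------------------------------------

class BleachDecayModel:
    """Exponential decay of surviving immobilized-spot counts.

    Fits log(counts) vs time by least squares over the nonzero counts of at
    most the first ``max_frames`` frames (decay dynamics drift at longer
    times, e.g. from uneven illumination).
    """

    def __init__(self, counts, frame_dt: float, max_frames: int = 150):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 1 or len(counts) < 10:
            raise ValueError("need at least 10 frames of spot counts")
        if frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if np.all(counts == 0):
            raise ValueError("all-zero spot counts")
        self.counts = counts[:max_frames]
        self.frame_dt = float(frame_dt)

    def fit(self, increase_tol: float = 0.05) -> BleachModel:
        t = np.arange(len(self.counts)) * self.frame_dt
        mask = self.counts > 0
        t, y = t[mask], np.log(self.counts[mask])
        if len(t) < 2:
            raise ValueError("not enough nonzero counts to fit")
        (slope, _), cov = np.polyfit(t, y, 1, cov=True)
        k = -float(slope)
        se = float(np.sqrt(cov[0, 0]))
        if k < -increase_tol:
            raise ValueError(
                f"spot counts increase (fitted rate {k:.4g}/s); not a bleach series"
            )
        return BleachModel(max(k, 0.0), frames_used=int(mask.sum()), k_bleach_se=se)


def estimate_bleach_rate(counts, frame_dt: float, max_frames: int = 150) -> BleachModel:
    """Least-squares exponential fit to a surviving-spot count series."""
    return BleachDecayModel(counts, frame_dt, max_frames=max_frames).fit()


# ---------------------------------------------------------------------------
# Observed dwell fit
# ---------------------------------------------------------------------------

class ExponentialDwellModel:
    """Maximum-likelihood exponential fit to observed dwell times.

    Events whose track was cut by the end of the acquisition contribute as
    right-censored observations (their dwell is a lower bound); set
    ``drop_censored=True`` to discard them instead, mirroring an analysis
    restricted to fully observed tracks.  A binned log-linear least-squares
    fit is available via ``fit(method="binned")``.
    """

    def __init__(self, events: pd.DataFrame | np.ndarray, drop_censored: bool = False,
                 min_events: int = 20):
        if isinstance(events, pd.DataFrame):
            dwells = events["dwell_obs"].to_numpy(dtype=float)
            if "end_cause" in events.columns:
                censored = events["end_cause"].to_numpy() == "censored"
            else:
                censored = np.zeros(len(dwells), dtype=bool)
        else:
            dwells = np.asarray(events, dtype=float)
            censored = np.zeros(len(dwells), dtype=bool)
        if np.any(dwells <= 0) or not np.all(np.isfinite(dwells)):
            raise ValueError("dwell times must be positive and finite")
        if drop_censored:
            dwells, censored = dwells[~censored], censored[~censored]
        if len(dwells) < min_events:
            raise ValueError(f"need at least {min_events} events, got {len(dwells)}")
        self.dwells = dwells
        self.censored = censored

    def fit(self, method: str = "mle", bin_width: float = 2.0) -> ExpFit:
        n = len(self.dwells)
        n_unc = int((~self.censored).sum())
        if method == "mle":
            if n_unc == 0:
                raise ValueError("all events censored; rate not identifiable")
            # censored-exponential MLE: events / total observed time
            rate = n_unc / float(self.dwells.sum())
        elif method == "binned":
            edges = np.arange(0.0, self.dwells.max() + bin_width, bin_width)
            counts, _ = np.histogram(self.dwells[~self.censored], bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            mask = counts > 0
            if mask.sum() < 2:
                raise ValueError("too few populated bins for a binned fit")
            # Poisson weights: log-counts of sparse tail bins are noisy and
            # would otherwise dominate the slope
            slope = np.polyfit(centers[mask], np.log(counts[mask]), 1,
                               w=np.sqrt(counts[mask]))[0]
            rate = -float(slope)
            if rate <= 0:
                raise ValueError("binned fit produced a non-decaying rate")
        else:
            raise ValueError(f"unknown method {method!r}")
        mean = 1.0 / rate
        # SE of the mean dwell is mean/sqrt(n); rate SE follows by delta method
        rate_se = rate / np.sqrt(n_unc)
        return ExpFit(rate=float(rate), rate_se=float(rate_se),
                      mean_dwell=float(mean), n=n, n_censored=n - n_unc)


def fit_observed_dwell(events, **kwargs) -> ExpFit:
    """MLE exponential fit of observed dwell times (see ExponentialDwellModel)."""
    drop = kwargs.pop("drop_censored", False)
    return ExponentialDwellModel(events, drop_censored=drop).fit(**kwargs)


# ---------------------------------------------------------------------------
# Bleach correction and derived quantities
# ---------------------------------------------------------------------------

def correct_dwell(fit: ExpFit, bleach: BleachModel) -> ExpFit:
    """True binding kinetics: k_off = k_obs - k_bleach.

    Returns an :class:`ExpFit` for the bleach-corrected off-rate; raises when
    the observed rate does not exceed the bleach rate (the correction is then
    unresolvable -- essentially every disappearance was a bleach).
    """
    if fit.rate <= bleach.k_bleach:
        raise ValueError(
            f"observed rate {fit.rate:.4g}/s <= bleach rate {bleach.k_bleach:.4g}/s; "
            "true off-rate unresolvable"
        )
    k_off = fit.rate - bleach.k_bleach
    return ExpFit(rate=float(k_off), rate_se=fit.rate_se,
                  mean_dwell=float(1.0 / k_off), n=fit.n, n_censored=fit.n_censored)


def bleach_loss_fraction(k_bleach: float, k_off: float) -> float:
    """Chance a spot disappearance was a bleach rather than an unbinding.

    The two competing exponentials split disappearances in proportion to their
    rates: k_bleach / (k_bleach + k_off).
    """
    if k_bleach < 0 or k_off < 0:
        raise ValueError("rates must be non-negative")
    if k_bleach == 0 and k_off == 0:
        raise ValueError("both rates zero; fraction undefined")
    return k_bleach / (k_bleach + k_off)


def estimate_on_rate(n_events, sigma_L: float, k_b: float, t: float) -> OnRateEstimate:
    """Per-cell pseudo on-rate from event counts under a bleaching ligand pool.

    ``n_events`` may be a scalar or a per-cell array; the estimate is the mean
    of the per-cell values with their SD.  The visible ligand density decays
    as sigma_L e^{-k_b t}, so the effective exposure is
    sigma_L (1 - e^{-k_b t}) / k_b, evaluated stably so that k_b -> 0 reduces
    to sigma_L * t.
    """
    if sigma_L <= 0 or t <= 0:
        raise ValueError("sigma_L and t must be positive")
    if k_b < 0:
        raise ValueError("k_b must be >= 0")
    n = np.atleast_1d(np.asarray(n_events, dtype=float))
    if np.any(n < 0):
        raise ValueError("event counts must be >= 0")
    if k_b == 0:
        exposure = sigma_L * t
    else:
        exposure = sigma_L * (-np.expm1(-k_b * t)) / k_b
    per_cell = n / exposure
    return OnRateEstimate(
        k_on_cell=float(per_cell.mean()),
        per_cell_values=per_cell,
        sd=float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0,
    )


def expected_events(k_on_cell: float, sigma_L: float, t: float) -> float:
    """Expected binding events: k_on_cell * sigma_L * t (no-depletion baseline)."""
    if min(k_on_cell, sigma_L, t) < 0:
        raise ValueError("all inputs must be >= 0")
    return k_on_cell * sigma_L * t
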