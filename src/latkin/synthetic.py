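"""Synthetic single-molecule fixtures with the statistical structure the
analysis assumes.

Every downstream stage (dwell fitting, success-probability estimation, hazard
extraction, trace analytics) can be exercised on tables generated here, with
known ground truth and no microscopy data:

* binding-event tables whose observed dwell is the minimum of an unbinding
  exponential (rate k_off) and a bleaching exponential (rate k_bleach),
  optionally discretized to the imaging frame interval;
* condensation outcomes drawn by thinning the nucleation hazard of a
  :class:`~latkin.success.SuccessModel` over the observed dwell;
* Poisson binding arrivals at rate k_on_cell * sigma_L;
* gamma-shaped LAT intensity pulses and their whole-cell superposition;
* immobilized-spot bleach decay series (binomial thinning per frame);
* FRAP-recovery and NFAT-translocation trace fixtures.

The generator emulates event statistics only -- no images, no diffusion
trajectories, no camera noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .success import SuccessModel

__all__ = [
    "EventGenConfig",
    "PulseModel",
    "WholeCellTrace",
    "generate_event_table",
    "sample_binding_arrivals",
    "lat_pulse",
    "superpose_wholecell",
    "generate_bleach_series",
    "generate_traces",
]

EVENT_COLUMNS = [
    "event_id", "cell_id", "t_start", "dwell_obs", "end_cause",
    "productive", "delay", "condensate_id",
]


@dataclass(frozen=True)
class EventGenConfig:
    """Generative parameters for a binding-event table.

    ``t_resolution`` is the imaging frame interval: observed dwells are
    rounded up to the next frame boundary and events shorter than one frame
    are dropped (they would never be seen in a time-lapse).  Set it to 0 for
    continuous dwells (useful for distributional tests).  ``t_acq`` enables
    acquisition-end right-censoring: events start uniformly in [0, t_acq) and
    tracks reaching t_acq are cut.
    """

    k_off: float
    k_bleach: float
    plat_model: SuccessModel
    n_events: int
    t_resolution: float = 2.0
    seed: int | None = None
    t_acq: float | None = None
    delay_grid_dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k_off", "k_bleach"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.k_off + self.k_bleach <= 0:
            raise ValueError("k_off + k_bleach must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.t_resolution < 0:
            raise ValueError("t_resolution must be >= 0")
        if self.t_acq is not None and self.t_acq <= 0:
            raise ValueError("t_acq must be positive when given")


def _sample_delays(dwells: np.ndarray, model: SuccessModel, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """First nucleation time per event by thinning the model hazard on a grid.

    Step firing probabilities are exact-to-grid:
    q_k = (P(t_{k+1}) - P(t_k)) / (1 - P(t_k)); a step may only fire while the
    complex is still observably bound.  Returns NaN where no nucleation
    occurred.
    """
    out = np.full(len(dwells), np.nan)
    if model.amplitude == 0 or len(dwells) == 0:
        return out
    n_steps = int(math.ceil(dwells.max() / dt))
    edges = np.arange(n_steps + 1) * dt
    P = np.asarray(model(edges))
    q = (P[1:] - P[:-1]) / (1.0 - P[:-1])
    # process in chunks to bound the uniforms matrix
    chunk = max(1, int(5_000_000 // max(n_steps, 1)))
    for lo in range(0, len(dwells), chunk):
        d = dwells[lo:lo + chunk]
        u = rng.uniform(size=(len(d), n_steps))
        fire = u < q[None, :]
        # a step k (ending at edges[k+1]) is only allowed while bound
        allowed = edges[1:][None, :] <= d[:, None]
        fire &= allowed
        any_fire = fire.any(axis=1)
        first = np.argmax(fire, axis=1)
        out[lo:lo + chunk][any_fire] = edges[first[any_fire] + 1]
    return out


def generate_event_table(cfg: EventGenConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a table of binding events (one row per pMHC:TCR event).

    Observed dwell = min(Exp(k_off), Exp(k_bleach)), discretized to the frame
    interval; ``end_cause`` records which exponential won (or ``censored``
    when the acquisition ended first).  The condensation delay is drawn by
    thinning the success-model hazard over the observed dwell; ``productive``
    is True iff nucleation occurred before the observed end.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows: list[pd.DataFrame] = []
    kept = 0
    batch = cfg.n_events
    guard = 0
    while kept < cfg.n_events:
        guard += 1
        if guard > 1000:
            raise RuntimeError("event generation failed to retain enough events")
        t_unbind = (rng.exponential(1.0 / cfg.k_off, batch)
                    if cfg.k_off > 0 else np.full(batch, np.inf))
        t_bleach = (rng.exponential(1.0 / cfg.k_bleach, batch)
                    if cfg.k_bleach > 0 else np.full(batch, np.inf))
        dwell = np.minimum(t_unbind, t_bleach)
        cause = np.where(t_bleach < t_unbind, "bleach", "unbind")
        if cfg.t_acq is not None:
            t_start = rng.uniform(0.0, cfg.t_acq, batch)
            cut = t_start + dwell > cfg.t_acq
            dwell = np.where(cut, cfg.t_acq - t_start, dwell)
            cause = np.where(cut, "censored", cause)
        else:
            t_start = np.zeros(batch)
        if cfg.t_resolution > 0:
            keep = dwell >= cfg.t_resolution
            dwell_rec = np.ceil(dwell / cfg.t_resolution) * cfg.t_resolution
        else:
            keep = dwell > 0
            dwell_rec = dwell
        delays = _sample_delays(dwell[keep], cfg.plat_model, cfg.delay_grid_dt, rng)
        rows.append(pd.DataFrame({
            "t_start": t_start[keep],
            "dwell_obs": dwell_rec[keep],
            "end_cause": cause[keep],
            "productive": np.isfinite(delays),
            "delay": delays,
        }))
        kept += int(keep.sum())
        batch = max(16, cfg.n_events - kept)
    df = pd.concat(rows, ignore_index=True).iloc[: cfg.n_events].copy()
    df.insert(0, "event_id", np.arange(len(df)))
    df.insert(1, "cell_id", "cell_0")
    df["condensate_id"] = np.where(
        df["productive"], "cond_" + df["event_id"].astype(str), None
    )
    # recorded delays keep the grid resolution; guaranteed <= dwell_obs
    assert not ((df["productive"]) & (df["delay"] > df["dwell_obs"])).any()
    return df[EVENT_COLUMNS]


def sample_binding_arrivals(k_on_cell: float, sigma_L: float, T: float,
                            seed=None) -> np.ndarray:
    """Homogeneous-Poisson binding arrival times on [0, T).

    The rate is k_on_cell * sigma_L (events/s); expected count = rate * T.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if k_on_cell < 0 or sigma_L < 0:
        raise ValueError("rates and densities must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(k_on_cell * sigma_L * T)
    return np.sort(rng.uniform(0.0, T, n))


# ---------------------------------------------------------------------------
# LAT pulses and whole-cell traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseModel:
    """Gamma-shaped LAT intensity pulse.

    The pulse is an amplitude-normalized gamma density: it rises to its peak
    (``amplitude`` LAT molecules) at (shape-1)*scale seconds after onset and
    decays back to zero.  Defaults give a 9.3 s rise and a pulse that has
    largely dissipated by ~30-40 s, matching a typical condensate's growth
    and lifetime.
    """

    shape: float = 3.0
    scale: float = 4.65
    amplitude: float = 258.0
    delay_dist: object = None  # callable (n, rng) -> delays, optional

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def peak_time(self) -> float:
        return max(self.shape - 1.0, 0.0) * self.scale

    def density(self, t) -> np.ndarray:
        """Unit-area gamma density of the pulse shape (for quadrature checks)."""
        from scipy.stats import gamma as gamma_dist

        return gamma_dist.pdf(np.asarray(t, dtype=float), self.shape, scale=self.scale)


def lat_pulse(t_grid, pulse: PulseModel, onset: float = 0.0) -> np.ndarray:
    """Pulse intensity (LAT molecules) on ``t_grid``; zero before ``onset``."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError("t_grid must be ascending")
    rel = t - onset
    peak_val = pulse.density(pulse.peak_time) if pulse.peak_time > 0 else pulse.density(0.0)
    vals = np.where(rel > 0, pulse.density(np.maximum(rel, 0.0)), 0.0)
    return pulse.amplitude * vals / peak_val


@dataclass
class WholeCellTrace:
    """Superposed whole-cell LAT trace with the first detection time."""

    t: np.ndarray
    intensity: np.ndarray
    onsets: np.ndarray
    first_detection: float | None
    threshold: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "intensity": self.intensity})


def superpose_wholecell(n_pulses: int, delay_sampler, pulse: PulseModel, seed=None,
                        t_grid=None, threshold: float | None = None,
                        arrivals=None) -> WholeCellTrace:
    """Superpose ``n_pulses`` LAT pulses at sampled (arrival + delay) onsets.

    ``delay_sampler`` is a callable ``(n, rng) -> delays`` (e.g. the sampler of
    an observed delay density).  When a ``threshold`` is given, the first
    crossing of the summed trace is reported (None if never crossed) --
    illustrating why the first detectable whole-cell signal gets earlier as
    more binding events are superposed.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delays = np.asarray(delay_sampler(n_pulses, rng), dtype=float)
    if arrivals is None:
        arrivals = np.zeros(n_pulses)
    onsets = np.asarray(arrivals, dtype=float) + delays
    if t_grid is None:
        horizon = onsets.max() + pulse.peak_time + 10.0 * pulse.scale
        t_grid = np.arange(0.0, horizon, 0.5)
    t_grid = np.asarray(t_grid, dtype=float)
    trace = np.zeros_like(t_grid)
    for onset in onsets:
        trace += lat_pulse(t_grid, pulse, onset=onset)
    first = None
    if threshold is not None:
        above = np.nonzero(trace >= threshold)[0]
        if above.size:
            first = float(t_grid[above[0]])
    return WholeCellTrace(t_grid, trace, onsets, first, threshold)


# ---------------------------------------------------------------------------
# Bleach series and trace fixtures
# ---------------------------------------------------------------------------

def generate_bleach_series(k_bleach: float, n0: int, n_frames: int,
                           frame_dt: float, seed=None) -> np.ndarray:
    """Surviving immobilized-spot counts per frame (binomial thinning).

    Each spot independently survives a frame interval with probability
    exp(-k_bleach * frame_dt); counts are therefore monotone non-increasing.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if k_bleach < 0 or frame_dt <= 0 or n_frames < 1:
        raise ValueError("invalid bleach-series parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = math.exp(-k_bleach * frame_dt)
    counts = np.empty(n_frames, dtype=int)
    counts[0] = n0
    for i in range(1, n_frames):
        counts[i] = rng.binomial(counts[i - 1], p)
    return counts


def generate_traces(kind: str, params: dict | None = None, seed=None) -> pd.DataFrame:
    """Trace fixtures for the quantitative-fluorescence analytics.

    ``kind='frap'``: exponential recovery I(t) = m (1 - e^{-k t}) toward the
    mobile-fraction plateau m, plus Gaussian noise.  ``kind='nfat'``: paired
    nuclear/cytosolic traces where the nuclear signal steps above the
    cytosolic one at ``t_cross`` (or never, when ``t_cross`` is None).
    """
    params = dict(params or {})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "frap":
        k = params.pop("k", 0.24)
        plateau = params.pop("plateau", 1.0)
        immobile = params.pop("immobile_fraction", 0.0)
        t_max = params.pop("t_max", 40.0)
        dt = params.pop("dt", 0.1)
        noise = params.pop("noise_sd", 0.0)
        if params:
            raise ValueError(f"unknown frap params: {sorted(params)}")
        t = np.arange(0.0, t_max, dt)
        mobile = plateau * (1.0 - immobile)
        intensity = mobile * (1.0 - np.exp(-k * t))
        if noise > 0:
            intensity = intensity + rng.normal(0.0, noise, len(t))
        return pd.DataFrame({"t": t, "intensity": intensity})
    if kind == "nfat":
        t_cross = params.pop("t_cross", 300.0)
        t_max = params.pop("t_max", 720.0)
        dt = params.pop("dt", 50.0)
        noise = params.pop("noise_sd", 0.0)
        gap = params.pop("gap", 0.2)
        if params:
            raise ValueError(f"unknown nfat params: {sorted(params)}")
        t = np.arange(0.0, t_max, dt)
        cyt = np.ones_like(t)
        if t_cross is None:
            nuc = cyt - gap
        else:
            nuc = np.where(t >= t_cross, cyt + gap, cyt - gap)
        if noise > 0:
            nuc = nuc + rng.normal(0.0, noise, len(t))
            cyt = cyt + rng.normal(0.0, noise, len(t))
        return pd.DataFrame({"t": t, "nuclear": nuc, "cytosolic": cyt})
    raise ValueError(f"unknown trace kind {kind!r}")
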