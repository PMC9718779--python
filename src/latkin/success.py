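"""Single-TCR antigen discrimination function and condensation hazard.

A single pMHC:TCR binding event either nucleates a LAT condensate or fails to.
The probability of success is a function of the binding dwell time alone: short
binding events almost never nucleate, long ones approach a plateau well below 1.
This module estimates that success probability P(tau) from an ensemble of
binding events (binned in dwell time, with binomial errors), fits the standard
parametric form -- an amplitude times a regularized lower incomplete gamma
function,

    P(t) = A * P_reg(N, lambda * t),

and converts between P(t) and the nucleation propensity (hazard)

    k_c(t) = P'(t) / (1 - P(t)),

the momentary probability per unit time that a still-engaged, still-silent
receptor nucleates a condensate.  The a-priori success probability of a ligand
with exponential dwell distribution follows by mixing P(t) over the dwell
density:  p(k_off) = integral k_off exp(-k_off t) P(t) dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.interpolate import UnivariateSpline
from scipy.special import gammainc, gammaincc, gammaincinv
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SuccessModel",
    "DwellBins",
    "SuccessCurve",
    "PropensityCurve",
    "SuccessProbabilityModel",
    "SuccessFitResults",
    "make_bins",
    "bin_success",
    "fit_success_curve",
    "extract_propensity",
    "integrate_hazard",
    "apriori_success",
    "apriori_success_closed_form",
    "observed_delay_density",
    "productive_counts",
]


# ---------------------------------------------------------------------------
# Parametric success model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuccessModel:
    """Amplitude-scaled regularized-gamma success probability.

    Parameters
    ----------
    amplitude : float
        Plateau probability A, 0 < A <= 1.  The measured single-TCR curve
        plateaus near 0.25.
    shape : float
        Gamma shape N >= 1 (number of effective proofreading steps; real
        valued).
    rate : float
        Step rate lambda in 1/s.
    """

    amplitude: float
    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (0 < self.amplitude <= 1):
            raise ValueError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if not (self.shape >= 1):
            raise ValueError(f"shape must be >= 1, got {self.shape}")
        if not (self.rate > 0):
            raise ValueError(f"rate must be > 0, got {self.rate}")

    @classmethod
    def from_half_max(cls, amplitude: float, shape: float, t_half_max: float) -> "SuccessModel":
        """Build a model whose half-maximum falls at ``t_half_max`` seconds."""
        if t_half_max <= 0:
            raise ValueError("t_half_max must be positive")
        rate = gammaincinv(shape, 0.5) / t_half_max
        return cls(amplitude, shape, rate)

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t):
        """P(t) = A * P_reg(N, lambda t); zero for t <= 0."""
        t = np.asarray(t, dtype=float)
        x = np.where(t > 0, self.rate * t, 0.0)
        return self.amplitude * gammainc(self.shape, x)

    def pdf(self, t):
        """dP/dt: amplitude-scaled gamma density of the delay to nucleation."""
        t = np.asarray(t, dtype=float)
        return self.amplitude * gamma_dist.pdf(t, self.shape, scale=1.0 / self.rate)

    def hazard(self, t):
        """Nucleation propensity k_c(t) = P'(t) / (1 - P(t)).

        For amplitude 1 this is the hazard of a gamma distribution and is
        evaluated in log space to remain stable at large lambda*t (where it
        approaches the asymptote lambda).
        """
        t = np.asarray(t, dtype=float)
        if self.amplitude == 1.0:
            from .proofreading import kpr_propensity

            return kpr_propensity(self.shape, self.rate, t)
        denom = 1.0 - self(t)
        return self.pdf(t) / denom

    @property
    def t_half_max(self) -> float:
        """Dwell time at which P(t) reaches half its plateau."""
        return float(gammaincinv(self.shape, 0.5) / self.rate)


# ---------------------------------------------------------------------------
# Binning and the empirical success curve
# ---------------------------------------------------------------------------

@dataclass
class DwellBins:
    """Dwell-time bins with linearly increasing widths.

    Widths grow linearly (first_width, first_width + increment, ...) to keep
    per-bin counts usable for rare long-dwelling events; the last bin absorbs
    the tail.
    """

    edges: np.ndarray
    n_total: np.ndarray | None = None
    n_productive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) < 2:
            raise ValueError("need at least two bin edges")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, dwells) -> np.ndarray:
        """Bin index per dwell; values beyond the last edge fall in the last bin."""
        dwells = np.asarray(dwells, dtype=float)
        idx = np.searchsorted(self.edges, dwells, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def make_bins(dwells, first_width: float = 4.0, increment: float = 2.0,
              n_bins: int | None = None) -> DwellBins:
    """Construct linearly-widening dwell-time bins covering ``dwells``.

    Bin k has width ``first_width + k * increment``.  Bins are generated until
    they cover the largest dwell, unless ``n_bins`` caps them (in which case
    the last bin absorbs the tail).
    """
    if first_width <= 0 or increment < 0:
        raise ValueError("first_width must be > 0 and increment >= 0")
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("no dwell times supplied")
    edges = [0.0]
    k = 0
    while edges[-1] < dwells.max() and (n_bins is None or k < n_bins):
        edges.append(edges[-1] + first_width + k * increment)
        k += 1
    return DwellBins(np.array(edges))


@dataclass
class SuccessCurve:
    """Binned success probability with binomial standard errors.

    ``p_hat`` is NaN for empty bins (flagged, never imputed); ``se`` is the
    binomial standard error sqrt(p(1-p)/n).
    """

    centers: np.ndarray
    p_hat: np.ndarray
    se: np.ndarray
    n: np.ndarray
    bins: DwellBins | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.centers, "p_hat": self.p_hat, "se": self.se, "n": self.n}
        )

    @property
    def valid(self) -> np.ndarray:
        return self.n > 0


def bin_success(events: pd.DataFrame, bins: DwellBins) -> SuccessCurve:
    """Empirical success probability per dwell-time bin.

    An event is productive if a condensate formed at any point during its
    observed lifetime; the per-bin estimate p_hat = n_productive / n_total is
    a calibrated probability (it does not depend on how the dwell marginal
    samples the bins).
    """
    dwells = events["dwell_obs"].to_numpy(dtype=float)
    productive = events["productive"].to_numpy(dtype=bool)
    if "delay" in events.columns:
        delay = events["delay"].to_numpy(dtype=float)
        bad = productive & np.isfinite(delay) & (delay > dwells)
        if bad.any():
            raise ValueError(
                f"{bad.sum()} events have delay > dwell_obs; invalid event table"
            )
    idx = bins.assign(dwells)
    n_total = np.bincount(idx, minlength=bins.n_bins)
    n_prod = np.bincount(idx, weights=productive.astype(float), minlength=bins.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n_total > 0, n_prod / np.maximum(n_total, 1), np.nan)
        se = np.where(n_total > 0, np.sqrt(p_hat * (1 - p_hat) / np.maximum(n_total, 1)), np.nan)
    bins.n_total = n_total
    bins.n_productive = n_prod.astype(int)
    return SuccessCurve(bins.centers, p_hat, se, n_total, bins=bins)


# ---------------------------------------------------------------------------
# Fitting (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------

class SuccessProbabilityModel:
    """Weighted least-squares fit of the parametric success model to a curve.

    The fit minimises sum_i ((p_hat_i - A P_reg(N, lambda t_i)) / s_i)^2 over
    non-empty bins, with s_i the binomial SE.  Because p_hat = 0 or 1 gives a
    zero SE, fit weights use a shrunk estimate p~ = (k + 1/2) / (n + 1) so no
    bin gets infinite weight; reported curve SEs remain the plain binomial
    ones.
    """

    def __init__(self, curve: SuccessCurve):
        mask = curve.valid & np.isfinite(curve.p_hat)
        if mask.sum() < 4:
            raise ValueError("need at least 4 non-empty bins to fit")
        self.curve = curve
        self.t = curve.centers[mask]
        self.p = curve.p_hat[mask]
        self.n = curve.n[mask]
        k = self.p * self.n
        p_shrunk = (k + 0.5) / (self.n + 1.0)
        self.sigma = np.sqrt(p_shrunk * (1 - p_shrunk) / self.n)

    @classmethod
    def from_events(cls, events: pd.DataFrame, first_width: float = 4.0,
                    increment: float = 2.0) -> "SuccessProbabilityModel":
        bins = make_bins(events["dwell_obs"].to_numpy(dtype=float), first_width, increment)
        return cls(bin_success(events, bins))

    @staticmethod
    def _f(t, amplitude, shape, rate):
        return amplitude * gammainc(shape, np.maximum(rate * t, 0.0))

    def fit(self, amplitude0: float | None = None, shape0: float = 2.0,
            rate0: float | None = None) -> "SuccessFitResults":
        if amplitude0 is None:
            # initialise the plateau at the last populated bin's estimate
            amplitude0 = float(np.clip(self.p[-1], 0.05, 1.0))
        if rate0 is None:
            above = self.t[self.p >= 0.5 * amplitude0]
            t_half0 = float(above[0]) if above.size else float(np.median(self.t))
            rate0 = float(gammaincinv(shape0, 0.5) / max(t_half0, 1e-6))
        try:
            popt, pcov = optimize.curve_fit(
                self._f, self.t, self.p, p0=[amplitude0, shape0, rate0],
                sigma=self.sigma, absolute_sigma=False,
                bounds=([1e-6, 1.0, 1e-6], [1.0, 50.0, 10.0]), maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"success-curve fit failed to converge (n_bins={len(self.t)}, "
                f"p0=({amplitude0:.3g}, {shape0:.3g}, {rate0:.3g})): {exc}"
            ) from exc
        return SuccessFitResults(self, popt, pcov)


class SuccessFitResults:
    """Results of the parametric success-probability fit."""

    param_names = ("amplitude", "shape", "rate")

    def __init__(self, model: SuccessProbabilityModel, params, cov):
        self.model_spec = model
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.bse = np.sqrt(np.diag(self.cov))
        self.model = SuccessModel(*self.params)

    @property
    def amplitude(self) -> float:
        return float(self.params[0])

    @property
    def shape(self) -> float:
        return float(self.params[1])

    @property
    def rate(self) -> float:
        return float(self.params[2])

    @property
    def t_half_max(self) -> float:
        return self.model.t_half_max

    @property
    def t_half_max_se(self) -> float:
        """Delta-method SE of the half-max time over (shape, rate)."""
        n, lam = self.shape, self.rate
        eps = 1e-6 * max(n, 1.0)
        dthalf_dn = (gammaincinv(n + eps, 0.5) - gammaincinv(n - eps, 0.5)) / (2 * eps * lam)
        dthalf_dlam = -gammaincinv(n, 0.5) / lam**2
        g = np.array([0.0, dthalf_dn, dthalf_dlam])
        return float(np.sqrt(g @ self.cov @ g))

    def predict(self, t):
        return self.model(t)

    @property
    def resid(self) -> np.ndarray:
        return self.model_spec.p - self.model(self.model_spec.t)

    def summary(self) -> str:
        lines = [
            "Success-probability fit: P(t) = A * P_reg(N, lambda t)",
            "-" * 54,
            f"{'bins used':<18}{len(self.model_spec.t):>10d}",
            f"{'events':<18}{int(self.model_spec.n.sum()):>10d}",
        ]
        for name, val, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<18}{val:>10.4f}  +/- {se:.4f}")
        lines.append(
            f"{'t_half_max (s)':<18}{self.t_half_max:>10.2f}  +/- {self.t_half_max_se:.2f}"
        )
        return "\n".join(lines)


def fit_success_curve(curve: SuccessCurve, **kwargs) -> SuccessFitResults:
    """Convenience wrapper: fit the parametric model to a binned curve."""
    return SuccessProbabilityModel(curve).fit(**kwargs)


# ---------------------------------------------------------------------------
# Hazard extraction and the probability <-> hazard round trip
# ---------------------------------------------------------------------------

@dataclass
class PropensityCurve:
    """Nucleation propensity k_c on a time grid."""

    t: np.ndarray
    k_c: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.k_c = np.asarray(self.k_c, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "k_c": self.k_c})
        if self.se is not None:
            df["se"] = self.se
        return df


def _empirical_hazard(curve: SuccessCurve, t_grid: np.ndarray,
                      smoothing: float | None = None) -> PropensityCurve:
    # Smoothing-spline derivative; finite differences of binned p_hat are far
    # too noisy once divided by (1 - P).
    mask = curve.valid & np.isfinite(curve.p_hat)
    t, p, n = curve.centers[mask], curve.p_hat[mask], curve.n[mask]
    # inverse-SE weights (shrunk so p_hat of 0 or 1 keeps finite weight);
    # with w = 1/se the natural smoothing factor is ~ the number of points
    k = p * n
    p_shrunk = (k + 0.5) / (n + 1.0)
    se = np.sqrt(p_shrunk * (1 - p_shrunk) / n)
    # anchor at the origin: P(0) = 0 by construction
    t = np.concatenate([[0.0], t])
    p = np.concatenate([[0.0], p])
    w = np.concatenate([[2.0 / se.min()], 1.0 / se])
    if smoothing is None:
        # leave-one-out CV over a coarse grid of smoothing factors
        candidates = len(t) * np.array([0.3, 0.6, 1.0, 2.0, 4.0])
        best, smoothing = np.inf, candidates[-1]
        for s in candidates:
            err = 0.0
            for i in range(1, len(t)):
                keep = np.arange(len(t)) != i
                try:
                    sp = UnivariateSpline(t[keep], p[keep], w=w[keep], k=3, s=s)
                except Exception:
                    err = np.inf
                    break
                err += (float(sp(t[i])) - p[i]) ** 2
            if err < best:
                best, smoothing = err, s
    spline = UnivariateSpline(t, p, w=w, k=3, s=smoothing)
    P = np.clip(spline(t_grid), 0.0, None)
    if np.any(P >= 1.0):
        raise ValueError("smoothed success probability reaches 1; hazard undefined")
    dP = spline.derivative()(t_grid)
    k_c = np.clip(dP, 0.0, None) / (1.0 - P)
    return PropensityCurve(t_grid, k_c)


def extract_propensity(P, t_grid, smoothing: float | None = None) -> PropensityCurve:
    """Nucleation propensity k_c(t) = P'(t)/(1 - P(t)) on ``t_grid``.

    ``P`` may be a parametric :class:`SuccessModel` (analytic derivative) or an
    empirical :class:`SuccessCurve` (cross-validated smoothing-spline
    derivative).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if isinstance(P, SuccessModel):
        return PropensityCurve(t_grid, P.hazard(t_grid))
    if isinstance(P, SuccessCurve):
        return _empirical_hazard(P, t_grid, smoothing=smoothing)
    raise TypeError(f"cannot extract propensity from {type(P).__name__}")


def integrate_hazard(k_c, t_grid) -> np.ndarray:
    """Recover P(t) from a hazard via P(t) = 1 - exp(-int_0^t k_c).

    ``k_c`` is a callable; each inter-grid segment is integrated with adaptive
    quadrature so the round trip with :func:`extract_propensity` closes to
    better than 1e-6.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < 0:
        raise ValueError("time grid must be non-negative")
    segs = np.zeros_like(t_grid)
    lo = 0.0
    total = 0.0
    for i, hi in enumerate(t_grid):
        if hi > lo:
            val, _ = integrate.quad(lambda x: float(np.asarray(k_c(x))), lo, hi, limit=200)
            total += val
        segs[i] = total
        lo = hi
    return -np.expm1(-segs)


# ---------------------------------------------------------------------------
# A-priori ligand success and derived densities
# ---------------------------------------------------------------------------

def apriori_success(k_off: float, model: SuccessModel) -> float:
    """Probability that a ligand with off-rate ``k_off`` nucleates a condensate.

    Mixes the success probability over the exponential dwell density:
    p(k_off) = int_0^inf k_off exp(-k_off t) P(t) dt, evaluated by adaptive
    quadrature.  Matches the closed form A (lambda/(lambda+k_off))^N to 1e-8.
    """
    if not np.isfinite(k_off) or k_off <= 0:
        raise ValueError("k_off must be positive and finite")
    # substitute u = k_off * t so the integrand is O(1) for any off-rate
    val, _ = integrate.quad(
        lambda u: np.exp(-u) * float(model(u / k_off)), 0.0, np.inf, limit=400,
    )
    return float(val)


def apriori_success_closed_form(k_off: float, model: SuccessModel) -> float:
    """Closed form of the dwell-mixed success probability.

    Integrating by parts, int k e^{-kt} P_reg(N, lam t) dt is the gamma moment
    generating function at -k, giving A * (lam / (lam + k))^N (valid for real
    N >= 1).
    """
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    return float(model.amplitude * (model.rate / (model.rate + k_off)) ** model.shape)


@dataclass
class DelayDensity:
    """Observed condensation-delay density on a grid, with a sampler."""

    t: np.ndarray
    density: np.ndarray
    _cdf: np.ndarray = field(repr=False, default=None)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(0.0, 1.0, size=n)
        return np.interp(u, self._cdf, self.t)


def observed_delay_density(k_obs: float, model: SuccessModel, t_grid) -> DelayDensity:
    """Density of observed delays between binding and condensation.

    Delays at time t are only observable from binding events still visible at
    t, so the observed density is proportional to exp(-k_obs t) * P'(t),
    normalized on the grid.  ``k_obs = 0`` gives the intrinsic delay density
    P'(t) (up to the amplitude).
    """
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    raw = np.exp(-k_obs * t_grid) * model.pdf(t_grid)
    norm = np.trapezoid(raw, t_grid)
    if norm <= 0:
        raise ValueError("delay density vanishes on the supplied grid")
    density = raw / norm
    cdf = integrate.cumulative_trapezoid(density, t_grid, initial=0.0)
    cdf /= cdf[-1]
    return DelayDensity(t_grid, density, cdf)


def productive_counts(bins: DwellBins, model: SuccessModel, n_obs: float,
                      k_obs: float) -> np.ndarray:
    """Expected productive events per dwell bin.

    The fitted exponential dwell distribution is integrated over each bin and
    multiplied by the success probability at the bin midpoint:
    E[prod_k] = n_obs * (e^{-k_obs * e_k} - e^{-k_obs * e_{k+1}}) * P(center_k).
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    e = bins.edges
    mass = np.exp(-k_obs * e[:-1]) - np.exp(-k_obs * e[1:])
    return n_obs * mass * np.asarray(model(bins.centers))
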