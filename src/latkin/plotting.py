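"""Plot helpers for the success curve, propensity, and proofreading families."""

from __future__ import annotations

import numpy as np

from .success import PropensityCurve, SuccessCurve, SuccessModel

__all__ = ["plot_success_curve", "plot_propensity"]


def plot_success_curve(curve: SuccessCurve, model: SuccessModel | None = None, ax=None):
    """Binned success probability with binomial error bars and optional fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = curve.valid
    ax.errorbar(curve.centers[mask], curve.p_hat[mask], yerr=curve.se[mask],
                fmt="o", capsize=2, label="binned data")
    if model is not None:
        t = np.linspace(0, curve.centers[mask].max() * 1.1, 400)
        ax.plot(t, model(t), "-", color="gray",
                label=f"fit (plateau {model.amplitude:.2f})")
    ax.set_xlabel("binding dwell time (s)")
    ax.set_ylabel("P(condensate)")
    ax.legend()
    return ax


def plot_propensity(curves: dict[str, PropensityCurve], ax=None):
    """Overlay nucleation-propensity curves (empirical and model families)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve.t, curve.k_c, label=label)
    ax.set_xlabel("time since binding (s)")
    ax.set_ylabel("nucleation propensity $k_c(t)$ (1/s)")
    ax.legend()
    return ax
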