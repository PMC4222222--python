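"""Diagnostic figures: corrected-volume-vs-ICV scatter and prediction-error
scatter with a 45-degree reference line."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless-safe; must precede pyplot import
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import residual_slope  # noqa: E402


def plot_corrected_vs_icv(icv, corrected, *, region=None, method=None, ax=None):
    """Scatter of corrected volumes against ICV with the fitted OLS line.

    After a successful correction the line is parallel to the x-axis.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    icv = np.asarray(icv, float)
    corrected = np.asarray(corrected, float)
    diag = residual_slope(corrected, icv, region=region, method=method)
    ax.scatter(icv, corrected, s=12, alpha=0.6, edgecolors="none")
    xs = np.linspace(icv.min(), icv.max(), 50)
    intercept = corrected.mean() - diag.slope * icv.mean()
    ax.plot(xs, intercept + diag.slope * xs, color="C3")
    title = " - ".join(str(s) for s in (region, method) if s)
    ax.set_title(f"{title}  (r={diag.pearson_r:.2f}, p={diag.p_value:.3f})" if title
                 else f"r={diag.pearson_r:.2f}, p={diag.p_value:.3f}", fontsize=9)
    ax.set_xlabel("ICV (cc)")
    ax.set_ylabel("corrected volume")
    return ax


def plot_prediction_errors(errors_x, errors_y, *, label_x="power law",
                           label_y="linear", ax=None):
    """Scatter of per-region LOOCV prediction errors for two models, with
    the 45-degree line; points above the line favour the x-axis model."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = np.asarray(errors_x, float)
    y = np.asarray(errors_y, float)
    ax.scatter(x, y, s=18, alpha=0.8, edgecolors="none")
    lim = (0, 1.05 * max(x.max(), y.max()))
    ax.plot(lim, lim, color="grey", lw=1)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel(f"prediction error, {label_x} (cc$^2$)")
    ax.set_ylabel(f"prediction error, {label_y} (cc$^2$)")
    return ax
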