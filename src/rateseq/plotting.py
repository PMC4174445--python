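"""Per-transcript fit visualization: data, fitted curve, CI band curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import KineticEstimate, NormalizedSeries, RunConfig
from .kinetics import model_y

__all__ = ["plot_fit"]


def plot_fit(
    series: NormalizedSeries, est: KineticEstimate, cfg: RunConfig, path
) -> None:
    """Scatter the normalized points with the fitted labeling curve.

    Dashed curves show the model evaluated at the bootstrap CI bounds on
    alpha (Y_eq held at the point estimate).  Raises for non-converged
    fits — there is no curve to draw.
    """
    if not est.converged:
        raise ValueError(f"{est.transcript_id}: fit did not converge; nothing to plot")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (rep, marker) in zip(sorted(series.points["replicate"].unique()), "osD^v"):
        sub = series.points[series.points["replicate"] == rep]
        inc = sub[sub["included"]]
        exc = sub[~sub["included"]]
        ax.plot(inc["time_min"], inc["value"], marker, ms=4, alpha=0.7, label=rep)
        if len(exc):
            ax.plot(exc["time_min"], exc["value"], "x", color="grey", ms=5)
    tmax = float(series.points["time_min"].max())
    tt = np.linspace(0, 1.05 * tmax, 300)
    ax.plot(tt, model_y(tt, est.alpha_total, est.y_eq, cfg.t_d), "k-", lw=1.5)
    for a in (est.ci_low, est.ci_high):
        if np.isfinite(a) and a > 0:
            ax.plot(tt, model_y(tt, a, est.y_eq, cfg.t_d), "k--", lw=0.8)
    ax.set_xlabel("time after label addition (min)")
    ax.set_ylabel("normalized labeled counts")
    ax.set_title(
        f"{est.transcript_id}: t½ = {est.half_life:.1f} min"
        if np.isfinite(est.half_life)
        else est.transcript_id
    )
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
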