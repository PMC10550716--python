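"""Figure helpers for sweep results (log-log scaling plots)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .scaling_analysis import SweepResult


def plot_width_sweep(sweep: SweepResult, path: str | Path) -> None:
    """Log-log plot of CVs and positional error against tissue width."""
    frame = sweep.to_frame()
    fig, (ax_cv, ax_sx) = plt.subplots(1, 2, figsize=(9, 4))
    cv = frame.drop_duplicates(subset=["n_rows"]).sort_values("n_rows")
    ax_cv.loglog(cv["n_rows"], cv["cv_lambda"], "o-", label=r"$CV_\lambda$")
    ax_cv.loglog(cv["n_rows"], cv["cv_c0"], "s-", label=r"$CV_0$")
    ax_cv.set_xlabel(r"$N_y$")
    ax_cv.set_ylabel("gradient variability")
    ax_cv.legend()
    if "target" in frame:
        for t, sub in frame.groupby("target"):
            sub = sub.sort_values("n_rows")
            ax_sx.errorbar(
                sub["n_rows"], sub["sigma_x_over_delta"],
                yerr=sub["sem_sigma_x"] / sub["delta_x"],
                fmt="o-", label=rf"$\mu_x = {t:g}\,\mu_\lambda$",
            )
        ny = np.asarray(sorted(frame["n_rows"].unique()), dtype=float)
        ax_sx.plot(ny, ny[0] ** 0.5 / np.sqrt(ny), "k--", lw=0.8, label=r"$\propto N_y^{-1/2}$")
        ax_sx.set_xscale("log")
        ax_sx.set_yscale("log")
        ax_sx.set_xlabel(r"$N_y$")
        ax_sx.set_ylabel(r"$\sigma_x/\delta$")
        ax_sx.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
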