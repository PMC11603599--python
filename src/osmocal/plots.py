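"""Diagnostic plots: running-virial convergence and the lambda scan."""

from __future__ import annotations

from .calibration import LambdaScan
from .virial import VirialEstimate

__all__ = ["plot_convergence", "plot_scan"]


def _axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_convergence(estimate: VirialEstimate, ax=None):
    """B(r*) per run with the plateau window shaded."""
    ax = _axes(ax)
    for i in range(estimate.B_running.shape[0]):
        label = f"run {i}"
        if estimate.run_ids and estimate.run_ids[i]:
            label = estimate.run_ids[i]
        ax.plot(estimate.r_star_grid, estimate.B_running[i], label=label)
    ax.axvspan(*estimate.plateau_window, alpha=0.15, color="grey")
    ax.axhline(estimate.plateau_mean, ls="--", color="k", lw=0.8)
    ax.set_xlabel("r* (nm)")
    ax.set_ylabel("B(r*) (L/mol)")
    ax.legend(fontsize="small")
    return ax


def plot_scan(scan: LambdaScan, lambda_star: float | None = None, ax=None):
    """B23 vs lambda with the experimental target band."""
    ax = _axes(ax)
    ax.errorbar(scan.lambdas, scan.values, yerr=scan.sems, fmt="o-", capsize=3)
    t, ts = scan.target
    ax.axhspan(t - ts, t + ts, alpha=0.2, color="green")
    ax.axhline(t, color="green", lw=0.8)
    if lambda_star is not None:
        ax.axvline(lambda_star, ls="--", color="k", lw=0.8)
    ax.set_xlabel("lambda")
    ax.set_ylabel("B23 (L/mol)")
    return ax
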