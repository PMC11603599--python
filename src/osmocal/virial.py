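"""Tail-corrected osmotic second virial coefficients from RDFs.

McMillan-Mayer theory gives the osmotic second virial coefficient of two
solute species from their radial distribution function,

    B_ij = -2 pi N_A \\int_0^inf [g_ij(r) - 1] r^2 dr .

In a finite periodic simulation g(r) approaches a plateau c that can
deviate slightly from one, which makes the truncated integral diverge
cubically in the cutoff r*.  The estimator here replaces the ideal-gas
limit 1 by the plateau estimate

    c_ij(r*, Delta) = mean of g over the trailing window [r* - Delta, r*]

so that

    B_ij(r*) = -2 pi N_A \\int_0^{r*} [g_ij(r) - c_ij(r*, Delta)] r^2 dr

is flat in r* once r* exceeds the correlation length.  Reported values
average B(r*) over a plateau window (protein-sugar default 8-10 nm) and
across independent runs, with the standard error of the per-run means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .rdf import RadialDistribution
from .units import NM3_TO_L_PER_MOL

__all__ = [
    "TailCorrection",
    "VirialEstimate",
    "InvalidWindowError",
    "tail_average",
    "virial_ideal",
    "virial_corrected",
    "plateau_estimate",
    "VirialEstimator",
]


class InvalidWindowError(ValueError):
    """An averaging window does not fit inside the RDF grid."""


@dataclass(frozen=True)
class TailCorrection:
    """Plateau estimate c over the trailing window [r* - Delta, r*]."""

    c: float
    window: tuple[float, float]
    delta: float
    r_star: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"tail average must be positive, got {self.c}")


@dataclass
class VirialEstimate:
    """Running virial coefficient B(r*) with its plateau summary."""

    r_star_grid: np.ndarray
    B_running: np.ndarray  # shape (n_runs, n_r_star), L/mol
    plateau_window: tuple[float, float]
    plateau_mean: float
    plateau_sem: float
    n_runs: int
    run_ids: tuple[str, ...] = ()
    per_run_plateau: np.ndarray | None = None


def _window_mask(rdf: RadialDistribution, r_star: float, delta: float) -> np.ndarray:
    if delta <= 0:
        raise InvalidWindowError("delta must be positive")
    lo = r_star - delta
    centers = rdf.bin_centers
    if lo < centers[0] - 1e-9 or r_star > rdf.r_max + 1e-9:
        raise InvalidWindowError(
            f"window [{lo}, {r_star}] outside RDF grid "
            f"[{centers[0]}, {rdf.r_max}]"
        )
    mask = (centers >= lo - 1e-12) & (centers <= r_star + 1e-12)
    if not mask.any():
        raise InvalidWindowError("window contains no bin centers")
    return mask


def tail_average(
    rdf: RadialDistribution,
    r_star: float,
    delta: float,
    r2_weighted: bool = False,
) -> TailCorrection:
    """Plateau estimate: mean of g over bins with centers in
    [r* - delta, r*].

    The unweighted mean is the default; ``r2_weighted`` switches to an
    r^2-weighted mean (weights the window the way the virial integral
    does).
    """
    mask = _window_mask(rdf, r_star, delta)
    g = rdf.g[mask]
    if r2_weighted:
        w = rdf.bin_centers[mask] ** 2
        c = float((g * w).sum() / w.sum())
    else:
        c = float(g.mean())
    return TailCorrection(
        c=c, window=(r_star - delta, r_star), delta=delta, r_star=r_star
    )


def _integrate_to(rdf: RadialDistribution, r_star: float, c: float) -> float:
    """-2 pi N_A * trapezoid of (g - c) r^2 from 0 to the last bin center
    at or below r_star, with g taken as 0 below the first bin center."""
    centers = rdf.bin_centers
    if r_star < centers[0] or r_star > rdf.r_max + 1e-9:
        raise InvalidWindowError(f"r_star={r_star} outside RDF grid")
    mask = centers <= r_star + 1e-12
    r = np.concatenate(([0.0], centers[mask]))
    f = np.concatenate(([0.0], (rdf.g[mask] - c) * centers[mask] ** 2))
    return -2.0 * np.pi * NM3_TO_L_PER_MOL * float(np.trapezoid(f, r))


def virial_ideal(rdf: RadialDistribution, r_star: float) -> float:
    """Uncorrected truncated virial integral (large-r limit taken as 1),
    in L/mol.  Diverges cubically in r* whenever the RDF plateau is off 1."""
    return _integrate_to(rdf, r_star, 1.0)


def virial_corrected(
    rdf: RadialDistribution,
    r_star: float,
    delta: float,
    r2_weighted: bool = False,
) -> float:
    """Tail-corrected virial coefficient B(r*) in L/mol.

    With the plateau c estimated over [r* - delta, r*]; identical to
    :func:`virial_ideal` when c = 1.
    """
    c = tail_average(rdf, r_star, delta, r2_weighted=r2_weighted).c
    return _integrate_to(rdf, r_star, c)


def _r_star_grid(
    rdf: RadialDistribution, delta: float, r_star_step: float
) -> np.ndarray:
    """r* values on bin centers, spaced ~r_star_step, where the trailing
    window fits."""
    centers = rdf.bin_centers
    feasible = centers[centers >= centers[0] + delta - 1e-12]
    stride = max(1, int(round(r_star_step / rdf.bin_width)))
    return feasible[::-1][::stride][::-1]


def plateau_estimate(
    rdfs: Sequence[RadialDistribution],
    delta: float = 2.0,
    plateau_window: tuple[float, float] = (8.0, 10.0),
    r_star_step: float = 0.1,
    r2_weighted: bool = False,
) -> VirialEstimate:
    """Running B(r*) per run plus the plateau mean +/- SEM.

    Each run's B(r*) is averaged over r* in ``plateau_window``; the
    reported mean averages those per-run values and the SEM is their
    standard error.  For a single run the SEM falls back to the scatter
    of B(r*) across the window.
    """
    if len(rdfs) == 0:
        raise ValueError("need at least one RDF")
    grid = _r_star_grid(rdfs[0], delta, r_star_step)
    lo, hi = plateau_window
    for rdf in rdfs:
        if lo - delta < rdf.bin_centers[0] - 1e-9 or hi > rdf.r_max + 1e-9:
            raise InvalidWindowError(
                f"plateau window {plateau_window} (with delta={delta}) "
                "does not fit inside every run's grid"
            )
    B = np.empty((len(rdfs), len(grid)))
    for i, rdf in enumerate(rdfs):
        for j, rs in enumerate(grid):
            B[i, j] = virial_corrected(rdf, rs, delta, r2_weighted=r2_weighted)
    in_win = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
    if not in_win.any():
        raise InvalidWindowError("plateau window contains no r* grid points")
    per_run = B[:, in_win].mean(axis=1)
    mean = float(per_run.mean())
    if len(rdfs) > 1:
        sem = float(per_run.std(ddof=1) / np.sqrt(len(rdfs)))
    else:
        vals = B[0, in_win]
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return VirialEstimate(
        r_star_grid=grid,
        B_running=B,
        plateau_window=plateau_window,
        plateau_mean=mean,
        plateau_sem=sem,
        n_runs=len(rdfs),
        run_ids=tuple(r.run_id for r in rdfs),
        per_run_plateau=per_run,
    )


class VirialEstimator(BaseEstimator):
    """Tail-corrected virial estimation with a scikit-learn interface.

    Parameters default to the protein-sugar protocol (Delta = 2 nm,
    plateau window 8-10 nm); for small-solute pairs Delta = 1 nm with a
    window around r* = 5 nm is the usual choice.

    Attributes (after ``fit`` on a list of :class:`RadialDistribution`):

    ``plateau_mean_`` / ``plateau_sem_``
        Plateau-averaged B in L/mol and its standard error across runs.
    ``B_running_`` / ``r_star_grid_``
        Per-run running estimates B(r*).
    ``tail_corrections_``
        Per-run plateau estimates c at the window's upper edge.
    """

    def __init__(
        self,
        delta: float = 2.0,
        plateau_window: tuple[float, float] = (8.0, 10.0),
        r_star_step: float = 0.1,
        r2_weighted: bool = False,
    ):
        self.delta = delta
        self.plateau_window = plateau_window
        self.r_star_step = r_star_step
        self.r2_weighted = r2_weighted

    def fit(self, X: Sequence[RadialDistribution], y=None):
        est = plateau_estimate(
            X,
            delta=self.delta,
            plateau_window=tuple(self.plateau_window),
            r_star_step=self.r_star_step,
            r2_weighted=self.r2_weighted,
        )
        self.estimate_ = est
        self.r_star_grid_ = est.r_star_grid
        self.B_running_ = est.B_running
        self.plateau_mean_ = est.plateau_mean
        self.plateau_sem_ = est.plateau_sem
        self.per_run_plateau_ = est.per_run_plateau
        self.tail_corrections_ = [
            tail_average(
                rdf, self.plateau_window[1], self.delta, r2_weighted=self.r2_weighted
            )
            for rdf in X
        ]
        return self
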