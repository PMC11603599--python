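"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline can be exercised without running
molecular dynamics: analytic RDFs follow the dilute-limit closure
``g(r) = baseline * exp(-beta u(r))`` of a pair potential whose second
virial coefficient is known in closed form; particle configurations
emulate either an ideal gas (``g = 1`` everywhere) or one fixed central
"protein" with a hard exclusion sphere in a bath of "sugar" beads; and
censored survival records draw exponential dissociation times truncated
at a finite run length.

The ``baseline`` of an analytic RDF plays the role of the finite-size
plateau offset that the tail-corrected virial estimator is built to
remove.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import DimerRecord
from .frames import FrameSet
from .potentials import PairPotentialModel
from .rdf import RadialDistribution

__all__ = [
    "SyntheticRdfSpec",
    "gen_analytic_rdf",
    "gen_ideal_gas_frames",
    "gen_excluded_sphere_frames",
    "gen_survival_times",
]

#: Mass assigned to synthetic beads, amu (a typical 4-to-1 coarse bead).
BEAD_MASS = 72.0


@dataclass(frozen=True)
class SyntheticRdfSpec:
    """Recipe for an analytic RDF fixture.

    ``baseline`` is the large-r plateau (1 for an infinite system; values
    slightly off 1 emulate the finite-size artifact).  ``noise_sd`` adds
    independent zero-mean Gaussian noise per bin, only where g > 0 so a
    hard core stays exactly empty.
    """

    potential: PairPotentialModel
    baseline: float = 1.0
    noise_sd: float = 0.0
    bin_width: float = 0.1
    r_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.r_max <= self.potential.sigma:
            raise ValueError("r_max must exceed the potential's sigma")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_analytic_rdf(spec: SyntheticRdfSpec, run_id: str = "") -> RadialDistribution:
    """Noisy dilute-limit RDF ``baseline * exp(-beta u)`` on a uniform grid."""
    n_bins = int(round(spec.r_max / spec.bin_width))
    edges = np.linspace(0.0, n_bins * spec.bin_width, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = spec.baseline * spec.potential.boltzmann_factor(centers)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=g.shape)
        g = np.where(g > 0, np.clip(g + noise, 0.0, None), g)
    return RadialDistribution(
        bin_edges=edges,
        g=g,
        n_frames=1,
        box_length=None,
        species_pair=("protein", "sugar"),
        run_id=run_id,
    )


def _single_bead_frameset(
    frames: list[np.ndarray],
    box_length: float,
    species: list[str],
) -> FrameSet:
    n = len(species)
    return FrameSet(
        frames=frames,
        box_length=box_length,
        molecule_index=np.arange(n),
        species_index={m: s for m, s in enumerate(species)},
        masses=np.full(n, BEAD_MASS),
    )


def gen_ideal_gas_frames(
    n_beads: int,
    n_frames: int,
    box_length: float,
    seed: int = 0,
    species: str = "sugar",
) -> FrameSet:
    """Independently uniform single-bead molecules — a Poisson gas with
    g(r) = 1 at every distance."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    frames = [
        rng.uniform(0.0, box_length, size=(n_beads, 3)) for _ in range(n_frames)
    ]
    return _single_bead_frameset(frames, box_length, [species] * n_beads)


def gen_excluded_sphere_frames(
    sigma: float,
    n_beads: int,
    n_frames: int,
    box_length: float,
    seed: int = 0,
) -> FrameSet:
    """One fixed central "protein" bead plus ``n_beads`` "sugar" beads
    uniform outside a hard sphere of radius ``sigma`` around it.

    The protein-sugar RDF of this set is a hard-sphere step, so the
    corrected virial estimate must recover ``(2 pi / 3) N_A sigma^3``.
    ``sigma = 0`` disables the exclusion (ideal gas around a tracer).
    """
    if sigma >= box_length / 2:
        raise ValueError("sigma must be below half the box length")
    volume = box_length**3
    acceptance = 1.0 - (4.0 / 3.0) * np.pi * sigma**3 / volume
    if acceptance < 1e-3:
        raise ValueError(
            f"rejection acceptance ratio {acceptance:.2e} < 1e-3: "
            "exclusion sphere nearly fills the box"
        )
    rng = np.random.default_rng(seed)
    center = np.full(3, box_length / 2.0)
    frames = []
    for _ in range(n_frames):
        placed = []
        need = n_beads
        while need > 0:
            batch = rng.uniform(0.0, box_length, size=(max(need * 2, 64), 3))
            d = np.sqrt(((batch - center) ** 2).sum(axis=1))
            ok = batch[d >= sigma][:need]
            placed.append(ok)
            need -= len(ok)
        frames.append(np.vstack([center[None, :], *placed]))
    return _single_bead_frameset(
        frames, box_length, ["protein"] + ["sugar"] * n_beads
    )


def gen_survival_times(
    rate: float,
    n_runs: int,
    run_length: float,
    seed: int = 0,
) -> DimerRecord:
    """Exponential dissociation times with administrative censoring.

    Each run draws an event time ``~ Exp(rate)``; events later than
    ``run_length`` are censored at ``run_length``.  ``rate = 0`` censors
    every run.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if run_length <= 0 or n_runs < 1:
        raise ValueError("need run_length > 0 and n_runs >= 1")
    rng = np.random.default_rng(seed)
    if rate == 0:
        times = np.full(n_runs, np.inf)
    else:
        times = rng.exponential(1.0 / rate, size=n_runs)
    durations = np.full(n_runs, float(run_length))
    event_times = np.where(times < run_length, times, np.nan)
    return DimerRecord(durations=durations, event_times=event_times)
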