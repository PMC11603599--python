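"""Osmolyte effects on dimer stability and dissociation kinetics.

Three ingredients quantify how a crowding sugar shifts a protein
monomer-dimer equilibrium:

* the virial-coefficient difference ``Delta B23 = 2 B23(monomer) -
  B23(dimer)``, positive when the sugar is preferentially excluded from
  the dimer and hence stabilises it;
* the apparent dissociation constant ``Kd(C) = Kd0 exp(-Delta B23 * C)``
  at sugar concentration ``C``;
* a censored maximum-likelihood dissociation rate from repeated runs
  started in the bound state, ``k = n_events / (aggregate bound time)``,
  where event-free runs contribute their full duration.

Residue-sugar contact statistics (mean contacting sugar molecules per
residue and the cumulative-number-of-residues curve) characterise how the
sugar organises around the protein surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .frames import FrameSet
from .rdf import MissingSpeciesError, _minimum_image, molecule_centers

__all__ = [
    "DimerRecord",
    "RateEstimate",
    "StabilityResult",
    "ContactProfile",
    "DissociationRateEstimator",
    "delta_b23",
    "kd_model",
    "detect_dissociation",
    "ml_dissociation_rate",
    "diffusion_limited_rate",
    "contact_profile",
    "cnr_curve",
]


@dataclass
class DimerRecord:
    """Per-run bound-state durations with optional dissociation times.

    ``event_times`` holds the dissociation time of each run in μs, or
    ``nan`` for runs that stayed bound to the end (censored at
    ``durations``).
    """

    durations: np.ndarray
    event_times: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        self.event_times = np.atleast_1d(np.asarray(self.event_times, dtype=float))
        if self.durations.shape != self.event_times.shape:
            raise ValueError("durations and event_times must align")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        obs = ~np.isnan(self.event_times)
        if np.any(self.event_times[obs] > self.durations[obs] + 1e-12):
            raise ValueError("event_time exceeds run duration")

    @property
    def n_runs(self) -> int:
        return len(self.durations)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.event_times)

    @property
    def bound_times(self) -> np.ndarray:
        """Per-run time spent bound: event time if observed, else duration."""
        return np.where(self.observed, self.event_times, self.durations)


@dataclass(frozen=True)
class RateEstimate:
    """Censored exponential ML rate with simple diagnostics.

    ``upper_bound_rule_of_three`` is the 95%-ish rule-of-three bound
    ``3 / total_time``, reported as a diagnostic when no event occurred.
    """

    rate: float
    n_events: int
    total_time: float
    zero_events: bool
    upper_bound_rule_of_three: float

    @property
    def mean_lifetime(self) -> float:
        return np.inf if self.rate == 0 else 1.0 / self.rate


def ml_dissociation_rate(record: DimerRecord) -> RateEstimate:
    """Maximum-likelihood dissociation rate for censored exponential data.

    ``k = n_events / sum(bound times)`` — the standard censored
    exponential MLE, with censored runs contributing their full duration
    to the denominator.  Zero events yield rate 0 with ``zero_events``
    set, alongside the rule-of-three upper bound.
    """
    total = float(record.bound_times.sum())
    if total <= 0:
        raise ValueError("record has no positive bound time")
    n_events = int(record.observed.sum())
    return RateEstimate(
        rate=n_events / total,
        n_events=n_events,
        total_time=total,
        zero_events=n_events == 0,
        upper_bound_rule_of_three=3.0 / total,
    )


class DissociationRateEstimator(BaseEstimator):
    """Censored exponential rate estimator with a scikit-learn interface.

    Fit on per-run durations and an event-observed mask (or event times);
    the fitted attributes expose the ML rate and mean bound lifetime.

    Examples
    --------
    >>> est = DissociationRateEstimator().fit([46.0, 45.0, 3.0, 17.0],
    ...                                       [False, False, True, True])
    >>> round(est.mean_lifetime_, 1)
    55.5
    """

    def fit(self, durations, event_observed=None, event_times=None):
        durations = np.asarray(durations, dtype=float)
        if event_times is not None:
            record = DimerRecord(durations, np.asarray(event_times, dtype=float))
        else:
            if event_observed is None:
                event_observed = np.zeros_like(durations, dtype=bool)
            event_observed = np.asarray(event_observed, dtype=bool)
            times = np.where(event_observed, durations, np.nan)
            record = DimerRecord(durations, times)
        est = ml_dissociation_rate(record)
        self.rate_ = est.rate
        self.n_events_ = est.n_events
        self.total_time_ = est.total_time
        self.zero_events_ = est.zero_events
        self.upper_bound_rule_of_three_ = est.upper_bound_rule_of_three
        self.mean_lifetime_ = est.mean_lifetime
        return self

    def predict_survival(self, t):
        """Survival probability exp(-k t) at the fitted rate."""
        return np.exp(-self.rate_ * np.asarray(t, dtype=float))


def delta_b23(B_mon: float, B_dim: float) -> float:
    """Stability shift ``2 B23(monomer) - B23(dimer)`` in L/mol."""
    return 2.0 * B_mon - B_dim


def kd_model(kd0: float, delta_B23: float, C) -> np.ndarray | float:
    """Apparent dissociation constant ``Kd0 exp(-Delta B23 * C)``.

    ``kd0`` in M (any concentration unit; the output carries it through),
    ``delta_B23`` in M^-1, ``C`` in M.
    """
    if kd0 <= 0:
        raise ValueError("kd0 must be positive")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    out = kd0 * np.exp(-delta_B23 * C)
    return float(out) if out.ndim == 0 else out


def diffusion_limited_rate(Kd: float, ka: float = 1e9) -> float:
    """Dissociation rate implied by ``Kd`` under diffusion-limited
    association: ``k_off = Kd * ka`` with ``ka`` in M^-1 s^-1 (default
    1e9) and ``Kd`` in M; returns s^-1."""
    if Kd < 0:
        raise ValueError("Kd must be non-negative")
    return Kd * ka


@dataclass(frozen=True)
class DissociationEvent:
    """Outcome of scanning a distance series: event time or censoring."""

    time: float
    is_event: bool


def detect_dissociation(
    times,
    distances,
    threshold: float = 6.0,
    dwell: int = 10,
) -> DissociationEvent:
    """First time a centre-centre distance exceeds ``threshold`` (nm) and
    stays above it for at least ``dwell`` consecutive samples.

    The dwell requirement suppresses single-sample excursions.  If no
    qualifying crossing occurs the series is censored at its final time.
    Threshold and dwell are conventions, not measured quantities; both
    are exposed for sensitivity checks.
    """
    times = np.asarray(times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if times.shape != distances.shape or times.size == 0:
        raise ValueError("times and distances must be equal-length, non-empty")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    above = distances > threshold
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= dwell:
            return DissociationEvent(time=float(times[k - dwell + 1]), is_event=True)
    return DissociationEvent(time=float(times[-1]), is_event=False)


@dataclass
class StabilityResult:
    """Bundle of stability predictions for one scaling condition."""

    B_mon: float
    B_dim: float
    kd0: float
    delta_B23: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_B23 = delta_b23(self.B_mon, self.B_dim)

    def kd(self, C) -> np.ndarray | float:
        return kd_model(self.kd0, self.delta_B23, C)


@dataclass
class ContactProfile:
    """Mean number of contacting sugar molecules per protein residue."""

    per_residue_mean_contacts: dict[int, float]
    cutoff: float
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if any(v < 0 for v in self.per_residue_mean_contacts.values()):
            raise ValueError("mean contacts must be non-negative")

    @property
    def means(self) -> np.ndarray:
        return np.array(
            [self.per_residue_mean_contacts[r] for r in sorted(self.per_residue_mean_contacts)]
        )


def contact_profile(
    frames: FrameSet,
    protein: str = "protein",
    sugar: str = "sugar",
    cutoff: float = 0.94,
    per_bead: bool = False,
) -> ContactProfile:
    """Per-residue mean sugar contacts.

    A sugar molecule is in contact with a residue if any of its beads
    lies within ``cutoff`` (default 0.94 nm) of the residue's centre of
    mass; each molecule counts once per frame per residue.  With
    ``per_bead=True`` every bead within the cutoff counts instead.
    """
    if protein not in frames.species:
        raise MissingSpeciesError(f"no {protein!r} molecules in frame set")
    if sugar not in frames.species:
        raise MissingSpeciesError(f"no {sugar!r} molecules in frame set")
    if frames.residue_index is None:
        raise ValueError("protein beads carry no residue annotation")
    L = frames.box_length
    prot_mols = frames.molecules_of(protein)
    prot_beads = np.flatnonzero(np.isin(frames.molecule_index, prot_mols))
    residues = np.unique(frames.residue_index[prot_beads])
    res_beads = {
        r: prot_beads[frames.residue_index[prot_beads] == r] for r in residues
    }
    sugar_mols = frames.molecules_of(sugar)
    sugar_beads = np.flatnonzero(np.isin(frames.molecule_index, sugar_mols))
    sugar_mol_of_bead = frames.molecule_index[sugar_beads]

    totals = {int(r): 0.0 for r in residues}
    for coords in frames.frames:
        xs = coords[sugar_beads]
        for r in residues:
            beads = res_beads[r]
            x = coords[beads]
            ref = x[0]
            delta = _minimum_image(x - ref, L)
            m = frames.masses[beads]
            com = np.mod(ref + (m[:, None] * delta).sum(axis=0) / m.sum(), L)
            d = np.sqrt((_minimum_image(xs - com, L) ** 2).sum(axis=1))
            within = d < cutoff
            if per_bead:
                totals[int(r)] += int(within.sum())
            else:
                totals[int(r)] += len(np.unique(sugar_mol_of_bead[within]))
    nf = frames.n_frames
    return ContactProfile(
        per_residue_mean_contacts={r: v / nf for r, v in totals.items()},
        cutoff=cutoff,
        n_runs=1,
    )


def cnr_curve(profile: ContactProfile, grid) -> np.ndarray:
    """Cumulative number of residues with mean contacts strictly below
    each grid value: ``CNR(x) = #{residues : mean < x}``.

    The curve steps at each distinct mean; just above zero it equals the
    number of residues that made no contact at all.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be non-decreasing")
    means = np.sort(profile.means)
    return np.searchsorted(means, grid, side="left").astype(int)
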