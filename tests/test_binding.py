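"""Dissociation kinetics, stability predictions and contact statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from sklearn.base import clone

from osmocal.binding import (
    DimerRecord,
    DissociationRateEstimator,
    StabilityResult,
    cnr_curve,
    contact_profile,
    delta_b23,
    detect_dissociation,
    diffusion_limited_rate,
    kd_model,
    ml_dissociation_rate,
)
from osmocal.frames import FrameSet
from osmocal.synthetic import gen_survival_times


def likelihood_argmax(record: DimerRecord) -> float:
    """Independent oracle: numerical argmax of the censored exponential
    log-likelihood n_e log k - k * sum(t)."""
    n_e = int(record.observed.sum())
    total = record.bound_times.sum()

    def nll(k):
        return -(n_e * np.log(k) - k * total)

    res = minimize_scalar(nll, bounds=(1e-9, 10.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


class TestMlRate:
    def test_four_run_worked_example(self):
        rec = DimerRecord(
            durations=[3.0, 17.0, 46.0, 45.0],
            event_times=[3.0, 17.0, np.nan, np.nan],
        )
        est = ml_dissociation_rate(rec)
        assert est.rate == pytest.approx(2.0 / 111.0, rel=1e-15)
        assert est.mean_lifetime == pytest.approx(55.5, rel=1e-15)
        assert est.n_events == 2 and est.total_time == 111.0

    def test_zero_events_flagged(self):
        rec = DimerRecord([10.0, 20.0], [np.nan, np.nan])
        est = ml_dissociation_rate(rec)
        assert est.rate == 0.0 and est.zero_events
        assert est.upper_bound_rule_of_three == pytest.approx(3.0 / 30.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_likelihood_argmax(self, seed):
        rec = gen_survival_times(0.05, 40, 30.0, seed=seed)
        if rec.observed.sum() == 0:
            pytest.skip("no events drawn")
        est = ml_dissociation_rate(rec)
        assert est.rate == pytest.approx(likelihood_argmax(rec), rel=1e-6)

    def test_all_events_matches_uncensored_mle(self):
        rec = gen_survival_times(5.0, 50, 1000.0, seed=7)
        assert rec.observed.all()
        est = ml_dissociation_rate(rec)
        assert est.rate == pytest.approx(likelihood_argmax(rec), rel=1e-6)

    def test_parameter_recovery(self):
        k = 0.1
        rec = gen_survival_times(k, 200, 100.0, seed=11)
        est = ml_dissociation_rate(rec)
        assert abs(est.rate - k) < 3 * k / np.sqrt(est.n_events)

    def test_invalid_record(self):
        with pytest.raises(ValueError):
            DimerRecord([5.0], [7.0])  # event after run end
        with pytest.raises(ValueError):
            DimerRecord([0.0], [np.nan])


class TestRateEstimatorInterface:
    def test_fit_and_attributes(self):
        est = DissociationRateEstimator().fit(
            [46.0, 45.0, 3.0, 17.0], [False, False, True, True]
        )
        assert est.mean_lifetime_ == pytest.approx(55.5)
        assert est.n_events_ == 2
        assert est.predict_survival(0.0) == 1.0

    def test_clone_contract(self):
        est = DissociationRateEstimator()
        assert clone(est).get_params() == est.get_params()


class TestStability:
    @pytest.mark.parametrize(
        "b_mon, b_dim, expected",
        [(0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (10.63, 21.26, 0.0)],
    )
    def test_delta_b23(self, b_mon, b_dim, expected):
        assert delta_b23(b_mon, b_dim) == pytest.approx(expected, abs=1e-12)

    def test_kd_model_values(self):
        assert kd_model(20e-6, 1.0, 0.0) == 20e-6
        assert kd_model(20e-6, 1.0, 1.0) == pytest.approx(20e-6 * np.exp(-1))

    def test_log_kd_affine_in_concentration(self):
        dB, kd0 = 1.3, 5e-5
        C = np.linspace(0, 2, 9)
        logkd = np.log(kd_model(kd0, dB, C))
        slopes = np.diff(logkd) / np.diff(C)
        assert np.allclose(slopes, -dB, rtol=1e-12)

    def test_positive_delta_b23_stabilizes(self):
        kd = kd_model(20e-6, 1.0, np.array([0.0, 0.5, 1.0]))
        assert np.all(np.diff(kd) < 0)

    def test_stability_result_bundle(self):
        res = StabilityResult(B_mon=5.0, B_dim=9.0, kd0=2e-5)
        assert res.delta_B23 == 1.0
        assert res.kd(0.0) == 2e-5

    def test_diffusion_limited_rate(self):
        k = diffusion_limited_rate(20e-6, 1e9)
        assert k == pytest.approx(2e4)
        assert 1.0 / k == pytest.approx(50e-6)  # 50 us
        assert diffusion_limited_rate(0.0) == 0.0
        assert diffusion_limited_rate(1.0) == 1e9


class TestDetectDissociation:
    def test_never_crosses_is_censored(self):
        t = np.arange(10.0)
        ev = detect_dissociation(t, np.full(10, 3.0), threshold=6.0, dwell=2)
        assert not ev.is_event and ev.time == 9.0

    def test_event_at_first_persistent_crossing(self):
        t = np.arange(20.0)
        d = np.where(t >= 10, 7.0, 3.0)
        ev = detect_dissociation(t, d, threshold=6.0, dwell=3)
        assert ev.is_event and ev.time == 10.0

    def test_single_sample_spike_ignored(self):
        t = np.arange(10.0)
        d = np.full(10, 3.0)
        d[4] = 9.0
        ev = detect_dissociation(t, d, threshold=6.0, dwell=3)
        assert not ev.is_event and ev.time == 9.0


def contact_frameset():
    """One 2-residue protein molecule plus two sugar molecules at known
    distances from the residue centres."""
    coords = np.array(
        [
            [5.0, 5.0, 5.0],  # residue 0 bead
            [7.0, 5.0, 5.0],  # residue 1 bead
            [5.5, 5.0, 5.0],  # sugar mol 1, bead a: 0.5 nm from residue 0
            [5.3, 5.0, 5.0],  # sugar mol 1, bead b: 0.3 nm from residue 0
            [8.0, 5.0, 5.0],  # sugar mol 2: 1.0 nm from residue 1
        ]
    )
    return FrameSet(
        frames=[coords],
        box_length=20.0,
        molecule_index=np.array([0, 0, 1, 1, 2]),
        species_index={0: "protein", 1: "sugar", 2: "sugar"},
        masses=np.ones(5),
        residue_index=np.array([0, 1, 0, 0, 0]),
    )


class TestContacts:
    def test_molecule_level_counting(self):
        prof = contact_profile(contact_frameset(), cutoff=0.94)
        # both beads of sugar 1 are within the cutoff of residue 0: one contact
        assert prof.per_residue_mean_contacts[0] == 1.0
        # sugar 2 sits exactly 1.0 nm from residue 1: outside 0.94 nm
        assert prof.per_residue_mean_contacts[1] == 0.0

    def test_per_bead_counting(self):
        prof = contact_profile(contact_frameset(), cutoff=0.94, per_bead=True)
        assert prof.per_residue_mean_contacts[0] == 2.0

    def test_missing_residue_annotation(self):
        fs = contact_frameset()
        fs.residue_index = None
        with pytest.raises(ValueError, match="residue"):
            contact_profile(fs)

    def test_cnr_steps(self):
        from osmocal.binding import ContactProfile

        prof = ContactProfile(
            per_residue_mean_contacts={0: 0.0, 1: 0.0, 2: 0.5, 3: 1.5},
            cutoff=0.94,
        )
        grid = np.array([0.0, 1e-9, 0.5, 1.0, 10.0])
        cnr = cnr_curve(prof, grid)
        assert cnr[0] == 0  # strict inequality: nothing below 0
        assert cnr[1] == 2  # just above zero: the two zero-contact residues
        assert cnr[-1] == 4  # all residues below the max grid point
        assert np.all(np.diff(cnr) >= 0)

    def test_cnr_single_step_when_identical(self):
        from osmocal.binding import ContactProfile

        prof = ContactProfile(
            per_residue_mean_contacts={i: 0.7 for i in range(5)}, cutoff=1.0
        )
        cnr = cnr_curve(prof, np.array([0.69, 0.71]))
        assert list(cnr) == [0, 5]
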