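"""Tail-corrected virial estimation against closed-form oracles."""

import numpy as np
import pytest
from sklearn.base import clone

from osmocal.potentials import closed_form_b2
from osmocal.rdf import RadialDistribution
from osmocal.synthetic import SyntheticRdfSpec, gen_analytic_rdf
from osmocal.units import NM3_TO_L_PER_MOL
from osmocal.virial import (
    InvalidWindowError,
    VirialEstimator,
    plateau_estimate,
    tail_average,
    virial_corrected,
    virial_ideal,
)


def flat_rdf(value=1.0, bin_width=0.1, r_max=10.0):
    n = int(round(r_max / bin_width))
    edges = np.linspace(0, r_max, n + 1)
    return RadialDistribution(bin_edges=edges, g=np.full(n, value))


class TestTailAverage:
    def test_flat_baseline(self):
        assert tail_average(flat_rdf(1.0), 10.0, 2.0).c == 1.0

    def test_constant_offset(self):
        assert tail_average(flat_rdf(1.02), 10.0, 2.0).c == pytest.approx(1.02)

    def test_window_bounds(self):
        tc = tail_average(flat_rdf(), 10.0, 2.0)
        assert tc.window == (8.0, 10.0)
        assert tc.r_star == 10.0 and tc.delta == 2.0

    def test_noisy_baseline_within_sampling_error(self):
        rng = np.random.default_rng(0)
        rdf = flat_rdf(1.0)
        rdf.g = rdf.g + rng.normal(0, 0.01, size=rdf.g.shape)
        c = tail_average(rdf, 10.0, 2.0).c  # 20 bins in the window
        assert abs(c - 1.0) < 3 * 0.01 / np.sqrt(20)

    def test_window_outside_grid(self):
        with pytest.raises(InvalidWindowError):
            tail_average(flat_rdf(r_max=5.0), 10.0, 2.0)
        with pytest.raises(InvalidWindowError):
            tail_average(flat_rdf(), 1.0, 2.0)

    def test_r2_weighted_flat_unchanged(self):
        assert tail_average(flat_rdf(1.02), 10.0, 2.0, r2_weighted=True).c == (
            pytest.approx(1.02)
        )


class TestVirialIntegrals:
    def test_ideal_gas_is_zero(self):
        assert virial_ideal(flat_rdf(1.0), 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_hard_sphere_oracle(self, fine_hs_rdf, hard_sphere_2nm):
        expected = closed_form_b2(hard_sphere_2nm)
        assert virial_ideal(fine_hs_rdf, 10.0) == pytest.approx(expected, rel=5e-3)
        assert virial_corrected(fine_hs_rdf, 10.0, 2.0) == pytest.approx(
            expected, rel=5e-3
        )

    def test_offset_baseline_diverges_cubically(self, fine_hs_rdf, fine_hs_rdf_offset):
        for r_star in (5.0, 7.0, 10.0):
            dev = virial_ideal(fine_hs_rdf_offset, r_star) - virial_ideal(
                fine_hs_rdf, r_star
            )
            cubic = -2 * np.pi * NM3_TO_L_PER_MOL * 0.02 * (r_star**3 - 2.0**3) / 3
            assert dev == pytest.approx(cubic, rel=5e-3)

    def test_corrected_removes_divergence(self, fine_hs_rdf_offset, hard_sphere_2nm):
        expected = 1.02 * closed_form_b2(hard_sphere_2nm)
        values = [
            virial_corrected(fine_hs_rdf_offset, r, 2.0) for r in (5.0, 7.5, 10.0)
        ]
        assert np.allclose(values, expected, rtol=1e-3)
        spread = (max(values) - min(values)) / abs(np.mean(values))
        assert spread < 1e-3

    def test_square_well_oracle(self, square_well_unit):
        rdf = gen_analytic_rdf(
            SyntheticRdfSpec(potential=square_well_unit, bin_width=0.01, r_max=10.0)
        )
        expected = closed_form_b2(square_well_unit)  # about -3.885 L/mol
        assert virial_corrected(rdf, 10.0, 2.0) == pytest.approx(expected, rel=5e-3)

    def test_constant_g_gives_zero(self):
        for c in (0.7, 1.0, 1.3):
            assert virial_corrected(flat_rdf(c), 10.0, 2.0) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_corrected_with_unit_tail_equals_ideal_bitwise(self, fine_hs_rdf):
        # baseline-1 fixture: the tail average is exactly 1
        assert tail_average(fine_hs_rdf, 10.0, 2.0).c == 1.0
        assert virial_corrected(fine_hs_rdf, 10.0, 2.0) == virial_ideal(
            fine_hs_rdf, 10.0
        )

    def test_converged_beyond_sigma(self, fine_hs_rdf):
        vals = [virial_corrected(fine_hs_rdf, r, 2.0) for r in (4.0, 6.0, 8.0, 10.0)]
        assert max(vals) - min(vals) < 1e-6

    def test_linear_in_g(self, fine_hs_rdf, fine_hs_rdf_offset):
        a = 0.3
        mixed = RadialDistribution(
            bin_edges=fine_hs_rdf.bin_edges,
            g=a * fine_hs_rdf.g + (1 - a) * fine_hs_rdf_offset.g,
        )
        expected = a * virial_corrected(fine_hs_rdf, 10.0, 2.0) + (
            1 - a
        ) * virial_corrected(fine_hs_rdf_offset, 10.0, 2.0)
        assert virial_corrected(mixed, 10.0, 2.0) == pytest.approx(expected, rel=1e-12)


class TestPlateauEstimate:
    def test_identical_runs_have_zero_sem(self, fine_hs_rdf, hard_sphere_2nm):
        est = plateau_estimate([fine_hs_rdf] * 4, delta=2.0)
        assert est.plateau_sem == 0.0
        assert est.plateau_mean == pytest.approx(
            closed_form_b2(hard_sphere_2nm), rel=5e-3
        )
        assert est.n_runs == 4

    def test_single_run_mean_over_window(self, fine_hs_rdf):
        est = plateau_estimate([fine_hs_rdf], delta=2.0, plateau_window=(8.0, 10.0))
        in_win = (est.r_star_grid >= 8.0) & (est.r_star_grid <= 10.0)
        assert est.plateau_mean == pytest.approx(
            est.B_running[0, in_win].mean(), rel=1e-12
        )

    def test_noisy_runs_recover_oracle(self, hard_sphere_2nm):
        rdfs = [
            gen_analytic_rdf(
                SyntheticRdfSpec(
                    potential=hard_sphere_2nm, noise_sd=0.005, seed=100 + k
                ),
                run_id=f"run{k}",
            )
            for k in range(4)
        ]
        est = plateau_estimate(rdfs, delta=2.0, plateau_window=(8.0, 10.0))
        expected = closed_form_b2(hard_sphere_2nm)
        assert est.plateau_sem > 0
        assert abs(est.plateau_mean - expected) < max(3 * est.plateau_sem, 0.05 * expected)

    def test_window_outside_grid_raises(self, fine_hs_rdf):
        with pytest.raises(InvalidWindowError):
            plateau_estimate([fine_hs_rdf], delta=2.0, plateau_window=(9.0, 12.0))


class TestVirialEstimatorInterface:
    def test_fit_exposes_plateau(self, fine_hs_rdf, hard_sphere_2nm):
        est = VirialEstimator(delta=2.0, plateau_window=(8.0, 10.0)).fit(
            [fine_hs_rdf, fine_hs_rdf]
        )
        assert est.plateau_mean_ == pytest.approx(
            closed_form_b2(hard_sphere_2nm), rel=5e-3
        )
        assert est.plateau_sem_ == 0.0
        assert len(est.tail_corrections_) == 2
        assert est.tail_corrections_[0].c == 1.0

    def test_sklearn_param_contract(self):
        est = VirialEstimator(delta=1.0, plateau_window=(4.0, 5.0))
        cloned = clone(est)
        assert cloned.get_params()["delta"] == 1.0
        cloned.set_params(delta=2.0)
        assert cloned.delta == 2.0
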