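"""Kinetics fitting: round trips, nesting, model selection, CIs, rates."""

import math

import numpy as np
import pytest

from hydrolase_duo.kinetics import (
    KineticsDataset,
    Timecourse,
    confidence_intervals,
    fit_mm,
    fit_substrate_inhibition,
    initial_rate,
    mm_velocity,
    select_model,
    si_velocity,
)
from hydrolase_duo.synth import KineticTruth, gen_timecourse, gen_velocity_table

# the three characterized enzymes' constants (kcat s⁻¹, Km µM, Kk µM)
ENZYME_TRUTHS = [
    (27.6, 23.17, 307.30),  # wild type
    (27.2, 174.70, 1468.0),  # C. thiooxydans homolog
    (7.7, 41.09, 575.0),  # Hydrogenophaga homolog
]


def noise_free(kcat, km, kk=math.inf, grid=None):
    grid = grid or tuple(np.geomspace(2.0, 1500.0, 14))
    return gen_velocity_table(
        KineticTruth(kcat=kcat, km=km, kk=kk, cv=0.0, substrate_uM=grid), seed=0
    )


class TestRoundTrips:
    def test_mm_round_trip(self):
        fit = fit_mm(noise_free(10.0, 50.0))
        assert fit.kcat == pytest.approx(10.0, rel=1e-4)
        assert fit.km == pytest.approx(50.0, rel=1e-4)

    @pytest.mark.parametrize("kcat, km, kk", ENZYME_TRUTHS)
    def test_substrate_inhibition_round_trip(self, kcat, km, kk):
        """Noise-free generation and refit recovers each enzyme's constants."""
        fit = fit_substrate_inhibition(noise_free(kcat, km, kk))
        assert fit.kcat == pytest.approx(kcat, rel=1e-3)
        assert fit.km == pytest.approx(km, rel=1e-3)
        assert fit.kk == pytest.approx(kk, rel=1e-3)

    def test_duplicated_replicates_leave_fit_unchanged(self):
        ds = noise_free(27.6, 23.17, 307.30)
        doubled = KineticsDataset(
            substrate_uM=np.concatenate([ds.substrate_uM] * 2),
            velocity=np.concatenate([ds.velocity] * 2),
        )
        a, b = fit_substrate_inhibition(ds), fit_substrate_inhibition(doubled)
        assert a.kcat == pytest.approx(b.kcat, rel=1e-6)
        assert a.km == pytest.approx(b.km, rel=1e-6)

    def test_scale_equivariance_in_enzyme_concentration(self):
        """Scaling E₀ and µM/s velocities together leaves constants unchanged."""
        truth = KineticTruth(kcat=27.6, km=23.17, kk=307.30, cv=0.0)
        base = gen_velocity_table(truth, seed=0)
        for factor in (1.0, 4.0):
            e0 = 5.0 * factor
            ds = KineticsDataset(
                substrate_uM=base.substrate_uM,
                velocity=base.velocity * e0 * 1e-3,  # to µM/s at this E₀
                velocity_units="uM_per_s",
                e0_nM=e0,
            )
            fit = fit_substrate_inhibition(ds)
            assert fit.kcat == pytest.approx(27.6, rel=1e-3)
            assert fit.km == pytest.approx(23.17, rel=1e-3)


class TestNesting:
    def test_si_predictions_approach_mm_as_kk_grows(self):
        s = np.geomspace(1, 1000, 20)
        mm = mm_velocity(s, 10.0, 50.0)
        gap = [np.max(np.abs(si_velocity(s, 10.0, 50.0, kk) - mm))
               for kk in (1e3, 1e5, 1e7)]
        assert gap[0] > gap[1] > gap[2]
        assert gap[2] < 1e-3

    def test_mm_generated_data_flags_si_fit_as_effectively_mm(self):
        fit = fit_substrate_inhibition(noise_free(10.0, 50.0))
        assert math.isinf(fit.kk)
        assert "effectively_mm" in fit.flags

    def test_efficiency_identity(self):
        fit = fit_substrate_inhibition(noise_free(27.6, 23.17, 307.30))
        assert fit.efficiency == fit.kcat / fit.km


class TestModelSelection:
    def test_noise_free_mm_data_selects_mm_with_zero_f(self):
        sel = select_model(noise_free(10.0, 50.0))
        assert sel.chosen == "MM"
        assert sel.f_statistic == 0.0

    def test_strong_inhibition_selected_reliably(self):
        """MM_SI wins on strongly inhibited data (Kk = 10·Km) at 5% noise."""
        wins = 0
        truth = KineticTruth(kcat=20.0, km=40.0, kk=400.0, cv=0.05)
        for seed in range(100):
            sel = select_model(gen_velocity_table(truth, seed=seed))
            wins += sel.chosen == "MM_SI"
        assert wins >= 95

    def test_mm_data_respects_test_size(self):
        """False-positive rate of the F-test stays near its nominal 5%."""
        wins = 0
        truth = KineticTruth(kcat=20.0, km=40.0, cv=0.05)
        for seed in range(100):
            sel = select_model(gen_velocity_table(truth, seed=seed))
            wins += sel.chosen == "MM"
        assert wins >= 90


class TestDegenerateInputs:
    def test_saturated_velocities_flagged(self):
        s = np.array([100.0, 200.0, 400.0, 800.0])
        ds = KineticsDataset(substrate_uM=s, velocity=np.full(4, 8.0))
        fit = fit_mm(ds)
        assert "degenerate_km" in fit.flags

    def test_no_observed_decline_flags_kk_unidentifiable(self):
        ds = noise_free(10.0, 50.0, 5e4, grid=tuple(np.geomspace(1, 300, 8)))
        fit = fit_substrate_inhibition(ds)
        assert "kk_unidentifiable" in fit.flags

    def test_too_few_levels_rejected(self):
        ds = KineticsDataset(substrate_uM=np.array([1.0, 10.0]),
                             velocity=np.array([1.0, 5.0]))
        with pytest.raises(ValueError, match="levels"):
            fit_mm(ds)
        with pytest.raises(ValueError, match="levels"):
            fit_substrate_inhibition(ds)

    def test_nonpositive_substrate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KineticsDataset(substrate_uM=np.array([0.0, 1.0, 2.0, 3.0]),
                            velocity=np.ones(4))


class TestConfidenceIntervals:
    def test_noise_free_intervals_collapse(self):
        ds = noise_free(27.6, 23.17, 307.30)
        fit = confidence_intervals(fit_substrate_inhibition(ds), ds, n_boot=100, seed=1)
        for lo, hi in fit.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_reproduces_intervals(self):
        truth = KineticTruth(kcat=27.6, km=23.17, kk=307.30, cv=0.05)
        ds = gen_velocity_table(truth, seed=2, replicates=3)
        a = confidence_intervals(fit_substrate_inhibition(ds), ds, n_boot=100, seed=5)
        b = confidence_intervals(fit_substrate_inhibition(ds), ds, n_boot=100, seed=5)
        assert a.ci == b.ci

    def test_coverage_of_true_parameters(self):
        """95% bootstrap CIs cover the generating kcat and Km most of the time."""
        truth = KineticTruth(kcat=27.6, km=23.17, kk=307.30, cv=0.05)
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            ds = gen_velocity_table(truth, seed=seed, replicates=3)
            fit = confidence_intervals(fit_substrate_inhibition(ds), ds,
                                       n_boot=100, seed=seed)
            lo, hi = fit.ci["kcat"]
            lo2, hi2 = fit.ci["km"]
            hits += (lo <= truth.kcat <= hi) and (lo2 <= truth.km <= hi2)
        assert hits >= int(0.80 * n_rep)

    def test_tiny_bootstrap_warns(self):
        ds = noise_free(10.0, 50.0)
        with pytest.warns(UserWarning, match="too few"):
            confidence_intervals(fit_mm(ds), ds, n_boot=10, seed=0)


class TestInitialRate:
    def test_linear_timecourse_slope_over_e0(self):
        t = np.linspace(0, 60, 31)
        tc = Timecourse(time_s=t, product_uM=0.0724 * t, e0_nM=5.0, substrate_uM=250.0)
        assert initial_rate(tc) == pytest.approx(14.48, abs=0.01)

    def test_flat_timecourse_gives_zero(self):
        t = np.linspace(0, 60, 10)
        tc = Timecourse(time_s=t, product_uM=np.zeros(10), e0_nM=5.0, substrate_uM=250.0)
        assert initial_rate(tc) == 0.0

    def test_catalytically_dead_enzyme_gives_zero(self):
        """An inactive catalytic mutant: no product, zero turnover."""
        truth = KineticTruth(kcat=1e-12, km=23.17, cv=0.0)
        tc = gen_timecourse(truth, substrate_uM=250.0)
        assert initial_rate(tc) == pytest.approx(0.0, abs=1e-9)

    def test_no_points_in_linear_window_rejected(self):
        t = np.linspace(0, 60, 10)
        tc = Timecourse(time_s=t, product_uM=np.full(10, 200.0), e0_nM=5.0,
                        substrate_uM=250.0)
        with pytest.raises(ValueError, match="linear window"):
            initial_rate(tc)

    def test_decreasing_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Timecourse(time_s=np.array([0.0, 2.0, 1.0]), product_uM=np.zeros(3),
                       e0_nM=5.0, substrate_uM=250.0)
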