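"""Relaxation-rate extraction, offset correction, NOE, tau_c, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import grid_search_rate
from solnmr import (RelaxationRates, RelaxationSeries, SpectrometerConfig,
                    SpinParams, classify_dynamics, estimate_tauc,
                    fit_exponential, het_noe, intensity_ratio,
                    modelfree_rates, r2_from_r1rho)
from solnmr.synth import R1_DELAYS, simulate_decay

CFG = SpectrometerConfig(field_h1=800.0, spinlock=1500.0)


class TestFitExponential:
    @pytest.mark.parametrize("rate", [0.1, 1.2, 5.0, 20.0, 50.0])
    def test_noise_free_exact(self, rate):
        series = simulate_decay(rate, 100.0, R1_DELAYS, noise_sd=0.0)
        r, i0, sd = fit_exponential(series)
        assert r == pytest.approx(rate, rel=1e-6)
        assert i0 == pytest.approx(100.0, rel=1e-6)
        assert sd == 0.0

    def test_constant_series_rate_zero(self):
        series = RelaxationSeries(1, R1_DELAYS, np.full(len(R1_DELAYS), 50.0))
        r, i0, _ = fit_exponential(series)
        assert r == pytest.approx(0.0, abs=1e-8)
        assert i0 == pytest.approx(50.0, rel=1e-8)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        series = simulate_decay(1.5, 100.0, R1_DELAYS, noise_sd=2.0, seed=11)
        r, _, _ = fit_exponential(series)
        r_grid = grid_search_rate(series.delays, series.intensities)
        assert r == pytest.approx(r_grid, abs=2e-4)  # grid resolution 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_exponential(RelaxationSeries(1, [0.0, 0.1], [10.0, 5.0]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_exponential(RelaxationSeries(1, R1_DELAYS, np.zeros(len(R1_DELAYS))))

    def test_monte_carlo_sd_scales_with_noise(self):
        lo = fit_exponential(simulate_decay(1.5, 100, R1_DELAYS, 1.0, seed=2),
                             n_mc=100)[2]
        hi = fit_exponential(simulate_decay(1.5, 100, R1_DELAYS, 5.0, seed=2),
                             n_mc=100)[2]
        assert 0 < lo < hi

    def test_recovery_within_3pct_median_over_100_residues(self):
        """2% intensity noise: median relative rate error stays below 3%."""
        errs = []
        for seed in range(100):
            rate = 1.0 + 0.02 * seed  # span ~[1, 3] s^-1, R1-like
            series = simulate_decay(rate, 100.0, R1_DELAYS, noise_sd=2.0,
                                    seed=seed)
            r, _, _ = fit_exponential(series, n_mc=0)
            errs.append(abs(r - rate) / rate)
        assert np.median(errs) < 0.03


class TestOffsetCorrection:
    @given(r1rho=st.floats(1.0, 30.0), r1=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_identity_at_zero_offset(self, r1rho, r1):
        r2, _ = r2_from_r1rho(r1rho, r1, CFG, offset=0.0)
        assert r2 == pytest.approx(r1rho, rel=1e-12)

    def test_45_degree_tilt(self):
        """offset = spinlock puts sin2 = cos2 = 1/2: R2 = 2 R1rho - R1."""
        r2, _ = r2_from_r1rho(10.0, 2.0, CFG, offset=CFG.spinlock)
        assert r2 == pytest.approx(18.0, rel=1e-12)

    def test_30_degree_tilt(self):
        cfg = SpectrometerConfig(spinlock=1000.0)
        offset = 1000.0 * math.tan(math.radians(30.0))
        r2, _ = r2_from_r1rho(8.0, 1.6, cfg, offset=offset)
        assert r2 == pytest.approx((8.0 - 1.6 * 0.25) / 0.75, rel=1e-12)

    def test_near_90_degrees_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            r2_from_r1rho(10.0, 2.0, CFG, offset=CFG.spinlock * 1e6)

    def test_uncertainty_propagation_quadrature(self):
        _, sd = r2_from_r1rho(10.0, 2.0, CFG, offset=CFG.spinlock,
                              r1rho_sd=0.3, r1_sd=0.4)
        assert sd == pytest.approx(math.hypot(0.3, 0.4 * 0.5) / 0.5, rel=1e-12)


class TestHetNoe:
    def test_equal_intensities_give_unity(self):
        assert het_noe(80.0, 80.0)[0] == 1.0

    def test_direct_ratio(self):
        assert het_noe(0.6, 0.8)[0] == pytest.approx(0.75, rel=1e-12)

    def test_rigid_residue_noe_above_criterion(self):
        """Synthetic rigid amide (S2=0.87, 6.2 ns, 800 MHz): NOE > 0.8,
        the rigidity criterion for ordered regions."""
        _, _, noe_true = modelfree_rates(SpinParams(0.87, 6.2, field_h1=800))
        noe, _ = het_noe(noe_true * 100.0, 100.0)
        assert noe > 0.8

    def test_reference_near_zero_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            het_noe(0.5, 0.2, noise_sd=0.1)


def _rates_for(params_list, with_noe=True):
    out = []
    for rid, p in enumerate(params_list, start=1):
        r1, r2, noe = modelfree_rates(p)
        out.append(RelaxationRates(residue_id=rid, r1=r1, r1_sd=0.01,
                                   r2=r2, r2_sd=0.05,
                                   noe=noe if with_noe else math.nan))
    return out


class TestTaucEstimator:
    def test_rigid_forward_round_trip(self):
        rates = _rates_for([SpinParams(1.0, 3.0, field_h1=800)] * 8)
        est = estimate_tauc(rates, CFG)
        assert est.tau_c == pytest.approx(3.0, rel=1e-6)

    def test_ordered_region_recovery_within_2pct(self):
        """Rates simulated for ordered-region residues (S2=0.87, tau_e=50 ps)
        at 800 MHz from a 6.2 ns tumbler invert back within 2%."""
        rates = _rates_for([SpinParams(0.87, 6.2, 50.0, 0.0, 800)] * 20,
                           with_noe=False)
        est = estimate_tauc(rates, CFG)
        assert est.tau_c == pytest.approx(6.2, rel=0.02)

    def test_exchange_outlier_is_trimmed(self):
        core = [SpinParams(0.87, 6.2, 10.0, 0.0, 800)] * 10
        est0 = estimate_tauc(_rates_for(core), CFG)
        with_rex = core + [SpinParams(0.87, 6.2, 10.0, 10.0, 800)]
        est1 = estimate_tauc(_rates_for(with_rex), CFG)
        assert est1.tau_c == pytest.approx(est0.tau_c, rel=1e-9)
        assert 11 in est1.trimmed_ids

    def test_flexible_residues_trimmed_by_noe(self):
        core = [SpinParams(0.87, 6.2, 10.0, 0.0, 800)] * 10
        mixed = core + [SpinParams(0.4, 6.2, 500.0, 0.0, 800)] * 3
        est = estimate_tauc(_rates_for(mixed), CFG)
        assert set(est.trimmed_ids) == {11, 12, 13}

    def test_monotone_in_ratio(self):
        """Feeding a larger R2/R1 ratio always yields a longer tau_c."""
        taus = []
        for tau_true in (3.0, 5.0, 8.0, 12.0):
            rates = _rates_for([SpinParams(1.0, tau_true, field_h1=800)] * 6)
            taus.append(estimate_tauc(rates, CFG).tau_c)
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_approx_closed_form_close_to_inversion(self):
        rates = _rates_for([SpinParams(1.0, 6.2, field_h1=800)] * 8)
        full = estimate_tauc(rates, CFG).tau_c
        approx = estimate_tauc(rates, CFG, method="approx").tau_c
        assert approx == pytest.approx(full, rel=0.1)

    def test_too_few_residues_rejected(self):
        rates = _rates_for([SpinParams(1.0, 6.2, field_h1=800)] * 3)
        with pytest.raises(ValueError, match=">= 5"):
            estimate_tauc(rates, CFG)


class TestClassification:
    def _base_rates(self):
        return _rates_for([SpinParams(0.87, 6.2, 10.0, 0.0, 800)] * 10)

    def test_low_noe_is_fast(self):
        rates = self._base_rates()
        rates[0].noe = 0.6
        labels = {l.residue_id: l.label for l in classify_dynamics(rates)}
        assert labels[1] == "fast"

    def test_elevated_r2_is_exchange(self):
        rates = self._base_rates()
        rates[0].r2 += 6.0  # far above the rigid-core spread
        labels = {l.residue_id: l.label for l in classify_dynamics(rates)}
        assert labels[1] == "exchange"

    def test_both_criteria(self):
        rates = self._base_rates()
        rates[0].noe = 0.5
        rates[0].r2 += 6.0
        assert classify_dynamics(rates)[0].label == "both"

    def test_typical_residue_is_rigid(self):
        labels = classify_dynamics(self._base_rates())
        assert labels[3].label == "rigid"

    def test_missing_amide_flagged(self):
        rates = self._base_rates() + [RelaxationRates(residue_id=99)]
        assert classify_dynamics(rates)[-1].label == "broadened/missing"

    def test_partition_covers_each_residue_once(self):
        rates = self._base_rates()
        rates[2].noe = 0.4
        rates[5].r2 += 8.0
        rates.append(RelaxationRates(residue_id=42))
        labels = classify_dynamics(rates)
        assert len(labels) == len(rates)
        assert sorted(l.residue_id for l in labels) == \
            sorted(r.residue_id for r in rates)
        assert all(l.label in {"rigid", "fast", "exchange", "both",
                               "broadened/missing"} for l in labels)


class TestIntensityRatio:
    def test_identical_tables(self):
        free = {1: 2.0, 2: 3.0}
        assert intensity_ratio(free, free) == {1: 1.0, 2: 1.0}

    def test_uniform_attenuation(self):
        free = {1: 2.0, 2: 5.0, 3: 1.0}
        bound = {k: 0.3 * v for k, v in free.items()}
        ratios = intensity_ratio(bound, free)
        assert all(v == pytest.approx(0.3) for v in ratios.values())

    def test_matches_elementwise_division(self):
        rng = np.random.default_rng(5)
        free = {i: float(v) for i, v in enumerate(rng.uniform(0.5, 2.0, 30), 1)}
        bound = {i: float(v) for i, v in enumerate(rng.uniform(0.0, 2.0, 30), 1)}
        ratios = intensity_ratio(bound, free)
        for rid in free:
            assert ratios[rid] == pytest.approx(bound[rid] / free[rid])

    def test_missing_in_bound_reported_as_zero(self):
        assert intensity_ratio({1: 1.0}, {1: 2.0, 2: 2.0})[2] == 0.0

    def test_zero_free_intensity_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            intensity_ratio({1: 1.0}, {1: 0.0})
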