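"""Background correction, calibration, elementary fits, and global refinement."""

import numpy as np
import pytest

from iffl import (CircuitConfig, InputSchedule, MeasurementModel, RateParams,
                  Trace, calibrate, correct_background, fit_binding,
                  fit_degradation, fit_transcription, gen_binding_assay,
                  gen_blank_assay, gen_circuit_assay, gen_degradation_assay,
                  gen_transcription_assay, refine_global, refined_rates)
from iffl.fitting import default_bounds


class TestBackgroundCorrection:
    def test_no_background_leaves_trace_unchanged(self, rates, config):
        sched = InputSchedule(((40.0, "A", 20.0),))  # blank before reaction
        mm = MeasurementModel(noise_sd=0.0, bleach_amp=0.0)
        raw, _ = gen_circuit_assay(rates, config, sched, mm, t_end=120)
        corrected, fit = correct_background(raw, (0.0, 38.0))
        assert np.allclose(corrected["fluor"], raw["fluor"], atol=1e-8)

    def test_noiseless_recovery_is_exact(self, rates, config):
        sched = InputSchedule(((60.0, "A", 20.0),))
        mm = MeasurementModel(noise_sd=0.0, bleach_amp=5.0, bleach_rate=0.004)
        raw, truth = gen_circuit_assay(rates, config, sched, mm, t_end=240)
        corrected, fit = correct_background(raw, (0.0, 58.0))
        assert fit["bleach_amp"] == pytest.approx(5.0, rel=1e-6)
        assert fit["bleach_rate"] == pytest.approx(0.004, rel=1e-6)
        y = np.interp(raw.t, truth.t, truth["y"])
        assert np.allclose(corrected["fluor"], y, atol=1e-6)

    def test_noisy_recovery_from_dedicated_blank(self):
        """At 2% noise the background parameters are recovered within 10%
        from a full-length blank measurement."""
        mm = MeasurementModel(noise_sd=0.08, bleach_amp=4.0, bleach_rate=0.003,
                              seed=11)
        blank = gen_blank_assay(mm, t_end=400.0)
        _, fit = correct_background(blank, blank=blank)
        assert fit["bleach_amp"] == pytest.approx(4.0, rel=0.1)
        assert fit["bleach_rate"] == pytest.approx(0.003, rel=0.1)

    def test_non_decaying_background_flagged(self):
        t = np.arange(0, 100.0)
        raw = Trace(t, {"fluor": 1.0 + 0.01 * t})
        _, fit = correct_background(raw, (0.0, 99.0))
        assert fit.warnings


class TestCalibration:
    def test_single_standard_slope(self):
        t = np.arange(5.0)
        tr = Trace(t, {"fluor": 2.0 * np.ones(5)})
        cal, slope = calibrate(tr, [(10.0, 10.0)])
        assert slope == pytest.approx(1.0)
        assert np.allclose(cal["rMG"], 2.0)

    def test_collinear_standards_agree(self):
        t = np.arange(5.0)
        tr = Trace(t, {"fluor": np.ones(5)})
        _, s1 = calibrate(tr, [(10.0, 30.0)])
        _, s2 = calibrate(tr, [(10.0, 30.0), (20.0, 60.0)])
        assert s1 == pytest.approx(s2) == pytest.approx(3.0)

    def test_recovers_generator_gain(self, clean_mm):
        mm = MeasurementModel(fluor_per_nM=2.5, noise_sd=0.0, bleach_amp=0.0)
        raw, truth = gen_binding_assay(10.0, 0.005, mm)
        cal, slope = calibrate(raw, [(10.0, 25.0)])
        assert slope == pytest.approx(2.5)
        assert np.allclose(cal["rMG"], truth["rMG"], atol=1e-12)


class TestBindingFit:
    def test_noiseless_rate_recovery(self, clean_mm):
        _, truth = gen_binding_assay(10.0, 0.005, clean_mm)
        fit = fit_binding(truth, 10.0)
        assert fit["k"] == pytest.approx(0.005, rel=1e-6)
        assert fit["intercept"] == pytest.approx(0.1)

    def test_fitted_curve_starts_at_c0(self, clean_mm):
        from iffl.synthetic_data import binding_decay
        _, truth = gen_binding_assay(10.0, 0.005, clean_mm)
        fit = fit_binding(truth, 10.0)
        assert binding_decay(np.array([0.0]), fit["k"], 10.0)[0] == \
            pytest.approx(10.0)

    def test_noisy_recovery_within_ten_percent(self):
        mm = MeasurementModel(noise_sd=0.2, seed=5)  # 2% of c0
        raw, _ = gen_binding_assay(10.0, 0.005, mm, t_end=240.0)
        cal, _ = calibrate(raw, [(10.0, 10.0)])
        fit = fit_binding(cal, 10.0)
        assert fit["k"] == pytest.approx(0.005, rel=0.1)


class TestTranscriptionFit:
    def test_noiseless_burst_parameters_recovered(self, rates, clean_mm):
        cfg = CircuitConfig(TrMG_tot=150.0, TiMG_tot=0.0)
        _, truths = gen_transcription_assay([20.0, 40.0, 80.0], rates, cfg,
                                            clean_mm, t_end=240.0)
        fit = fit_transcription(truths, cfg)
        assert fit["kp2"] == pytest.approx(rates.kp2, rel=1e-5)
        assert fit["B"] == pytest.approx(rates.B, rel=1e-4)
        assert fit["tau_b"] == pytest.approx(rates.tau_b, rel=1e-4)

    def test_burst_free_fit_with_b_fixed(self, rates, clean_mm):
        cfg = CircuitConfig(TrMG_tot=150.0, TiMG_tot=0.0)
        _, truths = gen_transcription_assay([20.0, 40.0],
                                            rates.replace(B=0.0), cfg,
                                            clean_mm)
        fit = fit_transcription(truths, cfg, fit_burst=False)
        assert fit["B"] == 0.0
        assert fit["kp2"] == pytest.approx(rates.kp2, rel=1e-8)

    def test_shared_rate_no_worse_than_per_trace_lines(self, rates, clean_mm):
        """On burst-free linear fixtures, the joint single-rate fit matches
        the per-trace through-origin regressions (nested-model property)."""
        cfg = CircuitConfig(TrMG_tot=150.0, TiMG_tot=0.0)
        _, truths = gen_transcription_assay([20.0, 40.0],
                                            rates.replace(B=0.0), cfg,
                                            clean_mm)
        fit = fit_transcription(truths, cfg, fit_burst=False)
        rss_independent = 0.0
        for tr in truths:
            slope = np.sum(tr.t * tr["rMG"]) / np.sum(tr.t**2)
            rss_independent += np.sum((tr["rMG"] - slope * tr.t) ** 2)
        assert fit.residual_ss <= rss_independent + 1e-9

    def test_single_trace_rejected(self, rates, clean_mm):
        cfg = CircuitConfig(TrMG_tot=150.0, TiMG_tot=0.0)
        _, truths = gen_transcription_assay([20.0], rates, cfg, clean_mm)
        with pytest.raises(ValueError):
            fit_transcription(truths, cfg)


class TestDegradationFit:
    def test_noiseless_rates_recovered_within_one_percent(self, rates, clean_mm):
        _, truth = gen_degradation_assay(1000.0, 100.0, 75.0, rates, clean_mm,
                                         t_end=400.0)
        fit = fit_degradation(truth, 1000.0, 100.0, k=rates.k)
        assert fit["beta1"] == pytest.approx(rates.beta1, rel=0.01)
        assert fit["gamma1"] == pytest.approx(rates.gamma1, rel=0.01)

    def test_without_recycling_degradation_stalls_at_stoichiometry(self, rates,
                                                                   clean_mm):
        _, truth = gen_degradation_assay(
            1000.0, 100.0, 75.0, rates.replace(gamma1=0.0, beta1=0.0),
            clean_mm, t_end=600.0)
        assert truth["rMG"][-1] >= 1000.0 - 100.0 - 1e-6

    def test_no_inhibitor_not_identifiable(self, rates, clean_mm):
        _, truth = gen_degradation_assay(1000.0, 0.0, 75.0, rates, clean_mm)
        with pytest.raises(ValueError):
            fit_degradation(truth, 1000.0, 0.0, k=rates.k)


@pytest.fixture(scope="module")
def noiseless_set():
    from iffl import FCD_CONFIG, REPRESENTATIVE_RATES
    truth = REPRESENTATIVE_RATES
    sched = InputSchedule(((0.0, "A", 20.0),))
    conds = [FCD_CONFIG, FCD_CONFIG.replace(rnase_r=150.0),
             FCD_CONFIG.replace(TrMG_tot=100.0, TiMG_tot=100.0)]
    triples = []
    for i, cfg in enumerate(conds):
        mm = MeasurementModel(noise_sd=0.0, bleach_amp=0.0,
                              sample_dt=2.0, seed=i)
        _, tr_truth = gen_circuit_assay(truth, cfg, sched, mm, t_end=300)
        t = np.arange(0.0, 301.0, 2.0)
        tr = Trace(t, {"rMG": np.interp(t, tr_truth.t, tr_truth["y"])})
        triples.append((tr, cfg, sched))
    return truth, triples


class TestGlobalRefinement:

    def test_truth_initialization_converges_to_noise_floor(self, noiseless_set):
        truth, triples = noiseless_set
        res = refine_global(triples, truth, n_starts=1)
        assert res.converged
        assert res.residual_ss < 1e-10

    def test_recovery_from_perturbed_initialization(self, noiseless_set):
        truth, triples = noiseless_set
        init = truth.replace(k=truth.k * 3, beta1=truth.beta1 / 3,
                             gamma1=truth.gamma1 * 2, kp1=truth.kp1 * 1.2)
        res = refine_global(triples, init, n_starts=1)
        for name in ("kp1", "kp2", "k", "beta1", "gamma1"):
            assert res.estimates[name] == pytest.approx(
                getattr(truth, name), rel=0.05), name

    def test_bounds_excluding_truth_pin_and_flag(self, noiseless_set):
        truth, triples = noiseless_set
        init = truth.replace(k=truth.k * 4)
        bounds = default_bounds(init)
        bounds["k"] = (truth.k * 2, truth.k * 8)  # excludes the true value
        res = refine_global(triples, init, bounds=bounds, n_starts=1)
        assert "k" in res.at_bound()
        assert any("bounds" in w for w in res.warnings)

    def test_objective_never_increases_from_initialization(self, noiseless_set):
        truth, triples = noiseless_set
        init = truth.replace(beta1=truth.beta1 * 2)
        res = refine_global(triples, init, n_starts=1)

        # residual at the initial point, same weighting
        weights = [1.0 / np.abs(tr["rMG"]).max() for tr, _, _ in triples]
        from iffl.fitting import _forward_y
        from iffl.trace import SimOptions
        theta0 = np.array([getattr(init, n) for n in
                           ("kp1", "kp2", "B", "tau_b", "k", "beta1", "gamma1")])
        rss0 = 0.0
        for (tr, cfg, sched), w in zip(triples, weights):
            pred = _forward_y(theta0, cfg, sched, tr.t, init,
                              SimOptions(rtol=1e-7, atol=1e-9, grid_dt=2.0))
            rss0 += np.sum((w * (pred - tr["rMG"])) ** 2)
        assert res.residual_ss <= rss0 + 1e-12

    def test_fit_is_deterministic(self, noiseless_set):
        truth, triples = noiseless_set
        init = truth.replace(k=truth.k * 2)
        a = refine_global(triples, init, n_starts=2, seed=4)
        b = refine_global(triples, init, n_starts=2, seed=4)
        assert a.estimates == b.estimates

    def test_refined_rates_round_trip(self, noiseless_set):
        truth, triples = noiseless_set
        res = refine_global(triples, truth, n_starts=1)
        rates = refined_rates(res, truth)
        assert isinstance(rates, RateParams)
        assert rates.kp2 == res.estimates["kp2"]
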