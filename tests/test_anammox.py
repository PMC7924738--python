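import math

import numpy as np
import pytest

from twbio.anammox import (
    GasProductionCurve,
    PressureTrace,
    SAAResult,
    Spike,
    TwoPhaseFit,
    bottle_saa,
    fit_two_phase,
    pressure_to_moles,
    saa_max,
    spike_comparison,
)
from twbio.simulate import TraceConfig, simulate_pressure_trace


def make_trace(pressures, unit="hPa", **kwargs):
    t = np.arange(len(pressures), dtype=float)
    defaults = dict(v_hs=0.115, temperature_k=303.15, m_vs=0.3,
                    spikes=[Spike(0.0, 11.0)])
    defaults.update(kwargs)
    return PressureTrace("b1", "TW", t, np.asarray(pressures, float), unit,
                         **defaults)


class TestPressureToMoles:
    def test_ideal_gas_hand_value(self):
        # 100 hPa over 0.115 L at 303.15 K -> 4.56e-4 mol
        trace = make_trace([0, 100, 200, 300, 400])
        curve = pressure_to_moles(trace, 0)
        assert curve.n_moles[1] == pytest.approx(4.5624e-4, rel=1e-3)

    def test_zero_pressure_zero_moles(self):
        curve = pressure_to_moles(make_trace([0, 0, 0, 0]), 0)
        assert np.all(curve.n_moles == 0)

    def test_linearity_in_pressure(self):
        p = [0, 10, 25, 40, 55]
        c1 = pressure_to_moles(make_trace(p), 0)
        c2 = pressure_to_moles(make_trace([2 * x for x in p]), 0)
        assert np.allclose(c2.n_moles, 2 * c1.n_moles)

    def test_rebaselined_to_zero(self):
        curve = pressure_to_moles(make_trace([50, 60, 70, 80]), 0)
        assert curve.n_moles[0] == 0

    def test_unit_must_be_declared(self):
        with pytest.raises(ValueError, match="unit"):
            make_trace([0, 1, 2, 3], unit="psi")

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PressureTrace("b", "s", [0, 2, 1, 3], [0, 1, 2, 3], "hPa",
                          spikes=[Spike(0.0, 11.0)])

    def test_too_few_points_in_window(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            pressure_to_moles(make_trace([0, 1, 2, 3, 4],
                                         spikes=[Spike(0.0, 11), Spike(2.0, 11)]), 0)


class TestTwoPhaseFit:
    def test_noiseless_two_line_exact(self):
        t = np.arange(0.0, 21.0)
        m1, m2, brk = 5e-5, 1e-5, 10.0
        y = np.where(t <= brk, m1 * t, m1 * brk + m2 * (t - brk))
        fit = fit_two_phase(GasProductionCurve(t, y))
        assert not fit.no_breakpoint
        assert fit.m1 == pytest.approx(m1, rel=1e-9)
        assert fit.m2 == pytest.approx(m2, rel=1e-9)
        assert fit.breakpoint == pytest.approx(brk, abs=1e-6)

    def test_breakpoint_off_grid_recovered(self):
        t = np.arange(0.0, 21.0)
        m1, m2, brk = 5e-5, 1e-5, 9.37
        y = np.where(t <= brk, m1 * t, m1 * brk + m2 * (t - brk))
        fit = fit_two_phase(GasProductionCurve(t, y))
        assert fit.breakpoint == pytest.approx(brk, abs=1e-5)
        assert fit.m1 == pytest.approx(m1, rel=1e-7)

    def test_perfectly_linear_flags_no_breakpoint(self):
        t = np.arange(0.0, 10.0)
        fit = fit_two_phase(GasProductionCurve(t, 3e-5 * t))
        assert fit.no_breakpoint
        assert fit.m1 == fit.m2 == pytest.approx(3e-5)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="5 points"):
            fit_two_phase(GasProductionCurve(np.arange(4.0), np.arange(4.0)))

    def test_noisy_slope_recovery(self):
        # full-pipeline parameter recovery at instrument-level noise
        errs = []
        for seed in range(50):
            cfg = TraceConfig(saa_true=(0.1,), m2_mol_h=1e-5, noise_sd_hpa=2.0)
            est = bottle_saa(simulate_pressure_trace(cfg, seed=seed), 0)
            errs.append(abs(est - 0.1) / 0.1)
        assert np.median(errs) < 0.05


class TestSaaMax:
    def test_arithmetic(self):
        fit = TwoPhaseFit(2.0e-5, 0.5e-5, 10.0, 0.0, 5, 5)
        assert saa_max(fit, 0.3) == pytest.approx(0.0336)

    def test_equal_slopes_zero(self):
        fit = TwoPhaseFit(1e-5, 1e-5, 10.0, 0.0, 5, 5)
        assert saa_max(fit, 0.3) == 0

    def test_algebraic_inverse(self):
        # SAA = 0.1 with M_VS = 0.3 g requires m1 - m2 = 4.46e-5 mol/h
        fit = TwoPhaseFit(4.4643e-5 + 1e-5, 1e-5, 10.0, 0.0, 5, 5)
        assert saa_max(fit, 0.3) == pytest.approx(0.1, rel=1e-3)

    def test_unit_invariance(self):
        cfg = TraceConfig(saa_true=(0.12,), m2_mol_h=5e-6)
        tr_hpa = simulate_pressure_trace(cfg, seed=3)
        tr_atm = PressureTrace(
            tr_hpa.bottle_id, tr_hpa.sample_id, tr_hpa.times,
            tr_hpa.pressures / 1013.25, "atm",
            v_hs=tr_hpa.v_hs, temperature_k=tr_hpa.temperature_k,
            m_vs=tr_hpa.m_vs, spikes=tr_hpa.spikes,
        )
        assert bottle_saa(tr_atm, 0) == pytest.approx(bottle_saa(tr_hpa, 0))

    def test_scales_inversely_with_inoculum(self):
        fit = TwoPhaseFit(3e-5, 1e-5, 10.0, 0.0, 5, 5)
        assert saa_max(fit, 0.15) == pytest.approx(2 * saa_max(fit, 0.3))


class TestSpikeComparison:
    @staticmethod
    def simulated_results(rng, spike2_factor=2.0, permute=False):
        samples = [f"TW{i}" for i in range(1, 9)]
        if permute:
            samples = samples[::-1]
        results = []
        for i, sid in enumerate(samples):
            base = 0.06 + 0.004 * i
            for spike, mean in ((1, base), (2, spike2_factor * base)):
                vals = list(mean * (1 + 0.1 * rng.standard_normal(2)))
                results.append(SAAResult(sid, spike, vals))
        return results

    def test_spike_doubling_detected(self):
        rng = np.random.default_rng(42)
        table = spike_comparison(self.simulated_results(rng))
        assert table.loc["C(spike)", "PR(>F)"] < 0.001

    def test_sample_label_permutation_leaves_spike_f(self):
        res = self.simulated_results(np.random.default_rng(7))
        f1 = spike_comparison(res).loc["C(spike)", "F"]
        permuted = [SAAResult("X" + r.sample_id, r.spike_index, r.per_bottle)
                    for r in res]
        f2 = spike_comparison(permuted).loc["C(spike)", "F"]
        assert f1 == pytest.approx(f2)

    def test_identical_values_documented(self):
        results = [SAAResult(f"TW{i}", s, [0.1, 0.1])
                   for i in range(1, 4) for s in (1, 2)]
        table = spike_comparison(results)
        p = table.loc["C(spike)", "PR(>F)"]
        assert math.isnan(p) or p >= 0.999

    def test_single_replicate_drops_interaction(self):
        results = [SAAResult(f"TW{i}", s, [0.1 + 0.01 * i * s])
                   for i in range(1, 4) for s in (1, 2)]
        with pytest.warns(UserWarning, match="interaction"):
            table = spike_comparison(results)
        assert not any("):C(" in idx for idx in table.index)
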