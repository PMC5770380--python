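"""TIRF trace selection, populations, cross-correlation, injection kinetics."""

import numpy as np
import pytest

from chromofret import kinetics as kin
from chromofret import synthetic as syn
from chromofret import tirf

from conftest import make_single_species_model


def make_trace(tid, n=1200, total=1000.0, e=0.3, bleach_a=None, bleach_d=None,
               bg=50.0, beta=0.1, noise=3.0, seed=0, recover_donor=True):
    """Deterministic synthetic trace with explicit bleach frames."""
    rng = np.random.default_rng(seed)
    d = np.full(n, bg + total * (1 - e))
    a = np.full(n, bg + total * e + beta * total * (1 - e))
    if bleach_a is not None and (bleach_d is None or bleach_a < bleach_d):
        d[bleach_a:] = bg + (total if recover_donor else total * (1 - e))
        a[bleach_a:] = bg + beta * total
    if bleach_d is not None:
        d[bleach_d:] = bg
        a[bleach_d:] = bg
    if noise > 0:
        d = d + rng.normal(0, noise, n)
        a = a + rng.normal(0, noise, n)
    return tirf.TIRFTrace(tid, 0.1, d, a, bleach_d, bleach_a)


#: 20-trace panel with hand-enumerated pass/fail per the four criteria
def build_selection_panel():
    panel, expected = [], {}
    i = 0
    # 5 good traces: bright, long pre-bleach, acceptor first w/ recovery, donor dies in time
    for k in range(5):
        panel.append(make_trace(i, total=900, bleach_a=400 + 30 * k, bleach_d=800 + 20 * k, seed=i))
        expected[i] = (True, "")
        i += 1
    # 3 dim traces -> initial_total
    for k in range(3):
        panel.append(make_trace(i, total=450, bleach_a=400, bleach_d=800, seed=i))
        expected[i] = (False, "initial_total")
        i += 1
    # 3 short pre-bleach (< 5 s = 50 frames)
    for k in range(3):
        panel.append(make_trace(i, total=900, bleach_a=30 + 5 * k, bleach_d=700, seed=i))
        expected[i] = (False, "prebleach_span")
        i += 1
    # 3 missing donor recovery after acceptor loss -> single_step
    for k in range(3):
        panel.append(make_trace(i, total=900, bleach_a=400, bleach_d=900, seed=i,
                                recover_donor=False))
        expected[i] = (False, "single_step")
        i += 1
    # 3 no donor bleach inside 120 s -> donor_bleach_window
    for k in range(3):
        panel.append(make_trace(i, total=900, bleach_a=600, bleach_d=None, seed=i))
        expected[i] = (False, "donor_bleach_window")
        i += 1
    # 3 good donor-first traces
    for k in range(3):
        panel.append(make_trace(i, total=900, bleach_a=None, bleach_d=700 + 10 * k, seed=i))
        expected[i] = (True, "")
        i += 1
    return panel, expected


class TestSelection:
    def test_enumerated_panel_exact(self):
        panel, expected = build_selection_panel()
        crit = tirf.SelectionCriteria(background_donor=50.0, background_acceptor=50.0)
        accepted, rejected = tirf.select_traces(panel, crit)
        got = {t.trace_id: (True, "") for t in accepted}
        got.update({t.trace_id: (False, r) for t, r in rejected})
        assert got == expected

    def test_order_independence(self):
        panel, _ = build_selection_panel()
        crit = tirf.SelectionCriteria(background_donor=50.0, background_acceptor=50.0)
        a1, _ = tirf.select_traces(panel, crit)
        a2, _ = tirf.select_traces(panel[::-1], crit)
        assert {t.trace_id for t in a1} == {t.trace_id for t in a2}

    def test_bleach_step_detection(self):
        tr = make_trace(0, bleach_a=400, bleach_d=800, noise=5.0, seed=3)
        det_a = tirf.detect_bleach_step(tr.acceptor)
        det_d = tirf.detect_bleach_step(tr.donor[400:])  # after acceptor loss
        assert det_a is not None and abs(det_a - 400) <= 2
        assert det_d is not None and abs(det_d - 400) <= 2
        flat = np.random.default_rng(0).normal(500, 5, 1000)
        assert tirf.detect_bleach_step(flat) is None


class TestEfficiencyTrace:
    def test_equal_channels_half(self):
        tr = tirf.TIRFTrace(0, 0.1, np.full(100, 400.0), np.full(100, 400.0))
        e, mask = tirf.efficiency_trace(tr, beta=0.0)
        np.testing.assert_allclose(e[mask], 0.5)

    def test_post_bleach_masked(self):
        tr = make_trace(0, bleach_a=300, bleach_d=700, noise=0.0)
        e, mask = tirf.efficiency_trace(tr, beta=0.1, background_donor=50, background_acceptor=50)
        assert mask[:300].all()
        assert not mask[300:].any()
        np.testing.assert_allclose(e[mask], 0.3, atol=1e-9)

    def test_two_state_matches_truth(self, pair568):
        lo = kin.FRETSpecies("lo", pair568, efficiency=0.15)
        hi = kin.FRETSpecies("hi", pair568, efficiency=0.6)
        m = kin.two_state_model(lo, hi, relaxation_time=2.0)
        cfg = syn.TIRFSimConfig(n_traces=15, trace_length=400, seed=4,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        traces, truths = syn.simulate_tirf_traces(m, cfg)
        within = 0
        total = 0
        for tr, gt in zip(traces, truths):
            e, mask = tirf.efficiency_trace(tr, beta=0.1, background_donor=50,
                                            background_acceptor=50)
            sd = np.std(e[mask] - gt.state_e[mask])
            z = np.abs(e[mask] - gt.state_e[mask]) / sd
            within += (z < 3).sum()
            total += mask.sum()
        assert within / total > 0.95


class TestPopulations:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0.4, 0.05, 10**4)
        fit = tirf.fit_population_gaussians(e, 1)
        assert fit.means[0] == pytest.approx(0.4, abs=0.01)
        assert fit.sigmas[0] == pytest.approx(0.05, rel=0.1)

    def test_two_separated_components(self):
        rng = np.random.default_rng(6)
        e = np.concatenate([rng.normal(0.1, 0.04, 6000), rng.normal(0.5, 0.06, 4000)])
        fit = tirf.fit_population_gaussians(e, 2)
        np.testing.assert_allclose(fit.means, [0.1, 0.5], atol=0.02)
        np.testing.assert_allclose(fit.weights, [0.6, 0.4], atol=0.05)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_bin_width_invariance(self):
        rng = np.random.default_rng(7)
        e = np.concatenate([rng.normal(0.15, 0.05, 5000), rng.normal(0.45, 0.07, 5000)])
        f1 = tirf.fit_population_gaussians(e, 2, bin_width=0.02)
        f2 = tirf.fit_population_gaussians(e, 2, bin_width=0.01)
        np.testing.assert_allclose(f1.means, f2.means, atol=0.005)

    def test_minimum_samples(self):
        with pytest.raises(kin.DomainError):
            tirf.fit_population_gaussians(np.random.default_rng(0).normal(0.3, 0.1, 100), 1)


class TestCrossCorrelation:
    def _dynamic_panel(self, t_r, n_traces=100, seed=0, length=1200):
        pair = kin.ALEXA568_647
        lo = kin.FRETSpecies("lo", pair, efficiency=0.15)
        hi = kin.FRETSpecies("hi", pair, efficiency=0.6)
        m = kin.two_state_model(lo, hi, relaxation_time=t_r)
        cfg = syn.TIRFSimConfig(n_traces=n_traces, trace_length=length, seed=seed,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        traces, _ = syn.simulate_tirf_traces(m, cfg)
        return traces

    def test_static_panel_amplitude_zero(self, pair568):
        m = make_single_species_model(pair568, 0.35)
        cfg = syn.TIRFSimConfig(n_traces=60, trace_length=800, seed=8,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        traces, _ = syn.simulate_tirf_traces(m, cfg)
        cc = tirf.trace_cross_correlation(traces, max_lag=3.0)
        ok = np.isfinite(cc.sem[1:]) & (cc.sem[1:] > 0)
        assert np.mean(np.abs(cc.pooled[1:][ok]) < 3 * cc.sem[1:][ok]) > 0.9

    @pytest.mark.parametrize("t_r", [0.2, 0.5])
    def test_relaxation_time_recovery(self, t_r):
        traces = self._dynamic_panel(t_r, seed=int(t_r * 100))
        cc = tirf.trace_cross_correlation(traces, max_lag=min(6 * t_r, 5.0))
        assert cc.fit_amplitudes[0] < 0  # anti-correlated FRET dynamics
        assert cc.fit_times[0] == pytest.approx(t_r, rel=0.25)

    def test_dynamic_fraction(self):
        dyn = self._dynamic_panel(0.3, n_traces=50, seed=9)
        static = []
        pair = kin.ALEXA568_647
        m = make_single_species_model(pair, 0.35)
        cfg = syn.TIRFSimConfig(n_traces=50, trace_length=1200, seed=10,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        static, _ = syn.simulate_tirf_traces(m, cfg)
        cc_mixed = tirf.trace_cross_correlation(list(dyn) + list(static), max_lag=3.0)
        frac = tirf.dynamic_trace_fraction(cc_mixed, threshold=3.0)
        assert abs(frac - 0.5) < 0.12
        assert tirf.dynamic_trace_fraction(cc_mixed, threshold=1e9) == 0.0


class TestInjection:
    def _injection_panel(self, tau=1.0, responder_fraction=0.8, n=120, seed=0):
        pair = kin.ALEXA568_647
        lo = kin.FRETSpecies("open", pair, efficiency=0.1)
        hi = kin.FRETSpecies("closed", pair, efficiency=0.6)
        pre = kin.KineticModel([lo, hi], np.zeros((2, 2)), static_weights=np.array([1.0, 0.0]))
        post = kin.KineticModel([lo, hi], np.array([[0.0, 1.0 / tau], [0.0, 0.0]]),
                                require_irreducible=False)
        cfg = syn.TIRFSimConfig(n_traces=n, trace_length=400, injection_time=5.0,
                                responder_fraction=responder_fraction, post_model=post,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0, seed=seed)
        return syn.simulate_tirf_traces(pre, cfg)

    def test_time_constant_recovery(self):
        traces, _ = self._injection_panel(tau=1.0, responder_fraction=1.0, seed=11)
        res = tirf.fit_injection_kinetics(traces, t_inject=5.0, beta=0.1,
                                          background_donor=50, background_acceptor=50,
                                          shift_threshold=0.2)
        assert res["tau"] == pytest.approx(1.0, rel=0.2)

    def test_responder_classification(self):
        traces, truths = self._injection_panel(tau=0.5, responder_fraction=0.5, n=200, seed=12)
        res = tirf.fit_injection_kinetics(traces, t_inject=5.0, beta=0.1,
                                          background_donor=50, background_acceptor=50,
                                          shift_threshold=0.2)
        true_frac = np.mean([t.is_responder for t in truths])
        assert abs(res["responder_fraction"] - true_frac) < 0.1

    def test_flat_traces_no_fit(self, pair568):
        m = make_single_species_model(pair568, 0.2)
        cfg = syn.TIRFSimConfig(n_traces=30, trace_length=300, seed=13,
                                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        traces, _ = syn.simulate_tirf_traces(m, cfg)
        res = tirf.fit_injection_kinetics(traces, t_inject=5.0, beta=0.1,
                                          background_donor=50, background_acceptor=50)
        assert res["responder_fraction"] == 0.0
        assert np.isnan(res["tau"])
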