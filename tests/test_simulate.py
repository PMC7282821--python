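"""Generator tests: exact Gillespie paths, emission model, truth bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

from pausekin.scenarios import SimScenario
from pausekin.simulate import (
    StatePath,
    emit_intensities,
    simulate_binding_timecourse,
    simulate_ctmc_path,
    simulate_injection_experiment,
)


def make_eq_scenario(**kw) -> SimScenario:
    base = dict(
        mode="equilibrium",
        rate_matrix={"NR->R": 0.8, "R->NR": 0.2},
        duration=100.0,
        n_traces=1,
        seed=0,
    )
    base.update(kw)
    return SimScenario(**base)


class TestCtmcPath:
    def test_zero_rates_yield_single_absorbing_segment(self):
        sc = make_eq_scenario(rate_matrix={"NR->R": 0.0, "R->NR": 0.0}, duration=50.0)
        path = simulate_ctmc_path(sc, seed=1)
        assert path.segments == [("NR", 0.0, 50.0)]
        assert path.absorbing

    def test_one_zero_rate_raises(self):
        sc = make_eq_scenario(rate_matrix={"NR->R": 0.5, "R->NR": 0.0})
        with pytest.raises(ValueError, match="exit rate"):
            simulate_ctmc_path(sc, seed=1)

    def test_stationary_occupancy_matches_detailed_balance(self):
        # k(NR->R)=0.8, k(R->NR)=0.2 -> pi_R = 0.8, the rotated-state
        # occupancy of pre-translocation ribosomes
        sc = make_eq_scenario(duration=10_000.0)
        path = simulate_ctmc_path(sc, seed=5)
        t_r = sum(d for s, _, d in path.segments if s == "R")
        assert t_r / path.total_time == pytest.approx(0.8, abs=0.02)

    def test_mean_dwell_matches_exponential_rate(self):
        # Monte-Carlo mean of NR dwells vs the closed form 1/k
        sc = make_eq_scenario(rate_matrix={"NR->R": 0.6, "R->NR": 0.2}, duration=200.0)
        dwells = []
        for seed in np.random.default_rng(77).integers(0, 2**31, size=400):
            path = simulate_ctmc_path(sc, seed=int(seed))
            dwells.extend(d for s, _, d in path.segments[:-1] if s == "NR")
        dwells = np.asarray(dwells)
        assert len(dwells) > 10_000
        assert dwells.mean() == pytest.approx(1.0 / 0.6, rel=0.02)

    def test_dwells_pass_ks_against_generative_exponential(self):
        sc = make_eq_scenario(rate_matrix={"NR->R": 0.6, "R->NR": 0.6}, duration=20_000.0)
        path = simulate_ctmc_path(sc, seed=3)
        dwells = np.array([d for s, _, d in path.segments[:-1] if s == "NR"])[:10_000]
        res = stats.kstest(dwells, "expon", args=(0, 1 / 0.6))
        assert res.pvalue > 0.01

    def test_seed_determinism(self):
        sc = make_eq_scenario()
        a = simulate_ctmc_path(sc, seed=9)
        b = simulate_ctmc_path(sc, seed=9)
        assert a.segments == b.segments


class TestEmission:
    def test_noiseless_emission_is_deterministic(self):
        sc = make_eq_scenario(
            fret_sd=0.0, intensity_noise_sd=0.0, total_intensity=1000.0, duration=5.0
        )
        path = StatePath([("NR", 0.0, 5.0)])
        tr = emit_intensities(path, sc, seed=0)
        assert np.allclose(tr.acceptor, 600.0)
        assert np.allclose(tr.donor, 400.0)

    def test_acceptor_bleach_drops_acceptor_and_dequenches_donor(self):
        sc = make_eq_scenario(
            fret_sd=0.0,
            intensity_noise_sd=0.0,
            duration=10.0,
            acceptor_bleach_rate=0.5,
        )
        path = StatePath([("NR", 0.0, 10.0)])
        tr = emit_intensities(path, sc, seed=12)
        t_acc = tr.truth["acceptor_bleach_time_s"]
        assert t_acc is not None
        after = tr.time >= t_acc
        assert np.allclose(tr.acceptor[after], 0.0)
        assert np.allclose(tr.donor[after], 1000.0)
        # naive FRET after acceptor bleach is ~0
        assert np.allclose(tr.acceptor[after] / (tr.acceptor[after] + tr.donor[after]), 0.0)

    def test_fret_noise_sd_recovered(self):
        sc = make_eq_scenario(fret_sd=0.08, intensity_noise_sd=0.0, duration=200.0)
        path = StatePath([("NR", 0.0, 200.0)])
        tr = emit_intensities(path, sc, seed=4)
        efret = tr.acceptor / (tr.acceptor + tr.donor)
        assert efret.std(ddof=1) == pytest.approx(0.08, rel=0.10)

    def test_frame_binning_majority_occupancy(self):
        path = StatePath([("NR", 0.0, 0.26), ("R", 0.26, 0.74)])
        labels = path.frame_labels(0.1, 10)
        # frame 2 covers [0.2, 0.3): 0.06 s NR vs 0.04 s R -> NR
        assert list(labels[:4]) == ["NR", "NR", "NR", "R"]


class TestInjectionExperiment:
    def test_degenerate_waits_give_exact_truth(self):
        sc = SimScenario(
            mode="injection",
            fixed_binding_wait=5.0,
            fixed_r_span=3.0,
            rate_matrix={},
            excursion_probability=0.0,
            duration=60.0,
            n_traces=5,
            seed=1,
        )
        traces = simulate_injection_experiment(sc)
        for tr in traces:
            assert tr.truth["tau_bd_true_s"] == 5.0
            assert tr.truth["tau_trl_true_s"] == 3.0
            assert tr.truth["n_excursions_true"] == 0
            assert not tr.truth["tau_bd_censored"]

    def test_binding_wait_median_recovered_in_truth(self):
        sc = SimScenario(
            mode="injection",
            binding_wait_median=3.8,
            translocation_median=1.5,
            rate_matrix={},
            duration=200.0,
            n_traces=500,
            seed=42,
        )
        traces = simulate_injection_experiment(sc)
        waits = [t.truth["tau_bd_true_s"] for t in traces if not t.truth["tau_bd_censored"]]
        assert np.median(waits) == pytest.approx(3.8, rel=0.10)

    def test_censoring_fraction_matches_competing_exponentials(self):
        # acceptor bleach at 0.02 /s competing with an exponential binding
        # wait of median 18.2 s: P(censored) = 1 - integral of the win
        # probability of the binding clock
        sc = SimScenario(
            mode="injection",
            binding_wait_median=18.2,
            translocation_median=10.7,
            rate_matrix={},
            acceptor_bleach_rate=0.02,
            duration=400.0,
            injection_time=10.0,
            n_traces=2000,
            seed=9,
        )
        traces = simulate_injection_experiment(sc)
        cens = np.mean([t.truth["tau_bd_censored"] for t in traces])
        kb = math.log(2) / 18.2
        kc = 0.02
        # bleach clock starts at t=0, binding clock at injection (10 s):
        # P(bleach < injection + wait) = 1 - e^{-kc T} E[e^{-kc W}]
        p_censored = 1.0 - math.exp(-kc * 10.0) * kb / (kb + kc)
        assert cens == pytest.approx(p_censored, abs=0.03)

    def test_excursion_marginal_probability_calibrated(self):
        sc = SimScenario(
            mode="injection",
            binding_wait_median=18.2,
            translocation_median=10.7,
            rate_matrix={},
            excursion_probability=0.64,
            duration=200.0,
            n_traces=3000,
            seed=10,
            fret_sd=0.0,
            intensity_noise_sd=0.0,
        )
        traces = simulate_injection_experiment(sc)
        frac = np.mean([t.truth["n_excursions_true"] > 0 for t in traces])
        assert frac == pytest.approx(0.64, abs=0.03)
        counts = {t.truth["n_excursions_true"] for t in traces}
        assert counts <= {0, 1, 2}

    def test_experiment_seed_determinism(self):
        sc = SimScenario(
            mode="injection",
            binding_wait_median=3.8,
            translocation_median=1.5,
            rate_matrix={},
            duration=40.0,
            n_traces=5,
            seed=77,
        )
        a = simulate_injection_experiment(sc)
        b = simulate_injection_experiment(sc)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.donor, y.donor)
            np.testing.assert_array_equal(x.acceptor, y.acceptor)


class TestBindingTimecourse:
    def test_half_life_point(self):
        t_half = math.log(2) / 0.1
        tc = simulate_binding_timecourse(0.1, [0.0, t_half], noise_sd=0.0, seed=0)
        assert tc.bound[0, 0] == pytest.approx(0.0)
        assert tc.bound[1, 0] == pytest.approx(0.5)

    def test_closed_form_everywhere(self):
        t = np.array([0.5, 1, 2, 4, 8, 16])
        tc = simulate_binding_timecourse(0.4, t, noise_sd=0.0, seed=0)
        expected = 1.0 - np.exp(-0.4 * t)
        np.testing.assert_allclose(tc.bound[:, 0], expected, rtol=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_binding_timecourse(0.0, [1, 2], noise_sd=0.0, seed=0)
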