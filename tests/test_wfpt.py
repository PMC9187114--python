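"""Wiener first-passage density: correctness against independent series
oracles, quadrature, closed forms and simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from itcvigour import wfpt
from itcvigour.models import ModelSpec, dataset_loglik


PARAMS = dict(v=0.6, a=3.27, tau=1.23, z=0.51)


class TestStimulusCoding:
    def test_ss_choice_negated(self):
        assert wfpt.encode_stimulus_coding("SS", 2.4) == -2.4
        assert wfpt.encode_stimulus_coding("LL", 2.4) == 2.4

    def test_round_trip(self):
        choice, rt = wfpt.decode_stimulus_coding(
            wfpt.encode_stimulus_coding(np.array(["SS", "LL"]), np.array([1.1, 2.2])))
        assert list(choice) == ["SS", "LL"]
        assert np.allclose(rt, [1.1, 2.2])

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            wfpt.encode_stimulus_coding("SS", 0.0)


def _series_oracle(t, v, a, w, K=200):
    """Brute-force large-K small-time series for the lower-boundary
    density (independent re-derivation used as oracle)."""
    tt = t / a**2
    k = np.arange(-K, K + 1)
    x = w + 2 * k
    f0 = np.sum(x * np.exp(-(x**2) / (2 * tt))) / np.sqrt(2 * np.pi * tt**3)
    return f0 / a**2 * np.exp(-v * a * w - v**2 * t / 2)


class TestDensity:
    def test_matches_brute_force_series(self):
        for t in (0.1, 0.5, 1.0, 2.5, 8.0):
            got = np.exp(wfpt.wfpt_logdensity(-(t + PARAMS["tau"]), **PARAMS))
            want = _series_oracle(t, PARAMS["v"], PARAMS["a"], PARAMS["z"])
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_two_boundary_density_integrates_to_one(self):
        tau = PARAMS["tau"]
        total = sum(
            quad(lambda t, s=s: np.exp(wfpt.wfpt_logdensity(s * (t + tau), **PARAMS)),
                 0, 300, limit=400)[0]
            for s in (-1.0, 1.0))
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_reflection_identity_to_machine_precision(self):
        t = 2.5
        upper = wfpt.wfpt_logdensity(t, 0.6, 3.27, 1.23, 0.51)
        lower_reflected = wfpt.wfpt_logdensity(-t, -0.6, 3.27, 1.23, 1 - 0.51)
        assert upper == pytest.approx(lower_reflected, rel=1e-14)

    def test_rt_at_or_below_nondecision_time_has_zero_density(self):
        assert wfpt.wfpt_logdensity(-1.0, **PARAMS) == -np.inf
        assert wfpt.wfpt_logdensity(PARAMS["tau"], **PARAMS) == -np.inf

    def test_continuity_across_series_switch(self):
        # away from the steep rise near tau, log-density on a fine grid
        # must show no jumps where the series branch switches
        t = np.linspace(PARAMS["tau"] + 0.3, 30.0, 20000)
        ld = wfpt.wfpt_logdensity(-t, **PARAMS)
        assert np.all(np.isfinite(ld))
        # a branch-switch discontinuity would spike the second difference;
        # smooth curvature at this grid spacing stays well below 1e-3
        assert np.abs(np.diff(ld, n=2)).max() < 1e-3

    def test_small_and_large_time_series_agree(self):
        # independent evaluation of both series at high truncation order
        a, v, w = PARAMS["a"], PARAMS["v"], PARAMS["z"]
        for t in (0.5, 1.0, 2.0, 5.0):
            tt = t / a**2
            k = np.arange(-300, 301)
            x = w + 2 * k
            small = np.sum(x * np.exp(-(x**2) / (2 * tt))) / np.sqrt(2 * np.pi * tt**3)
            kk = np.arange(1, 301)
            large = np.pi * np.sum(kk * np.exp(-(kk**2) * np.pi**2 * tt / 2)
                                   * np.sin(kk * np.pi * w))
            assert small == pytest.approx(large, abs=1e-6)
            got = np.exp(wfpt.wfpt_logdensity(-(t + PARAMS["tau"]), **PARAMS))
            want = small / a**2 * np.exp(-v * a * w - v**2 * t / 2)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)


class TestUpperProbability:
    def test_driftless_absorption_equals_start_fraction(self):
        assert wfpt.upper_probability(0.0, 2.0, 0.5) == pytest.approx(0.5)
        assert wfpt.upper_probability(0.0, 2.0, 0.7) == pytest.approx(0.7)

    def test_strong_drift_limit(self):
        assert wfpt.upper_probability(50.0, 2.0, 0.5) == pytest.approx(1.0)

    def test_matches_density_mass_split(self):
        tau = PARAMS["tau"]
        upper_mass = quad(lambda t: np.exp(wfpt.wfpt_logdensity(t + tau, **PARAMS)),
                          0, 300, limit=400)[0]
        assert upper_mass == pytest.approx(
            wfpt.upper_probability(PARAMS["v"], PARAMS["a"], PARAMS["z"]), abs=1e-4)


class TestSimulator:
    def test_driftless_symmetric_start_is_fair(self):
        srt = wfpt.simulate_ddm_trials(np.zeros(20000), 2.0, 0.5, 0.5, seed=2)
        assert np.mean(srt > 0) == pytest.approx(0.5, abs=0.02)

    def test_all_rts_exceed_nondecision_time(self):
        srt = wfpt.simulate_ddm_trials(np.full(2000, 0.4), 3.0, 1.23, 0.5, seed=3)
        assert np.abs(srt).min() > 1.23

    def test_seed_reproducibility_and_seed_invariance(self):
        args = (np.full(4000, 0.5), 3.0, 1.0, 0.5)
        a = wfpt.simulate_ddm_trials(*args, seed=11)
        b = wfpt.simulate_ddm_trials(*args, seed=11)
        assert np.array_equal(a, b)
        from scipy.stats import ks_2samp
        c = wfpt.simulate_ddm_trials(*args, seed=12)
        assert ks_2samp(np.abs(a), np.abs(c)).pvalue > 1e-4

    def test_larger_boundary_slows_responses(self):
        fast = wfpt.simulate_ddm_trials(np.full(4000, 0.5), 2.0, 1.0, 0.5, seed=5)
        slow = wfpt.simulate_ddm_trials(np.full(4000, 0.5), 3.5, 1.0, 0.5, seed=6)
        assert np.abs(slow).mean() > np.abs(fast).mean()


class TestDatasetLoglik:
    def _toy(self, n=5):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "subject_id": "s1", "trial": np.arange(n),
            "condition": [0, 1, 0, 1, 0][:n],
            "ss_amount": [10, 20, 10, 20, 10][:n],
            "ll_amount": [15, 30, 20, 76, 38][:n],
            "delay_days": [1, 7, 13, 58, 122][:n],
            "choice": ["LL", "SS", "LL", "LL", "SS"][:n],
            "rt_s": 2.0 + rng.uniform(size=n),
        })

    _params = pd.DataFrame({
        "subject_id": ["s1"], "alpha": [3.0], "tau": [1.2], "z": [0.5],
        "v_coeff": [0.77], "v_max": [1.07], "logk": [-4.45], "s": [-0.82],
    })

    def test_matches_per_trial_density_product(self):
        from itcvigour.valuation import DiscountParams, DriftScaling, drift_sigmoid, value_table
        trials = self._toy()
        spec = ModelSpec("ddm", "sigmoid", "absolute")
        total = dataset_loglik(trials, self._params, spec)
        vt = value_table(trials, DiscountParams(-4.45, -0.82))
        sc = DriftScaling(0.77, 1.07)
        manual = 0.0
        for _, row in vt.iterrows():
            v = drift_sigmoid(row.dsv, sc)
            srt = row.rt_s if row.choice == "LL" else -row.rt_s
            manual += wfpt.wfpt_logdensity(srt, v, 3.0, 1.2, 0.5)
        assert total == pytest.approx(manual, rel=1e-10)

    def test_duplicating_trials_doubles_loglik(self):
        trials = self._toy()
        spec = ModelSpec("ddm", "sigmoid", "absolute")
        one = dataset_loglik(trials, self._params, spec)
        doubled = pd.concat([trials, trials.assign(trial=trials.trial + 10)],
                            ignore_index=True)
        assert dataset_loglik(doubled, self._params, spec) == pytest.approx(2 * one, rel=1e-10)

    def test_unbiased_null_model_is_mirror_symmetric(self):
        trials = self._toy()
        params = pd.DataFrame({"subject_id": ["s1"], "alpha": [3.0],
                               "tau": [1.2], "z": [0.5], "v": [0.0]})
        spec = ModelSpec("ddm", "null", "absolute")
        ll = dataset_loglik(trials, params, spec)
        mirrored = trials.assign(choice=np.where(trials.choice == "LL", "SS", "LL"))
        assert dataset_loglik(mirrored, params, spec) == pytest.approx(ll, rel=1e-12)

    def test_order_invariance(self):
        trials = self._toy()
        spec = ModelSpec("ddm", "sigmoid", "absolute")
        shuffled = trials.sample(frac=1.0, random_state=1)
        assert dataset_loglik(shuffled, self._params, spec) == \
            pytest.approx(dataset_loglik(trials, self._params, spec), rel=1e-12)
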