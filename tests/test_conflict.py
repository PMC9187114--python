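"""Conflict measures, value outcomes, hierarchical regression and the
posterior decision machinery (directional BF, HDI, ROPE)."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from itcvigour.conflict import (bin_conflict, build_regression_design,
                                conflict_from_drift, conflict_from_softmax,
                                fit_hier_linear_regression, hdi_and_rope,
                                regression_report, value_outcomes)
from itcvigour.sampler import MCMCConfig
from itcvigour.stats import bf_evidence_label, directional_bayes_factor
from itcvigour.valuation import DriftScaling, drift_sigmoid


class TestConflictFlip:
    def test_half_is_maximum_conflict(self):
        assert conflict_from_softmax(0.5) == 0.5

    def test_high_probabilities_flipped(self):
        assert conflict_from_softmax(0.9) == pytest.approx(0.1)

    def test_mirror_probabilities_equal_conflict(self):
        p = np.array([0.1, 0.9, 0.25, 0.75])
        y = conflict_from_softmax(p)
        assert y[0] == pytest.approx(y[1]) and y[2] == pytest.approx(y[3])

    def test_flip_is_involution(self):
        p = np.linspace(0, 1, 101)
        assert np.allclose(conflict_from_softmax(p), conflict_from_softmax(1 - p))


class TestConflictBins:
    def test_printed_edge_examples(self):
        assert bin_conflict(0.07) == 1
        assert bin_conflict(0.47) == 5
        assert bin_conflict(0.5) == 5

    def test_boundary_convention(self):
        assert bin_conflict(0.10) == 1  # upper-edge inclusive
        assert bin_conflict(0.1000001) == 2

    def test_bins_invariant_under_flip(self):
        p = np.linspace(0.0, 1.0, 1001)
        a = bin_conflict(conflict_from_softmax(p))
        b = bin_conflict(conflict_from_softmax(1 - p))
        assert np.array_equal(a, b)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_conflict(0.6)


class TestDriftConflict:
    def test_matches_drift_sigmoid_elementwise(self):
        dsv = np.array([-10.0, -1.0, 0.0, 2.0, 30.0])
        means = {"v_coeff": 0.78, "v_max": 1.10, "s_vcoeff": -0.08, "s_vmax": -0.04}
        got = conflict_from_drift(dsv, means, I=1)
        want = drift_sigmoid(dsv, DriftScaling(0.78, 1.10, -0.08, -0.04), 1)
        assert np.allclose(got, want)
        assert got[2] == 0.0
        assert np.all(np.abs(got) <= 1.10 - 0.04 + 1e-12)


class TestValueOutcomes:
    def _trials(self):
        return pd.DataFrame({
            "subject_id": "s1", "trial": [0, 1, 2],
            "condition": [0, 0, 1], "ss_amount": [10.0, 10.0, 20.0],
            "ll_amount": [15.0, 38.0, 76.0], "delay_days": [1, 122, 58],
        })

    _params = pd.DataFrame({"subject_id": ["s1"], "logk": [-4.44], "s": [-0.8]})

    def test_hand_computed_values(self):
        out = value_outcomes(self._trials(), self._params)
        # trial 1: 38 / (1 + e^-4.44 * 122) = 15.57949; |dSV| = 5.57949
        assert out.abs_dsv[1] == pytest.approx(5.57949, abs=1e-4)
        assert out.ssv[1] == pytest.approx(25.57949, abs=1e-4)
        assert out.ssv_objective[1] == 48.0

    def test_value_sum_increases_with_amount(self):
        t = self._trials()
        t2 = t.assign(ll_amount=t.ll_amount + 5)
        a = value_outcomes(t, self._params).ssv
        b = value_outcomes(t2, self._params).ssv
        assert (b > a).all()

    def test_condition_subsetting(self):
        out = value_outcomes(self._trials(), self._params, condition="high")
        assert len(out) == 1 and (out.condition == 1).all()


def _synthetic_regression(seed, slopes=(0.5, 0.0, 0.0, 0.0), n_subj=12, n_trials=96,
                          subj_sd=0.1, resid_sd=0.5):
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for j in range(n_subj):
        b = np.asarray(slopes) + subj_sd * rng.standard_normal(4)
        amp, cen, wid = rng.standard_normal((3, n_trials))
        d = rng.poisson(3.0, n_trials).astype(float)
        y = b[0] * amp + b[1] * cen + b[2] * wid + b[3] * d \
            + resid_sd * rng.standard_normal(n_trials)
        for i in range(n_trials):
            rows.append({"subject_id": f"s{j:02d}", "trial": i, "amp": amp[i],
                         "cen": cen[i], "wid": wid[i], "d": d[i]})
        ys.append(y)
    return np.concatenate(ys), pd.DataFrame(rows)


REG_CFG = MCMCConfig(n_chains=2, burn_in=300, n_samples=700, seed=4)


class TestHierRegression:
    def test_known_slope_recovered(self):
        y, X = _synthetic_regression(seed=1)
        post = fit_hier_linear_regression(y, X, cfg=REG_CFG)
        assert np.median(post.draws("beta1")) == pytest.approx(0.5, abs=0.1)
        for name in ("beta2", "beta3", "beta4"):
            lo, hi = np.quantile(post.draws(name), [0.025, 0.975])
            assert lo < 0.05 and hi > -0.05

    def test_recovery_rate_and_null_calibration_over_replicates(self):
        """Across replicates the 95% HDIs cover generating slopes and
        bracket zero for null slopes in >= 90% of cases."""
        from itcvigour.stats import hdi
        hits = 0
        null_ok = 0
        n_rep = 10
        for r in range(n_rep):
            y, X = _synthetic_regression(seed=100 + r, slopes=(0.4, -0.3, 0.0, 0.1),
                                         n_subj=10, n_trials=60)
            post = fit_hier_linear_regression(y, X, cfg=REG_CFG)
            for name, truth in zip(("beta1", "beta2", "beta3", "beta4"),
                                   (0.4, -0.3, 0.0, 0.1)):
                lo, hi = hdi(post.draws(name), 0.95)
                if lo <= truth <= hi:
                    hits += 1
                if name == "beta3" and lo <= 0 <= hi:
                    null_ok += 1
        assert hits / (4 * n_rep) >= 0.9
        assert null_ok / n_rep >= 0.9

    def test_duplicating_rows_tightens_subject_posteriors(self):
        y, X = _synthetic_regression(seed=2, n_subj=8, n_trials=40)
        post1 = fit_hier_linear_regression(y, X, cfg=REG_CFG)
        y2 = np.concatenate([y, y])
        X2 = pd.concat([X, X.assign(trial=X.trial + 1000)], ignore_index=True)
        post2 = fit_hier_linear_regression(y2, X2, cfg=REG_CFG)
        m1, m2 = np.median(post1.draws("beta1")), np.median(post2.draws("beta1"))
        assert m1 == pytest.approx(m2, abs=0.1)
        # doubled information halves the subject-level posterior variance
        sd1 = post1.beta_subj[:, :, :, 1].std(axis=(0, 1)).mean()
        sd2 = post2.beta_subj[:, :, :, 1].std(axis=(0, 1)).mean()
        assert sd2 < sd1

    def test_zero_variance_predictor_rejected(self):
        y, X = _synthetic_regression(seed=3, n_subj=4, n_trials=20)
        X["wid"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_hier_linear_regression(y, X, cfg=REG_CFG)


class TestDirectionalBF:
    def test_symmetric_draws_give_unit_bf(self):
        draws = np.random.default_rng(5).normal(0, 1, 100_000)
        assert directional_bayes_factor(draws) == pytest.approx(1.0, abs=0.05)

    def test_unit_normal_matches_closed_form(self):
        draws = np.random.default_rng(6).normal(1.0, 1.0, 200_000)
        want = norm.cdf(-1.0) / norm.cdf(1.0)  # 0.18858
        assert directional_bayes_factor(draws) == pytest.approx(want, abs=0.01)

    def test_negation_inverts_bf(self):
        draws = np.random.default_rng(7).normal(0.7, 0.8, 50_000)
        bf = directional_bayes_factor(draws)
        inv = directional_bayes_factor(-draws)
        assert bf * inv == pytest.approx(1.0, rel=0.05)

    def test_one_sided_mass_capped(self):
        draws = np.random.default_rng(8).normal(50.0, 0.1, 5000)
        assert directional_bayes_factor(draws) < 1e-100

    def test_evidence_labels(self):
        assert bf_evidence_label(50.0).startswith("very strong")
        assert bf_evidence_label(0.02).startswith("very strong")
        assert "anecdotal" in bf_evidence_label(1.5)


class TestHdiRope:
    def test_concentrated_null_accepted(self):
        draws = np.random.default_rng(9).normal(0, 0.01, 20_000)
        assert hdi_and_rope(draws)["decision"] == "accept-null"

    def test_wide_posterior_undecided(self):
        draws = np.random.default_rng(10).normal(0, 1, 200_000)
        out = hdi_and_rope(draws)
        assert out["decision"] == "undecided"
        assert out["hdi95_lo"] == pytest.approx(-1.96, abs=0.04)
        assert out["hdi95_hi"] == pytest.approx(1.96, abs=0.04)

    def test_separated_posterior_rejected(self):
        draws = np.random.default_rng(11).normal(1.0, 0.1, 20_000)
        out = hdi_and_rope(draws)
        assert out["decision"] == "reject-null"
        assert out["rope_overlap_pct"] == 0.0

    def test_hdi85_nested_in_hdi95(self):
        draws = np.random.default_rng(12).gamma(2.0, size=20_000)
        out = hdi_and_rope(draws)
        assert out["hdi95_lo"] <= out["hdi85_lo"] <= out["hdi85_hi"] <= out["hdi95_hi"]


def test_end_to_end_vigour_value_regression_signs(ddm_cohort_small):
    """On a cohort generated with positive amplitude-value-sum coupling and
    negative fixation-value coupling, the value-sum regression recovers a
    positive amplitude slope and a negative fixation slope."""
    from itcvigour.cohort import grip_traces_for_subject
    from itcvigour.gripforce import fit_pulses
    fits = pd.concat([
        fit_pulses(grip_traces_for_subject(ddm_cohort_small, sid, seed=3), subject_id=sid)
        for sid in ddm_cohort_small.subject_params.subject_id
    ], ignore_index=True)
    X = build_regression_design(fits, ddm_cohort_small.trials)
    vo = value_outcomes(ddm_cohort_small.trials, ddm_cohort_small.subject_params)
    merged = X.merge(vo[["subject_id", "trial", "ssv"]], on=["subject_id", "trial"])
    # standardise the outcome per subject so ROPE limits are meaningful
    zssv = merged.groupby("subject_id")["ssv"].transform(
        lambda x: (x - x.mean()) / x.std())
    post = fit_hier_linear_regression(zssv.to_numpy(), merged, cfg=REG_CFG)
    report = regression_report(post).set_index("coefficient")
    assert report.loc["beta1", "median"] > 0          # grip amplitude
    assert report.loc["beta4", "median"] < 0          # fixation shifts
    assert report.loc["beta1", "bf"] < 1.0            # mass above zero dominates
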