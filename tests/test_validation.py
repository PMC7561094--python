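"""Validation statistics: calibration/HL, ROC, DeLong, NRI, DCA, optimism."""

import numpy as np
import pandas as pd
import pytest

from periorisk import (auroc, auroc_ordinal, calibration, continuous_nri,
                       decision_curve, delong_compare, net_benefit)
from periorisk.errors import DomainError
from periorisk.validation import auroc_metric, bootstrap_optimism


class TestCalibration:
    def test_perfect_calibration_zero_statistic(self, rng):
        """When predictions equal their group rates exactly, O = E."""
        rates = np.linspace(0.05, 0.5, 10)
        pred, obs = [], []
        for r in rates:
            k = 40
            deaths = int(round(r * k))
            pred += [r] * k
            obs += [1] * deaths + [0] * (k - deaths)
        # adjust each group's pred to its exact observed rate
        df = pd.DataFrame({"pred": pred, "obs": obs})
        df["pred"] = df.groupby("pred")["obs"].transform("mean")
        res = calibration(df["pred"], df["obs"])
        assert res.hl_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.hl_df == len(res.bins) - 2

    def test_hand_binned_toy_table(self):
        """20 records, 2 bins of 10 — against hand arithmetic."""
        pred = np.r_[np.full(10, 0.1), np.full(10, 0.3)]
        obs = np.r_[np.ones(2), np.zeros(8), np.ones(4), np.zeros(6)]
        res = calibration(pred, obs, n_bins=2)
        assert res.bins["n"].tolist() == [10, 10]
        assert res.bins["deaths"].tolist() == [2, 4]
        assert res.bins["obs_prop"].tolist() == [0.2, 0.4]
        # HL: bin1 E=1, (2-1)^2/(1*(1-0.1)) ; bin2 E=3, (4-3)^2/(3*(1-0.3))
        expected = 1 / 0.9 + 1 / 2.1
        assert res.hl_statistic == pytest.approx(expected)

    def test_counts_conserved(self, cohort_20k):
        pred = cohort_20k["true_risk"].to_numpy()
        obs = cohort_20k["death30_inpatient"].to_numpy()
        res = calibration(pred, obs)
        assert res.bins["n"].sum() == len(obs)
        assert res.bins["deaths"].sum() == obs.sum()

    def test_constant_predictor_degenerate_single_bin(self):
        res = calibration(np.full(100, 0.2), np.r_[np.ones(20), np.zeros(80)])
        assert res.degenerate
        assert len(res.bins) == 1
        assert np.isnan(res.hl_statistic)

    def test_overprediction_detected(self, cohort_100k):
        """A predictor that doubles true risk shows observed < predicted in
        every decile and a strongly significant HL statistic."""
        true = cohort_100k["true_risk"].to_numpy()
        obs = cohort_100k["death30_inpatient"].to_numpy()
        res = calibration(np.minimum(2 * true, 1.0), obs)
        assert (res.bins["obs_prop"] < res.bins["mean_pred"]).all()
        assert res.hl_p < 0.05

    def test_hl_nominal_rejection_rate_under_true_model(self):
        """Predictions equal to the generating probabilities: HL should
        reject at about the nominal 5% rate over repeated cohorts."""
        from periorisk import SyntheticCohortConfig, generate_cohort
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = generate_cohort(SyntheticCohortConfig(
                n_patients=20_000, mortality_target=None, seed=seed))
            res = calibration(df["true_risk"], df["death30_inpatient"])
            rejections += res.hl_p < 0.05
        assert rejections <= 3  # ~nominal; P(>3 | alpha=.05) < 2%


class TestAuroc:
    def test_perfect_and_constant_predictors(self):
        obs = np.r_[np.zeros(5), np.ones(5)]
        assert auroc(np.arange(10), obs).auroc == 1.0
        assert auroc(np.zeros(10), obs).auroc == 0.5

    def test_three_record_example(self):
        assert auroc([0.1, 0.4, 0.2], [0, 0, 1]).auroc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_trapezoid_of_roc_points(self, rng):
        pred = rng.choice(np.linspace(0, 1, 20), 500)  # many ties
        obs = rng.random(500) < 0.3
        res = auroc(pred, obs)
        assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auroc,
                                                               abs=1e-12)
        assert res.fpr[0] == res.tpr[0] == 0.0
        assert res.fpr[-1] == res.tpr[-1] == 1.0

    def test_ordinal_polygon_matches_hand_computed_area(self):
        """12-record, 3-category table: hand trapezoid."""
        cat = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
        obs = np.array([0, 0, 0, 0, 0, 0, 1, 0, 1, 1, 0, 1])
        # cases: cats (2,3,3,3); controls: (1,1,1,1,2,2,2,3)
        # P(case>ctrl) = (3*7 + 1*4)/32 ; ties = (3*1 + 1*3)/32
        expected = (25 + 0.5 * 6) / 32
        res = auroc_ordinal(cat, obs)
        assert res.auroc == pytest.approx(expected)
        assert len(res.fpr) == 4  # (0,0) + one point per threshold + (1,1)

    def test_ordinal_independent_categories_near_half(self, rng):
        cat = rng.integers(1, 7, 30_000)
        obs = rng.random(30_000) < 0.05
        res = auroc_ordinal(cat, obs)
        assert abs(res.auroc - 0.5) < 3 * np.sqrt(res.variance)

    def test_ordinal_needs_two_categories(self):
        with pytest.raises(DomainError):
            auroc_ordinal(np.ones(10), np.r_[np.ones(5), np.zeros(5)])


class TestDeLong:
    def test_self_comparison_null(self, rng):
        pred = rng.random(100)
        obs = rng.random(100) < 0.4
        res = delong_compare(pred, pred, obs)
        assert res.z == 0.0 and res.p == 1.0

    def test_monotone_transform_invariance(self, rng):
        pred = rng.random(200)
        obs = rng.random(200) < 0.3
        res = delong_compare(pred, np.exp(3 * pred) - 0.5, obs)
        assert res.auroc_a == pytest.approx(res.auroc_b, abs=1e-12)
        assert res.z == 0.0

    def test_swap_negates_z(self, rng):
        a, b = rng.random(300), rng.random(300)
        obs = rng.random(300) < 0.3
        r1 = delong_compare(a, b, obs)
        r2 = delong_compare(b, a, obs)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)
        assert r1.variance_diff >= 0

    def test_agrees_with_permutation_oracle(self):
        """Two correlated markers, n=500: DeLong p vs a 20,000-rep
        within-subject swap permutation of the AUROC difference."""
        rng = np.random.default_rng(77)
        n = 500
        latent = rng.normal(0, 1, n)
        obs = rng.random(n) < 1 / (1 + np.exp(-(latent - 1.2)))
        if obs.sum() < 10:  # pragma: no cover
            raise RuntimeError("degenerate draw")
        a = latent + rng.normal(0, 1.0, n)
        b = latent + rng.normal(0, 1.1, n)
        res = delong_compare(a, b, obs)

        def quick_auc(x):
            from scipy.stats import rankdata
            r = rankdata(x)
            m = obs.sum()
            return (r[obs].sum() - m * (m + 1) / 2) / (m * (~obs).sum())

        observed_diff = abs(quick_auc(a) - quick_auc(b))
        reps = 20_000
        count = 0
        for _ in range(reps):
            swap = rng.random(n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            if abs(quick_auc(aa) - quick_auc(bb)) >= observed_diff - 1e-12:
                count += 1
        p_perm = count / reps
        assert abs(res.p - p_perm) < 0.05


class TestNRI:
    def test_identity_is_zero(self, rng):
        pred = rng.random(50)
        obs = np.r_[np.ones(10), np.zeros(40)].astype(int)
        res = continuous_nri(pred, pred, obs)
        assert res.nri_total == 0.0

    def test_maximum_attained(self):
        obs = np.array([1, 1, 0, 0])
        old = np.array([0.2, 0.2, 0.2, 0.2])
        new = np.array([0.9, 0.9, 0.05, 0.05])
        res = continuous_nri(old, new, obs)
        assert res.nri_events == 1.0
        assert res.nri_nonevents == 1.0
        assert res.nri_total == 2.0

    def test_toy_counts_match_hand_enumeration(self):
        """4 events (3 up, 1 down), 6 nonevents (2 down, 3 up, 1 tie)."""
        obs = np.r_[np.ones(4), np.zeros(6)].astype(int)
        old = np.full(10, 0.5)
        new = np.array([0.6, 0.7, 0.8, 0.4,          # events
                        0.4, 0.3, 0.6, 0.7, 0.8, 0.5])  # nonevents
        res = continuous_nri(old, new, obs)
        assert res.nri_events == pytest.approx((3 - 1) / 4)
        assert res.nri_nonevents == pytest.approx((2 - 3) / 6)
        assert res.nri_total == pytest.approx(0.5 - 1 / 6)

    def test_antisymmetry(self, rng):
        a, b = rng.random(200), rng.random(200)
        obs = (rng.random(200) < 0.3).astype(int)
        r1 = continuous_nri(a, b, obs)
        r2 = continuous_nri(b, a, obs)
        assert r1.nri_total == pytest.approx(-r2.nri_total)
        assert r1.se == pytest.approx(r2.se)


class TestDecisionCurve:
    def test_hand_example(self):
        """n=100, 10 events, TP=8, FP=20 at t=0.2 -> NB = 0.03."""
        pred = np.zeros(100)
        obs = np.zeros(100, dtype=int)
        obs[:10] = 1
        pred[:8] = 0.9    # true positives
        pred[10:30] = 0.9  # false positives
        assert net_benefit(pred, obs, 0.2) == pytest.approx(
            0.08 - 0.20 * 0.25)

    def test_treat_none_zero_and_perfect_predictor(self, rng):
        obs = (rng.random(400) < 0.1).astype(int)
        prev = obs.mean()
        none_nb = net_benefit(np.zeros(400), obs, 0.3)
        assert none_nb == 0.0
        for t in [0.05, 0.3, 0.8]:
            assert net_benefit(obs.astype(float), obs, t) == pytest.approx(prev)

    def test_treat_all_crosses_zero_at_prevalence(self, rng):
        obs = (rng.random(1000) < 0.2).astype(int)
        prev = obs.mean()
        dc = decision_curve(rng.random(1000), obs,
                            grid=np.array([prev - 0.05, prev, prev + 0.05]))
        assert dc.nb_treat_all[0] > 0 > dc.nb_treat_all[2]
        assert dc.nb_treat_all[1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(dc.nb_treat_none == 0)

    def test_curve_matches_pointwise_net_benefit(self, rng):
        pred = rng.random(500)
        obs = (rng.random(500) < 0.15).astype(int)
        grid = np.array([0.01, 0.1, 0.25, 0.49])
        dc = decision_curve(pred, obs, grid)
        for t, nb in zip(grid, dc.nb_model):
            assert nb == pytest.approx(net_benefit(pred, obs, t), abs=1e-12)

    def test_threshold_domain(self):
        with pytest.raises(DomainError):
            net_benefit([0.1], [0], 0.0)
        with pytest.raises(DomainError):
            net_benefit([0.1], [0], 1.0)


class TestBootstrapOptimism:
    def test_constant_metric_zero_optimism(self):
        df = pd.DataFrame({"death30_inpatient": [0, 1] * 50, "x": range(100)})
        rep = bootstrap_optimism(
            df, lambda train: (lambda d: np.zeros(len(d))),
            lambda pred, obs: 0.7, B=20, seed=0)
        assert rep.optimism == 0.0
        assert rep.corrected == rep.apparent == 0.7

    def test_single_replicate_flagged_low_precision(self):
        df = pd.DataFrame({"death30_inpatient": [0, 1] * 50, "x": range(100)})
        rep = bootstrap_optimism(
            df, lambda train: (lambda d: d["x"].to_numpy(dtype=float)),
            auroc_metric, B=1, seed=5)
        assert rep.B == 1
        assert rep.low_precision
        assert rep.corrected == pytest.approx(rep.apparent - rep.optimism)

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame({"death30_inpatient": (rng.random(300) < 0.3).astype(int),
                           "x": rng.random(300)})
        fit = lambda train: (lambda d: d["x"].to_numpy())
        r1 = bootstrap_optimism(df, fit, auroc_metric, B=30, seed=9)
        r2 = bootstrap_optimism(df, fit, auroc_metric, B=30, seed=9)
        assert r1 == r2
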