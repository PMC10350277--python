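"""Signature scoring, C-index, Kaplan-Meier, log-rank, HR, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import brute_cindex
from radpipe import (SignatureModel, SurvivalData, bootstrap_cindex,
                     compare_models, compute_signature, group_hr,
                     harrell_cindex, kaplan_meier, load_published_signature,
                     logrank_test, signature_vs_stage, stratify,
                     train_signature)


def _surv(rng, n, beta=0.0, x=None, censor_frac=0.4):
    x = rng.standard_normal(n) if x is None else x
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(t.mean() / censor_frac, size=n) if censor_frac \
        else np.full(n, np.inf)
    return x, SurvivalData(np.maximum(np.minimum(t, c), 1e-9),
                           (t <= c).astype(int))


class TestPublishedSignature:
    def test_score_zero_at_training_means(self):
        m = load_published_signature()
        raw = dict(zip(m.features, m.mean))
        assert compute_signature(m, raw)[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_perturbations_return_each_coefficient(self):
        """Raising each signature feature one training SD above its mean
        (others at means) returns exactly that feature's coefficient."""
        m = load_published_signature()
        for i, name in enumerate(m.features):
            raw = dict(zip(m.features, m.mean))
            raw[name] = m.mean[i] + m.sd[i]
            score = compute_signature(m, raw)[0]
            assert score == pytest.approx(m.coef[i], abs=1e-10)

    def test_missing_feature_named_in_error(self):
        m = load_published_signature()
        raw = dict(zip(m.features[:-1], m.mean[:-1]))
        with pytest.raises(KeyError, match="ShortRunEmphasis"):
            compute_signature(m, raw)


class TestTrainSignature:
    def test_threshold_is_training_median(self, rng):
        x, surv = _surv(rng, 41, beta=0.8)
        feats = pd.DataFrame({"f1": x, "f2": rng.standard_normal(41)})
        model, _ = train_signature(feats, surv, ["f1", "f2"])
        scores = compute_signature(model, feats)
        assert (scores <= model.threshold).sum() == 21  # ceil(n/2) for odd n

    def test_retrain_is_deterministic(self, rng):
        x, surv = _surv(rng, 60, beta=0.8)
        feats = pd.DataFrame({"f1": x})
        m1, _ = train_signature(feats, surv, ["f1"])
        m2, _ = train_signature(feats, surv, ["f1"])
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.threshold == m2.threshold

    def test_scale_reparameterization_leaves_scores_unchanged(self, rng):
        """Z-scoring inside the model makes scores invariant to affine
        rescaling of a raw feature column."""
        x, surv = _surv(rng, 80, beta=0.8)
        feats = pd.DataFrame({"f1": x})
        scaled = pd.DataFrame({"f1": 2.0 * x + 10.0})
        m1, _ = train_signature(feats, surv, ["f1"])
        m2, _ = train_signature(scaled, surv, ["f1"])
        np.testing.assert_allclose(compute_signature(m1, feats),
                                   compute_signature(m2, scaled), atol=1e-8)

    def test_training_cindex_at_least_half(self, rng):
        x, surv = _surv(rng, 80, beta=0.5)
        feats = pd.DataFrame({"f1": x})
        model, _ = train_signature(feats, surv, ["f1"])
        assert harrell_cindex(compute_signature(model, feats), surv) >= 0.5


class TestStratify:
    def test_boundary_goes_low(self):
        labels = stratify(np.array([1.0, 2.0, 3.0]), 2.0)
        assert list(labels) == ["low", "low", "high"]

    def test_single_group_breaks_downstream_stats(self, rng):
        _, surv = _surv(rng, 30)
        labels = stratify(np.zeros(30), 1.0)  # everyone low
        with pytest.raises(ValueError):
            logrank_test(labels, surv)
        with pytest.raises(ValueError):
            group_hr(labels, surv)


class TestCindex:
    def test_perfect_concordance(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        assert harrell_cindex(np.array([3.0, 2.0, 1.0]), surv) == 1.0

    def test_all_tied_scores(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        assert harrell_cindex(np.array([1.0, 1.0, 1.0]), surv) == 0.5

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            n = 20
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            t = np.ceil(rng.exponential(5, n) * 2)
            e = (rng.random(n) < 0.6).astype(int)
            e[0] = 1
            surv = SurvivalData(t, e)
            assert harrell_cindex(scores, surv) == pytest.approx(
                brute_cindex(scores, t, e), abs=0)

    def test_no_comparable_pairs_rejected(self):
        surv = SurvivalData([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex(np.array([1.0, 2.0]), surv)

    def test_bootstrap_reproducible_and_degenerate_cases(self, rng):
        surv = SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        med, iqr, dist = bootstrap_cindex(np.array([4.0, 3.0, 2.0, 1.0]),
                                          surv, n_boot=20, rng=1)
        assert med == 1.0 and iqr == (1.0, 1.0)
        x, surv = _surv(rng, 50, beta=0.8)
        m1 = bootstrap_cindex(x, surv, n_boot=30, rng=7)
        m2 = bootstrap_cindex(x, surv, n_boot=30, rng=7)
        assert m1[0] == m2[0] and m1[1] == m2[1]

    def test_null_bootstrap_median_near_half(self, rng):
        x, surv = _surv(rng, 200, beta=0.0)
        med, _, _ = bootstrap_cindex(x, surv, n_boot=50, rng=3)
        assert abs(med - 0.5) < 0.05


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = kaplan_meier(SurvivalData([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.survival_at(10.0) == 1.0

    def test_hand_product_limit(self):
        km = kaplan_meier(SurvivalData([1.0, 2.0, 3.0], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_matches_lifelines_estimate(self, rng):
        from lifelines import KaplanMeierFitter

        _, surv = _surv(rng, 60, beta=0.3)
        km = kaplan_meier(surv)
        kmf = KaplanMeierFitter().fit(surv.time, surv.event)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    def test_band_covers_true_curve(self):
        """Uncensored exponential data: the Greenwood 95% band covers
        exp(-t/scale) at >= 90% of event times, averaged over seeds."""
        cover = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            t = r.exponential(10.0, 80)
            km = kaplan_meier(SurvivalData(t, np.ones(80, int)))
            true = np.exp(-km.times / 10.0)
            ok = (km.ci_lower <= true) & (true <= km.ci_upper)
            cover.append(ok.mean())
        assert np.mean(cover) >= 0.90


class TestLogrankAndHr:
    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array(["a"] * 4 + ["b"] * 4)
        stat, p = logrank_test(g, SurvivalData(t, e))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_p_uniform(self):
        pvals = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            _, surv = _surv(r, 60, beta=0.0)
            g = np.where(r.random(60) < 0.5, "a", "b")
            if len(np.unique(g)) < 2:
                continue
            pvals.append(logrank_test(g, surv)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_separation_significant(self, rng):
        x, surv = _surv(rng, 120, beta=1.5)
        g = np.where(x > np.median(x), "high", "low")
        assert logrank_test(g, surv)[1] < 0.001
        hr, (lo, hi) = group_hr(g, surv)
        assert hr > 1 and lo > 1

    def test_hr_inverts_under_label_swap(self, rng):
        x, surv = _surv(rng, 100, beta=1.0)
        g = np.where(x > 0, "high", "low")
        hr, _ = group_hr(g, surv, reference="low")
        hr_sw, _ = group_hr(g, surv, reference="high")
        assert hr_sw == pytest.approx(1.0 / hr, rel=1e-6)

    def test_hr_ci_coverage(self):
        """Generator HR = 2 between groups: the Wald CI covers 2 in
        >= 93% of replicates; permuted labels cover 1 similarly."""
        cover2 = cover1 = 0
        n_rep = 150
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            g = np.array(["high"] * 50 + ["low"] * 50)
            haz = np.where(g == "high", 2.0, 1.0)
            t = r.exponential(1.0 / haz)
            c = r.exponential(2.0, 100)
            surv = SurvivalData(np.maximum(np.minimum(t, c), 1e-9),
                                (t <= c).astype(int))
            _, (lo, hi) = group_hr(g, surv)
            cover2 += lo <= 2.0 <= hi
            gp = g[r.permutation(100)]
            _, (lo, hi) = group_hr(gp, surv)
            cover1 += lo <= 1.0 <= hi
        assert cover2 / n_rep >= 0.93
        assert cover1 / n_rep >= 0.93


class TestCompareModels:
    def test_identical_distributions_nonsignificant(self, rng):
        d = rng.normal(0.6, 0.02, 100)
        out = compare_models([d, d.copy()], ["a", "b"])
        assert out["p_adjusted"].iloc[0] > 0.9
        out3 = compare_models([d, d.copy(), d.copy()], ["a", "b", "c"])
        assert (out3["p_adjusted"] > 0.9).all()

    def test_one_shifted_among_three_detected(self, rng):
        a = rng.normal(0.60, 0.02, 100)
        b = rng.normal(0.60, 0.02, 100)
        c = rng.normal(0.70, 0.02, 100)
        out = compare_models([a, b, c], ["a", "b", "c"]).set_index(
            ["model_a", "model_b"])
        assert out.loc[("a", "c"), "p_adjusted"] < 0.05
        assert out.loc[("b", "c"), "p_adjusted"] < 0.05
        assert out.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_two_sample_path_matches_exact_rank_enumeration(self):
        """5+5 example: Mann-Whitney p equals the exact permutation
        distribution of the U statistic."""
        a = np.array([1.2, 3.4, 2.2, 5.1, 0.7])
        b = np.array([2.9, 6.3, 4.4, 7.0, 5.8])
        out = compare_models([a, b], ["a", "b"])
        pooled = np.concatenate([a, b])

        def ustat(idx_a):
            aa = pooled[list(idx_a)]
            bb = np.delete(pooled, list(idx_a))
            return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

        observed = ustat(range(5))
        us = [ustat(c) for c in itertools.combinations(range(10), 5)]
        dev = abs(observed - 12.5)
        p_exact = np.mean([abs(u - 12.5) >= dev - 1e-12 for u in us])
        assert out["p_adjusted"].iloc[0] == pytest.approx(p_exact, abs=1e-10)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            compare_models([rng.normal(size=10), rng.normal(size=12)],
                           ["a", "b"])


class TestSignatureVsStage:
    def test_null_omnibus_p_uniform(self):
        pvals = []
        for seed in range(150):
            r = np.random.default_rng(seed)
            scores = r.standard_normal(60)
            stage = r.choice(["III", "IVa", "IVb"], 60)
            _, surv = _surv(r, 60, beta=0.5, x=scores)
            out = signature_vs_stage(scores, stage, surv)
            pvals.append(out["omnibus_p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_stage_shift_detected_and_hrs_reported(self, rng):
        n = 120
        stage = rng.choice(["III", "IVa", "IVb"], n, p=[0.3, 0.4, 0.3])
        shift = np.where(stage == "III", 0.0, 1.5)
        scores = rng.standard_normal(n) + shift
        _, surv = _surv(rng, n, beta=0.5, x=scores)
        out = signature_vs_stage(scores, stage, surv)
        pw = out["pairwise"].set_index(["model_a", "model_b"])
        assert pw.loc[("III", "IVa"), "p_adjusted"] < 0.05
        assert pw.loc[("III", "IVb"), "p_adjusted"] < 0.05
        assert out["hr_signature"][0] > 1.0

    def test_constant_stage_rejected(self, rng):
        scores, surv = _surv(rng, 30, beta=0.5)
        with pytest.raises(ValueError):
            signature_vs_stage(scores, np.repeat("III", 30), surv)


class TestSurvivalDataContract:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData([1.0, -2.0], [1, 0])
        with pytest.raises(ValueError):
            SurvivalData([1.0, 2.0], [1, 2])
        with pytest.raises(ValueError):
            SurvivalData([1.0], [1, 0])

    def test_roundtrip_frame(self):
        s = SurvivalData([3.0, 5.0], [1, 0], np.array(["A", "B"]))
        s2 = SurvivalData.from_frame(s.to_frame())
        np.testing.assert_array_equal(s.time, s2.time)
        np.testing.assert_array_equal(s.patient_id, s2.patient_id)

    def test_model_json_roundtrip(self, tmp_path):
        m = SignatureModel(["a", "b"], [1.0, 2.0], [0.5, 1.5],
                           [0.3, -0.7], threshold=0.1)
        path = tmp_path / "sig.json"
        m.to_json(str(path))
        m2 = SignatureModel.from_json(str(path))
        assert m2.features == ["a", "b"]
        np.testing.assert_array_equal(m2.coef, m.coef)
        assert m2.threshold == 0.1
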