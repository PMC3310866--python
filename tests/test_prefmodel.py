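import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from cdrdesign.aminoacids import AA1
from cdrdesign.prefmodel import (
    evaluate,
    fit_logistic,
    loo_train_predict,
    mcc,
    optimize_thresholds,
    predict_binary,
    random_baseline,
    rank_amino_acids,
    rank_of_native,
    ranking_distribution,
    report_position,
)
from cdrdesign.synthfix import make_planted_model_tables


class TestFitLogistic:
    def test_constant_features_balanced_labels_give_half(self):
        f = np.zeros((10, 3))
        y = np.array([0, 1] * 5)
        model = fit_logistic(f, y)
        assert np.allclose(model.coef, 0.0, atol=1e-6)
        assert model.predict(np.zeros((1, 3)))[0] == pytest.approx(0.5,
                                                                   abs=1e-6)

    def test_separable_data_fits_perfectly(self):
        rngl = np.random.default_rng(3)
        f = rngl.normal(size=(30, 3))
        y = (f[:, 0] > 0).astype(int)
        model = fit_logistic(f, y)
        p = model.predict(f)
        # perfectly separable: some threshold classifies all rows correctly
        assert p[y == 1].min() > p[y == 0].max()

    def test_degenerate_labels_fall_back_to_intercept(self):
        f = np.random.default_rng(1).normal(size=(5, 3))
        model = fit_logistic(f, np.ones(5))
        assert model.degenerate
        assert model.predict(f).min() > 0.99

    def test_non_finite_feature_rejected(self):
        f = np.zeros((4, 3))
        f[2, 1] = np.nan
        with pytest.raises(ValueError, match="row 2"):
            fit_logistic(f, np.array([0, 1, 0, 1]))

    def test_weight_sign_recovery_on_simulated_folds(self):
        # 23 rows per fold as in a leave-one-out training set
        rngl = np.random.default_rng(7)
        true_w = np.array([1.2, -0.9, 0.6])
        signs = []
        for _ in range(200):
            f = rngl.normal(size=(23, 3))
            latent = f @ true_w + rngl.normal(0, 0.5, 23)
            y = (latent > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            m = fit_logistic(f, y)
            signs.append(np.sign(m.coef))
        med = np.median(np.array(signs), axis=0)
        assert np.array_equal(med, np.sign(true_w))


class TestLooProtocol:
    def test_two_positions_degenerate_but_defined(self):
        score, pref, _ = make_planted_model_tables(seed=1, n_positions=3)
        score = score[score["position"].isin(["01", "02"])]
        pref = pref[pref["position"].isin(["01", "02"])]
        out = loo_train_predict(score, pref)
        assert len(out) == 2 * 20
        assert out["pW"].between(0, 1).all()

    def test_position_order_irrelevant(self):
        score, pref, _ = make_planted_model_tables(seed=2, n_positions=6)
        a = loo_train_predict(score, pref)
        b = loo_train_predict(score.sample(frac=1, random_state=5),
                              pref.sample(frac=1, random_state=6))
        am = a.sort_values(["position", "aa"]).reset_index(drop=True)
        bm = b.sort_values(["position", "aa"]).reset_index(drop=True)
        assert np.allclose(am["pW"], bm["pW"], atol=1e-9)

    def test_noiseless_planted_rule_recovered_perfectly(self):
        score, pref, _ = make_planted_model_tables(seed=3, n_positions=24,
                                                   noise_sd=0.0)
        out = loo_train_predict(score, pref)
        thresholds = optimize_thresholds(out)
        merged = out.merge(thresholds[["aa", "t"]], on="aa")
        pred = predict_binary(merged["pW"], merged["t"])
        assert evaluate(pred, merged["deltaW"]).mcc == pytest.approx(1.0)

    def test_no_leakage_from_other_types_at_held_out_position(self):
        score, pref, _ = make_planted_model_tables(seed=4, n_positions=6)
        base = loo_train_predict(score, pref)
        # perturb every feature of type 'C' rows: predictions for other
        # types must not move
        poisoned = score.copy()
        poisoned.loc[poisoned["aa"] == "C", ["X", "Y", "Z"]] += 50.0
        out = loo_train_predict(poisoned, pref)
        for aa in ("A", "W", "Y"):
            b = base[base["aa"] == aa].sort_values("position")["pW"].to_numpy()
            o = out[out["aa"] == aa].sort_values("position")["pW"].to_numpy()
            assert np.allclose(b, o)

    def test_w_regression_objective_runs(self):
        score, pref, _ = make_planted_model_tables(seed=5, n_positions=6)
        out = loo_train_predict(score, pref, objective="w_regression")
        assert out["pW"].between(0, 1).all()

    def test_incomplete_type_coverage_rejected(self):
        score, pref, _ = make_planted_model_tables(seed=6, n_positions=5)
        holed = score[~((score["aa"] == "A") & (score["position"] == "01"))]
        with pytest.raises(ValueError, match="01"):
            loo_train_predict(holed, pref,
                              positions=[f"{i+1:02d}" for i in range(5)])


class TestThresholds:
    def test_perfect_separation_reaches_mcc_one(self):
        df = pd.DataFrame({
            "aa": ["A"] * 8,
            "pW": [0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9],
            "deltaW": [0, 0, 0, 0, 1, 1, 1, 1],
        })
        out = optimize_thresholds(df)
        assert out.loc[0, "mcc"] == pytest.approx(1.0)
        assert 0.4 < out.loc[0, "t"] <= 0.6

    def test_globally_optimal_over_candidate_grid(self, rng):
        pw = rng.random(40)
        labels = rng.integers(0, 2, 40)
        df = pd.DataFrame({"aa": ["K"] * 40, "pW": pw, "deltaW": labels})
        out = optimize_thresholds(df)
        best = out.loc[0, "mcc"]
        uniq = np.unique(pw)
        candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]])
        for t in candidates:
            pred = (pw >= t).astype(int)
            assert best >= matthews_corrcoef(labels, pred) - 1e-12

    def test_single_class_gets_degenerate_default(self):
        df = pd.DataFrame({"aa": ["A"] * 5, "pW": np.linspace(0, 1, 5),
                           "deltaW": [1] * 5})
        out = optimize_thresholds(df)
        assert out.loc[0, "t"] == 0.5
        assert out.loc[0, "degenerate"]


class TestBinaryAndEvaluate:
    def test_boundary_counts_as_positive(self):
        assert predict_binary(0.37, 0.37) == 1
        assert predict_binary(0.0, 0.5) == 0

    def test_elementwise_comparison(self, rng):
        pw = rng.random(100)
        t = rng.random(100)
        assert np.array_equal(predict_binary(pw, t), (pw >= t).astype(int))

    def test_perfect_prediction_scores_one(self):
        labels = np.array([1, 0, 1, 1, 0, 0])
        summary = evaluate(labels, labels)
        assert summary.mcc == pytest.approx(1.0)
        assert summary.accuracy == 1.0

    def test_balanced_wrongness(self):
        pred = np.array([1] * 10 + [0] * 10)
        obs = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        summary = evaluate(pred, obs)
        assert (summary.tp, summary.fp, summary.tn, summary.fn) == (5, 5, 5, 5)
        assert summary.accuracy == 0.5
        assert summary.mcc == 0.0

    def test_matches_sklearn_on_random_matrices(self, rng):
        for _ in range(10):
            pred = rng.integers(0, 2, 60)
            obs = rng.integers(0, 2, 60)
            assert evaluate(pred, obs).mcc == pytest.approx(
                matthews_corrcoef(obs, pred), abs=1e-12)

    def test_label_swap_negates_mcc_for_balanced_classes(self):
        assert mcc(8, 2, 7, 3) == pytest.approx(-mcc(2, 8, 3, 7))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


class TestReportsAndRanks:
    @pytest.fixture()
    def trained(self):
        score, pref, _ = make_planted_model_tables(seed=8, n_positions=8,
                                                   noise_sd=0.3)
        pred = loo_train_predict(score, pref)
        thresholds = optimize_thresholds(pred)
        return pred, thresholds

    def test_report_orders_by_margin_and_w(self, trained):
        pred, thresholds = trained
        rep = report_position(pred, thresholds, "01")
        margins = [m for _, m in rep["predicted"]]
        assert margins == sorted(margins, reverse=True)
        w_vals = [w for _, w in rep["experimental"]]
        assert w_vals == sorted(w_vals, reverse=True)
        assert set(rep["true_positive"]) <= {a for a, _ in rep["predicted"]}

    def test_report_empty_when_nothing_predicted(self, trained):
        pred, thresholds = trained
        high = thresholds.copy()
        high["t"] = 1.1
        rep = report_position(pred, high, "01")
        assert rep["predicted"] == []

    def test_ranks_are_a_permutation(self, trained, rng):
        act = pd.Series(rng.normal(size=20), index=list(AA1))
        ranks = rank_amino_acids(act)
        assert sorted(ranks) == list(range(1, 21))
        assert ranks[act.idxmax()] == 1

    def test_ranks_match_sorting_oracle(self, rng):
        act = pd.Series(rng.normal(size=20), index=list(AA1))
        ranks = rank_amino_acids(act)
        oracle = {aa: 1 + sum(act[b] > act[aa] for b in AA1) for aa in AA1}
        assert {aa: ranks[aa] for aa in AA1} == oracle

    def test_native_rank_report(self, trained):
        pred, thresholds = trained
        native = {"01": "A", "02": "W"}
        out = rank_of_native(pred, thresholds, native)
        assert set(out["position"]) == {"01", "02"}
        assert out["rank"].between(1, 20).all()

    def test_ranking_distribution_sums_to_hundred(self, rng):
        df = pd.DataFrame({
            "rank": rng.integers(1, 21, 200),
            "interface_class": rng.choice(["core", "rim"], 200),
        })
        dist = ranking_distribution(df)
        sums = dist.groupby("interface_class")["percent"].sum()
        assert np.allclose(sums, 100.0)

    def test_ranking_distribution_concentrates(self):
        df = pd.DataFrame({"rank": [1] * 7, "interface_class": ["core"] * 7})
        dist = ranking_distribution(df)
        assert dist.loc[dist["rank"] == 1, "percent"].item() == 100.0

    def test_uniform_ranks_approach_five_percent(self, rng):
        df = pd.DataFrame({
            "rank": rng.integers(1, 21, 20_000),
            "interface_class": ["rim"] * 20_000,
        })
        dist = ranking_distribution(df)
        assert np.allclose(dist["percent"], 5.0, atol=0.8)


class TestRandomBaseline:
    def test_recall_one_when_everything_predicted(self):
        out = random_baseline(24, 20, 5.7, 20)
        assert out["recall"] == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            random_baseline(24, 20, 5.7, 25)
        with pytest.raises(ValueError):
            random_baseline(0, 20, 5.7, 5.7)

    def test_monte_carlo_agreement(self, rng):
        n, m, k = 20, 6, 6
        trials = 20_000
        tp = np.zeros(trials)
        for i in range(trials):
            truth = np.zeros(n, dtype=bool)
            truth[rng.choice(n, m, replace=False)] = True
            pred = np.zeros(n, dtype=bool)
            pred[rng.choice(n, k, replace=False)] = True
            tp[i] = np.sum(truth & pred)
        closed = random_baseline(24, n, m, k)
        mc_recall = tp.mean() / m
        se = tp.std() / np.sqrt(trials) / m
        assert abs(closed["recall"] - mc_recall) < 3 * se + 1e-9
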