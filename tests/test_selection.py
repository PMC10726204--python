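"""Integrated feature selection: rankings, thresholds, combination, RFE."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from yieldvi.evaluate import DegenerateTargetError
from yieldvi.feature_sets import FeatureRanking, FeatureSubset
from yieldvi.models import ModelSpec
from yieldvi.selection import (
    EmptySubsetError,
    ForestConfig,
    RFEConfig,
    apply_threshold,
    combine_subsets,
    pcrf_rfe,
    pearson_ranking,
    rf_ranking,
    rfe_select,
)
from yieldvi.vegindex import list_indices


def pearson_by_fractions(xs, ys):
    """Exact rational covariance and variances (Pearson oracle pieces)."""
    xs = [Fraction(v) for v in xs]
    ys = [Fraction(v) for v in ys]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    return cov, vx, vy


def make_table(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestPearsonRanking:
    def test_exact_linear_feature_scores_one(self, rng):
        y = rng.normal(8, 1.4, 30)
        table = make_table({"lin": 2 * y + 1, "noise": rng.normal(size=30)})
        scores = pearson_ranking(table, y).as_dict()
        assert scores["lin"] == pytest.approx(1.0)

    def test_perfect_anticorrelation_scores_one(self):
        table = make_table({"f": [1.0, 2.0, 3.0]})
        scores = pearson_ranking(table, [3.0, 2.0, 1.0]).as_dict()
        assert scores["f"] == pytest.approx(1.0)

    def test_hand_rational_example_is_four_fifths(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov=1, var_x=5/4, var_y=5/4 -> r=4/5
        cov, vx, vy = pearson_by_fractions([1, 2, 3, 4], [1, 3, 2, 4])
        assert cov == Fraction(1)
        assert vx == vy == Fraction(5, 4)
        table = make_table({"f": [1.0, 2.0, 3.0, 4.0]})
        scores = pearson_ranking(table, [1.0, 3.0, 2.0, 4.0]).as_dict()
        assert scores["f"] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_feature_warns_and_scores_zero(self, rng):
        y = rng.normal(8, 1, 20)
        table = make_table({"flat": np.ones(20), "ok": y + rng.normal(0, 0.1, 20)})
        with pytest.warns(UserWarning, match="variance"):
            scores = pearson_ranking(table, y).as_dict()
        assert scores["flat"] == 0.0

    def test_constant_yield_rejected(self, rng):
        table = make_table({"f": rng.normal(size=10)})
        with pytest.raises(DegenerateTargetError):
            pearson_ranking(table, np.full(10, 8.0))

    def test_missing_values_dropped_pairwise(self, rng):
        y = rng.normal(8, 1, 20)
        f = y + rng.normal(0, 0.01, 20)
        f[3] = np.nan
        clean = pearson_ranking(make_table({"f": np.delete(f, 3)}), np.delete(y, 3)).as_dict()
        withnan = pearson_ranking(make_table({"f": f}), y).as_dict()
        assert withnan["f"] == pytest.approx(clean["f"], abs=1e-12)

    def test_affine_rescaling_leaves_score_unchanged(self, rng):
        y = rng.normal(8, 1.4, 40)
        f = 0.3 * y + rng.normal(0, 0.5, 40)
        s1 = pearson_ranking(make_table({"f": f}), y).as_dict()["f"]
        s2 = pearson_ranking(make_table({"f": -5.0 * f + 17.0}), y).as_dict()["f"]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_scores_bounded_by_one(self, vitable, yields):
        scores = pearson_ranking(vitable, yields).as_dict()
        assert all(0.0 <= s <= 1.0 for s in scores.values())


class TestRFRanking:
    def test_same_seed_identical_ranking(self, rng):
        y = rng.normal(8, 1.4, 60)
        table = make_table(
            {"s": y + rng.normal(0, 0.3, 60), "n1": rng.normal(size=60), "n2": rng.normal(size=60)}
        )
        cfg = ForestConfig(n_trees=100)
        r1 = rf_ranking(table, y, cfg, seed=11)
        r2 = rf_ranking(table, y, cfg, seed=11)
        assert r1.scores == r2.scores

    def test_planted_signal_ranked_first_among_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            y = rng.normal(8, 1.4, 200)
            cols = {"signal": y + rng.normal(0, 0.4, 200)}
            cols.update({f"n{i}": rng.normal(size=200) for i in range(8)})
            ranking = rf_ranking(make_table(cols), y, ForestConfig(n_trees=150), seed=seed)
            hits += ranking.names[0] == "signal"
        assert hits >= 9

    def test_null_target_gives_no_standout_importance(self):
        # with yield independent of all features, scores stay near zero
        tops = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            y = rng.normal(8, 1.4, 200)
            cols = {f"n{i}": rng.normal(size=200) for i in range(8)}
            ranking = rf_ranking(make_table(cols), y, ForestConfig(n_trees=150), seed=seed)
            tops.append(ranking.scores[0][1])
        assert np.mean(tops) < 10.0  # percent OOB-MSE increase stays small

    def test_too_few_rows_rejected(self, rng):
        table = make_table({"a": rng.normal(size=5)})
        with pytest.raises(ValueError, match="at least 10"):
            rf_ranking(table, rng.normal(size=5), ForestConfig(n_trees=10), seed=0)


class TestThreshold:
    def make_ranking(self, scores):
        return FeatureRanking.from_scores("PC", scores)

    def test_boundary_is_strictly_greater(self):
        ranking = self.make_ranking({"NDVI": 0.9, "SAVI": 0.53, "OSAVI": 0.2})
        sub = apply_threshold(ranking, 0.53)
        assert set(sub.names) == {"NDVI"}

    def test_tau_below_minimum_keeps_all(self):
        ranking = self.make_ranking({"NDVI": 0.9, "SAVI": 0.53, "OSAVI": 0.2})
        assert len(apply_threshold(ranking, 0.1)) == 3

    def test_tau_above_maximum_keeps_none(self):
        ranking = self.make_ranking({"NDVI": 0.9, "SAVI": 0.53})
        assert len(apply_threshold(ranking, 0.95)) == 0

    def test_threshold_monotonicity(self, vitable, yields):
        ranking = pearson_ranking(vitable, yields)
        taus = [0.1, 0.3, 0.53, 0.7, 0.9]
        subs = [set(apply_threshold(ranking, t).names) for t in taus]
        for smaller_tau, larger_tau in zip(subs, subs[1:]):
            assert larger_tau <= smaller_tau

    def test_quantile_mode_keeps_top_fraction(self, vitable, yields):
        ranking = pearson_ranking(vitable, yields)
        sub = apply_threshold(ranking, 0.2, mode="quantile")
        assert 0 < len(sub) <= int(np.ceil(0.2 * 35)) + 1

    def test_provenance_records_method_and_tau(self):
        ranking = self.make_ranking({"NDVI": 0.9})
        sub = apply_threshold(ranking, 0.53)
        assert sub.provenance[0]["method"] == "PC"
        assert sub.provenance[0]["threshold"] == 0.53


class TestCombine:
    def subset_of(self, names):
        return FeatureSubset.create(names, [{"step": "test"}])

    def test_union_counts_with_shared_features(self):
        # 16- and 20-member subsets with a 25-member union share 11
        # features by inclusion-exclusion
        names = list_indices()
        shared, only_a, only_b = names[:11], names[11:16], names[16:25]
        a = self.subset_of(shared + only_a)  # 16
        b = self.subset_of(shared + only_b)  # 20
        assert len(a) == 16 and len(b) == 20
        assert len(combine_subsets(a, b, "union")) == 25
        assert len(combine_subsets(a, b, "intersection")) == 11

    def test_intersection_from_union_arithmetic(self):
        names = list_indices()
        # |A|=24, |B|=15, |A u B|=26  ->  |A n B| = 24+15-26 = 13
        shared, only_a, only_b = names[:13], names[13:24], names[24:26]
        a = self.subset_of(shared + only_a)
        b = self.subset_of(shared + only_b)
        assert len(a) == 24 and len(b) == 15
        assert len(combine_subsets(a, b, "union")) == 26
        assert len(combine_subsets(a, b, "intersection")) == 13

    def test_union_idempotent(self):
        a = self.subset_of(["NDVI", "SAVI"])
        assert set(combine_subsets(a, a, "union").names) == set(a.names)

    def test_inclusion_exclusion_identity(self, vitable, yields):
        ranking = pearson_ranking(vitable, yields)
        a = apply_threshold(ranking, 0.5)
        b = apply_threshold(ranking, 0.7)
        u = combine_subsets(a, b, "union")
        i = combine_subsets(a, b, "intersection")
        assert len(u) == len(a) + len(b) - len(i)


def planted_matrix(seed: int, n: int = 200, n_noise: int = 9):
    """3 informative features + pure-noise features (recovery oracle input)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(8, 1.4, n)
    cols = {
        "NDVI": y + rng.normal(0, 0.35, n),
        "SAVI": 1.5 * y + rng.normal(0, 0.5, n),
        "OSAVI": -y + rng.normal(0, 0.35, n),
    }
    # names[18:] avoids colliding with the planted NDVI/SAVI/OSAVI columns
    cols.update({name: rng.normal(size=n) for name in list_indices()[18:18 + n_noise]})
    return pd.DataFrame(cols), y


class TestRFE:
    def base_config(self, seed=0, patience=5):
        return RFEConfig(ModelSpec("cubist"), patience=patience, cv_folds=4, seed=seed)

    def test_result_contained_in_start_and_nonempty(self):
        X, y = planted_matrix(1)
        start = FeatureSubset.create(list(X.columns), [{"step": "test"}])
        out = rfe_select(X, y, start, self.base_config(seed=1))
        assert set(out.names) <= set(start.names)
        assert len(out) >= 1

    def test_best_score_no_worse_than_start_score(self):
        X, y = planted_matrix(2)
        start = FeatureSubset.create(list(X.columns), [{"step": "test"}])
        out = rfe_select(X, y, start, self.base_config(seed=2))
        trace = out.provenance[-1]["trace"]
        assert out.provenance[-1]["best_cv_rmse"] <= trace[0]["cv_rmse"] + 1e-12
        assert len(trace) - 1 <= len(start) - 1  # eliminations bounded

    def test_empty_start_rejected(self):
        X, y = planted_matrix(3)
        empty = FeatureSubset(names=(), provenance=({"step": "test"},))
        with pytest.raises(EmptySubsetError):
            rfe_select(X, y, empty, self.base_config())

    def test_recovers_planted_features(self):
        hits = 0
        for seed in range(8):
            X, y = planted_matrix(400 + seed)
            start = FeatureSubset.create(list(X.columns), [{"step": "test"}])
            out = rfe_select(X, y, start, self.base_config(seed=seed, patience=8))
            hits += len(set(out.names) & {"NDVI", "SAVI", "OSAVI"}) >= 2
        assert hits >= 7

    def test_deterministic_given_seed(self):
        X, y = planted_matrix(4)
        start = FeatureSubset.create(list(X.columns), [{"step": "test"}])
        a = rfe_select(X, y, start, self.base_config(seed=5))
        b = rfe_select(X, y, start, self.base_config(seed=5))
        assert a.names == b.names
        assert a.provenance == b.provenance


class TestIntegratedPipeline:
    def test_composition_equals_manual_chaining(self):
        X, y = planted_matrix(7)
        fc = ForestConfig(n_trees=100)
        rfe_cfg = RFEConfig(ModelSpec("cubist"), patience=5, cv_folds=4, seed=7)
        combined = pcrf_rfe(X, y, rfe_cfg, pc_tau=0.53, rf_tau=1.9,
                            forest_config=fc, forest_seed=7)
        pc = pearson_ranking(X, y)
        rf = rf_ranking(X, y, fc, seed=7)
        union = combine_subsets(apply_threshold(pc, 0.53), apply_threshold(rf, 1.9), "union")
        manual = rfe_select(X, y, union, rfe_cfg)
        assert combined.names == manual.names

    def test_default_thresholds_recorded_in_provenance(self):
        X, y = planted_matrix(8)
        rfe_cfg = RFEConfig(ModelSpec("cubist"), patience=3, cv_folds=4, seed=8)
        out = pcrf_rfe(X, y, rfe_cfg, forest_config=ForestConfig(n_trees=100), forest_seed=8)
        taus = {p["method"]: p["threshold"] for p in out.provenance if p.get("step") == "threshold"}
        assert taus == {"PC": 0.53, "RF": 1.9}

    def test_planted_features_survive_union_stage(self):
        X, y = planted_matrix(9)
        pc = apply_threshold(pearson_ranking(X, y), 0.53)
        rf = apply_threshold(rf_ranking(X, y, ForestConfig(n_trees=150), seed=9), 1.9)
        union = combine_subsets(pc, rf, "union")
        assert {"NDVI", "SAVI", "OSAVI"} <= set(union.names)

    def test_empty_union_raises_with_relaxation_hint(self):
        X, y = planted_matrix(10)
        rfe_cfg = RFEConfig(ModelSpec("cubist"), patience=3, cv_folds=4, seed=10)
        with pytest.raises(EmptySubsetError, match="relax"):
            pcrf_rfe(X, y, rfe_cfg, pc_tau=2.0, rf_tau=1e9,
                     forest_config=ForestConfig(n_trees=50), forest_seed=10)
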