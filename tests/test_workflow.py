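import itertools

import numpy as np
import pytest
from sklearn.model_selection import KFold

from cpgclock.base_selectors import KBestSelector
from cpgclock.boruta import BorutaConfig
from cpgclock.clock import evaluate_feature_set
from cpgclock.data_io import FeatureSet, MethylationMatrix
from cpgclock.workflow import (
    EmptyIntersectionError,
    SelectionRecord,
    aggregate_unique,
    chain,
    intersect_per_fold_then_refine,
    post_selection_intersection,
    run_cv_selection,
    top_frequent,
)

from conftest import planted_dataset


class FixedSelector:
    """Returns a fixed feature list (restricted to the matrix at hand)."""

    def __init__(self, name, cpgs):
        self.name = name
        self.cpgs = tuple(cpgs)

    def select(self, m):
        present = [c for c in self.cpgs if c in set(m.cpg_ids)]
        return FeatureSet(tuple(present), provenance=self.name)


class SpySelector:
    """Records exactly which samples each per-fold run was shown."""

    name = "spy"

    def __init__(self):
        self.seen: list[frozenset] = []

    def select(self, m):
        self.seen.append(frozenset(m.sample_ids))
        return FeatureSet(tuple(m.cpg_ids[:2]), provenance="spy")


def record(method, fold, cpgs):
    return SelectionRecord(method, fold, FeatureSet(tuple(cpgs)))


class TestChain:
    def test_single_stage_chain_is_that_selector(self):
        m, _ = planted_dataset(0, n_cpgs=40, n_samples=60)
        sel = KBestSelector(k=7)
        assert chain([sel]).select(m).cpg_ids == sel.select(m).cpg_ids

    def test_composite_output_subset_of_every_stage(self):
        m, _ = planted_dataset(1, n_cpgs=40, n_samples=60)
        s1, s2 = KBestSelector(k=15), KBestSelector(k=5)
        out = chain([s1, s2]).select(m)
        assert set(out) <= set(s1.select(m))
        assert len(out) == 5

    def test_empty_stage_output_identifies_the_stage(self):
        m, _ = planted_dataset(2, n_cpgs=10, n_samples=30)
        bad = FixedSelector("bad-stage", ["cg_not_present"])
        with pytest.raises(ValueError, match="bad-stage"):
            chain([KBestSelector(k=5), bad]).select(m)

    def test_later_stages_only_see_earlier_survivors(self):
        m, _ = planted_dataset(3, n_cpgs=30, n_samples=50)
        spy = SpySelector()
        first = KBestSelector(k=6)
        chained = chain([first, FixedSelector("keep", m.cpg_ids)])
        out = chained.select(m)
        assert set(out) == set(first.select(m))


class TestRunCvSelection:
    def test_record_count_is_methods_times_folds(self):
        m, _ = planted_dataset(4, n_cpgs=20, n_samples=60)
        methods = [KBestSelector(k=3), KBestSelector(k=5, name="kbest-five")]
        records = run_cv_selection(m, methods, folds=10, seed=1)
        assert len(records) == 20
        assert all(r.ok for r in records)
        assert {r.fold_index for r in records} == set(range(10))

    def test_selection_never_sees_the_held_out_fold(self):
        m, _ = planted_dataset(5, n_cpgs=15, n_samples=50)
        spy = SpySelector()
        run_cv_selection(m, {"spy": spy}, folds=5, seed=42)
        folds = list(KFold(5, shuffle=True, random_state=42).split(m.X))
        assert len(spy.seen) == 5
        for seen, (train_idx, test_idx) in zip(spy.seen, folds):
            held_out = {m.sample_ids[i] for i in test_idx}
            assert seen == {m.sample_ids[i] for i in train_idx}
            assert not (seen & held_out)

    def test_failing_method_recorded_and_run_continues(self):
        m, _ = planted_dataset(6, n_cpgs=10, n_samples=40)

        class Exploding:
            name = "boom"

            def select(self, m):
                raise RuntimeError("kaput")

        with pytest.warns(UserWarning, match="boom"):
            records = run_cv_selection(
                m, [Exploding(), KBestSelector(k=2)], folds=4, seed=0
            )
        boom = [r for r in records if r.method_name == "boom"]
        assert all(not r.ok and "kaput" in r.error for r in boom)
        assert all(r.ok for r in records if r.method_name != "boom")

    def test_too_few_samples_rejected(self):
        m, _ = planted_dataset(7, n_cpgs=10, n_samples=5)
        with pytest.raises(ValueError):
            run_cv_selection(m, [KBestSelector(k=2)], folds=10, seed=0)


class TestAggregation:
    def test_union_of_two_folds(self):
        table = aggregate_unique(
            [record("m1", 0, ["a", "b"]), record("m1", 1, ["b", "c"])]
        )
        assert set(table["m1"]) == {"a", "b", "c"}

    def test_method_absent_from_records_absent_from_table(self):
        table = aggregate_unique([record("m1", 0, ["a"])])
        assert table.names() == ["m1"]

    def test_three_fold_union_matches_brute_force(self, rng):
        pool = [f"cg{i}" for i in range(30)]
        per_fold = [list(rng.choice(pool, size=8, replace=False)) for _ in range(3)]
        records = [record("m", i, sel) for i, sel in enumerate(per_fold)]
        brute = set(itertools.chain.from_iterable(per_fold))
        assert set(aggregate_unique(records)["m"]) == brute

    def test_aggregation_order_insensitive(self):
        recs = [record("m1", 0, ["b", "a"]), record("m1", 1, ["c"])]
        assert (
            aggregate_unique(recs)["m1"].cpg_ids
            == aggregate_unique(recs[::-1])["m1"].cpg_ids
        )


class TestTopFrequent:
    def test_ubiquitous_cpg_ranks_first(self):
        records = [record("m", i, ["always", f"x{i}"]) for i in range(4)]
        assert top_frequent(records, 1).cpg_ids == ("always",)

    def test_ranking_matches_brute_force_tally(self, rng):
        pool = [f"cg{i}" for i in range(12)]
        records = [
            record(m, f, list(rng.choice(pool, size=4, replace=False)))
            for m in ("A", "B") for f in range(5)
        ]
        counts: dict = {}
        for r in records:
            for c in r.selected.cpg_ids:
                counts[c] = counts.get(c, 0) + 1
        expected = sorted(counts, key=lambda c: (-counts[c], c))[:5]
        got = top_frequent(records, 5)
        assert list(got.cpg_ids) == expected
        assert list(got.scores) == [float(counts[c]) for c in expected]

    def test_too_few_distinct_features_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            top_frequent([record("m", 0, ["a"])], 5)


class TestIntersections:
    def test_post_selection_intersection_matches_brute_force(self):
        table = aggregate_unique(
            [record("m1", 0, ["a", "b", "c"]), record("m2", 0, ["b", "c", "d"])]
        )
        assert set(post_selection_intersection(table)) == {"b", "c"}

    def test_identical_methods_intersect_to_identity(self):
        table = aggregate_unique(
            [record("m1", 0, ["a", "b"]), record("m2", 0, ["a", "b"])]
        )
        assert set(post_selection_intersection(table)) == {"a", "b"}

    def test_single_shared_cpg_survives(self):
        table = aggregate_unique(
            [record("m1", 0, ["a", "b"]), record("m2", 0, ["a", "z"])]
        )
        assert post_selection_intersection(table).cpg_ids == ("a",)

    def test_per_fold_intersection_then_refine_recovers_consensus(self):
        m, truth = planted_dataset(8, n_cpgs=40, n_samples=120)
        planted = list(truth.cpg_ids)
        nulls = [c for c in m.cpg_ids if c not in set(planted)]
        records = [
            record("m1", f, planted + nulls[f : f + 2]) for f in range(3)
        ] + [
            record("m2", f, planted + nulls[f + 5 : f + 7]) for f in range(3)
        ]
        fs = intersect_per_fold_then_refine(
            records, m, BorutaConfig(n_trees=30, n_iterations=40, seed=0)
        )
        assert set(fs) == set(planted)

    def test_disjoint_methods_raise_empty_intersection(self):
        m, _ = planted_dataset(9, n_cpgs=10, n_samples=30)
        records = [
            record("m1", 0, m.cpg_ids[:3]),
            record("m2", 0, m.cpg_ids[5:8]),
        ]
        with pytest.raises(EmptyIntersectionError):
            intersect_per_fold_then_refine(records, m)


class TestEvaluateFeatureSet:
    def test_noiseless_truth_scores_near_perfectly(self):
        m, truth = planted_dataset(10, noise_sd=0.0)
        report = evaluate_feature_set(m, truth, repeats=5, seed=0,
                                      penalty_grid=[(0.0, 0.0)])
        assert report.mean_r2 >= 0.999

    def test_noise_features_on_empty_signal_data_score_poorly(self):
        r2s = []
        for seed in range(5):
            m, _ = planted_dataset(seed, n_informative=0)
            fs = FeatureSet(tuple(m.cpg_ids[:10]))
            rep = evaluate_feature_set(m, fs, repeats=5, seed=seed)
            r2s.append(rep.mean_r2)
        assert np.mean(r2s) <= 0.2

    def test_report_carries_all_summary_columns(self):
        m, truth = planted_dataset(11)
        rep = evaluate_feature_set(m, truth, repeats=4, seed=1)
        assert rep.r2_std >= 0 and rep.mae_years >= 0 and rep.median_ae_years >= 0
        assert list(rep.per_split.columns) == ["split", "r2", "mae", "median_ae"]
        assert len(rep.per_split) == 4

    def test_kfold_mode_uses_each_sample_once_as_test(self):
        m, truth = planted_dataset(12, n_samples=60, n_cpgs=30)
        rep = evaluate_feature_set(m, truth, repeats=5, seed=2, mode="kfold")
        assert len(rep.per_split) == 5

    def test_unknown_cpgs_reported_by_name(self):
        m, _ = planted_dataset(13, n_cpgs=10, n_samples=30)
        with pytest.raises(KeyError, match="cg_missing"):
            evaluate_feature_set(m, FeatureSet(("cg_missing",)), repeats=2, seed=0)

    def test_empty_feature_set_rejected(self):
        m, _ = planted_dataset(14, n_cpgs=10, n_samples=30)
        with pytest.raises(ValueError, match="empty"):
            evaluate_feature_set(m, FeatureSet(()), repeats=2, seed=0)
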