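import numpy as np
import pytest

from conftest import constant_stage_member, make_pool
from flystage.ensemble import (
    AnnotationError,
    PoolSpec,
    PredictionHistogram,
    StageAnnotation,
    annotate,
    annotate_images,
    assign_thirds,
    build_pool,
    disagreement_rate,
    enumerate_pool_plan,
    load_pool,
    save_pool,
    vote,
    vote_matrix,
)
from flystage.gabor import feature_group_structure


def _histogram(votes_by_stage: dict) -> PredictionHistogram:
    stages = np.arange(3, 18)
    votes = np.zeros(15)
    for s, v in votes_by_stage.items():
        votes[s - 3] = v
    return PredictionHistogram(stages=stages, votes=votes)


class TestPoolSpec:
    def test_default_pool_has_1050_members(self):
        spec = PoolSpec()
        assert spec.size == 7 * 5 * 30 == 1050
        assert len(list(enumerate_pool_plan(spec))) == 1050

    def test_single_cell_pool_has_one_member(self):
        spec = PoolSpec(algorithms=("lasso_ls",), training_ratios=(0.7,), n_partitions=1)
        assert spec.size == 1

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            PoolSpec(algorithms=("boosting",))

    def test_splits_shared_across_algorithms_within_cell(self):
        spec = PoolSpec(training_ratios=(0.5,), n_partitions=2)
        plan = list(enumerate_pool_plan(spec))
        by_cell = {}
        for algo, ri, ratio, p, seed in plan:
            by_cell.setdefault((ri, p), set()).add(seed)
        assert all(len(seeds) == 1 for seeds in by_cell.values())


class TestBuildPool:
    def test_pool_size_and_confidences(self, blob_data):
        X, y = blob_data
        spec = PoolSpec(algorithms=("lasso_ls", "svm_hinge_l2"),
                        training_ratios=(0.6, 0.8), n_partitions=2, master_seed=9)
        pool = build_pool(X, y, spec=spec, groups=feature_group_structure(4, 5))
        assert len(pool.members) == 8
        assert all(0.0 <= m.confidence <= 1.0 for m in pool.members)

    def test_same_master_seed_reproduces_pool_bitwise(self, blob_data):
        X, y = blob_data
        spec = PoolSpec(algorithms=("lasso_logistic",), training_ratios=(0.7,),
                        n_partitions=2, master_seed=3)
        p1 = build_pool(X, y, spec=spec)
        p2 = build_pool(X, y, spec=spec)
        for m1, m2 in zip(p1.members, p2.members):
            assert m1.confidence == m2.confidence
            np.testing.assert_array_equal(m1.train_indices, m2.train_indices)
            for a, b in zip(m1.ovr.models, m2.ovr.models):
                np.testing.assert_array_equal(a.weights, b.weights)

    def test_validation_confidence_matches_manual_recount(self, blob_data):
        X, y = blob_data
        spec = PoolSpec(algorithms=("svm_hinge_l2",), training_ratios=(0.7,),
                        n_partitions=1, master_seed=1)
        pool = build_pool(X, y, spec=spec)
        m = pool.members[0]
        acc = np.mean(m.predict(X[m.val_indices]) == y[m.val_indices])
        assert m.confidence == pytest.approx(acc)


class TestVoting:
    def test_weighted_vote_histogram_example(self):
        members = [
            constant_stage_member(10, 0.8),
            constant_stage_member(10, 0.7),
            constant_stage_member(9, 0.6),
        ]
        pool = make_pool(members)
        hist = vote(pool, np.zeros(4))
        assert hist.vote_for(10) == pytest.approx(1.5)
        assert hist.vote_for(9) == pytest.approx(0.6)
        assert hist.total == pytest.approx(2.1)

    def test_single_member_casts_one_scaled_vote(self):
        pool = make_pool([constant_stage_member(12, 0.85)])
        hist = vote(pool, np.zeros(4))
        assert hist.vote_for(12) == pytest.approx(0.85)
        assert hist.total == pytest.approx(0.85)

    def test_vote_conservation_over_random_inputs(self, blob_data, rng):
        X, y = blob_data
        spec = PoolSpec(algorithms=("lasso_ls", "lasso_logistic"),
                        training_ratios=(0.7,), n_partitions=2, master_seed=4)
        pool = build_pool(X, y, spec=spec)
        total_conf = pool.confidences.sum()
        H = vote_matrix(pool, rng.normal(size=(100, 20)))
        np.testing.assert_allclose(H.sum(axis=1), total_conf, atol=1e-10)

    def test_dimension_mismatch_rejected(self, blob_data):
        X, y = blob_data
        pool = build_pool(X, y, spec=PoolSpec(algorithms=("lasso_ls",),
                                              training_ratios=(0.7,), n_partitions=1))
        with pytest.raises(AnnotationError):
            vote(pool, np.zeros(7))


class TestAnnotate:
    def test_early_substage_when_lower_neighbor_dominates(self):
        ann = annotate(_histogram({10: 5, 9: 4, 11: 1}))
        assert ann.stage == 10
        assert ann.substage == "E"
        assert ann.stage_score == pytest.approx(10 + 0.5 * (1 - 4) / 5)  # 9.7
        assert ann.stage_score < 10

    def test_symmetric_neighbors_give_integer_score_and_late_flag(self):
        ann = annotate(_histogram({8: 5, 7: 2, 9: 2}))
        assert ann.stage_score == pytest.approx(8.0)
        assert ann.substage == "L"

    def test_edge_stages_have_no_refinement(self):
        for s in (3, 17):
            ann = annotate(_histogram({s: 5, 10: 1}))
            assert ann.stage == s
            assert ann.substage is None and ann.stage_score is None

    def test_argmax_tie_resolves_to_smaller_stage(self):
        ann = annotate(_histogram({6: 3, 12: 3}))
        assert ann.stage == 6

    def test_score_stays_within_half_stage(self, rng):
        for _ in range(200):
            votes = dict(zip(range(3, 18), rng.random(15)))
            ann = annotate(_histogram(votes))
            if ann.stage_score is not None:
                assert ann.stage - 0.5 <= ann.stage_score <= ann.stage + 0.5

    def test_score_increases_with_upper_neighbor_votes(self):
        scores = [
            annotate(_histogram({10: 6, 9: 2, 11: up})).stage_score
            for up in (0.5, 1.5, 3.0, 5.0)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(AnnotationError):
            annotate(_histogram({}))


class TestThirds:
    def _cohort(self, scores, stage=10, substage="E"):
        return [
            StageAnnotation(stage=stage, substage=substage, stage_score=s)
            for s in scores
        ]

    def test_cohort_of_six_splits_evenly(self):
        anns = assign_thirds(self._cohort([9.6, 9.61, 9.7, 9.71, 9.8, 9.81]))
        assert [a.third for a in anns] == ["a", "a", "b", "b", "c", "c"]

    def test_remainder_goes_to_earliest_group(self):
        anns = assign_thirds(self._cohort([9.6 + 0.01 * i for i in range(7)]))
        counts = {t: sum(a.third == t for a in anns) for t in "abc"}
        assert counts == {"a": 3, "b": 2, "c": 2}

    def test_shuffled_cohort_gets_same_thirds_as_sorted(self, rng):
        scores = list(9.55 + 0.4 * rng.random(11))
        sorted_anns = assign_thirds(self._cohort(sorted(scores)))
        by_score_sorted = {a.stage_score: a.third for a in sorted_anns}
        shuffled = assign_thirds(self._cohort(scores))
        assert all(by_score_sorted[a.stage_score] == a.third for a in shuffled)

    def test_tiny_cohort_fills_groups_in_order(self):
        anns = assign_thirds(self._cohort([9.7, 9.9]))
        assert [a.third for a in anns] == ["a", "b"]

    def test_edge_stage_annotations_keep_no_third(self):
        anns = assign_thirds([StageAnnotation(stage=3)])
        assert anns[0].third is None


class TestDisagreement:
    class _FakeMember:
        def __init__(self, algorithm, preds):
            self.algorithm = algorithm
            self.training_ratio = 0.5
            self.partition_index = 0
            self.excluded = False
            self.val_indices = np.arange(len(preds))
            self._preds = np.asarray(preds)

        def predict(self, X):
            return self._preds[: len(X)]

    def _pool_of(self, members):
        from flystage.ensemble import ModelPool

        spec = PoolSpec(algorithms=("lasso_ls", "lasso_logistic"),
                        training_ratios=(0.5,), n_partitions=1)
        return ModelPool(members=tuple(members), classes=np.arange(3, 18),
                         spec=spec, feature_dim=3)

    def test_example_disagreement_one_third(self):
        pool = self._pool_of([
            self._FakeMember("lasso_ls", [10, 9, 9]),
            self._FakeMember("lasso_logistic", [10, 10, 9]),
        ])
        assert disagreement_rate(pool, np.zeros((3, 3))) == pytest.approx(1 / 3)

    def test_identical_algorithms_never_disagree(self):
        pool = self._pool_of([
            self._FakeMember("lasso_ls", [10, 9, 8]),
            self._FakeMember("lasso_logistic", [10, 9, 8]),
        ])
        assert disagreement_rate(pool, np.zeros((3, 3))) == 0.0

    def test_single_algorithm_pool_is_an_error(self):
        pool = self._pool_of([self._FakeMember("lasso_ls", [10, 9, 8])])
        with pytest.raises(ValueError):
            disagreement_rate(pool, np.zeros((3, 3)))


class TestPersistence:
    def test_pool_round_trip_preserves_annotations(self, blob_data, tmp_path, rng):
        X, y = blob_data
        spec = PoolSpec(algorithms=("lasso_logistic", "svm_hinge_l2"),
                        training_ratios=(0.7,), n_partitions=1, master_seed=2)
        pool = build_pool(X, y, spec=spec)
        save_pool(pool, tmp_path / "pool")
        back = load_pool(tmp_path / "pool")
        Xq = rng.normal(size=(10, 20))
        a1 = annotate_images(pool, Xq, thirds=False)
        a2 = annotate_images(back, Xq, thirds=False)
        assert a1.equals(a2)
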