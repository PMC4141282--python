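"""Harness tests: splits, feature-learning modes, runs, rank-sum statistics."""

import itertools

import numpy as np
import pytest

from patchrec import experiment_harness as eh, synthetic_data as sd
from patchrec.experiment_harness import (
    DataPools,
    ExperimentSpec,
    RunResult,
    build_feature_learning_set,
    compare_patch_sizes,
    make_face_split,
    make_object_split,
    rank_sum_p,
    run_experiment,
    significance_band,
)


@pytest.fixture(scope="module")
def object_pool():
    return sd.generate_objects(sd.ObjectGenSpec(n_categories=4, seed=21))


@pytest.fixture(scope="module")
def face_pool():
    return sd.generate_faces(sd.FaceGenSpec(n_identities=5, seed=22))


class TestObjectSplit:
    def test_train_test_sizes(self, object_pool):
        # 30 train + 50 test per category
        s = make_object_split(object_pool, n_classes=4, seed=0)
        assert len(s.train) == 120 and len(s.test) == 200

    def test_disjoint_and_deterministic(self, object_pool):
        s1 = make_object_split(object_pool, 3, seed=7)
        s2 = make_object_split(object_pool, 3, seed=7)
        assert s1.train == s2.train and s1.test == s2.test
        assert set(i for i, _ in s1.train).isdisjoint(i for i, _ in s1.test)

    def test_small_category_rejected_by_name(self):
        pool = sd.generate_objects(sd.ObjectGenSpec(n_categories=2, seed=1))
        pool = [li for li in pool if not (li.label == 1 and li.meta["index"] >= 40)]
        with pytest.raises(ValueError, match="1"):
            make_object_split(pool, 2, seed=0)


class TestFaceSplit:
    def test_counts_and_view_separation(self, face_pool):
        s = make_face_split(face_pool, n_classes=4, seed=0)
        # 5 train views x 3 expressions, 4 test views x 3 expressions
        assert len(s.train) == 4 * 15 and len(s.test) == 4 * 12
        train_views = {face_pool[i].meta["view"] for i, _ in s.train}
        test_views = {face_pool[i].meta["view"] for i, _ in s.test}
        assert train_views == set(sd.TRAIN_VIEWS)
        assert test_views == set(sd.TEST_VIEWS)
        assert train_views.isdisjoint(test_views)

    def test_twelve_test_images_per_identity(self, face_pool):
        s = make_face_split(face_pool, n_classes=3, seed=1)
        per_ident = {}
        for _, lab in s.test:
            per_ident[lab] = per_ident.get(lab, 0) + 1
        assert set(per_ident.values()) == {12}

    def test_missing_view_rejected(self, face_pool):
        broken = [li for li in face_pool
                  if not (li.label == 0 and li.meta["view"] == 45.0)]
        with pytest.raises(ValueError, match="45"):
            make_face_split(broken, 3, seed=0)

    def test_face_n_classes_menu(self):
        for n in (10, 20, 30, 40):
            ExperimentSpec(task="face_id", mode="within", n_classes=n)
        with pytest.raises(ValueError):
            ExperimentSpec(task="face_id", mode="within", n_classes=7)


class TestFeatureLearningSet:
    def test_within_returns_train_images(self, face_pool):
        s = make_face_split(face_pool, 3, seed=2)
        pools = DataPools(faces=face_pool)
        name, ids = build_feature_learning_set(s, "within", pools, "face_id", 0)
        assert name == "faces" and ids == [i for i, _ in s.train]

    def test_between_labels_disjoint_from_split(self, face_pool):
        s = make_face_split(face_pool, 3, seed=2)
        pools = DataPools(faces=face_pool)
        name, ids = build_feature_learning_set(s, "between", pools, "face_id", 0)
        split_idents = {lab for _, lab in s.train}
        learn_idents = {face_pool[i].label for i in ids}
        assert learn_idents and learn_idents.isdisjoint(split_idents)

    def test_natural_is_pool_independent_of_split(self, face_pool):
        nat = sd.generate_natural_pool(6, seed=3)
        pools = DataPools(faces=face_pool, natural=nat)
        ids = set()
        for seed in (0, 1):
            s = make_face_split(face_pool, 3, seed=seed)
            name, i = build_feature_learning_set(s, "natural", pools, "face_id", seed)
            assert name == "natural"
            ids.add(tuple(i))
        assert len(ids) == 1 and list(ids)[0] == tuple(range(6))


@pytest.fixture(scope="module")
def easy_pools():
    return DataPools(
        objects=sd.generate_objects(sd.ObjectGenSpec(n_categories=2, seed=30)))


class TestRunExperiment:
    def test_separable_categories_reach_perfect_accuracy(self, easy_pools):
        spec = ExperimentSpec(task="object_cat", mode="within", sizes=(12,),
                              n_classes=2, n_runs=2, seed=0, n_per_size=30)
        res = run_experiment(spec, easy_pools)
        assert res[0].accuracies == [100.0, 100.0]

    def test_shuffled_labels_sit_at_chance(self, easy_pools):
        spec = ExperimentSpec(task="object_cat", mode="within", sizes=(8,),
                              n_classes=2, n_runs=6, seed=1, n_per_size=20,
                              shuffle_labels=True)
        res = run_experiment(spec, easy_pools)
        # chance is 50%; binomial sampling error over 6 runs x 100 test images
        assert abs(res[0].mean - 50.0) < 15.0

    def test_between_mode_runs_end_to_end(self):
        pools = DataPools(
            objects=sd.generate_objects(sd.ObjectGenSpec(n_categories=4, seed=31)))
        spec = ExperimentSpec(task="object_cat", mode="between", sizes=(8,),
                              n_classes=2, n_runs=1, seed=2, n_per_size=15)
        res = run_experiment(spec, pools)
        assert len(res) == 1 and 0.0 <= res[0].mean <= 100.0
        assert res[0].mean > 50.0   # disjoint-class features still separate

    def test_reproducible_under_seed(self, easy_pools):
        spec = ExperimentSpec(task="object_cat", mode="within", sizes=(8,),
                              n_classes=2, n_runs=2, seed=5, n_per_size=15)
        r1 = run_experiment(spec, easy_pools)
        r2 = run_experiment(spec, easy_pools)
        assert r1[0].accuracies == r2[0].accuracies


def brute_force_ranksum_p(a, b):
    """Exact two-sided rank-sum p-value by full enumeration (tie-free data)."""
    combined = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(combined)) + 1
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(combined)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, size=2)
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.8, 1, n2)
        assert rank_sum_p(list(a), list(b)) == pytest.approx(
            brute_force_ranksum_p(a, b), abs=1e-12)

    def test_matrix_shape_symmetry_diagonal(self):
        rng = np.random.default_rng(3)
        results = [RunResult(key=("t", "m", "h", s, 2),
                             accuracies=list(rng.normal(60 + s, 5, 10)))
                   for s in (4, 8, 12, 16, 20, 24)]
        pm = compare_patch_sizes(results)
        assert pm.matrix.shape == (6, 6)
        assert np.allclose(pm.matrix, pm.matrix.T)
        assert np.allclose(np.diag(pm.matrix), 1.0)
        assert ((pm.matrix > 0) & (pm.matrix <= 1)).all()

    def test_unequal_runs_rejected(self):
        r1 = RunResult(key=("t", "m", "h", 4, 2), accuracies=[1.0, 2.0])
        r2 = RunResult(key=("t", "m", "h", 8, 2), accuracies=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            compare_patch_sizes([r1, r2])

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_p([1.0], [2.0])

    def test_significance_bands(self):
        assert significance_band(0.2) == ""
        assert significance_band(0.04) == "*"
        assert significance_band(0.005) == "**"
        assert significance_band(0.0005) == "***"
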