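"""Tumor-content filtering, representative selection, slide similarity and
expert matching — including the exhaustive minimum-SSE clustering oracle."""

import numpy as np
import pytest

from somseg import (
    ExpertMatcher, FeatureSet, RepresentativeSet, SimilarityConfig,
    SimilarityMatrix, build_similarity_matrix, filter_tumor_patches,
    match_expert, pair_count, pairwise_mean_similarity, select_representatives,
    tumor_fraction,
)
from somseg.core_io import LabelMask
from conftest import make_patch


def feature_set(vectors, slide_id="s"):
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    return FeatureSet(slide_id, vectors, [(i, 0) for i in range(len(vectors))])


def rep(vectors, slide_id="s"):
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    return RepresentativeSet(slide_id, vectors, [(i, 0) for i in range(len(vectors))])


# --- exhaustive minimum-SSE clustering oracle (independent of KMeans) -------

def _partitions(items, k):
    """All set partitions of ``items`` into exactly k nonempty parts."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest, k - 1):
        yield [[first]] + part
    for part in _partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]


def oracle_representatives(X, k):
    """Brute-force minimum-SSE partition, then centroid-nearest member per
    cluster (ties -> lowest row index)."""
    n = len(X)
    k_eff = min(k, np.unique(X, axis=0).shape[0])
    best_sse, best_part = np.inf, None
    for part in _partitions(list(range(n)), k_eff):
        sse = sum(
            float(((X[idx] - X[idx].mean(axis=0)) ** 2).sum()) for idx in part
        )
        if sse < best_sse - 1e-12:
            best_sse, best_part = sse, part
    reps = []
    for idx in best_part:
        c = X[idx].mean(axis=0)
        d = np.linalg.norm(X[idx] - c, axis=1)
        reps.append(X[idx[int(np.argmin(d))]])
    return best_sse, sorted(map(tuple, reps))


class TestTumorFraction:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (np.ones((3, 3)), 1.0),
            (np.array([[1, 1], [1, 0]]), 0.75),
            (np.zeros((2, 2)), 0.0),
        ],
    )
    def test_fractions(self, codes, expected, scheme):
        assert tumor_fraction(LabelMask(codes.astype(int), scheme), {1, 2}) == expected

    def test_ignore_pixels_count_in_denominator(self, scheme):
        codes = np.array([[1, scheme.ignore_code], [1, 1]])
        assert tumor_fraction(LabelMask(codes, scheme), {1}) == 0.75

    def test_empty_crop_errors(self):
        with pytest.raises(ValueError):
            tumor_fraction(np.zeros((0, 0)), {1})


class TestFilterTumorPatches:
    def _patches(self, fractions, scheme):
        out = []
        for i, f in enumerate(fractions):
            n_tumor = int(round(f * 100))
            codes = np.zeros(100, dtype=int)
            codes[:n_tumor] = 1
            out.append(
                make_patch(np.zeros((10, 10, 3), np.uint8), codes.reshape(10, 10),
                           scheme, origin=(i, 0))
            )
        return out

    def test_strictly_above_threshold_retained_in_order(self, scheme):
        patches = self._patches([0.5, 0.61, 1.0], scheme)
        kept = filter_tumor_patches(patches, {1})
        assert [p.origin for p in kept] == [(1, 0), (2, 0)]

    def test_exact_threshold_excluded(self, scheme):
        patches = self._patches([0.60], scheme)
        assert filter_tumor_patches(patches, {1}) == []

    def test_monotone_in_threshold(self, scheme):
        patches = self._patches(np.linspace(0, 1, 21), scheme)
        n_low = len(filter_tumor_patches(patches, {1}, SimilarityConfig(tumor_content_threshold=0.6)))
        n_high = len(filter_tumor_patches(patches, {1}, SimilarityConfig(tumor_content_threshold=0.9)))
        assert n_high <= n_low


class TestSelectRepresentatives:
    def test_identical_vectors_collapse_to_one(self):
        fs = feature_set([[1.0, 2.0]] * 3)
        out = select_representatives(fs, SimilarityConfig(k_representatives=5))
        assert len(out) == 1
        np.testing.assert_array_equal(out.vectors[0], [1.0, 2.0])

    def test_two_well_separated_triplets(self):
        # exhaustive minimum-SSE clustering puts the triplets in separate
        # clusters with means 0.1 and 10.1; their nearest members are 0.1, 10.1
        fs = feature_set([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        out = select_representatives(fs, SimilarityConfig(k_representatives=2))
        assert sorted(out.vectors.ravel().tolist()) == [0.1, 10.1]

    def test_default_k_returns_five_members(self, rng):
        X = rng.normal(size=(20, 4))
        fs = feature_set(X)
        out = select_representatives(fs, SimilarityConfig())
        assert len(out) == 5
        for row in out.vectors:
            assert any(np.array_equal(row, x) for x in X)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(12, 3))
        cfg = SimilarityConfig(kmeans_seed=7)
        a = select_representatives(feature_set(X), cfg)
        b = select_representatives(feature_set(X), cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_empty_feature_set_errors(self):
        with pytest.raises(ValueError):
            fs = FeatureSet("s", np.zeros((0, 3)), [])
            select_representatives(fs)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_sse_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 9))
        X = gen.normal(size=(n, 3))
        cfg = SimilarityConfig(kmeans_seed=seed)
        out = select_representatives(feature_set(X), cfg)
        _, oracle = oracle_representatives(X, cfg.k_representatives)
        assert sorted(map(tuple, out.vectors)) == pytest.approx(oracle)


class TestPairwiseMeanSimilarity:
    def test_identical_single_vector_is_one(self):
        a = rep([[1.0, 2.0, 3.0]])
        assert pairwise_mean_similarity(a, a) == pytest.approx(1.0)

    def test_default_sets_give_25_comparisons(self, rng):
        a = rep(rng.normal(size=(5, 4)), "a")
        b = rep(rng.normal(size=(5, 4)), "b")
        assert pair_count(a, b) == 25

    def test_unit_vector_grid_example(self):
        a = rep([[1.0, 0.0], [0.0, 1.0]], "a")
        b = rep([[1.0, 0.0], [0.70711, 0.70711]], "b")
        assert pairwise_mean_similarity(a, b) == pytest.approx(0.60355, abs=1e-4)

    def test_symmetry(self, rng):
        a = rep(rng.normal(size=(3, 4)), "a")
        b = rep(rng.normal(size=(4, 4)), "b")
        for metric in ("cosine", "neg_L1", "neg_L2"):
            assert pairwise_mean_similarity(a, b, metric) == pytest.approx(
                pairwise_mean_similarity(b, a, metric)
            )

    def test_self_similarity_below_one_for_distinct_reps(self, rng):
        a = rep(rng.normal(size=(5, 8)))
        assert pairwise_mean_similarity(a, a) < 1.0

    def test_zero_norm_vector_errors_under_cosine(self):
        a = rep([[0.0, 0.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            pairwise_mean_similarity(a, a)


class TestSimilarityMatrixAndMatching:
    def test_identical_slide_single_rep_entry_is_one(self, rng):
        v = rng.normal(size=(1, 4))
        m = build_similarity_matrix([rep(v, "a")], [rep(v, "q")])
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_annotated_vs_annotated_symmetric(self, rng):
        reps = [rep(rng.normal(size=(3, 4)), f"s{i}") for i in range(3)]
        m = build_similarity_matrix(reps, reps)
        np.testing.assert_allclose(m.values, m.values.T)

    def test_duplicate_ids_rejected(self, rng):
        r = rep(rng.normal(size=(2, 3)), "dup")
        with pytest.raises(ValueError, match="duplicate"):
            build_similarity_matrix([r, r], [rep(rng.normal(size=(2, 3)), "q")])

    def test_argmax_and_tie_break(self):
        m = SimilarityMatrix(["A", "B", "C"], ["q"], np.array([[0.4, 0.9, 0.1]]))
        assert match_expert(m, "q") == "B"
        m_tie = SimilarityMatrix(["B", "A"], ["q"], np.array([[0.7, 0.7]]))
        assert match_expert(m_tie, "q") == "A"

    def test_unknown_query_errors(self):
        m = SimilarityMatrix(["A"], ["q"], np.ones((1, 1)))
        with pytest.raises(KeyError):
            match_expert(m, "nope")

    def test_distance_argmax_equals_distance_argmin(self, rng):
        annot = [rep(rng.normal(size=(2, 4)), f"a{i}") for i in range(4)]
        q = rep(rng.normal(size=(2, 4)), "q")
        m = build_similarity_matrix(annot, [q], "neg_L2")
        # the most similar expert under neg_L2 minimises mean pairwise L2
        dists = [-pairwise_mean_similarity(q, a, "neg_L2") for a in annot]
        assert match_expert(m, "q") == f"a{int(np.argmin(dists))}"

    def test_cosine_and_neg_l2_agree_on_unit_sphere(self, rng):
        def unit(rows):
            X = rng.normal(size=(rows, 5))
            return X / np.linalg.norm(X, axis=1, keepdims=True)

        annot = [rep(unit(3), f"a{i}") for i in range(5)]
        queries = [rep(unit(3), f"q{i}") for i in range(6)]
        m_cos = build_similarity_matrix(annot, queries, "cosine")
        m_l2 = build_similarity_matrix(annot, queries, "neg_L2")
        for q in m_cos.query_ids:
            assert match_expert(m_cos, q) == match_expert(m_l2, q)

    def test_expert_matcher_estimator_api(self, rng):
        annot = [rep(rng.normal(size=(2, 4)), f"a{i}") for i in range(3)]
        queries = [rep(rng.normal(size=(2, 4)), f"q{i}") for i in range(2)]
        matcher = ExpertMatcher().fit(annot)
        preds = matcher.predict(queries)
        matrix = matcher.transform(queries)
        assert preds == [match_expert(matrix, q.slide_id) for q in queries]
        assert matcher.get_params()["metric"] == "cosine"

    def test_matrix_csv_json_roundtrip(self, rng, tmp_path):
        annot = [rep(rng.normal(size=(2, 3)), f"a{i}") for i in range(2)]
        q = [rep(rng.normal(size=(2, 3)), "q0")]
        m = build_similarity_matrix(annot, q)
        m.to_json(tmp_path / "m.json")
        back = SimilarityMatrix.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.values, m.values)
        m.to_csv(tmp_path / "m.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "m.csv", index_col=0)
        np.testing.assert_allclose(df.values, m.values)
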