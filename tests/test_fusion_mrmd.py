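import math

import numpy as np
import pytest

from pprkit.errors import (
    AlignmentError,
    EmptyInputError,
    UndefinedMetricError,
    ValidationError,
)
from pprkit.fusion_mrmd import (
    FeatureMatrix,
    concatenate,
    max_relevance,
    mean_distance,
    pearson,
    rank_mrmd,
    read_matrix,
    select_subset,
    write_arff,
    write_matrix,
)


def make_matrix(values, labels, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FeatureMatrix(
        tuple(ids or (f"i{j}" for j in range(n))),
        tuple(names or (f"f{j}" for j in range(m))),
        values,
        np.asarray(labels),
    )


# --- independent brute-force MRMD ranking (loops only, no numpy algebra) ---


def brute_force_mrmd_order(values, labels, names):
    n, m = len(values), len(values[0])

    def corr(xs, ys):
        mx = sum(xs) / n
        my = sum(ys) / n
        num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
        dy = math.sqrt(sum((y - my) ** 2 for y in ys))
        return num / (dx * dy)

    cols = [[values[i][j] for i in range(n)] for j in range(m)]
    scaled = []
    for col in cols:
        lo, hi = min(col), max(col)
        scaled.append([(v - lo) / (hi - lo) if hi > lo else 0.0 for v in col])
    mr = [abs(corr(col, list(labels))) if max(col) > min(col) else 0.0 for col in cols]
    md = []
    for j in range(m):
        total = 0.0
        for k in range(m):
            if k != j:
                total += math.sqrt(
                    sum((a - b) ** 2 for a, b in zip(scaled[j], scaled[k]))
                )
        md.append(total / (m - 1))
    top = max(md)
    if top > 0:
        md = [v / top for v in md]
    scores = [r + d for r, d in zip(mr, md)]
    order = sorted(range(m), key=lambda j: (-scores[j], j))
    return [names[j] for j in order]


def informative_block_matrix(rng, n=120, n_noise=17):
    """3 complementary informative columns among uniform noise: each one
    elevates a different third of the positives, so no single column
    separates the classes but all three together do."""
    labels = np.repeat([0, 1], n // 2)
    blocks = np.array_split(np.flatnonzero(labels == 1), 3)
    noise = rng.random((n, n_noise))
    informative = rng.normal(0, 0.2, (n, 3))
    for j, block in enumerate(blocks):
        informative[block, j] += 2.0
    names = [f"noise{i}" for i in range(n_noise)] + ["inf0", "inf1", "inf2"]
    return make_matrix(np.column_stack([noise, informative]), labels, names=names)


class TestConcatenate:
    def test_fused_dimension_is_sum_of_parts(self, rng):
        a = make_matrix(rng.random((6, 4)), [0, 0, 0, 1, 1, 1], names=[f"a{i}" for i in range(4)])
        b = make_matrix(rng.random((6, 3)), [0, 0, 0, 1, 1, 1], names=[f"b{i}" for i in range(3)])
        fused = concatenate([a, b])
        assert fused.n_features == 7
        assert fused.names == a.names + b.names
        assert np.array_equal(fused.values[:, :4], a.values)

    def test_instance_mismatch_rejected(self, rng):
        a = make_matrix(rng.random((4, 2)), [0, 0, 1, 1], ids=list("abcd"))
        b = make_matrix(rng.random((4, 2)), [0, 0, 1, 1], ids=list("abce"),
                        names=["x", "y"])
        with pytest.raises(AlignmentError, match="1"):
            concatenate([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            concatenate([])


class TestPearson:
    def test_identity_and_negation(self, rng):
        x = rng.random(20)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson(np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4])) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson(np.ones(5), np.arange(5.0))


class TestRelevanceAndDistance:
    def test_label_copy_has_full_relevance(self, rng):
        labels = np.array([0, 1] * 10)
        values = np.column_stack([labels.astype(float), rng.random(20)])
        assert max_relevance(make_matrix(values, labels))[0] == pytest.approx(1.0)

    def test_noise_has_low_relevance(self, rng):
        labels = np.repeat([0, 1], 500)
        values = rng.random((1000, 3))
        assert np.all(max_relevance(make_matrix(values, labels)) < 0.15)

    def test_constant_column_scores_zero_with_warning(self, rng):
        labels = np.array([0, 1] * 5)
        values = np.column_stack([np.full(10, 3.0), rng.random(10)])
        with pytest.warns(UserWarning, match="constant"):
            mr = max_relevance(make_matrix(values, labels))
        assert mr[0] == 0.0

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(UndefinedMetricError):
            max_relevance(make_matrix(rng.random((6, 2)), [1] * 6))

    def test_outlier_column_gets_max_distance(self):
        """4-instance toy: c1 ≈ c2, c3 far away → md(c3) = 1."""
        values = np.array(
            [[0.0, 0.05, 1.0], [0.2, 0.25, 0.9], [0.4, 0.45, 0.1], [1.0, 1.0, 0.0]]
        )
        md = mean_distance(make_matrix(values, [0, 0, 1, 1]))
        assert md[2] == pytest.approx(1.0)
        assert md.max() == 1.0 and np.all((md >= 0) & (md <= 1))

    def test_duplicate_only_matrix_gives_zero_distances(self):
        values = np.column_stack([np.arange(4.0), np.arange(4.0)])
        md = mean_distance(make_matrix(values, [0, 0, 1, 1]))
        assert np.all(md == 0.0)


class TestRankMrmd:
    def test_label_copy_ranks_first(self, rng):
        labels = np.repeat([0, 1], 15)
        values = np.column_stack([rng.random((30, 4)), labels.astype(float)])
        ranking = rank_mrmd(make_matrix(values, labels))
        assert ranking.order[0] == "f4"

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Own ranking equals an independent pure-Python reimplementation."""
        for trial in range(50):
            n = int(rng.integers(6, 31))
            m = int(rng.integers(2, 13))
            values = rng.random((n, m)).round(3)
            labels = np.zeros(n, dtype=int)
            labels[: n // 2] = 1
            rng.shuffle(labels)
            matrix = make_matrix(values, labels)
            expected = brute_force_mrmd_order(values.tolist(), labels.tolist(),
                                              list(matrix.names))
            assert list(rank_mrmd(matrix).order) == expected, f"trial {trial}"

    def test_stable_tie_break_preserves_column_order(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        ranking = rank_mrmd(make_matrix(values, [0, 1, 0, 1]))
        assert ranking.order == ("f0", "f1")

    def test_positive_scaling_leaves_ranking_unchanged(self, rng):
        labels = np.repeat([0, 1], 10)
        values = rng.random((20, 5))
        base = rank_mrmd(make_matrix(values, labels))
        scaled = rank_mrmd(make_matrix(values * [3.0, 0.5, 10.0, 1.0, 7.0], labels))
        assert base.order == scaled.order
        assert np.allclose(base.mr, scaled.mr) and np.allclose(base.md, scaled.md)


class TestSelectSubset:
    def test_fixed_n_returns_rank_prefix(self, rng):
        labels = np.repeat([0, 1], 10)
        matrix = make_matrix(rng.random((20, 10)), labels)
        ranking = rank_mrmd(matrix)
        result = select_subset(matrix, ranking, strategy="fixed_n", n=5)
        assert result.chosen_columns == ranking.order[:5]

    def test_auc_scan_recovers_informative_columns(self, rng):
        """3 complementary informative columns among 17 noise ones: the scan
        keeps a small prefix containing all 3."""
        matrix = informative_block_matrix(rng, n=120, n_noise=17)
        ranking = rank_mrmd(matrix)
        result = select_subset(matrix, ranking, strategy="auc_scan",
                               grid=[1, 2, 3, 5, 8, 12, 20], seed=7, cv_folds=4)
        assert {"inf0", "inf1", "inf2"} <= set(result.chosen_columns)
        assert len(result.trace) == 7
        assert result.chosen_columns == ranking.order[: len(result.chosen_columns)]

    def test_empty_grid_rejected(self, rng):
        labels = np.repeat([0, 1], 5)
        matrix = make_matrix(rng.random((10, 3)), labels)
        with pytest.raises(ValidationError):
            select_subset(matrix, rank_mrmd(matrix), strategy="auc_scan", grid=[])


class TestPersistence:
    def test_delimited_round_trip(self, tmp_path, rng):
        matrix = make_matrix(rng.random((8, 5)), [0, 1] * 4)
        path = tmp_path / "matrix.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path)
        assert back.names == matrix.names
        assert back.instance_ids == matrix.instance_ids
        assert np.allclose(back.values, matrix.values)
        assert np.array_equal(back.labels, matrix.labels)

    def test_arff_structure(self, tmp_path, rng):
        matrix = make_matrix(rng.random((4, 3)), [0, 0, 1, 1])
        path = tmp_path / "matrix.arff"
        write_arff(matrix, path)
        text = path.read_text()
        assert text.count("@ATTRIBUTE") == 4  # 3 features + class
        assert text.count("\n") >= 4 + 2 + 4
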