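"""SOM training: PCA hint, initialisation, batch updates, BMU rules."""

import numpy as np
import pytest

from somscape import (
    TrainingMatrix,
    best_matching_unit,
    build_lattice,
    init_codebook,
    map_assignments,
    pca_shape_hint,
    train_som,
)
from somscape.som import Codebook, _bmu_indices, _kernel, batch_update, smoothed_distortion


def _tm(X, prefix="g"):
    X = np.asarray(X, dtype=float)
    return TrainingMatrix(
        X, [f"{prefix}{i}" for i in range(X.shape[0])], [f"c{j}" for j in range(X.shape[1])]
    )


# ------------------------------------------------------------- pca hint
def test_two_blob_cloud_has_two_density_modes():
    rng = np.random.default_rng(1)
    X = np.vstack(
        [rng.normal([5, 0, 0], 1, (200, 3)), rng.normal([-5, 0, 0], 1, (200, 3))]
    )
    hint = pca_shape_hint(_tm(X))
    assert hint.n_modes == 2
    assert hint.scores.shape == (400, 2)
    assert hint.explained_variance_ratio[0] > 0.8


def test_single_blob_has_one_mode():
    rng = np.random.default_rng(1)
    hint = pca_shape_hint(_tm(rng.normal(size=(400, 3))))
    assert hint.n_modes == 1


def test_explained_variance_matches_eigen_oracle():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(5, 4))
    X = np.repeat(base, 40, axis=0) + rng.normal(scale=1e-3, size=(200, 4))
    hint = pca_shape_hint(_tm(X))
    Xc = X - X.mean(0)
    evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (len(X) - 1)))[::-1]
    expected = evals[:2] / evals.sum()
    np.testing.assert_allclose(hint.explained_variance_ratio, expected, atol=1e-10)
    assert hint.explained_variance_ratio.sum() <= 1.0 + 1e-12


def test_constant_matrix_is_zero_variance_error():
    with pytest.raises(ValueError, match="zero variance"):
        pca_shape_hint(_tm(np.ones((10, 3))))


# ------------------------------------------------------- initialisation
def test_linear_init_on_one_node_lattice_is_column_means(small_matrix):
    lat = build_lattice("custom", 1, custom_mask=lambda x, y: x == 0 and y == 0)
    cb = init_codebook(small_matrix, lat, method="linear")
    np.testing.assert_allclose(cb.weights[0], small_matrix.values.mean(0), atol=1e-12)


def test_random_init_deterministic_per_seed(small_matrix):
    lat = build_lattice("sheet", 2)
    a = init_codebook(small_matrix, lat, method="random", seed=5)
    b = init_codebook(small_matrix, lat, method="random", seed=5)
    c = init_codebook(small_matrix, lat, method="random", seed=6)
    assert np.array_equal(a.weights, b.weights)
    assert not np.array_equal(a.weights, c.weights)


def test_linear_init_spans_top_two_components():
    rng = np.random.default_rng(4)
    # exactly rank-2 data
    X = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 5))
    data = _tm(X)
    lat = build_lattice("diamond", 3)
    cb = init_codebook(data, lat, method="linear")
    Xc = X - X.mean(0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    basis = vt[:2]
    centred = cb.weights - X.mean(0)
    residual = centred - (centred @ basis.T) @ basis
    assert np.abs(residual).max() < 1e-9


def test_single_column_falls_back_to_random(small_matrix, caplog):
    lat = build_lattice("sheet", 1)
    one_col = _tm(small_matrix.values[:, :1])
    with caplog.at_level("INFO", logger="somscape.som"):
        cb = init_codebook(one_col, lat, method="linear", seed=1)
    assert cb.weights.shape == (9, 1)
    assert any("falling back" in r.message for r in caplog.records)


# ------------------------------------------------------------- training
def test_identical_rows_collapse_to_that_vector_with_zero_qe():
    v = np.array([1.5, -2.0, 3.0])
    data = _tm(np.tile(v, (20, 1)))
    lat = build_lattice("sheet", 1)
    tm = train_som(data, lat, rough_iters=1, finetune_iters=1, seed=0)
    np.testing.assert_allclose(tm.codebook.weights, np.tile(v, (9, 1)), atol=1e-12)
    assert tm.qe_trace[-1] == pytest.approx(0.0, abs=1e-12)


def test_one_node_lattice_learns_the_column_mean(small_matrix):
    lat = build_lattice("custom", 1, custom_mask=lambda x, y: x == 0 and y == 0)
    tm = train_som(small_matrix, lat, rough_iters=1, finetune_iters=1, seed=0)
    np.testing.assert_allclose(
        tm.codebook.weights[0], small_matrix.values.mean(0), atol=1e-12
    )


def test_training_is_deterministic(small_matrix):
    lat = build_lattice("diamond", 2)
    a = train_som(small_matrix, lat, seed=9)
    b = train_som(small_matrix, lat, seed=9)
    assert np.array_equal(a.codebook.weights, b.codebook.weights)
    assert a.qe_trace == b.qe_trace


def test_qe_never_ends_above_start(small_matrix):
    lat = build_lattice("hexagon", 2)
    tm = train_som(small_matrix, lat, seed=1)
    assert tm.qe_trace[-1] <= tm.qe_trace[0] + 1e-12
    assert len(tm.qe_trace) == 10 + 20 + 1


def test_codebook_rows_exist_only_for_lattice_nodes(small_matrix):
    lat = build_lattice("trefoil", 3)
    tm = train_som(small_matrix, lat, seed=2)
    assert tm.codebook.weights.shape == (lat.n_nodes, 3)


def test_non_finite_data_rejected():
    X = np.ones((5, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError):
        _tm(X)


def test_batch_update_never_increases_smoothed_distortion():
    """One batch step is a descent step on the kernel-smoothed distortion."""
    shapes = ["sheet", "diamond", "hexagon", "triangle", "butterfly", "trefoil", "square"]
    for s in range(20):
        rng = np.random.default_rng(s)
        lat = build_lattice(shapes[s % 7], 2 + s % 3)
        X = rng.normal(size=(50 + s, 3))
        H = _kernel(lat, [0.5, 1.0, 2.0, 4.0][s % 4])
        W = rng.normal(size=(lat.n_nodes, 3))
        bmu = _bmu_indices(W, X)
        before = smoothed_distortion(W, X, H, bmu)
        after = smoothed_distortion(batch_update(W, X, H, bmu), X, H)
        assert after <= before + 1e-9, f"instance {s}"


# ------------------------------------------------------------------ bmu
def test_bmu_basic_and_tie_to_lowest_index():
    cb = Codebook(np.array([[0.0, 0.0], [10.0, 10.0]]), ["a", "b"])
    assert best_matching_unit(cb, np.array([1.0, 1.0])) == 0
    tie = Codebook(np.array([[0.0, 0.0], [2.0, 0.0]]), ["a", "b"])
    assert best_matching_unit(tie, np.array([1.0, 0.0])) == 0
    with pytest.raises(ValueError):
        best_matching_unit(cb, np.array([np.inf, 0.0]))


def test_bmu_matches_exhaustive_scan():
    rng = np.random.default_rng(3)
    W = rng.normal(size=(30, 4))
    cb = Codebook(W, list("abcd"))
    for row in rng.normal(size=(100, 4)):
        expected = int(np.argmin(((W - row) ** 2).sum(1)))
        assert best_matching_unit(cb, row) == expected


def test_map_assignments_counts_and_errors(small_matrix):
    lat = build_lattice("sheet", 2)
    tm = train_som(small_matrix, lat, seed=0)
    hits = map_assignments(tm, small_matrix)
    assert hits.hit_counts.sum() == 30
    assert set(hits.bmu) == set(small_matrix.row_ids)
    wrong = TrainingMatrix(small_matrix.values, small_matrix.row_ids, ["x", "y", "z"])
    with pytest.raises(ValueError):
        map_assignments(tm, wrong)


def test_identical_rows_share_one_bmu():
    data = _tm(np.tile([1.0, 2.0], (15, 1)))
    lat = build_lattice("square", 1)
    tm = train_som(data, lat, rough_iters=1, finetune_iters=1, seed=0)
    hits = map_assignments(tm, data)
    assert len(set(hits.bmu.values())) == 1
    assert hits.hit_counts.max() == 15


def test_three_cluster_modal_bmus_distinct(trefoil_three_group):
    data, labels, tm, hits = trefoil_three_group
    bmus = np.array([hits.bmu[r] for r in data.row_ids])
    modal = [np.bincount(bmus[labels == g]).argmax() for g in range(3)]
    assert len(set(modal)) == 3
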