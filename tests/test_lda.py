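import numpy as np
import pytest

from meglda.lda import (ClusterSet, default_delta, h_delta, lda_directions,
                        project, spread_matrices)


def gaussian_clusters(means, p=200, scale=0.3, seed=0):
    rng = np.random.default_rng(seed)
    mats = [np.asarray(mu)[:, None] + scale * rng.standard_normal(
        (len(mu), p)) for mu in means]
    return ClusterSet(mats, [f"c{i}" for i in range(len(means))])


# ------------------------------------------------------------ spread matrices

def test_repeated_columns_give_zero_within_spread():
    col = np.array([1.0, -2.0, 3.0])
    clusters = ClusterSet([np.tile(col[:, None], 5),
                           np.tile(2 * col[:, None], 7)], ["a", "b"])
    Sw, _ = spread_matrices(clusters)
    assert np.allclose(Sw, 0.0)


def test_equal_cluster_means_give_zero_between_spread():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((4, 30))
    Xc = X - X.mean(axis=1, keepdims=True)
    clusters = ClusterSet([Xc, Xc[:, ::-1]], ["a", "b"])
    _, Sb = spread_matrices(clusters)
    assert np.allclose(Sb, 0.0, atol=1e-10)


def test_scatter_decomposition_oracle():
    """S_w + S_b equals the total scatter of the pooled data."""
    rng = np.random.default_rng(2)
    mats = [rng.standard_normal((5, p)) + mu
            for p, mu in ((11, 0.0), (17, 1.0), (23, -2.0))]
    clusters = ClusterSet(mats, ["a", "b", "c"])
    Sw, Sb = spread_matrices(clusters)
    pooled = np.concatenate(mats, axis=1)
    centered = pooled - pooled.mean(axis=1, keepdims=True)
    total = centered @ centered.T
    assert np.allclose(Sw + Sb, total)
    for S in (Sw, Sb):
        assert np.allclose(S, S.T)
        assert np.all(np.linalg.eigvalsh(S) > -1e-8 * np.abs(S).max())


# ------------------------------------------------------------- eigenproblem

def test_three_clusters_give_two_positive_eigenvalues():
    rng = np.random.default_rng(3)
    means = [10 * rng.standard_normal(10) for _ in range(3)]
    result = lda_directions(gaussian_clusters(means, seed=4))
    assert result.n_directions == 2
    assert result.eigenvalues[0] >= result.eigenvalues[1] > 0


def test_identical_clusters_give_zero_directions():
    X = np.random.default_rng(5).standard_normal((4, 40))
    result = lda_directions(ClusterSet([X, X.copy()], ["a", "b"]))
    assert result.n_directions == 0


def test_leading_direction_matches_angular_grid_oracle():
    """In 2-D the maximizer of H_δ is found by a dense angle scan."""
    clusters = gaussian_clusters([[0.0, 0.0], [2.0, 1.0]], p=300, seed=6)
    delta = 1e-3
    result = lda_directions(clusters, delta)
    Sw, Sb = spread_matrices(clusters)

    angles = np.linspace(0.0, np.pi, 3600, endpoint=False)
    ratios = [h_delta(np.array([np.cos(a), np.sin(a)]), Sw, Sb, delta)
              for a in angles]
    best = angles[int(np.argmax(ratios))]
    q = result.directions[:, 0]
    got = np.arctan2(q[1], q[0]) % np.pi
    diff = abs(got - best)
    diff = min(diff, np.pi - diff)
    assert np.degrees(diff) < 1.0


def test_eigenvalue_equals_ratio_at_eigenvector():
    clusters = gaussian_clusters(
        [[0, 0, 0, 1.0], [3, 0, 1, 0.0], [0, 2, 0, 0.0]], p=150, seed=7)
    result = lda_directions(clusters)
    Sw, Sb = spread_matrices(clusters)
    for j in range(result.n_directions):
        ratio = h_delta(result.directions[:, j], Sw, Sb, result.delta)
        assert np.isclose(ratio, result.eigenvalues[j], rtol=1e-8)


def test_leading_direction_beats_random_unit_vectors():
    clusters = gaussian_clusters([[0, 0, 0], [1, 2, 0], [0, 1, 2]],
                                 p=100, seed=8)
    result = lda_directions(clusters)
    Sw, Sb = spread_matrices(clusters)
    best = h_delta(result.directions[:, 0], Sw, Sb, result.delta)
    rng = np.random.default_rng(9)
    qs = rng.standard_normal((1000, 3))
    qs /= np.linalg.norm(qs, axis=1, keepdims=True)
    rand = max(h_delta(q, Sw, Sb, result.delta) for q in qs)
    assert best >= rand


def test_scale_equivariance_with_matched_delta():
    """Scaling data by c and δ by c² leaves the directions unchanged."""
    clusters = gaussian_clusters([[0, 0, 1.0], [2, 1, 0.0]], p=120, seed=10)
    c = 13.7
    scaled = ClusterSet([c * X for X in clusters.matrices], clusters.labels)
    delta = 1e-4
    a = lda_directions(clusters, delta)
    b = lda_directions(scaled, c ** 2 * delta)
    assert np.allclose(a.directions, b.directions, atol=1e-10)
    assert np.allclose(b.eigenvalues, a.eigenvalues, rtol=1e-10)


def test_rank_bound_on_positive_eigenvalues():
    rng = np.random.default_rng(11)
    for trial in range(20):
        k = int(rng.integers(2, 5))
        n = int(rng.integers(3, 8))
        means = [rng.standard_normal(n) for _ in range(k)]
        clusters = gaussian_clusters(means, p=40, seed=100 + trial)
        result = lda_directions(clusters)
        _, Sb = spread_matrices(clusters)
        rank_sb = np.linalg.matrix_rank(Sb, tol=1e-8 * np.abs(Sb).max())
        assert result.n_directions <= min(k - 1, rank_sb)


def test_directions_unit_norm_and_sign_fixed():
    result = lda_directions(gaussian_clusters(
        [[0, 0, 0], [2, -1, 0], [0, 1, -2]], p=80, seed=12))
    for j in range(result.n_directions):
        q = result.directions[:, j]
        assert np.isclose(np.linalg.norm(q), 1.0)
        assert q[np.argmax(np.abs(q))] > 0


def test_default_delta_follows_trace():
    Sw = np.diag([1.0, 3.0])
    assert np.isclose(default_delta(Sw), 1e-6 * 4.0 / 2)


def test_two_cluster_direction_agrees_with_sklearn():
    """Independent cross-check: sklearn's eigen-solver LDA direction."""
    sklearn = pytest.importorskip("sklearn.discriminant_analysis")
    clusters = gaussian_clusters([[0, 0, 0.5], [1.5, 1.0, 0.0]],
                                 p=400, seed=13)
    result = lda_directions(clusters, delta=0.0)
    X = np.concatenate(clusters.matrices, axis=1).T
    y = np.repeat([0, 1], [400, 400])
    sk = sklearn.LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
    v = sk.scalings_[:, 0] / np.linalg.norm(sk.scalings_[:, 0])
    q = result.directions[:, 0]
    assert min(np.linalg.norm(q - v), np.linalg.norm(q + v)) < 1e-6


# ------------------------------------------------------------------- project

def test_projection_on_canonical_axes_extracts_rows():
    rng = np.random.default_rng(14)
    X = rng.standard_normal((5, 9))
    clusters = ClusterSet([X, X + 1.0], ["a", "b"])
    # hand-built result with canonical directions

    class Stub:
        directions = np.eye(5)[:, :2]

    with pytest.raises(ValueError):
        project(ClusterSet([X[:3], X[:3]], ["a", "b"]), Stub)
    Z = project(clusters, Stub)[0]
    assert np.array_equal(Z, X[:2])


def test_projection_matches_dot_product_loop():
    clusters = gaussian_clusters([[0, 0, 0], [1, 1, 0]], p=30, seed=15)
    result = lda_directions(clusters)
    Z = project(clusters, result)
    for j, X in enumerate(clusters.matrices):
        expected = np.empty((result.n_directions, X.shape[1]))
        for d in range(result.n_directions):
            for ell in range(X.shape[1]):
                expected[d, ell] = float(result.directions[:, d] @ X[:, ell])
        assert np.allclose(Z[j], expected)
        assert np.allclose(result.projections[j], expected)


def test_projection_bounded_by_cauchy_schwarz():
    x = np.array([[3.0], [4.0]])
    clusters = ClusterSet([x, -x], ["a", "b"])
    result = lda_directions(clusters)
    for Z in project(clusters, result):
        assert np.all(np.abs(Z) <= np.linalg.norm(x) + 1e-12)
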