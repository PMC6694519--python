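import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permdisp

from actampl.beta import NMDS, beta_dispersion, bray_curtis, nmds
from actampl.tables import ValidationError


class TestBrayCurtis:
    def test_identity_and_symmetry(self):
        x = np.array([[6, 2], [4, 8]], dtype=float)
        d = bray_curtis(x).data
        assert d[0, 0] == 0 and d[1, 1] == 0
        assert d[0, 1] == d[1, 0]

    def test_disjoint_supports_give_one(self):
        x = np.array([[5, 0], [0, 7]], dtype=float)
        assert bray_curtis(x).data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=(6,4), y=(2,8): sum|x-y| / sum(x+y) = 8/20
        x = np.array([[6, 2], [4, 8]], dtype=float)
        assert bray_curtis(x).data[0, 1] == pytest.approx(0.4)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.array([[1, 0], [2, 0]], dtype=float))

    def test_proportion_invariance(self):
        """On proportions, jointly rescaling raw abundances changes nothing."""
        rng = np.random.default_rng(0)
        x = rng.integers(1, 50, size=(6, 4)).astype(float)
        p = x / x.sum(axis=0)
        scaled = x * rng.uniform(0.5, 3.0, size=4)  # per-sample depth change
        p2 = scaled / scaled.sum(axis=0)
        np.testing.assert_allclose(bray_curtis(p).data, bray_curtis(p2).data)


def _pava_increasing(y):
    """Hand-rolled pool-adjacent-violators (test oracle, independent of
    sklearn's isotonic regression)."""
    y = list(map(float, y))
    blocks = [[v, 1] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]) / (
                blocks[i][1] + blocks[i + 1][1]
            )
            blocks[i] = [v, blocks[i][1] + blocks[i + 1][1]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for v, w in blocks:
        out.extend([v] * w)
    return np.array(out)


def _oracle_stress1(coords, dissim):
    d = pdist(coords)
    order = np.lexsort((d, dissim))
    dhat = _pava_increasing(d[order])
    return np.sqrt(((d[order] - dhat) ** 2).sum() / (d**2).sum())


def _oracle_min_stress(dissim, n_grid=7, seed=0):
    """Brute-force grid search over 4-point planar configurations (p0 at the
    origin, p1 on the positive x-axis; stress-1 is scale- and
    rotation-invariant), refined locally from the best grid point."""
    grid = np.linspace(-1.0, 1.0, n_grid)
    best, best_cfg = np.inf, None
    for x1 in np.linspace(0.1, 1.0, 4):
        for x2 in grid:
            for y2 in grid:
                for x3 in grid:
                    for y3 in grid:
                        cfg = np.array([[0, 0], [x1, 0], [x2, y2], [x3, y3]])
                        s = _oracle_stress1(cfg, dissim)
                        if s < best:
                            best, best_cfg = s, cfg
    res = minimize(
        lambda f: _oracle_stress1(f.reshape(4, 2), dissim) ** 2,
        best_cfg.ravel(),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-14},
    )
    return min(best, np.sqrt(max(res.fun, 0.0)))


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = nmds(d, k=2, restarts=5, seed=0)
        assert res.stress < 1e-6
        assert res.converged

    def test_collinear_points_embed_exactly(self):
        pts = np.arange(4.0)
        d = np.abs(pts[:, None] - pts[None, :])
        res = nmds(d, k=2, restarts=5, seed=0)
        assert res.stress < 1e-6

    def test_matches_brute_force_oracle_on_small_instances(self):
        """Bray-Curtis of random 2-taxon samples, n=4 subsets."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            counts = rng.integers(1, 40, size=(2, 4)).astype(float)
            dm = bray_curtis(counts / counts.sum(axis=0))
            res = nmds(dm, k=2, restarts=10, seed=trial)
            oracle = _oracle_min_stress(squareform(dm.data), seed=trial)
            assert res.stress <= oracle + 1e-3

    def test_stress_not_worse_than_metric_start(self):
        rng = np.random.default_rng(3)
        x = rng.random(size=(8, 5))
        d = squareform(pdist(x))
        from actampl.beta import _pcoa_coords, _stress1_squared

        start = np.sqrt(_stress1_squared(_pcoa_coords(d, 2), squareform(d)))
        res = nmds(d, k=2, restarts=5, seed=0)
        assert res.stress <= start + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            NMDS(n_components=2).fit(np.zeros((2, 2)))

    def test_estimator_protocol(self):
        d = np.ones((4, 4)) - np.eye(4)
        est = NMDS(n_components=2, n_restarts=3, random_state=0)
        emb = est.fit_transform(d)
        assert emb.shape == (4, 2)
        assert est.get_params()["n_restarts"] == 3
        assert hasattr(est, "stress_") and hasattr(est, "converged_")


class TestBetaDispersion:
    def test_mirror_image_clouds_are_null(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(6, 2))
        pts = np.vstack([cloud, -cloud])
        d = squareform(pdist(pts))
        res = beta_dispersion(d, ["a"] * 6 + ["b"] * 6, n_permutations=199, seed=1)
        assert res.F == pytest.approx(0.0, abs=1e-8)
        assert res.p_perm == pytest.approx(1.0)

    def test_scaled_cloud_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            a = rng.normal(size=(9, 3))
            b = 3 * rng.normal(size=(9, 3))
            d = squareform(pdist(np.vstack([a, b])))
            res = beta_dispersion(d, ["a"] * 9 + ["b"] * 9, n_permutations=199, seed=s)
            hits += res.p_perm < 0.05
        assert hits >= 19  # >= 95% of seeded replicates

    def test_matches_skbio_permdisp_f(self):
        """Independent cross-check of the dispersion F statistic."""
        rng = np.random.default_rng(4)
        pts = rng.random(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        grouping = ["a"] * 5 + ["b"] * 5
        ours = beta_dispersion(dm, grouping, n_permutations=99, seed=0)
        theirs = permdisp(dm, grouping, test="centroid", permutations=99)
        assert ours.F == pytest.approx(float(theirs["test statistic"]), rel=1e-6)

    def test_group_of_one_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError):
            beta_dispersion(d, ["a", "a", "b"], n_permutations=9)

    def test_negative_eigenvalue_axes_handled(self):
        # Bray-Curtis matrices are generally non-Euclidean; distances must
        # still be real and non-negative
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, size=(12, 8)).astype(float) + 0.01
        dm = bray_curtis(counts)
        res = beta_dispersion(dm.data, ["a"] * 4 + ["b"] * 4, n_permutations=49, seed=0)
        assert np.isfinite(res.distances).all()
        assert (res.distances >= 0).all()
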