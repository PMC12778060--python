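import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from fractalmorph.space import (
    ComplexityDataset,
    assemble,
    generalized_variance,
    isomap_embed,
    kde_map,
    posture_sensitivity,
    rgv_disparity,
)


def _table(n=6, singular_idx=()):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        rows.append(
            dict(
                id=f"s{i}", group="a" if i % 2 else "b",
                D_SI=rng.uniform(1, 2), sd_D_SI=0.01,
                D_SK=rng.uniform(1, 2), sd_D_SK=0.01,
                L_SI=rng.uniform(0, 2), sd_L_SI=0.01,
                L_SK=rng.uniform(0, 1), sd_L_SK=0.01,
                singular=i in singular_idx,
            )
        )
    return pd.DataFrame(rows)


class TestAssemble:
    def test_drops_singular_rows(self):
        ds = assemble(_table(5, singular_idx=(2,)))
        assert len(ds) == 4

    def test_zscored_columns(self):
        ds = assemble(_table(20), standardize=True)
        assert np.allclose(ds.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(ds.X.std(axis=0), 1.0, atol=1e-9)

    def test_raw_passthrough(self):
        t = _table(5)
        ds = assemble(t, standardize=False)
        assert np.allclose(ds.X[:, 0], t["D_SI"])

    def test_all_singular_rejected(self):
        with pytest.raises(ValueError):
            assemble(_table(3, singular_idx=(0, 1, 2)))


class TestIsomap:
    def test_full_graph_equals_classical_scaling(self, rng):
        X = rng.normal(size=(40, 4))
        emb = isomap_embed(X, k=39)
        D = squareform(pdist(X))
        n = len(X)
        J = np.eye(n) - 1.0 / n
        B = -0.5 * J @ (D**2) @ J
        ev, evec = np.linalg.eigh(B)
        idx = np.argsort(ev)[::-1][:2]
        oracle = evec[:, idx] * np.sqrt(np.clip(ev[idx], 0, None))
        assert np.allclose(
            squareform(pdist(emb.coords)), squareform(pdist(oracle)), atol=1e-8
        )

    def test_flat_manifold_distances_preserved(self, rng):
        # points on a 2-D plane linearly embedded in 4-D
        basis = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        Z = rng.uniform(-1, 1, size=(35, 2))
        X = Z @ basis.T
        emb = isomap_embed(X, k=34)
        d0 = pdist(X)
        d1 = pdist(emb.coords)
        assert np.allclose(d0, d1, rtol=0.01, atol=1e-9)

    def test_disconnected_graph_reports_components(self, rng):
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(7, 4)) + 1000.0
        X = np.vstack([a, b])
        with pytest.raises(ValueError, match=r"\[10, 7\]"):
            isomap_embed(X, k=3)
        emb = isomap_embed(X, k=3, largest_component=True)
        assert len(emb.coords) == 10
        assert emb.n_components_graph == 2


class TestKde:
    def test_single_point_peak_location(self):
        g = kde_map(np.array([[0.3, -0.2]]), radius=0.15, grid=101,
                    bounds=(-1, 1, -1, 1))
        i, j = np.unravel_index(np.argmax(g.values), g.values.shape)
        xc = (g.x_edges[i] + g.x_edges[i + 1]) / 2
        yc = (g.y_edges[j] + g.y_edges[j + 1]) / 2
        assert abs(xc - 0.3) < 0.02 and abs(yc + 0.2) < 0.02

    def test_additivity_of_identical_points(self):
        one = kde_map(np.array([[0.0, 0.0]]), grid=50, bounds=(-1, 1, -1, 1))
        two = kde_map(np.array([[0.0, 0.0], [0.0, 0.0]]), grid=50,
                      bounds=(-1, 1, -1, 1))
        assert np.allclose(two.values, 2 * one.values)
        assert np.all(two.values >= 0)

    def test_integral_equals_point_count(self, rng):
        pts = rng.uniform(-0.5, 0.5, size=(7, 2))
        g = kde_map(pts, radius=0.15, grid=200, bounds=(-2, 2, -2, 2))
        cell = (g.x_edges[1] - g.x_edges[0]) * (g.y_edges[1] - g.y_edges[0])
        assert g.values.sum() * cell == pytest.approx(7.0, rel=0.02)


class TestGeneralizedVariance:
    def test_identity_covariance(self, rng):
        X = rng.normal(size=(20000, 4))
        assert generalized_variance(X) == pytest.approx(1.0, rel=0.1)

    def test_diagonal_case(self, rng):
        X = rng.normal(size=(20000, 2)) * np.array([2.0, 1.0])
        assert generalized_variance(X) == pytest.approx(4.0, rel=0.1)

    def test_collinear_rows_are_degenerate(self):
        X = np.outer(np.arange(10.0), np.ones(3))
        assert generalized_variance(X) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cofactor_expansion(self, rng):
        def det4(M):
            # brute-force cofactor expansion along the first row
            if M.shape == (1, 1):
                return M[0, 0]
            total = 0.0
            for j in range(M.shape[1]):
                minor = np.delete(np.delete(M, 0, axis=0), j, axis=1)
                total += (-1) ** j * M[0, j] * det4(minor)
            return total

        for _ in range(5):
            X = rng.normal(size=(30, 4)) @ rng.normal(size=(4, 4))
            C = np.cov(X, rowvar=False, ddof=1)
            assert generalized_variance(X) == pytest.approx(
                det4(C), rel=1e-9, abs=1e-12
            )

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            generalized_variance(np.zeros((4, 4)))


def _dataset(A, B):
    X = np.vstack([A, B])
    groups = np.array(["A"] * len(A) + ["B"] * len(B))
    return ComplexityDataset(
        X=X, ids=[str(i) for i in range(len(X))], groups=groups, standardized=False
    )


class TestDisparity:
    def test_seeded_runs_identical(self, rng):
        ds = _dataset(rng.normal(size=(120, 4)), rng.normal(size=(120, 4)) * 2)
        r1 = rgv_disparity(ds, n_rarefy=30, n_boot=50, seed=9)
        r2 = rgv_disparity(ds, n_rarefy=30, n_boot=50, seed=9)
        assert r1.summary.equals(r2.summary)
        for g in r1.groups:
            assert np.array_equal(r1.ratios[g], r2.ratios[g])

    def test_denominator_is_largest_group(self, rng):
        ds = _dataset(rng.normal(size=(100, 4)), rng.normal(size=(100, 4)) * 3)
        res = rgv_disparity(ds, n_rarefy=40, n_boot=50, seed=0)
        assert res.denominator_group == "B"
        assert np.all(res.ratios["B"] == 1.0)

    def test_isotropic_shrink_scales_as_c_pow_dims(self, rng):
        A = rng.normal(size=(400, 4))
        c = 0.1
        res = rgv_disparity(_dataset(A, A * c), n_rarefy=50, n_boot=300, seed=4)
        mean_b = res.summary.set_index("group").loc["B", "ratio_mean"]
        # c^dims with dims=4, within half an order of magnitude
        assert 10**-4.5 < mean_b < 10**-3.5

    def test_small_group_rarefied_to_own_size(self, rng):
        ds = _dataset(rng.normal(size=(100, 4)), rng.normal(size=(20, 4)))
        res = rgv_disparity(ds, n_rarefy=50, n_boot=20, seed=1)
        assert np.isfinite(res.summary["ratio_mean"]).all()

    def test_tiny_group_rejected(self, rng):
        ds = _dataset(rng.normal(size=(100, 4)), rng.normal(size=(4, 4)))
        with pytest.raises(ValueError):
            rgv_disparity(ds, n_rarefy=50, n_boot=10, seed=1)


def test_posture_sensitivity_of_identical_copies(std_line):
    out = posture_sensitivity([std_line, std_line, std_line])
    for key in ("two_sigma_D_SI", "two_sigma_D_SK", "two_sigma_L_SI", "two_sigma_L_SK"):
        assert out[key] == pytest.approx(0.0, abs=1e-12)
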