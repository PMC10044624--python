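import numpy as np
import pandas as pd
import pytest

from gwlct.core import (
    CovariancePair,
    DegenerateSupportError,
    global_lct,
    local_statistic,
    max_linear_combination,
    permutation_pvalue,
    run_gwlct,
    weighted_moments,
    weighted_shrunken_cov,
)
from gwlct.datasets import GeneSetCollection, SpatialExpressionDataset
from gwlct.weights import KernelSpec

from conftest import make_dataset


def naive_weighted_cov(X, y, w):
    """Brute-force double-loop weighted covariance (independent oracle).

    Weights renormalized to sum to the positive-weight cell count m,
    cross-products divided by m - 1.
    """
    keep = np.flatnonzero(w > 0)
    m = keep.size
    wt = w[keep] * m / w[keep].sum()
    xb = np.array([sum(wt[a] * X[i, keep[a]] for a in range(m)) / m for i in range(X.shape[0])])
    yb = sum(wt[a] * y[keep[a]] for a in range(m)) / m
    g = X.shape[0]
    S = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            S[i, j] = sum(
                wt[a] * (X[i, keep[a]] - xb[i]) * (X[j, keep[a]] - xb[j])
                for a in range(m)
            ) / (m - 1)
    sxy = np.array(
        [
            sum(wt[a] * (X[i, keep[a]] - xb[i]) * (y[keep[a]] - yb) for a in range(m))
            / (m - 1)
            for i in range(g)
        ]
    )
    syy = sum(wt[a] * (y[keep[a]] - yb) ** 2 for a in range(m)) / (m - 1)
    return S, sxy, syy


def grid_search_rho(X, y, w, n_points=3600):
    """Maximal weighted correlation over a dense grid of unit directions (g=2)."""
    theta = np.linspace(0, np.pi, n_points, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    Z = dirs @ X  # (P, n)
    keep = w > 0
    wn = w[keep] / w[keep].sum()
    Zk, yk = Z[:, keep], y[keep]
    zbar = Zk @ wn
    ybar = yk @ wn
    Zc = Zk - zbar[:, None]
    yc = yk - ybar
    num = (Zc * wn) @ yc
    den = np.sqrt(((Zc**2) @ wn) * np.sum(wn * yc**2))
    r = np.abs(num) / np.where(den > 0, den, np.inf)
    return float(r.max())


class TestWeightedMoments:
    def test_uniform_weights_reduce_to_sample_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        mean, var = weighted_moments(x, np.ones(40))
        assert mean == pytest.approx(x.mean())
        assert var == pytest.approx(x.var(ddof=1))

    def test_zero_weight_drops_cells(self):
        mean, var = weighted_moments(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 0.0])
        )
        assert mean == pytest.approx(1.5)
        assert var == pytest.approx(0.5)

    def test_point_mass_is_degenerate(self):
        with pytest.raises(DegenerateSupportError):
            weighted_moments(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


class TestShrunkenCovariance:
    def test_full_shrinkage_is_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 30))
        y = rng.normal(size=30)
        cov = weighted_shrunken_cov(X, y, np.ones(30), shrinkage=1.0)
        off = cov.scov_xx - np.diag(np.diag(cov.scov_xx))
        assert np.allclose(off, 0.0)

    def test_no_shrinkage_uniform_weights_is_sample_cov(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 25))
        y = rng.normal(size=25)
        cov = weighted_shrunken_cov(X, y, np.ones(25), shrinkage=0.0)
        np.testing.assert_allclose(cov.scov_xx, np.cov(X), atol=1e-12)
        np.testing.assert_allclose(
            cov.scov_xy, [np.cov(X[i], y)[0, 1] for i in range(4)], atol=1e-12
        )
        assert cov.scov_yy == pytest.approx(np.var(y, ddof=1))

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2, 5))
        y = rng.normal(size=5)
        w = np.array([0.3, 1.0, 0.0, 0.7, 0.25])
        cov = weighted_shrunken_cov(X, y, w, shrinkage=0.0)
        S, sxy, syy = naive_weighted_cov(X, y, w)
        np.testing.assert_allclose(cov.scov_xx, S, atol=1e-10)
        np.testing.assert_allclose(cov.scov_xy, sxy, atol=1e-10)
        assert cov.scov_yy == pytest.approx(syy, abs=1e-10)

    def test_estimated_intensity_within_unit_interval(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 12))
        y = rng.normal(size=12)
        w = rng.uniform(0.1, 1.0, size=12)
        cov = weighted_shrunken_cov(X, y, w)
        assert 0.0 <= cov.shrinkage_intensity <= 1.0

    def test_collinear_genes_still_positive_definite(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        X = np.vstack([base, base, rng.normal(size=20)])
        y = rng.normal(size=20)
        cov = weighted_shrunken_cov(X, y, np.ones(20))
        assert np.linalg.eigvalsh(cov.scov_xx).min() > 0

    def test_constant_gene_gets_variance_floor(self):
        X = np.vstack([np.full(10, 2.0), np.arange(10.0)])
        y = np.arange(10.0)
        cov = weighted_shrunken_cov(X, y, np.ones(10))
        assert cov.scov_xx[0, 0] > 0
        assert np.linalg.eigvalsh(cov.scov_xx).min() > 0


class TestMaxLinearCombination:
    def test_single_gene_set(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        cov = weighted_shrunken_cov(x[None, :], y, np.ones(50), shrinkage=0.0)
        model = max_linear_combination(cov)
        np.testing.assert_allclose(model.beta_star, [1.0])
        assert model.rho == pytest.approx(abs(np.corrcoef(x, y)[0, 1]))

    def test_single_informative_gene_under_diagonal_cov(self):
        cov = CovariancePair(
            scov_xx=np.diag([2.0, 1.0, 3.0]),
            scov_xy=np.array([0.8, 0.0, 0.0]),
            scov_yy=1.5,
            shrinkage_intensity=0.0,
        )
        model = max_linear_combination(cov)
        np.testing.assert_allclose(model.beta_star, [1.0, 0.0, 0.0], atol=1e-12)

    def test_sign_convention_first_nonzero_positive(self):
        cov = CovariancePair(
            scov_xx=np.eye(2),
            scov_xy=np.array([-0.5, -0.1]),
            scov_yy=1.0,
            shrinkage_intensity=0.0,
        )
        beta = max_linear_combination(cov).beta_star
        assert beta[0] > 0
        assert np.linalg.norm(beta) == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 30))
            X = rng.normal(size=(2, n))
            y = rng.normal(size=n) + rng.normal() * X[0]
            w = rng.uniform(0.05, 1.0, size=n)
            cov = weighted_shrunken_cov(X, y, w, shrinkage=0.0)
            rho = max_linear_combination(cov).rho
            assert rho == pytest.approx(grid_search_rho(X, y, w), abs=1e-3)


class TestLocalStatistic:
    def test_perfect_association_single_gene(self):
        ds = make_dataset(n_cells=25, n_genes=3, seed=8)
        ds.phenotype = ds.expression[0].copy()
        for center in (0, 7, 24):
            model = local_statistic(ds, ["g0"], center, KernelSpec("bisquare", "fixed", 50.0))
            assert model.rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_phenotype_gives_smaller_rho_than_spiked(self):
        rho_null, rho_alt = [], []
        for seed in range(10):
            ds_null = make_dataset(n_cells=60, n_genes=3, seed=seed)
            ds_alt = make_dataset(n_cells=60, n_genes=3, seed=seed, signal_gene=1)
            spec = KernelSpec("bisquare", "fixed", 100.0)
            rho_null.append(local_statistic(ds_null, ["g0", "g1", "g2"], 5, spec).rho)
            rho_alt.append(local_statistic(ds_alt, ["g0", "g1", "g2"], 5, spec).rho)
        assert np.median(rho_null) < np.median(rho_alt)

    def test_missing_genes_dropped(self):
        ds = make_dataset(n_cells=20, n_genes=3, seed=9)
        m1 = local_statistic(ds, ["g0", "g1"], 0, KernelSpec("bisquare", "fixed", 50.0))
        m2 = local_statistic(
            ds, ["g0", "g1", "NOT_A_GENE"], 0, KernelSpec("bisquare", "fixed", 50.0)
        )
        np.testing.assert_allclose(m1.beta_star, m2.beta_star)


class TestPermutationPvalue:
    def test_extreme_statistic_attains_floor(self):
        ds = make_dataset(n_cells=30, n_genes=3, seed=10)
        ds.phenotype = ds.expression[0].copy()
        res = permutation_pvalue(
            ds, ["g0"], 4, KernelSpec("bisquare", "fixed", 100.0), B=499, seed=1
        )
        assert res.p_value == pytest.approx(1 / 500)
        assert res.rho == pytest.approx(1.0, abs=1e-9)

    def test_resolution_and_range(self):
        ds = make_dataset(n_cells=20, n_genes=3, seed=11)
        res = permutation_pvalue(
            ds, ["g0", "g1"], 2, KernelSpec("bisquare", "fixed", 50.0), B=49, seed=2
        )
        assert 0 < res.p_value <= 1
        assert (res.p_value * 50) == pytest.approx(round(res.p_value * 50))

    def test_invalid_permutation_count(self):
        ds = make_dataset(n_cells=10, n_genes=2, seed=12)
        with pytest.raises(ValueError):
            permutation_pvalue(ds, ["g0"], 0, KernelSpec("bisquare", "fixed", 50.0), B=0)

    def test_matches_exhaustive_relabeling_on_four_cells(self):
        from itertools import permutations as iperm

        ds = make_dataset(n_cells=4, n_genes=2, seed=13)
        rho_obs, p_mc = global_lct(ds, ["g0", "g1"], B=2000, seed=5)

        def stat(y):
            d2 = SpatialExpressionDataset(
                expression=ds.expression,
                gene_ids=ds.gene_ids,
                coords=ds.coords,
                phenotype=y,
            )
            r, _ = global_lct(d2, ["g0", "g1"], B=1, seed=0)
            return r

        rhos = [stat(ds.phenotype[list(p)]) for p in iperm(range(4))]
        p_exact = np.mean([r >= rho_obs - 1e-12 for r in rhos])
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(p_mc - p_exact) <= 2 * se + 1e-9


class TestRunGwlct:
    def test_cardinality_one_set_ten_locations(self):
        ds = make_dataset(n_genes=3, seed=14, side=4)
        ds = SpatialExpressionDataset(
            expression=ds.expression[:, :10],
            gene_ids=ds.gene_ids,
            coords=ds.coords[:10],
            phenotype=ds.phenotype[:10],
        )
        res = run_gwlct(
            ds,
            GeneSetCollection({"s": ["g0", "g1"]}),
            KernelSpec("bisquare", "fixed", 50.0),
            B=19,
            seed=0,
        )
        assert len(res) == 10
        assert set(res["gene_set"]) == {"s"}

    def test_determinism_same_seed(self, two_sets):
        ds = make_dataset(n_cells=20, n_genes=5, seed=15)
        spec = KernelSpec("bisquare", "adaptive", 8)
        a = run_gwlct(ds, two_sets, spec, B=29, seed=7)
        b = run_gwlct(ds, two_sets, spec, B=29, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_pvalues(self, two_sets):
        ds = make_dataset(n_cells=20, n_genes=5, seed=16)
        spec = KernelSpec("bisquare", "adaptive", 8)
        a = run_gwlct(ds, two_sets, spec, B=199, seed=1)
        b = run_gwlct(ds, two_sets, spec, B=199, seed=2)
        assert not np.array_equal(a["p_value"], b["p_value"])
        np.testing.assert_allclose(a["rho"], b["rho"])  # observed stat seed-free

    def test_degenerate_location_flagged_not_fatal(self):
        # location 0 is isolated: no other cell within the 0.5 bandwidth
        coords = np.array([[0.0, 0], [50.1, 0], [50, 50], [50.1, 50], [50, 50.1]])
        rng = np.random.default_rng(17)
        ds = SpatialExpressionDataset(
            expression=rng.normal(size=(2, 5)),
            gene_ids=np.array(["g0", "g1"], dtype=object),
            coords=coords,
            phenotype=rng.normal(size=5),
        )
        res = run_gwlct(
            ds,
            GeneSetCollection({"s": ["g0", "g1"]}),
            KernelSpec("bisquare", "fixed", 0.5),
            B=9,
            seed=0,
        )
        assert (res["flag"] == "degenerate").sum() >= 1
        assert res.loc[res["flag"] == "degenerate", "p_value"].isna().all()
        assert (res["flag"] == "ok").sum() >= 1

    def test_bh_adjustment_column(self, two_sets):
        ds = make_dataset(n_cells=15, n_genes=5, seed=18)
        res = run_gwlct(
            ds, two_sets, KernelSpec("bisquare", "fixed", 50.0), B=19, seed=0, adjust="bh"
        )
        assert "p_adjusted" in res
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()


class TestGlobalLCT:
    def test_perfect_association_floor_pvalue(self):
        ds = make_dataset(n_cells=40, n_genes=3, seed=19)
        ds.phenotype = ds.expression[0].copy()
        rho, p = global_lct(ds, ["g0"], B=499, seed=3)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(0.002)

    def test_equals_local_statistic_at_infinite_bandwidth(self):
        ds = make_dataset(n_cells=30, n_genes=4, seed=20, signal_gene=2)
        genes = ["g0", "g1", "g2", "g3"]
        rho_g, _ = global_lct(ds, genes, B=1, seed=0)
        h = 1e4 * ds.diameter()
        for center in (0, 13, 29):
            model = local_statistic(ds, genes, center, KernelSpec("bisquare", "fixed", h))
            assert model.rho == pytest.approx(rho_g, abs=1e-6)

    def test_rho_invariant_to_affine_rescaling(self):
        ds = make_dataset(n_cells=30, n_genes=3, seed=21, signal_gene=0)
        genes = ["g0", "g1", "g2"]
        rho1, _ = global_lct(ds, genes, B=1, seed=0)
        ds2 = SpatialExpressionDataset(
            expression=ds.expression * np.array([[2.0], [0.5], [7.0]]) + np.array([[1.0], [-3.0], [0.0]]),
            gene_ids=ds.gene_ids,
            coords=ds.coords,
            phenotype=3.0 * ds.phenotype - 11.0,
        )
        rho2, _ = global_lct(ds2, genes, B=1, seed=0)
        assert rho1 == pytest.approx(rho2, abs=1e-9)
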