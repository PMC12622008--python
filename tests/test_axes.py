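"""Tests of gradient convolution, weighted KDE, region rules, and marker tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.stats import spearmanr

from tlsniche.axes import (
    assign_tbp,
    categorize_imaging,
    convolve_along_axis,
    normalize_expression,
    region_mean_expression,
    weighted_kde_2d,
    zone_marker_test,
)


def _expr(n, genes=("g1", "g2"), fill=None, seed=0):
    rng = np.random.default_rng(seed)
    data = fill if fill is not None else rng.poisson(5, size=(n, len(genes)))
    return pd.DataFrame(
        np.asarray(data, dtype=float),
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        columns=list(genes),
    )


class TestConvolve:
    def test_constant_expression_gives_constant_profile(self):
        expr = _expr(40, fill=np.full((40, 2), 3.0))
        axis = pd.Series(np.linspace(0, 400, 40), index=expr.index)
        prof = convolve_along_axis(expr, axis, window=7)
        assert np.allclose(prof.profile.to_numpy(), 3.0)

    def test_window_one_is_identity(self):
        expr = _expr(30, seed=2)
        axis = pd.Series(np.linspace(0, 100, 30), index=expr.index)
        prof = convolve_along_axis(expr, axis, window=1)
        ordered = expr.loc[prof.cell_ids]
        assert np.allclose(prof.profile.to_numpy(), ordered.to_numpy())

    def test_shift_equivariance(self):
        expr = _expr(50, seed=3)
        axis = pd.Series(np.linspace(0, 440, 50), index=expr.index)
        base = convolve_along_axis(expr, axis, window=9)
        shifted = convolve_along_axis(expr + 11.0, axis, window=9)
        assert np.allclose(shifted.profile.to_numpy(),
                           base.profile.to_numpy() + 11.0)

    def test_distance_cut_and_tie_break(self):
        expr = _expr(4)
        axis = pd.Series([500.0, 10.0, 10.0, 460.0], index=expr.index)
        prof = convolve_along_axis(expr, axis, window=1, max_dist=450.0)
        assert list(prof.cell_ids) == ["c1", "c2"]  # ties break by cell id

    def test_no_cells_in_range_fails(self):
        expr = _expr(3)
        axis = pd.Series([500.0, 600.0, 700.0], index=expr.index)
        with pytest.raises(ValueError, match="no cells"):
            convolve_along_axis(expr, axis)

    def test_gradient_profile_monotone_on_synthetic_tissue(self, recovery_tissue):
        _, (cells, expr, truth) = recovery_tissue
        cd4 = cells["cell_type"].str.startswith("CD4")
        norm = normalize_expression(expr)
        prof = convolve_along_axis(
            norm.loc[cells.index[cd4]], truth.d_tls_true[cd4], window=50
        )
        rho = spearmanr(
            np.arange(len(prof.profile)), prof.profile["Tcf7"]
        ).statistic
        assert rho <= -0.9


class TestWeightedKDE:
    def test_point_mass_mode_at_the_weighted_cell(self):
        n = 30
        rng = np.random.default_rng(4)
        d_tls = pd.Series(rng.uniform(0, 400, n))
        d_bronchi = pd.Series(rng.uniform(0, 400, n))
        w = pd.Series(np.zeros(n))
        w.iloc[7] = 5.0
        gx, gy, dens = weighted_kde_2d(d_tls, d_bronchi, w, bandwidth=20.0)
        iy, ix = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(gx[ix] - d_tls.iloc[7]) < 15.0
        assert abs(gy[iy] - d_bronchi.iloc[7]) < 15.0

    def test_normalization_and_weight_rescaling(self):
        n = 50
        rng = np.random.default_rng(5)
        d_tls = pd.Series(rng.uniform(0, 300, n))
        d_bronchi = pd.Series(rng.uniform(0, 300, n))
        w = pd.Series(rng.uniform(0.1, 2.0, n))
        gx, gy, dens = weighted_kde_2d(d_tls, d_bronchi, w, bandwidth=25.0)
        dx, dy = gx[1] - gx[0], gy[1] - gy[0]
        assert dens.sum() * dx * dy == pytest.approx(1.0, abs=1e-6)
        _, _, dens2 = weighted_kde_2d(d_tls, d_bronchi, 3.7 * w, bandwidth=25.0)
        assert np.allclose(dens, dens2)

    def test_uniform_weights_match_unweighted_formula(self):
        n = 25
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 100, n)
        bw = 15.0
        gx, gy, dens = weighted_kde_2d(
            pd.Series(x), pd.Series(y), pd.Series(np.ones(n)), bandwidth=bw,
            grid_size=40,
        )
        # independent unweighted computation on the same grid
        ref = np.zeros((40, 40))
        for xi, yi in zip(x, y):
            ref += (
                np.exp(-0.5 * ((gy[:, None] - yi) / bw) ** 2)
                * np.exp(-0.5 * ((gx[None, :] - xi) / bw) ** 2)
            )
        ref /= ref.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert np.allclose(dens, ref)

    def test_all_zero_weights_fail(self):
        s = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="all-zero"):
            weighted_kde_2d(s, s, pd.Series([0.0, 0.0]), bandwidth=10.0)


class TestRegionRules:
    @pytest.mark.parametrize(
        "d_tls, d_bronchi, expected",
        [
            (0.0, 400.0, "T"),
            (400.0, 10.0, "B"),
            (300.0, 300.0, "P"),
            (50.0, 10.0, "T"),  # T wins over B at the boundary
            (500.0, 500.0, "none"),
        ],
    )
    def test_tbp_rule(self, d_tls, d_bronchi, expected):
        out = assign_tbp(pd.Series([d_tls]), pd.Series([d_bronchi]))
        assert out.iloc[0] == expected

    def test_tbp_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        d_tls = pd.Series(rng.uniform(0, 400, 200))
        d_bronchi = pd.Series(rng.uniform(0, 400, 200))
        t_small = assign_tbp(d_tls, d_bronchi, t_max=30.0) == "T"
        t_large = assign_tbp(d_tls, d_bronchi, t_max=80.0) == "T"
        assert (t_large | ~t_small).all()  # raising t_max never removes T

    @pytest.mark.parametrize(
        "d_tls, d_bronchi, d_vessel, expected",
        [
            (30.0, 300.0, 300.0, "TLS"),
            (200.0, 30.0, 300.0, "bronchi"),
            (60.0, 300.0, 80.0, "vessel"),
            (200.0, 200.0, 200.0, "alveolar"),
            (200.0, 50.0, 200.0, "other"),  # exactly 50 from bronchi: no clause
        ],
    )
    def test_imaging_rule(self, d_tls, d_bronchi, d_vessel, expected):
        out = categorize_imaging(
            pd.Series([d_tls]), pd.Series([d_bronchi]), pd.Series([d_vessel])
        )
        assert out.iloc[0] == expected

    def test_region_means_single_cells_equal_rows(self):
        expr = _expr(3, seed=8)
        labels = pd.Series(["T", "B", "P"], index=expr.index)
        means = region_mean_expression(expr, labels)
        for region, cid in zip(("T", "B", "P"), expr.index):
            assert np.allclose(means.loc[region], expr.loc[cid])

    def test_region_means_permutation_null(self):
        rng = np.random.default_rng(9)
        expr = _expr(600, seed=9)
        labels = pd.Series(rng.choice(["T", "B", "P"], 600), index=expr.index)
        means = region_mean_expression(expr, labels)
        # identically distributed groups: means agree within 2 SE
        for gene in expr.columns:
            se = expr[gene].std() / np.sqrt(200)
            spread = means[gene].max() - means[gene].min()
            assert spread < 4 * se  # pairwise |delta| < 2 SE each side


class TestZoneMarkers:
    def _adata(self, X):
        X = np.asarray(X)
        return ad.AnnData(
            X=sparse.csr_matrix(X),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]),
        )

    def test_low_detection_gene_never_tested(self):
        rng = np.random.default_rng(10)
        X = rng.poisson(5, size=(200, 3))
        X[:, 0] = 0
        X[:4, 0] = 9  # 4% detection in zone A only
        adata = self._adata(X)
        zones = pd.Series(["A"] * 100 + ["B"] * 100, index=adata.obs_names)
        table = zone_marker_test(adata, zones)
        assert "g0" not in set(table["gene"])

    def test_planted_eightfold_marker_detected(self):
        rng = np.random.default_rng(11)
        X = rng.poisson(5, size=(400, 20))
        X[:200, 0] = rng.poisson(40, size=200)
        adata = self._adata(X)
        zones = pd.Series(["A"] * 200 + ["B"] * 200, index=adata.obs_names)
        table = zone_marker_test(adata, zones)
        hit = table[(table["gene"] == "g0") & (table["zone"] == "A")]
        assert bool(hit["passed"].iloc[0])
        assert hit["log2fc"].iloc[0] > 1

    def test_bh_adjustment_monotone_in_rank(self):
        rng = np.random.default_rng(12)
        X = rng.poisson(5, size=(120, 15))
        adata = self._adata(X)
        zones = pd.Series(["A"] * 60 + ["B"] * 60, index=adata.obs_names)
        table = zone_marker_test(adata, zones).sort_values("pval")
        assert (table["padj"].diff().dropna() >= -1e-12).all()

    def test_single_usable_zone_fails(self):
        adata = self._adata(np.ones((4, 3)))
        zones = pd.Series(["A", "A", "A", "B"], index=adata.obs_names)
        with pytest.raises(ValueError, match="at least 2 zones"):
            zone_marker_test(adata, zones)
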