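"""Ordination, kernel occupancy, analog masks, and novelty detection."""

import numpy as np
import pytest

from nichedyn.core import ContractError
from nichedyn.ordination import (
    compute_analog_mask,
    estimate_occupancy_grid,
    exdet_nt1,
    exdet_nt2,
    fit_scaled_pca,
    novelty_summary,
    project_scores,
    variance_check,
)
from conftest import toy_grid


class TestScaledPCA:
    def test_perfectly_correlated_pair_is_rank_one(self, rng):
        x = rng.normal(size=100)
        o = fit_scaled_pca(np.column_stack([x, 2 * x + 1]), n_axes=2)
        assert o.variance_fractions[0] == pytest.approx(1.0)

    def test_uncorrelated_pair_splits_evenly(self, rng):
        X = rng.normal(size=(20000, 2))
        o = fit_scaled_pca(X, n_axes=2)
        assert o.variance_fractions == pytest.approx([0.5, 0.5], abs=0.02)

    def test_loadings_match_eigendecomposition(self, rng):
        X = rng.normal(size=(50, 5)) @ rng.normal(size=(5, 5))
        o = fit_scaled_pca(X, n_axes=5)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = np.corrcoef(Z, rowvar=False)
        w, v = np.linalg.eigh(corr)
        w = w[::-1]
        assert np.allclose(np.sort(o.all_variance_fractions)[::-1] * w.sum(), w,
                           atol=1e-10)
        # each loading vector spans the same direction as an eigenvector
        for j in range(5):
            col = o.loadings[:, j]
            assert np.linalg.norm(corr @ col - w[j] * col) < 1e-8

    def test_sign_convention_largest_element_positive(self, rng):
        X = rng.normal(size=(40, 4))
        o = fit_scaled_pca(X, n_axes=4)
        for j in range(4):
            col = o.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ContractError, match="0"):
            fit_scaled_pca(X)


class TestProjection:
    def test_calibration_rows_reproduce_scores(self, rng):
        X = rng.normal(size=(30, 3))
        o = fit_scaled_pca(X, n_axes=2)
        s1 = project_scores(o, X)
        Z = (X - o.means) / o.sds
        assert np.allclose(s1, Z @ o.loadings)

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(30, 3))
        o = fit_scaled_pca(X, n_axes=2)
        assert np.allclose(project_scores(o, o.means), 0.0, atol=1e-12)

    def test_duplicated_calibration_rows_leave_scores_unchanged(self, rng):
        X = rng.normal(size=(25, 3))
        o1 = fit_scaled_pca(np.vstack([X, X]), n_axes=2)
        o2 = fit_scaled_pca(np.vstack([X, X, X, X]), n_axes=2)
        # duplicating every row twice more rescales nothing (same moments
        # up to the ddof correction, which shrinks with n)
        assert np.allclose(
            project_scores(o1, X), project_scores(o2, X), atol=2e-2
        )

    def test_dimension_mismatch(self, rng):
        o = fit_scaled_pca(rng.normal(size=(10, 3)), n_axes=2)
        with pytest.raises(ContractError):
            project_scores(o, np.zeros((2, 4)))


@pytest.mark.parametrize(
    "fractions,threshold,expected",
    [((0.6, 0.3), 0.75, True), ((0.5, 0.2), 0.75, False), ((0.5, 0.2), 0.0, True)],
)
def test_variance_check(fractions, threshold, expected):
    from nichedyn.ordination import Ordination

    f = np.array(fractions)
    o = Ordination(np.zeros(2), np.ones(2), np.eye(2), f, f / f.sum())
    assert variance_check(o, threshold) is expected


class TestOccupancyGrid:
    def test_unit_mass_normalization(self, rng):
        P = rng.normal(size=(50, 2))
        B = rng.uniform(-4, 4, size=(500, 2))
        g = estimate_occupancy_grid(P, B, resolution=60)
        assert g.z.sum() * g.cell_area == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_concentrates_at_the_point(self, rng):
        P = np.tile([[0.5, -0.25]], (10, 1)) + rng.normal(0, 1e-6, size=(10, 2))
        B = rng.uniform(-2, 2, size=(400, 2))
        g = estimate_occupancy_grid(P, B, resolution=50, correction=False)
        i, j = np.unravel_index(np.argmax(g.z), g.z.shape)
        c1, c2 = g.centers1[i], g.centers2[j]
        w1 = g.edges1[1] - g.edges1[0]
        w2 = g.edges2[1] - g.edges2[0]
        assert abs(c1 - 0.5) <= w1 and abs(c2 + 0.25) <= w2

    def test_correction_flattens_occupancy_matching_background(self, rng):
        # presences drawn exactly like the background: corrected occupancy
        # approaches uniformity over the occupied support as n grows
        B = rng.uniform(0, 1, size=(4000, 2))
        P = B[rng.choice(len(B), 1500, replace=False)]
        g = estimate_occupancy_grid(P, B, resolution=30, correction=True)
        interior = g.z[5:-5, 5:-5]
        ratio = interior.max() / interior[interior > 0].min()
        g0 = estimate_occupancy_grid(P, B, resolution=30, correction=False)
        interior0 = g0.z[5:-5, 5:-5]
        ratio0 = interior0.max() / interior0[interior0 > 0].min()
        assert ratio < ratio0  # correction removes availability structure
        assert ratio < 3.0

    def test_too_few_presences_rejected(self, rng):
        with pytest.raises(ContractError):
            estimate_occupancy_grid(rng.normal(size=(4, 2)),
                                    rng.normal(size=(50, 2)))


class TestAnalogMask:
    def test_toy_intersection(self):
        native = toy_grid(np.ones((1, 4)), background=[[1.0, 1.0, 1.0, 0.0]])
        alien = toy_grid(np.ones((1, 4)), background=[[0.0, 1.0, 1.0, 1.0]])
        m = compute_analog_mask(native, alien, 0.0)
        assert m.mask.tolist() == [[False, True, True, False]]
        assert m.analog_fraction == pytest.approx(0.5)

    def test_identical_backgrounds_give_common_support(self):
        bg = [[0.0, 2.0, 3.0], [1.0, 0.0, 1.0]]
        a, b = toy_grid(np.ones((2, 3)), bg), toy_grid(np.ones((2, 3)), bg)
        m = compute_analog_mask(a, b, 0.0)
        assert np.array_equal(m.mask, np.asarray(bg) > 0)

    def test_mask_monotone_in_quantile(self, rng):
        P = rng.normal(size=(60, 2))
        B1 = rng.normal(size=(800, 2))
        B2 = rng.normal(0.5, 1.0, size=(800, 2))
        ext = (-5, 5, -5, 5)
        g1 = estimate_occupancy_grid(P, B1, 40, ext)
        g2 = estimate_occupancy_grid(P, B2, 40, ext)
        prev = None
        for q in (0.0, 0.25, 0.5, 0.75):
            m = compute_analog_mask(g1, g2, q).mask
            if prev is not None:
                assert np.all(m <= prev)
            prev = m

    def test_mismatched_grids_rejected(self):
        a = toy_grid(np.ones((2, 2)))
        b = toy_grid(np.ones((3, 3)))
        with pytest.raises(ContractError):
            compute_analog_mask(a, b)


class TestExDet:
    ref2 = np.array([[0.0, 0.0], [10.0, 5.0], [5.0, 2.5], [2.0, 4.0]])

    def test_interior_point_scores_zero(self):
        assert exdet_nt1(self.ref2, np.array([5.0, 2.0])) == 0.0

    def test_one_variable_below_range(self):
        ref = np.array([[0.0, 0.0], [10.0, 1.0]])
        assert exdet_nt1(ref, np.array([-1.0, 0.5])) == pytest.approx(-0.1)

    def test_two_variables_sum(self):
        # ranges of length 10 and 5, both 0.2 below their minima
        assert exdet_nt1(self.ref2, np.array([-0.2, -0.2])) == pytest.approx(-0.06)

    def test_nt1_never_positive(self, rng):
        ref = rng.normal(size=(40, 3))
        for _ in range(50):
            assert exdet_nt1(ref, rng.normal(scale=3, size=3)) <= 0.0

    def test_nt2_zero_at_centroid(self, rng):
        ref = rng.normal(size=(60, 3))
        assert exdet_nt2(ref, ref.mean(axis=0)) == pytest.approx(0.0, abs=1e-12)

    def test_nt2_one_at_most_distant_reference_row(self, rng):
        ref = rng.normal(size=(60, 3))
        mu = ref.mean(0)
        inv = np.linalg.inv(np.cov(ref, rowvar=False))
        d2 = np.einsum("ij,jk,ik->i", ref - mu, inv, ref - mu)
        worst = ref[np.argmax(d2)]
        assert exdet_nt2(ref, worst) == pytest.approx(1.0)

    def test_nt2_matches_direct_mahalanobis(self, rng):
        ref = rng.normal(size=(80, 4))
        x = rng.normal(size=4)
        mu = ref.mean(0)
        inv = np.linalg.inv(np.cov(ref, rowvar=False))
        d2 = float((x - mu) @ inv @ (x - mu))
        dmax = np.max(np.einsum("ij,jk,ik->i", ref - mu, inv, ref - mu))
        assert exdet_nt2(ref, x) == pytest.approx(d2 / dmax, rel=1e-12)

    def test_zero_range_variable_rejected(self):
        ref = np.array([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(ContractError):
            exdet_nt1(ref, np.array([0.0, 2.5]))


class TestNoveltySummary:
    def test_nested_envelope_has_no_novelty(self, rng):
        native = rng.normal(size=(500, 2))
        inner = native[np.linalg.norm(native, axis=1) < 1.0]
        rep = novelty_summary(inner, native)
        assert rep.percent_novel == 0.0 and not rep.exceeds_5pct

    def test_two_novel_of_twenty(self, rng):
        native = rng.uniform(0, 1, size=(200, 2))
        alien = np.tile([[0.5, 0.5]], (20, 1)).astype(float)
        alien[0] = [2.0, 0.5]
        alien[1] = [-1.0, 0.5]
        rep = novelty_summary(alien, native)
        assert rep.percent_novel == pytest.approx(10.0)
        assert rep.exceeds_5pct

    def test_matches_cellwise_scores(self, rng):
        native = rng.normal(size=(300, 2))
        alien = rng.normal(loc=1.5, size=(100, 2))
        rep = novelty_summary(alien, native)
        novel = 0
        for row in alien:
            nt1 = exdet_nt1(native, row)
            if nt1 < 0:
                novel += 1
            elif exdet_nt2(native, row) > 1:
                novel += 1
        assert rep.percent_novel == pytest.approx(100.0 * novel / len(alien))
        # exclusivity: NT2 is only evaluated where NT1 == 0
        assert np.all(np.isnan(rep.nt2[rep.nt1 < 0]))
        assert np.all(rep.nt1 <= 0)
        assert np.all(rep.nt2[~np.isnan(rep.nt2)] >= 0)
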