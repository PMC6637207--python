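"""Segmentation, feature extraction, canonical LDA, Wilks, ellipses, ranking."""

import numpy as np
import pytest
from scipy import stats

from smatkit import synthetic
from smatkit.hcia import (
    FEATURE_NAMES,
    DualChannelCellImage,
    canonical_contour,
    classify,
    cross_validated_accuracy,
    extract_features,
    extract_population,
    fit_lda,
    rank_predictors,
    segment_cells,
    transform,
    wilks_test,
)


def disk_image(centers, radius=10, size=96, nuc_radius=3):
    """Uniform-disk cells with centered nuclei on a dark background."""
    yy, xx = np.mgrid[0:size, 0:size]
    sa = np.zeros((size, size))
    nuc = np.zeros((size, size))
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        sa[d2 <= radius ** 2] = 100.0
        nuc[d2 <= nuc_radius ** 2] = 200.0
    return DualChannelCellImage(sa, sa.copy(), nuc)


class TestSegmentation:
    def test_blank_image_zero_cells(self):
        z = np.zeros((64, 64))
        seg = segment_cells(DualChannelCellImage(z, z, z))
        assert seg.n_cells == 0 and seg.border_excluded == 0

    def test_separated_cells_counted_exactly(self):
        img = disk_image([(20, 20), (20, 70), (70, 20), (70, 70), (45, 45)])
        seg = segment_cells(img)
        assert seg.n_cells == 5

    def test_touching_cells_split_by_nuclear_seeds(self):
        img = disk_image([(48, 40), (48, 56)])  # overlapping disks, 2 nuclei
        seg = segment_cells(img)
        assert seg.n_cells == 2

    def test_border_cells_excluded_and_counted(self):
        img = disk_image([(5, 48), (48, 48)])
        seg = segment_cells(img)
        assert seg.n_cells == 1 and seg.border_excluded >= 1

    def test_every_cell_contains_a_nucleus(self):
        img = disk_image([(25, 25), (25, 70), (70, 45)])
        seg = segment_cells(img)
        for cid in seg.cell_ids:
            assert np.any(seg.nuclei_labels[seg.cell_labels == cid] > 0)


class TestFeatures:
    def test_uniform_square_cell_conventions(self):
        size = 40
        sa = np.zeros((size, size))
        sa[12:28, 12:28] = 50.0
        nuc = np.zeros((size, size))
        nuc[18:22, 18:22] = 200.0
        img = DualChannelCellImage(sa, sa.copy(), nuc)
        seg = segment_cells(img)
        assert seg.n_cells == 1
        vec = dict(zip(FEATURE_NAMES,
                       extract_features(img, seg, seg.cell_ids[0])))
        assert vec["eccentricity"] == pytest.approx(0.0, abs=1e-9)
        assert vec["sa_mean"] == pytest.approx(50.0)
        assert vec["sa_asm"] == pytest.approx(1.0)   # single gray level
        assert vec["solidity"] == pytest.approx(1.0, abs=0.05)

    def test_feature_vector_has_41_finite_entries(self, dual_stain_features):
        X = dual_stain_features[list(FEATURE_NAMES)].to_numpy()
        assert X.shape[1] == 41
        assert np.all(np.isfinite(X))
        shape_cols = X[:, :9]
        assert np.all(shape_cols >= 0)

    def test_ellipse_beats_circle_on_eccentricity_and_perimeter(self):
        yy, xx = np.mgrid[0:80, 0:80]
        nuc = np.zeros((80, 80))
        nuc[38:42, 38:42] = 200.0
        circle = ((yy - 40) ** 2 + (xx - 40) ** 2) <= 20 ** 2
        ellipse = ((yy - 40) / 10.0) ** 2 + ((xx - 40) / 40.0) ** 2 <= 1.0

        feats = {}
        for name, mask in (("circle", circle), ("ellipse", ellipse)):
            sa = np.where(mask, 100.0, 0.0)
            img = DualChannelCellImage(sa, sa.copy(), nuc)
            seg = segment_cells(img, exclude_border=False)
            feats[name] = dict(zip(
                FEATURE_NAMES, extract_features(img, seg, seg.cell_ids[0])))
        assert feats["ellipse"]["eccentricity"] > feats["circle"]["eccentricity"]
        assert feats["ellipse"]["perimeter"] > feats["circle"]["perimeter"]

    def test_translation_invariance(self):
        def field(offset):
            size = 120
            sa = np.zeros((size, size))
            nuc = np.zeros((size, size))
            yy, xx = np.mgrid[0:size, 0:size]
            cy, cx = 40 + offset, 45 + offset
            mask = ((yy - cy) / 12.0) ** 2 + ((xx - cx) / 18.0) ** 2 <= 1.0
            sa[mask] = 60.0 + (((xx[mask] - cx) * 3 + (yy[mask] - cy) * 5) % 7) * 10.0
            nuc[(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = 200.0
            img = DualChannelCellImage(sa, sa.copy(), nuc)
            seg = segment_cells(img, exclude_border=False)
            assert seg.n_cells == 1
            return extract_features(img, seg, seg.cell_ids[0])

        np.testing.assert_allclose(field(0), field(17), rtol=1e-9)


class TestLDA:
    def test_one_dimensional_closed_form(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 400), rng.normal(1, 1, 400)][:, None]
        y = np.r_[np.zeros(400), np.ones(400)]
        model = fit_lda(x, y, standardize=False)
        gap = abs(model.group_means[1, 0] - model.group_means[0, 0])
        d = (x[y == 1].mean() - x[y == 0].mean()) / np.sqrt(
            ((x - x.mean()) ** 2).sum() / len(x))  # rough scale check only
        assert gap == pytest.approx(_mahalanobis_1d(x, y), rel=1e-9)
        assert 0.5 < gap < 1.5 and d > 0

    def test_eigenvalues_match_dense_generalized_eigenproblem(self):
        rng = np.random.default_rng(1)
        means = np.array([[0, 0], [2, 1], [-1, 2]], float)
        X = np.vstack([rng.multivariate_normal(m, [[1, 0.3], [0.3, 2]], 60)
                       for m in means])
        y = np.repeat([0, 1, 2], 60)
        model = fit_lda(X, y, standardize=False)

        _, _, s_w, s_b = _scatters(X, y)
        oracle = np.sort(np.real(np.linalg.eig(
            np.linalg.inv(s_w) @ s_b)[0]))[::-1][:2]
        np.testing.assert_allclose(model.eigenvalues, oracle, atol=1e-8)

    def test_scores_have_identity_pooled_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 5)) + np.repeat(
            rng.normal(0, 2, size=(3, 5)), 50, axis=0)
        y = np.repeat([0, 1, 2], 50)
        model = fit_lda(X, y)
        scores = transform(model, X)
        _, _, s_w, _ = _scatters(scores, y)
        np.testing.assert_allclose(s_w / (len(X) - 3), np.eye(2), atol=1e-8)

    def test_permuted_labels_collapse_leading_eigenvalue(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(m, 1, size=(80, 3))
                       for m in (0.0, 3.0)])
        y = np.repeat([0, 1], 80)
        strong = fit_lda(X, y).eigenvalues[0]
        nulls = [fit_lda(X, rng.permutation(y)).eigenvalues[0]
                 for _ in range(20)]
        assert np.median(nulls) < 0.1 * strong

    def test_perfect_separation_classifies_100(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(10, 0.1, (50, 2))])
        y = np.repeat(["a", "b"], 50)
        model = fit_lda(X, y)
        assert classify(model, X, y).percent_correct == 100.0

    def test_identical_distributions_classify_at_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 4))
        y = np.repeat(list("abcd"), 500)
        rep = classify(fit_lda(X, y), X, y)
        assert rep.percent_correct == pytest.approx(25.0, abs=5.0)
        assert rep.confusion.sum() == 2000

    def test_resubstitution_not_below_cross_validation(self):
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(10):
            X = rng.normal(size=(80, 10))
            X[40:, 0] += 1.0
            y = np.repeat([0, 1], 40)
            resub = classify(fit_lda(X, y), X, y).percent_correct
            cv = cross_validated_accuracy(X, y, n_splits=4, seed=0)
            diffs.append(resub - cv)
        assert np.mean(diffs) >= 0

    def test_unseen_label_rejected(self):
        X = np.random.default_rng(7).normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        model = fit_lda(X, y)
        with pytest.raises(ValueError):
            classify(model, X, np.repeat([0, 2], 10))


class TestWilks:
    def test_duplicated_groups_give_lambda_one(self):
        rng = np.random.default_rng(8)
        block = rng.normal(size=(30, 3))
        X = np.vstack([block, block])
        y = np.repeat([0, 1], 30)
        res = wilks_test(X, y)
        assert res.lambda_ == pytest.approx(1.0, abs=1e-12)
        assert res.p_f == pytest.approx(1.0, abs=1e-12)

    def test_one_feature_two_groups_equals_anova_f(self):
        rng = np.random.default_rng(9)
        x = np.r_[rng.normal(0, 1, 25), rng.normal(0.8, 1, 30)][:, None]
        y = np.r_[np.zeros(25), np.ones(30)]
        res = wilks_test(x, y)
        f_anova = stats.f_oneway(x[y == 0, 0], x[y == 1, 0])
        assert res.f_stat == pytest.approx(f_anova.statistic, rel=1e-10)
        assert res.p_f == pytest.approx(f_anova.pvalue, rel=1e-10)

    def test_agrees_with_statsmodels_manova(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(10)
        X = rng.normal(size=(90, 4)) + np.repeat(
            [[0, 0, 0, 0], [0.5, 0, 0.2, 0], [0, 0.7, 0, 0.1]], 30, axis=0)
        y = np.repeat(list("abc"), 30)
        res = wilks_test(X, y)
        df = pd.DataFrame(X, columns=list("wxyz"))
        df["g"] = y
        mv = MANOVA.from_formula("w + x + y + z ~ g", data=df)
        tbl = mv.mv_test().results["g"]["stat"]
        assert res.lambda_ == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res.p_f == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Pr > F"]), rel=1e-6)

    def test_too_many_features_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="reduce"):
            wilks_test(rng.normal(size=(10, 12)), np.repeat([0, 1], 5))


class TestContour:
    def test_isotropic_half_mass_radius(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(5, 1, (500, 2))])
        y = np.repeat([0, 1], 500)
        model = fit_lda(X, y)
        scores = np.random.default_rng(13).normal(size=(4000, 2))
        ell = canonical_contour(model, scores, np.zeros(4000), 0, coverage=0.5)
        expected = np.sqrt(stats.chi2.ppf(0.5, 2))  # ~1.177 for unit variance
        np.testing.assert_allclose(ell.semi_axes, expected, rtol=0.1)
        inside = _inside_fraction(scores, ell)
        assert inside == pytest.approx(0.5, abs=0.04)

    def test_high_coverage_contains_almost_all(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=(1000, 2))
        model = fit_lda(np.vstack([scores, scores + 4]),
                        np.repeat([0, 1], 1000))
        ell = canonical_contour(model, scores, np.zeros(1000), 0,
                                coverage=0.999)
        assert _inside_fraction(scores, ell) > 0.99

    def test_invalid_coverage(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(3, 1, (10, 2))])
        model = fit_lda(X, np.repeat([0, 1], 10))
        with pytest.raises(ValueError):
            canonical_contour(model, X, np.repeat([0, 1], 10), 0, coverage=1.5)


class TestRanking:
    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(200, 8))
        y = np.repeat([0, 1], 100)
        X[y == 1, 3] += 4.0
        ranking = rank_predictors(X, y, n_boot=100, seed=0)
        assert ranking.features[0] == "f3"
        assert ranking.importances[0] > 0.5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(80, 5))
        y = np.repeat([0, 1], 40)
        a = rank_predictors(X, y, n_boot=60, seed=9)
        b = rank_predictors(X, y, n_boot=60, seed=9)
        assert a.features == b.features
        np.testing.assert_array_equal(a.importances, b.importances)

    def test_intensity_and_texture_dominate_on_divergent_populations(
            self, dual_stain_features):
        # the generator diverges conditions in intensity balance and texture,
        # not in shape, so shape descriptors should not lead the ranking
        X = dual_stain_features[list(FEATURE_NAMES)].to_numpy()
        y = dual_stain_features["condition"].to_numpy()
        ranking = rank_predictors(X, y, n_boot=200, seed=0,
                                  feature_names=FEATURE_NAMES)
        top5 = set(ranking.features[:5])
        shape_set = set(FEATURE_NAMES[:9])
        assert len(top5 & shape_set) == 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _scatters(X, y):
    from smatkit.hcia import _scatter_matrices

    return _scatter_matrices(np.asarray(X, float), np.asarray(y))


def _mahalanobis_1d(x, y):
    x = x[:, 0]
    n = len(x)
    s_w = sum(((x[y == g] - x[y == g].mean()) ** 2).sum() for g in (0, 1))
    pooled_sd = np.sqrt(s_w / (n - 2))
    return abs(x[y == 1].mean() - x[y == 0].mean()) / pooled_sd


def _inside_fraction(points, ell):
    c, s = np.cos(ell.angle_rad), np.sin(ell.angle_rad)
    rot = np.array([[c, s], [-s, c]])
    local = (points - ell.center) @ rot.T
    q = (local[:, 0] / ell.semi_axes[0]) ** 2 + \
        (local[:, 1] / ell.semi_axes[1]) ** 2
    return float((q <= 1.0).mean())
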