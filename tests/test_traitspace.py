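import numpy as np
import pandas as pd
import pytest

from traitvar.io import CORE_TRAITS
from traitvar.traitspace import (build_species_matrix, run_pca, ssd_to_ldmc,
                                 subspace_congruence, subspace_projection)


def factor_matrix(n_species=120, noise_sd=0.05, seed=0, truncate_size=None):
    """Species x 6 matrix from two planted factors plus small noise."""
    rng = np.random.default_rng(seed)
    L = np.array([[0.9, 0.0], [0.8, 0.2], [0.85, 0.0],
                  [0.0, 0.9], [0.1, -0.85], [0.0, 0.8]])
    z = rng.normal(0, 1, (n_species, 2))
    if truncate_size is not None:
        z[:, 0] = np.clip(z[:, 0], -truncate_size, truncate_size)
    X = z @ L.T + rng.normal(0, noise_sd, (n_species, 6))
    return (pd.DataFrame(X, columns=CORE_TRAITS,
                         index=[f"sp{i:03d}" for i in range(n_species)]), L)


class TestSpeciesMatrix:
    def make_records(self, cells):
        """cells: list of (species, trait, values)."""
        rows = []
        for sp, tr, vals in cells:
            for v in vals:
                rows.append({"species": sp, "trait": tr, "value": v})
        return pd.DataFrame(rows)

    def test_incomplete_species_excluded_and_listed(self):
        cells = [(f"sp{i}", t, [1.0]) for i in range(3) for t in CORE_TRAITS]
        cells += [("sp3", t, [1.0]) for t in CORE_TRAITS[:5]]  # misses LDMC
        stm = build_species_matrix(self.make_records(cells))
        assert "sp3" in stm.dropped_species
        assert len(stm.matrix) == 3

    def test_single_record_cell_is_log_value(self):
        cells = [(f"sp{i}", t, [2.0]) for i in range(3) for t in CORE_TRAITS]
        stm = build_species_matrix(self.make_records(cells))
        assert np.allclose(stm.matrix.to_numpy(), np.log(2.0))

    def test_mean_log_equals_log_geometric_mean(self):
        vals = [1.5, 2.5, 7.0]
        cells = [(f"sp{i}", t, [1.0]) for i in range(2) for t in CORE_TRAITS]
        cells += [("spX", t, vals) for t in CORE_TRAITS]
        stm = build_species_matrix(self.make_records(cells))
        gm = np.prod(vals) ** (1 / 3)
        assert stm.matrix.loc["spX"].iloc[0] == pytest.approx(np.log(gm),
                                                              abs=1e-12)

    def test_too_few_complete_species(self):
        cells = [("sp0", t, [1.0]) for t in CORE_TRAITS]
        with pytest.raises(ValueError, match="3 species"):
            build_species_matrix(self.make_records(cells))


class TestPCA:
    def test_perfectly_correlated_pair_gives_one_axis(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        mat = pd.DataFrame({"t1": a, "t2": 2 * a + 1})
        pca = run_pca(mat)
        assert pca.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_sums_to_one_and_contributions_to_100(self):
        mat, _ = factor_matrix()
        pca = run_pca(mat)
        assert pca.explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pca.contributions.sum(axis=0), 100.0, atol=1e-9)

    def test_reconstruction_with_all_axes(self):
        mat, _ = factor_matrix(n_species=40)
        pca = run_pca(mat)
        X = mat.to_numpy()
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-9)

    def test_sign_convention_deterministic(self):
        mat, _ = factor_matrix(seed=3)
        pca = run_pca(mat)
        for col in pca.loadings.columns:
            v = pca.loadings[col]
            assert v.iloc[np.argmax(np.abs(v.to_numpy()))] > 0

    def test_planted_two_factor_structure_recovered(self):
        mat, L = factor_matrix(noise_sd=0.05, seed=1)
        pca = run_pca(mat)
        # first two axes dominate every other pair
        assert pca.explained[0] + pca.explained[1] > 2 * pca.explained[2]
        sd = mat.to_numpy().std(0, ddof=1)
        cong = subspace_congruence(pca.loadings.iloc[:, :2].to_numpy(),
                                   L / sd[:, None])
        assert cong > 0.95

    def test_rescaling_invariance_with_standardization(self):
        mat, _ = factor_matrix(seed=2)
        scaled = mat * [10.0, 0.1, 3.0, 1.0, 100.0, 7.0]
        p1, p2 = run_pca(mat), run_pca(scaled)
        assert np.allclose(p1.explained, p2.explained, atol=1e-12)
        assert np.allclose(p1.loadings.to_numpy(), p2.loadings.to_numpy(),
                           atol=1e-9)

    def test_agrees_with_sklearn(self):
        from sklearn.decomposition import PCA

        mat, _ = factor_matrix(seed=4, n_species=50)
        pca = run_pca(mat, standardize=False)
        sk = PCA().fit(mat.to_numpy())
        assert np.allclose(pca.explained, sk.explained_variance_ratio_,
                           atol=1e-9)
        assert np.allclose(np.abs(pca.loadings.to_numpy()),
                           np.abs(sk.components_.T), atol=1e-9)

    def test_zero_variance_column_named(self):
        mat = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            run_pca(mat)


class TestSubspaceProjection:
    def test_full_subset_identical_ranges(self):
        mat, _ = factor_matrix()
        pca = run_pca(mat)
        scores, missing = subspace_projection(pca, mat.index)
        assert not missing
        pd.testing.assert_frame_equal(scores, pca.scores)

    def test_single_species_degenerate_range(self):
        mat, _ = factor_matrix()
        pca = run_pca(mat)
        scores, _ = subspace_projection(pca, [mat.index[0]])
        assert (scores.max() - scores.min()).eq(0).all()

    def test_unknown_species_listed(self):
        mat, _ = factor_matrix()
        pca = run_pca(mat)
        _, missing = subspace_projection(pca, ["not a species"])
        assert missing == ["not a species"]

    def test_truncated_size_scores_shrink_size_axis_only(self):
        """A subset generated with truncated size-factor scores occupies a
        reduced range on the size axis but the full economics range."""
        full, L = factor_matrix(n_species=400, seed=5)
        trunc, _ = factor_matrix(n_species=400, seed=6, truncate_size=0.5)
        both = pd.concat([full, trunc.set_index(
            pd.Index([f"tr{i:03d}" for i in range(len(trunc))]))])
        pca = run_pca(both)
        # identify which of the first two axes is the size axis
        sd = both.to_numpy().std(0, ddof=1)
        size_dir = (L[:, 0] / sd) / np.linalg.norm(L[:, 0] / sd)
        align = np.abs(pca.loadings.iloc[:, :2].to_numpy().T @ size_dir)
        size_axis = pca.loadings.columns[int(np.argmax(align))]
        econ_axis = pca.loadings.columns[1 - int(np.argmax(align))]
        sub, _ = subspace_projection(pca, [f"tr{i:03d}" for i in range(400)])
        rng_full = pca.scores.max() - pca.scores.min()
        rng_sub = sub.max() - sub.min()
        assert rng_sub[size_axis] / rng_full[size_axis] < 0.75
        assert rng_sub[econ_axis] / rng_full[econ_axis] > 0.85


class TestSSDConversion:
    def test_exact_line_recovered(self):
        ssd = np.array([0.2, 0.4, 0.6, 0.9])
        ldmc = np.exp(0.3 + 0.8 * np.log(ssd))
        pairs = pd.DataFrame({"ssd": ssd, "ldmc": ldmc})
        pred, conv = ssd_to_ldmc([0.5], pairs)
        assert conv.slope == pytest.approx(0.8, abs=1e-9)
        assert conv.intercept == pytest.approx(0.3, abs=1e-9)
        assert pred[0] == pytest.approx(np.exp(0.3 + 0.8 * np.log(0.5)))

    def test_prediction_at_calibration_point_on_fitted_line(self):
        rng = np.random.default_rng(0)
        ssd = rng.uniform(0.2, 1.0, 30)
        ldmc = np.exp(0.1 + 0.6 * np.log(ssd) + rng.normal(0, 0.05, 30))
        pairs = pd.DataFrame({"ssd": ssd, "ldmc": ldmc})
        pred, conv = ssd_to_ldmc([ssd[0]], pairs)
        assert pred[0] == pytest.approx(
            np.exp(conv.intercept + conv.slope * np.log(ssd[0])))

    def test_planted_slope_recovered_within_error(self):
        rng = np.random.default_rng(1)
        ssd = rng.uniform(0.2, 1.0, 500)
        ldmc = np.exp(0.2 + 0.7 * np.log(ssd) + rng.normal(0, 0.1, 500))
        _, conv = ssd_to_ldmc([0.5], pd.DataFrame({"ssd": ssd, "ldmc": ldmc}))
        assert conv.slope == pytest.approx(0.7, abs=0.05)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ssd_to_ldmc([0.5], pd.DataFrame({"ssd": [1, 2], "ldmc": [1, 2]}))
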