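import numpy as np
import pandas as pd
import pytest

from ftirco.spectra_io import REGIONS, SampleMeta, SpectraSet, WavenumberAxis
from ftirco.chemometrics import (
    ChemometricsError,
    anova_effect_matrices,
    pca,
    run_region_pca,
    variation_contribution,
    variation_table,
)
from ftirco.preprocess import preprocess_branch1
from ftirco import synthetic_data as sd


def _design_set(matrix, n_levels, pi_levels, reps, axis_values=None):
    """Build a single-strain set with a factorial (N, Pi, rep) layout."""
    matrix = np.asarray(matrix, dtype=float)
    if axis_values is None:
        axis_values = np.arange(matrix.shape[1], dtype=float) + 500.0
    rows = []
    i = 0
    for n in n_levels:
        for pi in pi_levels:
            for r in range(1, reps + 1):
                rows.append(
                    SampleMeta(
                        sample_id=f"x{i}",
                        strain="MCI",
                        n_source=n,
                        pi_level=pi,
                        bio_rep=r,
                    ).as_dict()
                )
                i += 1
    return SpectraSet(WavenumberAxis(axis_values), matrix, pd.DataFrame(rows))


class TestPCA:
    def test_rank_one_matrix_has_pc1_fraction_one(self, rng):
        v = rng.normal(size=12)
        scores = rng.normal(size=6)
        matrix = 3.0 + np.outer(scores, v)
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 3)
        res = pca(sset, n_components=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_times_loadings_reconstructs_centered_matrix(self, rng):
        matrix = rng.normal(size=(6, 9))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 3)
        res = pca(sset, n_components=5)  # rank of centered 6x9 matrix
        reconstructed = res.scores @ res.loadings
        np.testing.assert_allclose(
            reconstructed, matrix - matrix.mean(axis=0), atol=1e-8
        )

    def test_explained_variance_matches_covariance_eigenvalue_oracle(self, rng):
        matrix = rng.normal(size=(6, 9))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 3)
        res = pca(sset, n_components=4)
        Xc = matrix - matrix.mean(axis=0)
        eigvals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        eigvals = eigvals[eigvals > 1e-12]
        expected = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            res.explained_variance_fraction, expected[:4], atol=1e-10
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        matrix = rng.normal(size=(10, 15))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 5)
        res = pca(sset, n_components=3)
        sk = SkPCA(n_components=3).fit(matrix)
        np.testing.assert_allclose(
            res.explained_variance_fraction, sk.explained_variance_ratio_, atol=1e-10
        )
        for k in range(3):
            dot = abs(np.dot(res.loadings[k], sk.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loading_sign_convention(self, rng):
        matrix = rng.normal(size=(8, 10))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 4)
        res = pca(sset, n_components=3)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_scores_invariant_to_sample_reordering(self, rng):
        matrix = rng.normal(size=(8, 10))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1"], 4)
        perm = rng.permutation(8)
        res_a = pca(sset, n_components=2)
        res_b = pca(sset.select(perm), n_components=2)
        np.testing.assert_allclose(res_b.scores, res_a.scores[perm], atol=1e-8)

    def test_too_few_samples_rejected(self, rng):
        sset = _design_set(rng.normal(size=(1, 5)), ["YE"], ["Pi1"], 1)
        with pytest.raises(ChemometricsError):
            pca(sset, 1)


class TestAnovaEffectMatrices:
    def test_identical_rows_give_zero_effects_and_residual(self):
        matrix = np.tile(np.arange(5.0), (12, 1))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 3)
        em = anova_effect_matrices(sset)
        for arr in (em.a_n, em.a_pi, em.a_int, em.residual):
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)

    def test_pure_n_effect_leaves_other_matrices_zero(self):
        # rows differ only by N level
        ye_row, as_row = np.zeros(4), np.ones(4)
        matrix = np.vstack([ye_row] * 6 + [as_row] * 6)
        rows = []
        for i, n in enumerate(["YE"] * 6 + ["AS"] * 6):
            rows.append(
                SampleMeta(
                    sample_id=f"x{i}",
                    strain="MCI",
                    n_source=n,
                    pi_level=["Pi1", "Pi2", "Pi4"][i % 3],
                    bio_rep=1 + i % 2,
                ).as_dict()
            )
        sset = SpectraSet(
            WavenumberAxis(np.arange(4.0) + 500.0), matrix, pd.DataFrame(rows)
        )
        em = anova_effect_matrices(sset)
        assert np.abs(em.a_n).max() > 0
        np.testing.assert_allclose(em.a_pi, 0.0, atol=1e-12)
        np.testing.assert_allclose(em.a_int, 0.0, atol=1e-12)
        np.testing.assert_allclose(em.residual, 0.0, atol=1e-12)

    def test_matches_brute_force_group_mean_oracle(self, rng):
        # balanced 2x3 with 2 reps per cell
        matrix = rng.normal(size=(12, 7))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2", "Pi4"], 2)
        em = anova_effect_matrices(sset)
        meta = sset.meta
        m = matrix.mean(axis=0)
        for i in range(12):
            n, pi = meta.loc[i, "n_source"], meta.loc[i, "pi_level"]
            n_mean = matrix[(meta["n_source"] == n).to_numpy()].mean(axis=0)
            pi_mean = matrix[(meta["pi_level"] == pi).to_numpy()].mean(axis=0)
            cell = matrix[
                ((meta["n_source"] == n) & (meta["pi_level"] == pi)).to_numpy()
            ].mean(axis=0)
            np.testing.assert_allclose(em.a_n[i], n_mean - m, atol=1e-12)
            np.testing.assert_allclose(em.a_pi[i], pi_mean - m, atol=1e-12)
            np.testing.assert_allclose(
                em.a_int[i], cell - m - (n_mean - m) - (pi_mean - m), atol=1e-12
            )

    def test_reconstruction_is_exact(self, rng):
        matrix = rng.normal(size=(24, 5))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 6)
        em = anova_effect_matrices(sset)
        np.testing.assert_allclose(
            em.grand_mean + em.a_n + em.a_pi + em.a_int + em.residual,
            matrix,
            atol=1e-10,
        )

    def test_balanced_sum_of_squares_decomposition(self, rng):
        matrix = rng.normal(size=(24, 5))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 6)
        em = anova_effect_matrices(sset)
        total = np.sum((matrix - matrix.mean(axis=0)) ** 2)
        parts = sum(
            np.sum(a**2) for a in (em.a_n, em.a_pi, em.a_int, em.residual)
        )
        assert parts == pytest.approx(total, rel=1e-8)

    def test_single_level_factor_warns_and_zeroes(self, rng):
        matrix = rng.normal(size=(6, 4))
        sset = _design_set(matrix, ["AS"], ["Pi1", "Pi2"], 3)
        em = anova_effect_matrices(sset)
        assert em.warnings
        np.testing.assert_allclose(em.a_n, 0.0)

    def test_unbalanced_missing_cell_reconstruction_still_exact(self, rng):
        # drop one (N, Pi) cell entirely, as for no-growth combinations
        matrix = rng.normal(size=(12, 5))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2", "Pi4"], 2)
        keep = ~(
            (sset.meta["n_source"] == "AS") & (sset.meta["pi_level"] == "Pi4")
        ).to_numpy()
        sub = sset.select(keep)
        em = anova_effect_matrices(sub)
        np.testing.assert_allclose(
            em.grand_mean + em.a_n + em.a_pi + em.a_int + em.residual,
            sub.matrix,
            atol=1e-10,
        )


class TestVariationContribution:
    def test_pure_n_variation_gives_100_percent_n(self, rng):
        base = rng.normal(size=6)
        matrix = np.vstack([base] * 6 + [base + 1.0] * 6)
        rows = []
        for i, n in enumerate(["YE"] * 6 + ["AS"] * 6):
            rows.append(
                SampleMeta(
                    sample_id=f"x{i}",
                    strain="MCI",
                    n_source=n,
                    pi_level=["Pi1", "Pi2", "Pi4"][i % 3],
                    bio_rep=1 + i % 2,
                ).as_dict()
            )
        sset = SpectraSet(
            WavenumberAxis(np.arange(6.0) + 500.0), matrix, pd.DataFrame(rows)
        )
        vc = variation_contribution(sset)
        assert vc["var_N"] == pytest.approx(100.0, abs=1e-9)
        assert vc["var_Pi"] == pytest.approx(0.0, abs=1e-9)
        assert vc["var_int"] == pytest.approx(0.0, abs=1e-9)

    def test_shares_sum_to_100(self, rng):
        matrix = rng.normal(size=(24, 8))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 6)
        vc = variation_contribution(sset)
        assert vc["var_N"] + vc["var_Pi"] + vc["var_int"] == pytest.approx(
            100.0, abs=1e-6
        )
        assert min(vc["var_N"], vc["var_Pi"], vc["var_int"]) >= 0

    def test_invariant_to_positive_scaling(self, rng):
        matrix = rng.normal(size=(24, 8))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 6)
        scaled = SpectraSet(sset.axis, 7.3 * sset.matrix, sset.meta.copy())
        a = variation_contribution(sset)
        b = variation_contribution(scaled)
        for key in ("var_N", "var_Pi", "var_int"):
            assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_zero_variation_is_an_error(self):
        matrix = np.tile(np.arange(4.0), (12, 1))
        sset = _design_set(matrix, ["YE", "AS"], ["Pi1", "Pi2"], 3)
        with pytest.raises(ChemometricsError):
            variation_contribution(sset)

    def test_pi_driven_polyp_effect_attributed_to_pi(self):
        """A synthetic strain whose polyphosphate concentration rises
        linearly with the Pi level must show Pi as the dominant factor on the
        polyphosphate region."""
        effects = sd.EffectModel(
            n_effect={},
            pi_slope={"polyphosphate": 0.06},
            int_slope={},
        )
        design = sd.expand_technical(sd.build_design(strains=("RST",)), tech_reps=3)
        sset, _ = sd.simulate_biomass_set(design, effects, seed=42)
        b1 = preprocess_branch1(sset, window=61)
        vc = variation_contribution(b1, REGIONS["polyphosphate"])
        assert vc["var_Pi"] > vc["var_N"] and vc["var_Pi"] > vc["var_int"]


class TestRegionPCA:
    def test_region_channel_count_matches_interval_oracle(self, study_biomass):
        sset, _ = study_biomass
        b1 = preprocess_branch1(sset, window=11)
        res = run_region_pca(b1, "lipid")
        region = REGIONS["lipid"]
        expected = sum(
            any(lo <= v <= hi for lo, hi in region.intervals)
            for v in b1.axis.values
        )
        for r in res.values():
            assert r.loadings.shape[1] == expected

    def test_results_carry_region_and_split_labels(self, study_biomass):
        sset, _ = study_biomass
        b1 = preprocess_branch1(sset, window=61)
        res = run_region_pca(b1, "polyphosphate")
        assert set(res) == {"YE", "AS"}
        for split, r in res.items():
            assert r.labels["region"] == "polyphosphate"
            assert r.labels["split"] == split
            assert r.labels["window_used"] == 61

    def test_single_strain_rank_one_structure_gives_pc1_one(self, rng):
        axis = WavenumberAxis.hts_default()
        region = REGIONS["lipid"]
        mask = region.mask(axis)
        direction = rng.normal(size=int(mask.sum()))
        matrix = np.zeros((6, len(axis)))
        matrix[:, mask] = np.outer(np.arange(6.0), direction)
        sset = _design_set(
            matrix, ["YE"], ["Pi1", "Pi2", "Pi4"], 2, axis_values=axis.values
        )
        res = run_region_pca(sset, "lipid")
        assert res["YE"].explained_variance_fraction[0] == pytest.approx(
            1.0, abs=1e-10
        )


class TestVariationTable:
    def test_rows_are_strains_times_regions(self, study_biomass):
        sset, _ = study_biomass
        b1 = preprocess_branch1(sset, window=11)
        vt = variation_table(b1, regions=("lipid", "chitin_chitosan"))
        assert len(vt) == 9 * 2
        sums = vt["var_N"] + vt["var_Pi"] + vt["var_int"]
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)
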