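"""Drift correction, roll-up, GIS normalization, CV QC, covariate regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.api as sm

from csfprm.normalize import (NormalizationError, apply_drift_correction,
                              compute_cv, drift_factors, gis_cv_table,
                              gis_normalize, regress_covariates,
                              rollup_protein)

from conftest import study_matrices


def ref_matrix(values):
    return pd.DataFrame(values,
                        index=[f"ref{i}" for i in range(len(values))],
                        columns=[f"inj{j}" for j in range(len(values[0]))])


class TestDriftFactors:
    def test_constant_references_give_unit_factors(self):
        refs = ref_matrix([[100.0] * 5, [200.0] * 5])
        factors = drift_factors(refs)
        assert np.allclose(factors, 1.0)
        data = pd.DataFrame(np.arange(10.0).reshape(2, 5) + 1,
                            columns=refs.columns)
        corrected = apply_drift_correction(data, factors)
        assert np.allclose(corrected, data)

    def test_doubled_injection_gets_factor_two(self):
        base = np.tile([100.0, 250.0], (7, 1)).T  # 2 refs x 7 injections
        base[:, 3] *= 2.0
        factors = drift_factors(ref_matrix(base))
        assert factors.iloc[3] == pytest.approx(2.0, rel=1e-12)
        others = factors.drop(factors.index[3])
        assert np.allclose(others, 1.0)

    def test_missing_reference_injection_is_an_error(self):
        refs = ref_matrix([[100.0, np.nan, 100.0], [90.0, np.nan, 90.0]])
        with pytest.raises(NormalizationError, match="inj1"):
            drift_factors(refs)

    def test_recovers_injected_drift(self, default_study):
        """Estimated per-injection factors track the simulated drift curve
        (rank correlation > 0.95 at the default reference noise)."""
        _, reference, _ = study_matrices(default_study)
        factors = drift_factors(reference)
        truth = default_study.injection_drift.reindex(factors.index)
        rho = sps.spearmanr(factors, truth).statistic
        assert rho > 0.95

    def test_second_pass_factors_are_constant_near_one(self, default_study):
        """Re-estimating factors on corrected data yields a single constant
        (no injection-to-injection structure left), close to 1."""
        _, reference, _ = study_matrices(default_study)
        factors = drift_factors(reference)
        corrected_refs = apply_drift_correction(reference, factors)
        refactors = drift_factors(corrected_refs)
        assert np.allclose(refactors, refactors.iloc[0], rtol=1e-9)
        assert abs(np.log(refactors.iloc[0])) < 0.05


class TestRollup:
    def test_single_peptide_protein_is_identity(self):
        peps = pd.DataFrame([[10.0, 20.0]], index=["p1"], columns=["a", "b"])
        mapping = pd.Series({"p1": "PROT"})
        out = rollup_protein(peps, mapping)
        assert np.allclose(out.loc["PROT"], [10.0, 20.0])

    def test_three_peptides_sum(self):
        peps = pd.DataFrame({"a": [10.0, 20.0, 30.0]},
                            index=["p1", "p2", "p3"])
        mapping = pd.Series("PROT", index=["p1", "p2", "p3"])
        assert rollup_protein(peps, mapping).loc["PROT", "a"] == 60.0

    def test_default_panel_rolls_up_to_41_proteins(self, default_cascade):
        assert len(default_cascade["proteins_raw"]) == 41

    def test_missing_peptides_excluded_not_zero_filled(self):
        peps = pd.DataFrame({"a": [10.0, np.nan], "b": [np.nan, np.nan]},
                            index=["p1", "p2"])
        mapping = pd.Series("PROT", index=["p1", "p2"])
        out = rollup_protein(peps, mapping)
        assert out.loc["PROT", "a"] == 10.0      # observed peptide only
        assert np.isnan(out.loc["PROT", "b"])    # no peptide observed

    def test_ambiguous_peptide_mapping_is_an_error(self):
        peps = pd.DataFrame({"a": [1.0]}, index=["p1"])
        mapping = pd.Series(["A", "B"], index=["p1", "p1"])
        with pytest.raises(NormalizationError, match="more than one"):
            rollup_protein(peps, mapping)


class TestGisNormalize:
    def test_per_batch_gis_mean_is_exactly_one(self, default_cascade,
                                               default_study):
        ratios = default_cascade["proteins_ratio"]
        meta = default_study.metadata.set_index("sample_id")
        for b, sub in meta[meta["group"] == "GIS"].groupby("batch"):
            batch_mean = ratios[sub.index].mean(axis=1)
            assert np.allclose(batch_mean, 1.0, atol=1e-10)

    def test_value_equal_to_batch_mean_maps_to_one(self):
        mat = pd.DataFrame({"g1": [4.0], "g2": [6.0], "s1": [5.0]},
                           index=["PROT"])
        meta = pd.DataFrame({"sample_id": ["g1", "g2", "s1"],
                             "group": ["GIS", "GIS", "AD"],
                             "batch": [1, 1, 1]})
        out = gis_normalize(mat, meta)
        assert out.loc["PROT", "s1"] == pytest.approx(1.0)

    def test_batch_scale_shift_is_removed(self, default_cascade, default_study):
        """Multiplying one batch by 2x changes nothing after per-batch GIS
        normalization."""
        proteins = default_cascade["proteins_raw"]
        meta = default_study.metadata.set_index("sample_id")
        shifted = proteins.copy()
        b2 = meta.index[meta["batch"] == 2]
        shifted[b2] = shifted[b2] * 2.0
        a = gis_normalize(proteins, default_study.metadata)
        b = gis_normalize(shifted, default_study.metadata)
        pd.testing.assert_frame_equal(a, b)

    def test_idempotent(self, default_cascade, default_study):
        ratios = default_cascade["proteins_ratio"]
        again = gis_normalize(ratios, default_study.metadata)
        assert np.allclose(again.values.astype(float),
                           ratios.values.astype(float))

    def test_batch_without_gis_is_an_error(self):
        mat = pd.DataFrame({"g1": [4.0], "s1": [5.0]}, index=["PROT"])
        meta = pd.DataFrame({"sample_id": ["g1", "s1"],
                             "group": ["GIS", "AD"], "batch": [1, 2]})
        with pytest.raises(NormalizationError, match="batch 2"):
            gis_normalize(mat, meta)

    def test_global_variant(self):
        mat = pd.DataFrame({"g1": [4.0], "g2": [8.0], "s1": [3.0]},
                           index=["PROT"])
        meta = pd.DataFrame({"sample_id": ["g1", "g2", "s1"],
                             "group": ["GIS", "GIS", "AD"],
                             "batch": [1, 2, 1]})
        out = gis_normalize(mat, meta, per_batch=False)
        assert out.loc["PROT", "s1"] == pytest.approx(0.5)


class TestComputeCv:
    def test_identical_replicates_zero(self):
        assert compute_cv([7.0, 7.0, 7.0]) == 0.0

    def test_textbook_example(self):
        # sample SD of {90, 100, 110} is 10, mean 100 -> 10%
        assert compute_cv([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_degenerate_inputs_are_nan(self):
        assert np.isnan(compute_cv([5.0]))
        assert np.isnan(compute_cv([1.0, -3.0]))  # non-positive mean

    def test_precision_flag_threshold(self, default_cascade, default_study):
        tab = gis_cv_table(default_cascade["proteins_ratio"],
                           default_study.metadata)
        assert ((tab["cv_pct"] <= 30.0) == tab["high_precision"]).all()


class TestRegressCovariates:
    @staticmethod
    def _meta(n, rng):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "group": "AD",
            "age": rng.uniform(55, 85, n),
            "sex": rng.integers(0, 2, n),
        })

    def test_null_covariates_reduce_to_centering(self):
        """A constant protein vector regresses to exactly zero."""
        rng = np.random.default_rng(0)
        meta = self._meta(20, rng)
        mat = pd.DataFrame([[3.0] * 20], index=["PROT"],
                           columns=meta["sample_id"])
        out = regress_covariates(mat, meta)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_pure_age_effect_regresses_to_zero(self):
        rng = np.random.default_rng(1)
        meta = self._meta(30, rng)
        mat = pd.DataFrame([0.05 * meta["age"].to_numpy()], index=["PROT"],
                           columns=meta["sample_id"])
        out = regress_covariates(mat, meta)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_matches_statsmodels_ols_residuals(self):
        """Residuals agree with an independent statsmodels OLS fit."""
        rng = np.random.default_rng(2)
        meta = self._meta(40, rng)
        y = (0.03 * meta["age"].to_numpy() + 0.4 * meta["sex"].to_numpy()
             + rng.normal(0, 0.5, 40))
        mat = pd.DataFrame([y], index=["PROT"], columns=meta["sample_id"])
        out = regress_covariates(mat, meta)
        X = sm.add_constant(meta[["age", "sex"]].to_numpy(float))
        resid = sm.OLS(y, X).fit().resid
        assert np.allclose(out.loc["PROT"].to_numpy(), resid - resid.mean(),
                           atol=1e-10)

    def test_zero_mean_and_covariate_orthogonality(self, default_cascade,
                                                   default_study):
        out = default_cascade["proteins_regressed"]
        meta = default_study.metadata.set_index("sample_id")
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-10)
        age = meta.loc[out.columns, "age"].to_numpy(float)
        sex = meta.loc[out.columns, "sex"].to_numpy(float)
        for cov in (age, sex):
            c = out.to_numpy() @ (cov - cov.mean()) / len(cov)
            assert np.allclose(c, 0.0, atol=1e-10)

    def test_idempotent(self, default_cascade, default_study):
        out = default_cascade["proteins_regressed"]
        again = regress_covariates(out, default_study.metadata)
        assert np.allclose(again, out, atol=1e-10)

    def test_single_sex_cohort_drops_covariate_with_warning(self):
        rng = np.random.default_rng(3)
        meta = self._meta(15, rng)
        meta["sex"] = 1
        mat = pd.DataFrame([rng.normal(0, 1, 15)], index=["PROT"],
                           columns=meta["sample_id"])
        with pytest.warns(UserWarning, match="sex"):
            out = regress_covariates(mat, meta)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_gis_columns_rejected(self, default_cascade, default_study):
        log2 = default_cascade["proteins_log2"]
        meta = default_study.metadata.copy()
        gis_col = meta.loc[meta["group"] == "GIS", "sample_id"].iloc[0]
        bad = log2.copy()
        bad[gis_col] = 0.0
        with pytest.raises(NormalizationError, match="GIS"):
            regress_covariates(bad, meta)


class TestCascadeQc:
    def test_drift_correction_reduces_mean_gis_cv(self, default_cascade,
                                                  default_study):
        """On the default study (drift on) mean peptide GIS CV strictly
        decreases after reference normalization."""
        pre = gis_cv_table(default_cascade["peptides_raw"],
                           default_study.metadata)["cv_pct"].mean()
        post = gis_cv_table(default_cascade["peptides_corrected"],
                            default_study.metadata)["cv_pct"].mean()
        assert post < pre
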