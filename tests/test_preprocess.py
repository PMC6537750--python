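"""Normalization pipeline: outlier flagging, sample QC, KNN imputation,
standardization, residualization, and composite idempotence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from brainclock import synth
from brainclock.preprocess import (
    CovariateSpec,
    ImputePolicy,
    OutlierPolicy,
    drop_outlier_samples,
    flag_outliers,
    knn_impute,
    preprocess_cohort,
    residualize_covariates,
    standardize,
)


def _mat(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{i}" for i in range(arr.shape[1])],
    )


class TestFlagOutliers:
    def test_five_samples_cannot_be_flagged(self):
        # leave-in |z| is bounded by (n-1)/sqrt(n) = 1.789 < 4 at n=5,
        # however extreme the value
        m = _mat([[0.0, 0.0, 0.0, 0.0, 1e9]])
        mask = flag_outliers(m, OutlierPolicy())
        assert not mask.to_numpy().any()

    def test_constant_gene_never_flagged(self):
        m = _mat(np.ones((3, 10)))
        assert not flag_outliers(m, OutlierPolicy()).to_numpy().any()

    def test_injected_outliers_all_flagged_low_false_rate(self):
        cfg = synth.SimConfig(
            n_genes=2000, n_up=0, n_down=0,
            cohorts=(synth.CohortSpec("a", 200, (25.0, 97.0)),),
            nuisance_effects={}, seed=21,
        )
        mats, _, _ = synth.generate_multi_cohort(cfg)
        corrupted, truth_mask = synth.inject_outliers(mats[0], 0.002, 10, 22)
        mask = flag_outliers(corrupted, OutlierPolicy())
        tm, fm = truth_mask.to_numpy(), mask.to_numpy()
        assert fm[tm].all()  # every 10-SD injection caught
        false_rate = fm[~tm].sum() / (~tm).sum()
        assert false_rate < 1e-4  # Normal tail P(|z|>4) ~ 6.3e-5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            flag_outliers(_mat([[1.0, 2.0]]), OutlierPolicy())


class TestDropOutlierSamples:
    def test_no_flags_no_drops(self):
        m = _mat(np.arange(12.0).reshape(3, 4))
        mask = pd.DataFrame(False, index=m.index, columns=m.columns)
        out, dropped = drop_outlier_samples(m, mask, OutlierPolicy())
        assert dropped == [] and out.equals(m)

    def test_threshold_logic_exact(self):
        m = _mat(np.zeros((10, 4)))
        mask = pd.DataFrame(False, index=m.index, columns=m.columns)
        mask.iloc[0, 1] = True  # 10% of genes flagged in sample s1
        out, dropped = drop_outlier_samples(
            m, mask, OutlierPolicy(max_outlier_fraction=0.05)
        )
        assert dropped == ["s1"]
        assert list(out.columns) == ["s0", "s2", "s3"]

    def test_shifted_sample_is_unique_drop(self):
        rng = np.random.default_rng(33)
        x = rng.normal(0, 1, (400, 100))
        x[:, 17] += 6.0  # one sample shifted +6 SD on every gene
        m = _mat(x)
        mask = flag_outliers(m, OutlierPolicy())
        _, dropped = drop_outlier_samples(m, mask, OutlierPolicy())
        assert dropped == ["s17"]

    def test_all_dropped_is_hard_error(self):
        m = _mat(np.zeros((2, 3)))
        mask = pd.DataFrame(True, index=m.index, columns=m.columns)
        with pytest.raises(ValueError, match="all samples"):
            drop_outlier_samples(m, mask, OutlierPolicy())


class TestKnnImpute:
    def test_duplicate_neighbor_exact(self):
        m = _mat([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0], [7.5, np.nan, 1.0]])
        out = knn_impute(m, ImputePolicy(k=1))
        assert out.iloc[2, 1] == 7.5  # s0 duplicates s1 on observed genes

    def test_nearest_neighbor_hand_case(self):
        # A=(1,2,3), B=(1,2,?), C=(10,10,10): A is B's nearest -> impute 3
        m = _mat(
            np.array([[1, 1, 10], [2, 2, 10], [3, np.nan, 10]], dtype=float),
            samples=["A", "B", "C"],
        )
        out = knn_impute(m, ImputePolicy(k=1))
        assert out.loc["g2", "B"] == 3.0

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (50, 30))
        miss = rng.random(x.shape) < 0.02
        xm = x.copy()
        xm[miss] = np.nan
        out = knn_impute(_mat(xm), ImputePolicy(k=5))
        assert (out.to_numpy()[~miss] == x[~miss]).all()

    def test_imputation_error_below_noise(self):
        """Masking 1% of a smooth (age-driven) matrix: imputed entries land
        closer to the underlying noise-free signal than one noise SD (the
        noisy realization itself is unpredictable to better than noise_sd)."""
        kwargs = dict(
            n_genes=400, n_up=200, n_down=200, slope_scale=0.1,
            nuisance_effects={}, cohorts=(synth.CohortSpec("a", 120, (25.0, 97.0)),),
            seed=17,
        )
        noisy, _, _ = synth.generate_multi_cohort(synth.SimConfig(noise_sd=0.5, **kwargs))
        signal, _, _ = synth.generate_multi_cohort(synth.SimConfig(noise_sd=0.0, **kwargs))
        rng = np.random.default_rng(18)
        miss = rng.random(noisy[0].shape) < 0.01
        masked = noisy[0].mask(pd.DataFrame(miss, index=noisy[0].index, columns=noisy[0].columns))
        out = knn_impute(masked, ImputePolicy(k=10))
        rmse = np.sqrt(np.mean((out.to_numpy()[miss] - signal[0].to_numpy()[miss]) ** 2))
        assert rmse < 0.5

    def test_all_missing_sample_rejected(self):
        m = _mat([[np.nan, 1.0, 2.0], [np.nan, 3.0, 4.0]])
        with pytest.raises(ValueError, match="all entries missing"):
            knn_impute(m, ImputePolicy(k=1))


class TestStandardize:
    def test_unit_moments(self):
        rng = np.random.default_rng(2)
        out = standardize(_mat(rng.normal(3, 7, (20, 40))))
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_constant_gene_dropped_with_warning(self):
        m = _mat([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize(m)
        assert list(out.index) == ["g1"]

    @given(
        arrays(
            np.float64, (5, 8),
            elements=st.floats(-100, 100, allow_nan=False),
        ).filter(lambda a: (a.std(axis=1) > 1e-3).all())
    )
    def test_idempotent(self, arr):
        once = standardize(_mat(arr))
        twice = standardize(once)
        assert np.abs(twice.to_numpy() - once.to_numpy()).max() < 1e-12


class TestResidualize:
    def test_empty_spec_mean_centers(self):
        rng = np.random.default_rng(3)
        m = _mat(rng.normal(5, 2, (10, 20)))
        samples = pd.DataFrame(index=m.columns)
        out = residualize_covariates(m, samples, CovariateSpec())
        expected = m.sub(m.mean(axis=1), axis=0)
        assert np.abs(out - expected).to_numpy().max() < 1e-10

    def test_perfectly_explained_gene_zeroed(self):
        rin = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 6.5])
        m = _mat((5 * rin)[None, :])
        samples = pd.DataFrame({"rin": rin}, index=m.columns)
        out = residualize_covariates(m, samples, CovariateSpec(("rin",)))
        assert np.abs(out.to_numpy()).max() < 1e-10

    def test_residuals_orthogonal_to_design(self, small_sim):
        _, (mats, samples, _) = small_sim
        std = standardize(mats[0])
        out = residualize_covariates(
            std, samples, CovariateSpec(("rin", "sex", "pmi", "batch"))
        )
        rin = samples.loc[out.columns, "rin"].to_numpy(float)
        rin = rin - rin.mean()
        corr = out.to_numpy() @ rin / (np.linalg.norm(rin) * np.linalg.norm(out, axis=1))
        assert np.abs(corr).max() < 1e-10

    def test_projection_applied_twice_equals_once(self, small_sim):
        _, (mats, samples, _) = small_sim
        spec = CovariateSpec(("rin", "sex"))
        once = residualize_covariates(mats[0], samples, spec)
        twice = residualize_covariates(once, samples, spec)
        assert np.abs(twice - once).to_numpy().max() < 1e-10

    def test_age_refused_as_covariate(self):
        with pytest.raises(ValueError, match="age"):
            CovariateSpec(("rin", "age"))

    def test_rank_deficient_design_names_columns(self):
        rin = np.array([5.0, 6.0, 7.0, 8.0])
        samples = pd.DataFrame({"rin": rin, "rin2": 2 * rin}, index=[f"s{i}" for i in range(4)])
        m = _mat(np.ones((2, 4)) * np.arange(4))
        with pytest.raises(ValueError, match="collinear.*rin"):
            residualize_covariates(m, samples, CovariateSpec(("rin", "rin2")))


class TestFullPipeline:
    def test_composite_idempotence(self):
        cfg = synth.SimConfig(
            n_genes=150, n_up=20, n_down=20,
            cohorts=(synth.CohortSpec("a", 60, (25.0, 97.0)),), seed=5,
        )
        mats, samples, _ = synth.generate_multi_cohort(cfg)
        corrupted, _ = synth.inject_outliers(mats[0], 0.005, 8, 6)
        spec = CovariateSpec(("rin", "sex"))
        c1, _ = preprocess_cohort(corrupted, samples, spec)
        c2, _ = preprocess_cohort(c1, samples, spec)
        assert np.abs(c2 - c1.loc[c2.index]).to_numpy().max() < 1e-8

    def test_cleaning_improves_held_out_prediction(self):
        """With strong nuisance structure (RIN/batch loadings on the order
        of the noise), residualizing improves the held-out clock R versus
        training on merely standardized data."""
        from brainclock import clock

        cfg = synth.SimConfig(
            n_genes=300, n_up=40, n_down=40,
            nuisance_effects={"rin": 1.0, "sex": 0.5, "pmi": 0.5, "batch": 1.0},
            cohorts=(
                synth.CohortSpec("a", 100, (25.0, 97.0)),
                synth.CohortSpec("b", 100, (25.0, 90.0)),
            ),
            seed=42,
        )
        mats, samples, _ = synth.generate_multi_cohort(cfg)
        ages = samples["age"]
        spec = CovariateSpec(("rin", "sex", "pmi", "batch"))
        rs = {}
        for label, prep in {
            "cleaned": lambda m: preprocess_cohort(m, samples, spec)[0],
            "raw": lambda m: standardize(m),
        }.items():
            tr, va = prep(mats[0]), prep(mats[1])
            fit = clock.train_clock(
                tr, ages, va, ages,
                hyper=clock.ClockHyperparams((0.01,), (10.0, 99.0)),
                fallback_top_k=50,
            )
            rs[label] = fit.valid_r
        assert rs["cleaned"] > rs["raw"]
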