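import numpy as np
import pytest

from selstab.datasets import (
    BINARY,
    CONTINUOUS,
    ConfigurationError,
    Dataset,
    SyntheticSpec,
    default_study_spec,
    expand_polynomials,
    generate_dataset,
    standardize_two_sd,
)


def _simple_spec(**overrides):
    base = dict(
        n_subjects=200,
        n_covariates=6,
        block_sizes=(3, 3),
        within_block_correlation=0.5,
        binary_fraction=0.0,
        true_support=(1,),
        true_coefficients=(10.0,),
        noise_sd=1.0,
        seed=3,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


class TestSyntheticSpec:
    def test_block_sizes_must_partition_covariates(self):
        with pytest.raises(ConfigurationError):
            _simple_spec(block_sizes=(3, 2))

    def test_support_and_coefficients_must_align(self):
        with pytest.raises(ConfigurationError):
            _simple_spec(true_support=(1, 2))

    def test_duplicate_support_rejected(self):
        with pytest.raises(ConfigurationError):
            _simple_spec(true_support=(1, 1), true_coefficients=(1.0, 2.0))

    def test_noise_sd_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            _simple_spec(noise_sd=0.0)


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        a = generate_dataset(_simple_spec())
        b = generate_dataset(_simple_spec())
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_noiseless_limit_recovers_true_coefficient(self):
        ds = generate_dataset(_simple_spec(noise_sd=1e-9))
        x = ds.X[:, 1]
        beta = float(np.sum(x * (ds.y - ds.y.mean())) / np.sum(x * x))
        assert abs(beta - 10.0) < 1e-3
        resid = ds.y - ds.y.mean() - beta * x
        assert 1 - np.sum(resid**2) / np.sum((ds.y - ds.y.mean()) ** 2) > 0.999

    def test_study_scale_dimensions(self):
        ds = generate_dataset(default_study_spec(seed=0))
        assert ds.n == 408
        assert ds.p >= 337

    def test_equicorrelation_structure_at_large_n(self):
        spec = SyntheticSpec(
            n_subjects=5000,
            n_covariates=10,
            block_sizes=(10,),
            within_block_correlation=0.8,
            binary_fraction=0.0,
            true_support=(0,),
            true_coefficients=(1.0,),
            noise_sd=1.0,
            seed=5,
        )
        ds = generate_dataset(spec)
        corr = np.corrcoef(ds.X, rowvar=False)
        off = corr[np.triu_indices(10, k=1)]
        assert 0.75 < off.mean() < 0.85

    def test_binary_fraction_materialises(self):
        spec = _simple_spec(binary_fraction=0.5, n_covariates=10,
                            block_sizes=(5, 5))
        ds = generate_dataset(spec)
        assert ds.covariate_kind.count(BINARY) == 5


class TestSignalPlausibility:
    def test_true_support_ols_attains_the_target_cv_r2_band(self):
        """Under the default study-emulating configuration, OLS on the true
        support cross-validates in the R-squared band of the motivating
        study's best models."""
        from selstab.stability import refit_subset_cv

        spec = default_study_spec(seed=0)
        ds = generate_dataset(spec)
        ids = [f"V{j + 1}" for j in spec.true_support]
        cv = refit_subset_cv(ds, ids, k=10, repeats=2, seed=0)
        assert 0.55 <= cv.cv_r2 <= 0.75


class TestStandardizeTwoSd:
    def test_continuous_column_mean_zero_sd_half(self):
        ds = Dataset(
            X=np.array([[0.0], [2.0], [4.0], [6.0]]),
            y=np.zeros(4),
            covariate_ids=["V1"],
            covariate_kind=[CONTINUOUS],
        )
        out = standardize_two_sd(ds)
        assert abs(out.X[:, 0].mean()) < 1e-12
        assert abs(np.std(out.X[:, 0], ddof=1) - 0.5) < 1e-12

    def test_idempotent(self, small_ds):
        again = standardize_two_sd(small_ds)
        assert np.max(np.abs(again.X - small_ds.X)) < 1e-12

    def test_standardization_contract_all_continuous_columns(self, small_ds):
        cont = [k in (CONTINUOUS, "polynomial_term") for k in small_ds.covariate_kind]
        Xc = small_ds.X[:, cont]
        assert np.max(np.abs(Xc.mean(axis=0))) < 1e-10
        assert np.max(np.abs(np.std(Xc, axis=0, ddof=1) - 0.5)) < 1e-10

    def test_binary_centred_not_rescaled(self):
        x = np.array([1.0, 0, 0, 1, 0, 0, 0, 0, 0, 1])  # mean 0.3
        ds = Dataset(
            X=x[:, None], y=np.zeros(10), covariate_ids=["V1"],
            covariate_kind=[BINARY],
        )
        out = standardize_two_sd(ds)
        assert set(np.round(out.X[:, 0], 10)) == {-0.3, 0.7}

    def test_zero_variance_continuous_dropped(self, caplog):
        ds = Dataset(
            X=np.column_stack([np.ones(5), np.arange(5.0)]),
            y=np.zeros(5),
            covariate_ids=["V1", "V2"],
            covariate_kind=[CONTINUOUS, CONTINUOUS],
        )
        out = standardize_two_sd(ds)
        assert out.covariate_ids == ["V2"]


class TestExpandPolynomials:
    def test_three_columns_appended_for_power_four(self, rng):
        ds = Dataset(
            X=rng.standard_normal((50, 2)),
            y=np.zeros(50),
            covariate_ids=["V1", "V2"],
            covariate_kind=[CONTINUOUS, CONTINUOUS],
        )
        out = expand_polynomials(ds, ["V1"], max_power=4)
        assert out.p == 5
        assert out.covariate_ids[-3:] == ["V1^2", "V1^3", "V1^4"]
        assert out.parent_and_power("V1^3") == ("V1", 3)

    def test_square_nearly_uncorrelated_with_symmetric_parent(self, rng):
        x = rng.standard_normal(10_000)
        ds = Dataset(
            X=x[:, None], y=np.zeros(10_000), covariate_ids=["V1"],
            covariate_kind=[CONTINUOUS],
        )
        out = expand_polynomials(standardize_two_sd(ds), ["V1"], max_power=2)
        r = np.corrcoef(out.X[:, 0], out.X[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_empty_request_is_identity(self, small_ds):
        out = expand_polynomials(small_ds, [], max_power=4)
        assert out is small_ds

    def test_binary_covariate_rejected(self):
        ds = Dataset(
            X=np.array([[0.0], [1.0], [0.0], [1.0]]),
            y=np.zeros(4),
            covariate_ids=["V1"],
            covariate_kind=[BINARY],
        )
        with pytest.raises(ConfigurationError):
            expand_polynomials(ds, ["V1"])


class TestCsvRoundTrip:
    def test_csv_round_trip_preserves_data_and_metadata(self, small_ds, tmp_path):
        path = tmp_path / "data.csv"
        small_ds.to_csv(path)
        back = Dataset.from_csv(path)
        assert np.allclose(back.X, small_ds.X)
        assert np.allclose(back.y, small_ds.y)
        assert back.covariate_ids == small_ds.covariate_ids
        assert back.covariate_kind == small_ds.covariate_kind
        assert back.truth == small_ds.truth

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("y,V1\n1.0,2.0\n2.0,\n")
        with pytest.raises(ConfigurationError):
            Dataset.from_csv(path)
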