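"""Phenotype preparation and per-metabolite linear models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metabometa.cohort import (
    CohortDataset,
    compute_homa_ir,
    exclude_outliers,
    fit_full,
    fit_univariate,
    log_transform,
    percent_change,
    prepare_cohort,
)
from metabometa.errors import DataError, DomainError, SchemaError

from _oracles import ols_oracle


def _dataset(pheno, abundance, name="C", log_scale=True):
    ann = pd.DataFrame(index=abundance.columns)
    return CohortDataset(
        name=name, phenotypes=pheno, abundance=abundance,
        annotation=ann, log_scale=log_scale,
    )


def _basic_pheno(n, y, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "homa_ir_baseline": 2.0,
            "pct_change_homa_ir": y,
            "age": rng.normal(55, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["AA", "EA"], n),
            "triglycerides_baseline": rng.normal(130, 40, n),
            "pct_change_weight": rng.normal(-8, 3, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestHomaIr:
    def test_mass_convention_constant_cancels(self):
        assert compute_homa_ir(405.0, 1.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert compute_homa_ir(100.0, 10.0) == pytest.approx(1000.0 / 405.0)

    def test_molar_convention(self):
        assert compute_homa_ir(5.0, 9.0, convention="molar") == pytest.approx(2.0)

    @pytest.mark.parametrize("glucose,insulin", [(0.0, 5.0), (100.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, glucose, insulin):
        with pytest.raises(DomainError):
            compute_homa_ir(glucose, insulin)


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,followup,expected", [(4.0, 1.0, -75.0), (2.0, 2.0, 0.0), (2.0, 3.0, 50.0)]
    )
    def test_arithmetic(self, baseline, followup, expected):
        assert percent_change(baseline, followup) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)


class TestOutlierExclusion:
    def test_hand_computed_rule(self):
        # mean 20, SD sqrt(2000)=44.72; |100-20| = 80 < 5*44.72 -> keep all
        pheno = _basic_pheno(5, [0.0, 0.0, 0.0, 0.0, 100.0])
        kept, excluded = exclude_outliers(pheno, k=5.0)
        assert excluded == [] and len(kept) == 5
        # with k chosen below 80/44.72 the same point is excluded
        kept, excluded = exclude_outliers(pheno, k=1.5)
        assert excluded == ["s4"]

    def test_all_equal_values_excludes_none(self):
        pheno = _basic_pheno(5, [3.0] * 5)
        kept, excluded = exclude_outliers(pheno)
        assert excluded == [] and len(kept) == 5

    def test_single_pass_no_reiteration(self):
        # after removing the gross outlier the next point would become >5 SD,
        # but the rule uses pre-exclusion moments only once
        y = [0.0] * 50 + [10.0, 400.0]
        pheno = _basic_pheno(52, y)
        kept, excluded = exclude_outliers(pheno)
        assert excluded == ["s51"]
        assert "s50" in kept.index

    def test_too_few_finite_outcomes(self):
        pheno = _basic_pheno(3, [1.0, np.nan, np.nan])
        with pytest.raises(DataError):
            exclude_outliers(pheno)


class TestLogTransform:
    def test_zeros_become_missing_and_count_as_zeroness(self):
        raw = pd.DataFrame({"m1": [np.e, 0.0, 1.0, np.nan]})
        logged, stats = log_transform(raw)
        assert logged["m1"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(logged["m1"].iloc[1])
        assert stats.loc["m1", "zeroness"] == pytest.approx(0.25)
        assert stats.loc["m1", "missingness"] == pytest.approx(0.25)

    def test_log_scale_passthrough(self):
        raw = pd.DataFrame({"m1": [-3.0, 2.0]})
        logged, stats = log_transform(raw, already_log=True)
        pd.testing.assert_frame_equal(logged, raw.astype(float))
        assert stats.loc["m1", "zeroness"] == 0.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(DataError):
            log_transform(pd.DataFrame({"m1": [-1.0, 2.0]}))


class TestUnivariateFit:
    def test_noiseless_line_recovered_exactly(self):
        n = 10
        x = np.linspace(0, 3, n)
        pheno = _basic_pheno(n, -10.0 * x + 3.0)
        ds = _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index))
        res = fit_univariate(ds, "m")
        assert res.beta == pytest.approx(-10.0, abs=1e-9)
        assert res.se == pytest.approx(0.0, abs=1e-6)
        assert res.n == n

    def test_matches_normal_equations_oracle(self, regression_fixture):
        df = regression_fixture
        pheno = _basic_pheno(len(df), df["y"].to_numpy())
        ds = _dataset(pheno, pd.DataFrame({"m": df["x"].to_numpy()}, index=pheno.index))
        res = fit_univariate(ds, "m")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta, se, p = ols_oracle(X, df["y"].to_numpy())
        assert res.beta == pytest.approx(beta[1], rel=1e-10)
        assert res.se == pytest.approx(se[1], rel=1e-10)
        assert res.p == pytest.approx(p[1], rel=1e-10)

    def test_constant_metabolite_is_skip_signal(self):
        pheno = _basic_pheno(8, np.arange(8.0))
        ds = _dataset(pheno, pd.DataFrame({"m": np.ones(8)}, index=pheno.index))
        assert fit_univariate(ds, "m") is None

    def test_complete_case_count_varies_with_missingness(self):
        pheno = _basic_pheno(10, np.arange(10.0))
        x = np.arange(10.0)
        x[:3] = np.nan
        ds = _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index))
        assert fit_univariate(ds, "m").n == 7

    def test_closed_form_slope_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        pheno = _basic_pheno(40, y)
        ds = _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index))
        res = fit_univariate(ds, "m")
        expected = np.corrcoef(x, y)[0, 1] * y.std(ddof=1) / x.std(ddof=1)
        assert res.beta == pytest.approx(expected, rel=1e-10)

    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        shift=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_equivariance_of_slope(self, scale, shift):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        pheno = _basic_pheno(30, y)
        base = fit_univariate(
            _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index)), "m"
        )
        moved = fit_univariate(
            _dataset(pheno, pd.DataFrame({"m": scale * x + shift}, index=pheno.index)),
            "m",
        )
        assert moved.beta == pytest.approx(base.beta / scale, rel=1e-8)
        assert moved.se == pytest.approx(base.se / scale, rel=1e-8)
        assert moved.p == pytest.approx(base.p, rel=1e-8)


class TestFullModelFit:
    def test_confounder_adjustment_matches_oracle(self, regression_fixture):
        df = regression_fixture
        n = len(df)
        rng = np.random.default_rng(1)
        pheno = _basic_pheno(n, df["y"].to_numpy(), rng)
        pheno["age"] = df["c"].to_numpy() * 4 + 50  # confounder enters via age
        ds = _dataset(pheno, pd.DataFrame({"m": df["x"].to_numpy()}, index=pheno.index))
        res = fit_full(ds, "m")
        # oracle design mirrors the documented encoding (largest level ref)
        sex_ref = pheno["sex"].value_counts().index[0]
        race_ref = pheno["race"].value_counts().index[0]
        cols = [
            np.ones(n), df["x"], pheno["age"], pheno["triglycerides_baseline"],
            pheno["pct_change_weight"],
        ]
        cols += [(pheno["sex"] == lv).astype(float)
                 for lv in sorted(set(pheno["sex"]) - {sex_ref})]
        cols += [(pheno["race"] == lv).astype(float)
                 for lv in sorted(set(pheno["race"]) - {race_ref})]
        beta, se, p = ols_oracle(np.column_stack(cols), df["y"].to_numpy())
        assert res.beta == pytest.approx(beta[1], rel=1e-10)
        assert res.se == pytest.approx(se[1], rel=1e-10)
        assert res.p == pytest.approx(p[1], rel=1e-10)

    def test_independent_covariates_leave_beta_close_to_univariate(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = -4.0 * x + rng.normal(scale=2.0, size=n)
        pheno = _basic_pheno(n, y, rng)
        ds = _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index))
        uni = fit_univariate(ds, "m")
        full = fit_full(ds, "m")
        assert abs(full.beta - uni.beta) < 2 * uni.se

    def test_single_level_race_dropped_automatically(self):
        rng = np.random.default_rng(4)
        n = 30
        x = rng.normal(size=n)
        pheno = _basic_pheno(n, 2 * x + rng.normal(size=n), rng)
        pheno["race"] = "AA"
        ds = _dataset(pheno, pd.DataFrame({"m": x}, index=pheno.index))
        res = fit_full(ds, "m")
        assert res is not None and res.n == n


class TestPrepareCohort:
    def test_derives_pct_change_and_applies_pipeline(self):
        rng = np.random.default_rng(9)
        n = 40  # one displaced subject exceeds 5 SD only for n > ~27
        pheno = _basic_pheno(n, np.zeros(n), rng).drop(columns="pct_change_homa_ir")
        pheno["homa_ir_followup"] = pheno["homa_ir_baseline"] * np.concatenate(
            [1 + rng.normal(0, 0.1, n - 1), [200.0]]
        )
        raw = pd.DataFrame({"m": np.exp(rng.normal(size=n))}, index=pheno.index)
        ds = CohortDataset(
            name="C", phenotypes=pheno, abundance=raw,
            annotation=pd.DataFrame(index=["m"]), log_scale=False,
        )
        prepared = prepare_cohort(ds)
        assert prepared.log_scale
        assert prepared.excluded_subjects == [f"s{n - 1}"]
        assert prepared.n_samples == n - 1
        assert "pct_change_homa_ir" in prepared.phenotypes

    def test_mismatched_sample_ids_rejected(self):
        pheno = _basic_pheno(5, np.zeros(5))
        raw = pd.DataFrame({"m": np.ones(5)}, index=[f"x{i}" for i in range(5)])
        with pytest.raises(SchemaError):
            CohortDataset(name="C", phenotypes=pheno, abundance=raw,
                          annotation=pd.DataFrame(index=["m"]))
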