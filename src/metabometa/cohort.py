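"""Per-cohort phenotype preparation and per-metabolite linear models.

The outcome of interest is the percent change in HOMA-IR (Homeostatic Model
Assessment of Insulin Resistance) over a weight-loss intervention.  Within
each cohort, every metabolite is regressed against that outcome in two model
forms:

``univariate``
    %ΔHOMA-IR ~ intercept + log(metabolite)

``full``
    %ΔHOMA-IR ~ intercept + log(metabolite) + age + sex + race
    + baseline clinical triglycerides + percent change in weight

Abundances enter the models as the natural log of the LC-MS peak area;
subjects whose outcome lies more than ``k`` (default 5) standard deviations
from the cohort mean are excluded once, before any model is fit.  All fits
are complete-case per metabolite, so the effective ``n`` varies across
metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from metabometa.errors import DataError, DegenerateDesignError, DomainError, SchemaError

#: covariates entering the "full" (covariate-adjusted) model
FULL_COVARIATES = ("age", "sex", "race", "triglycerides_baseline", "pct_change_weight")

#: phenotype columns every cohort table must provide
REQUIRED_PHENOTYPES = (
    "homa_ir_baseline",
    "pct_change_homa_ir",
    "age",
    "sex",
    "race",
    "triglycerides_baseline",
    "pct_change_weight",
)


@dataclass
class CohortDataset:
    """One cohort: phenotype table, abundance matrix and metabolite annotation.

    ``abundance`` is samples × metabolites; its index must equal the
    phenotype index.  ``log_scale`` records whether the matrix already holds
    natural-log values (the scale the models consume).  ``abundance_stats``
    holds per-metabolite ``missingness`` and ``zeroness`` fractions computed
    from the raw matrix by :func:`log_transform`.
    """

    name: str
    phenotypes: pd.DataFrame
    abundance: pd.DataFrame
    annotation: pd.DataFrame
    log_scale: bool = False
    abundance_stats: pd.DataFrame | None = None
    excluded_subjects: list = field(default_factory=list)

    def __post_init__(self):
        if not self.phenotypes.index.is_unique:
            raise SchemaError(f"cohort {self.name}: duplicate subject ids")
        if not self.abundance.index.equals(self.phenotypes.index):
            missing = self.abundance.index.difference(self.phenotypes.index)
            raise SchemaError(
                f"cohort {self.name}: abundance/phenotype sample ids differ "
                f"(e.g. {list(missing[:3])!r} absent from phenotypes)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.phenotypes)

    @property
    def metabolites(self) -> pd.Index:
        return self.abundance.columns


@dataclass(frozen=True)
class RegressionResult:
    """Per-metabolite, per-cohort effect estimate from one model form.

    ``beta`` is in percent-change-of-HOMA-IR units per natural-log unit of
    metabolite abundance; ``n`` is the complete-case count.
    """

    metabolite: str
    cohort: str
    model_form: str
    beta: float
    se: float
    n: int
    p: float


def compute_homa_ir(glucose, insulin, convention: str = "mass"):
    """HOMA-IR from fasting glucose and insulin.

    Parameters
    ----------
    glucose : scalar or array
        Fasting glucose, mg/dL under the ``"mass"`` convention (the US
        clinical unit) or mmol/L under ``"molar"``.
    insulin : scalar or array
        Fasting insulin, µU/mL.
    convention : {"mass", "molar"}
        Denominator constant: 405 for mg/dL glucose, 22.5 for mmol/L.
    """
    if convention == "mass":
        denom = 405.0
    elif convention == "molar":
        denom = 22.5
    else:
        raise ValueError(f"unknown HOMA-IR convention {convention!r}")
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise DomainError("glucose and insulin must be strictly positive")
    out = g * i / denom
    return float(out) if out.ndim == 0 else out


def percent_change(baseline, followup):
    """100 × (followup − baseline) / baseline; baseline must be nonzero."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if np.any(b == 0):
        raise DomainError("percent change undefined at zero baseline")
    out = 100.0 * (f - b) / b
    return float(out) if out.ndim == 0 else out


def exclude_outliers(
    phenotypes: pd.DataFrame, k: float = 5.0
) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose outcome lies > k SD from the cohort mean.

    Mean and SD are computed over all finite ``pct_change_homa_ir`` values
    before any exclusion; the rule is applied in a single pass (no
    re-iteration after removal).  If the SD is zero, nothing is excluded.

    Returns the retained phenotype table and the excluded subject ids.
    """
    pct = pd.to_numeric(phenotypes["pct_change_homa_ir"], errors="coerce")
    finite = pct[np.isfinite(pct)]
    if len(finite) < 3:
        raise DataError("need at least 3 finite outcome values to screen outliers")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd == 0.0:
        return phenotypes, []
    out_mask = (pct - mean).abs() > k * sd
    out_mask = out_mask.fillna(False)
    excluded = list(phenotypes.index[out_mask])
    return phenotypes.loc[~out_mask], excluded


def log_transform(
    abundance: pd.DataFrame, already_log: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-log transform of a raw peak-area matrix.

    Zeros map to missing but are tallied separately ("zeroness") from values
    that were missing in the raw data ("missingness"); both fractions are
    returned per metabolite.  A matrix already flagged as log scale passes
    through unchanged (zeroness 0).

    Returns ``(log_matrix, stats)`` where ``stats`` has columns
    ``missingness`` and ``zeroness`` indexed by metabolite.
    """
    vals = abundance.astype(float)
    if already_log:
        stats = pd.DataFrame(
            {
                "missingness": vals.isna().mean(),
                "zeroness": 0.0,
            }
        )
        return vals, stats
    if (vals < 0).any().any():
        bad = vals.columns[(vals < 0).any()][:3]
        raise DataError(f"negative abundances (e.g. in {list(bad)!r})")
    missingness = vals.isna().mean()
    zeroness = (vals == 0).mean()
    with np.errstate(divide="ignore"):
        logged = np.log(vals.where(vals > 0))
    stats = pd.DataFrame({"missingness": missingness, "zeroness": zeroness})
    return logged, stats


def prepare_cohort(
    dataset: CohortDataset, outlier_k: float = 5.0
) -> CohortDataset:
    """Apply the pre-analysis pipeline to a raw cohort.

    Fills ``pct_change_homa_ir`` from baseline/follow-up HOMA-IR where
    absent, excludes outcome outliers once, and log-transforms the abundance
    matrix (recording missingness/zeroness).  Returns a new dataset; the
    excluded subject ids are recorded on ``excluded_subjects``.
    """
    pheno = dataset.phenotypes.copy()
    if "pct_change_homa_ir" not in pheno.columns:
        if not {"homa_ir_baseline", "homa_ir_followup"} <= set(pheno.columns):
            raise SchemaError(
                "need pct_change_homa_ir or both homa_ir_baseline and homa_ir_followup"
            )
        pheno["pct_change_homa_ir"] = percent_change(
            pheno["homa_ir_baseline"], pheno["homa_ir_followup"]
        )
    kept, excluded = exclude_outliers(pheno, k=outlier_k)
    abundance = dataset.abundance.loc[kept.index]
    logged, stats = log_transform(abundance, already_log=dataset.log_scale)
    return replace(
        dataset,
        phenotypes=kept,
        abundance=logged,
        log_scale=True,
        abundance_stats=stats,
        excluded_subjects=list(excluded),
    )


def _encode_covariates(pheno: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns for the full model.

    Categorical covariates (sex, race) become 0/1 indicators with the
    largest observed category as the reference level; single-level
    categoricals drop out entirely.
    """
    cols = {}
    for name in ("age", "triglycerides_baseline", "pct_change_weight"):
        cols[name] = pd.to_numeric(pheno[name], errors="coerce")
    design = pd.DataFrame(cols, index=pheno.index)
    for cat in ("sex", "race"):
        series = pheno[cat].astype("object")
        counts = series.value_counts()
        if len(counts) <= 1:
            continue
        reference = counts.index[0]
        for level in sorted(lv for lv in counts.index if lv != reference):
            design[f"{cat}[{level}]"] = (series == level).astype(float)
    return design


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # QR with column pivoting: columns pivoted past the numerical rank
        # are the ones expressible as combinations of the others.
        _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise DegenerateDesignError(
            f"rank-deficient design: {bad!r} collinear with other columns",
            columns=bad,
        )


def _fit_ols(y: pd.Series, X: pd.DataFrame, metabolite: str, cohort: str,
             model_form: str) -> RegressionResult:
    res = sm.OLS(y.to_numpy(float), X.to_numpy(float)).fit()
    j = list(X.columns).index(metabolite)
    return RegressionResult(
        metabolite=metabolite,
        cohort=cohort,
        model_form=model_form,
        beta=float(res.params[j]),
        se=float(res.bse[j]),
        n=int(len(y)),
        p=float(res.pvalues[j]),
    )


def fit_univariate(
    dataset: CohortDataset, metabolite: str
) -> RegressionResult | None:
    """OLS of %ΔHOMA-IR on intercept + log metabolite.

    Returns None (a skip signal) when fewer than 3 complete cases remain or
    the metabolite has no variance among them — the metabolite is then
    reported as absent for this cohort.
    """
    if not dataset.log_scale:
        raise DataError("fit expects a log-scale abundance matrix; run prepare_cohort")
    x = dataset.abundance[metabolite]
    y = pd.to_numeric(dataset.phenotypes["pct_change_homa_ir"], errors="coerce")
    mask = x.notna() & y.notna()
    if mask.sum() < 3:
        return None
    x, y = x[mask], y[mask]
    if float(np.var(x)) == 0.0:
        return None
    X = pd.DataFrame({"const": 1.0, metabolite: x})
    return _fit_ols(y, X, metabolite, dataset.name, "univariate")


def fit_full(dataset: CohortDataset, metabolite: str) -> RegressionResult | None:
    """Covariate-adjusted OLS; reports the metabolite coefficient only.

    Adjusts for age, sex, race (indicator set, largest category as
    reference), baseline clinical triglycerides and percent weight change.
    Raises :class:`DegenerateDesignError` if the encoded design is rank
    deficient; returns None under the same skip conditions as
    :func:`fit_univariate`.
    """
    if not dataset.log_scale:
        raise DataError("fit expects a log-scale abundance matrix; run prepare_cohort")
    covs = _encode_covariates(dataset.phenotypes)
    x = dataset.abundance[metabolite]
    y = pd.to_numeric(dataset.phenotypes["pct_change_homa_ir"], errors="coerce")
    mask = x.notna() & y.notna() & covs.notna().all(axis=1)
    n = int(mask.sum())
    if n < covs.shape[1] + 3:
        return None
    x, y, covs = x[mask], y[mask], covs[mask]
    if float(np.var(x)) == 0.0:
        return None
    # re-encode on complete cases so single-level categoricals drop cleanly
    covs = _encode_covariates(dataset.phenotypes.loc[mask[mask].index])
    X = pd.concat(
        [pd.Series(1.0, index=x.index, name="const"), x.rename(metabolite), covs],
        axis=1,
    )
    _check_full_rank(X)
    return _fit_ols(y, X, metabolite, dataset.name, "full")


def fit_all(
    dataset: CohortDataset,
    model_form: str = "univariate",
    metabolites=None,
) -> pd.DataFrame:
    """Fit one model form for every metabolite in a prepared cohort.

    Skipped metabolites (too few complete cases, zero variance) are omitted
    from the returned table; downstream meta-analysis marks them "?" for
    this cohort.
    """
    if model_form not in ("univariate", "full"):
        raise ValueError(f"unknown model_form {model_form!r}")
    fit = fit_univariate if model_form == "univariate" else fit_full
    rows = []
    for met in metabolites if metabolites is not None else dataset.metabolites:
        res = fit(dataset, met)
        if res is not None:
            rows.append(res)
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["metabolite", "cohort", "model_form", "beta", "se", "n", "p"],
    )
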