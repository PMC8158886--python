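"""Cross-cohort meta-analysis of per-metabolite regression estimates.

Per metabolite, the per-cohort effect estimates (β, SE) are pooled by
inverse-variance weighting in two forms:

* **fixed effects** — weights 1/SEᵢ², assuming one common effect;
* **random effects** — DerSimonian–Laird moment estimate of the
  between-study variance τ², weights 1/(SEᵢ² + τ²).

Heterogeneity between cohorts is summarised by Cochran's Q (χ² with k−1
degrees of freedom under homogeneity), H = √(Q/df) and
I² = max(0, (Q−df)/Q).  Association p-values (normal theory on the pooled
z) are Benjamini–Hochberg adjusted across all retained metabolites within
one model form; heterogeneity p-values are reported nominally, reflecting
the lower power of the Q test.

Metabolites enter the meta-analysis only if they are named (known) and have
pooled missingness below 25% after combining all cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from metabometa.errors import DataError

#: exact output column order of the per-model-form results table
META_COLUMNS_CORE = [
    "Metabolite",
    "N_Samples",
    "N_Studies",
    "Beta_Fixed",
    "SE_Fixed",
    "Zvalue_Fixed",
    "Pvalue_Fixed",
    "Beta_Random",
    "SE_Random",
    "Zvalue_Random",
    "Pvalue_Random",
    "Q",
    "Q_df",
    "Q_Pvalue",
    "Tau2",
    "H",
    "I2",
]

META_COLUMNS_TAIL = [
    "Cohort_Direction",
    "Method",
    "HMDB_ID",
    "super_class",
    "class",
    "sub_class",
    "missingness",
    "zeroness",
    "CV",
    "Pvalue_Adj_Fixed",
    "Pvalue_Adj_Random",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's (β, SE, n) for a metabolite."""

    cohort: str
    beta: float
    se: float
    n: int

    def __post_init__(self):
        if not self.se > 0:
            raise DataError(f"standard error must be positive (got {self.se})")


class PooledEffect(NamedTuple):
    beta: float
    se: float
    z: float
    p: float


def _pool(betas: np.ndarray, weights: np.ndarray) -> PooledEffect:
    wsum = weights.sum()
    beta = float((weights * betas).sum() / wsum)
    se = float(wsum ** -0.5)
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return PooledEffect(beta, se, z, p)


def fixed_effects(estimates: Sequence[StudyEstimate]) -> PooledEffect:
    """Inverse-variance weighted fixed-effects pooling (weights 1/SEᵢ²)."""
    if len(estimates) == 0:
        raise DataError("no study estimates to pool")
    betas = np.array([e.beta for e in estimates], dtype=float)
    weights = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    return _pool(betas, weights)


def cochran_q(estimates: Sequence[StudyEstimate]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q with fixed-effects weights.

    Returns ``(Q, df, p)`` with p from the upper tail of χ²(k−1).  A single
    study gives Q = 0, df = 0 and a missing p (heterogeneity undefined).
    """
    if len(estimates) == 0:
        raise DataError("no study estimates")
    if len(estimates) == 1:
        return 0.0, 0, math.nan
    betas = np.array([e.beta for e in estimates], dtype=float)
    weights = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    beta_fixed = (weights * betas).sum() / weights.sum()
    q = float((weights * (betas - beta_fixed) ** 2).sum())
    df = len(estimates) - 1
    return q, df, float(sps.chi2.sf(q, df))


def dersimonian_laird(
    estimates: Sequence[StudyEstimate],
) -> tuple[float, PooledEffect]:
    """DerSimonian–Laird random-effects pooling.

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed-effects weights w,
    then inverse-variance pooling with weights 1/(SEᵢ² + τ²).  Returns
    ``(tau2, PooledEffect)``; with one study τ² = 0 and the pooled effect
    equals the input.
    """
    if len(estimates) == 0:
        raise DataError("no study estimates")
    betas = np.array([e.beta for e in estimates], dtype=float)
    variances = np.array([e.se**2 for e in estimates], dtype=float)
    if len(estimates) == 1:
        return 0.0, _pool(betas, 1.0 / variances)
    w = 1.0 / variances
    q, df, _ = cochran_q(estimates)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (variances + tau2)
    return float(tau2), _pool(betas, w_star)


def h_and_i2(q: float, df: int) -> tuple[float, float]:
    """H = √(Q/df); I² = max(0, (Q − df)/Q), with I² = 0 when Q = 0."""
    if df < 1:
        raise DataError("heterogeneity statistics need df >= 1")
    h = math.sqrt(q / df)
    i2 = 0.0 if q == 0.0 else max(0.0, (q - df) / q)
    return h, i2


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing entries pass through as missing and do not count toward the
    family size m.  Values outside (0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise DataError("p-values must lie in (0, 1]")
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pooled_missingness(
    abundance_stats: dict[str, pd.DataFrame],
    cohort_sizes: dict[str, int],
    metabolites: Iterable[str],
) -> pd.DataFrame:
    """Per-metabolite missingness and zeroness over the pooled samples.

    A metabolite not measured at all in a cohort counts as missing for every
    sample of that cohort — the same convention the study-level filter uses.
    """
    metabolites = pd.Index(metabolites)
    total = sum(cohort_sizes.values())
    missing = pd.Series(0.0, index=metabolites)
    zero = pd.Series(0.0, index=metabolites)
    for name, stats in abundance_stats.items():
        n = cohort_sizes[name]
        m = stats["missingness"].reindex(metabolites, fill_value=1.0)
        z = stats["zeroness"].reindex(metabolites, fill_value=0.0)
        missing += m * n
        zero += z * n
    return pd.DataFrame(
        {"missingness": missing / total, "zeroness": zero / total}
    )


def missingness_filter(
    annotation: pd.DataFrame,
    pooled_stats: pd.DataFrame,
    max_missingness: float = 0.25,
) -> tuple[pd.Index, int]:
    """Retain named metabolites with pooled missingness strictly below the cut.

    Unnamed (unknown-identity) features are removed regardless of
    missingness; ``annotation`` marks them via a boolean ``known`` column
    (absent column means all known).  Returns (retained ids, number removed).
    """
    ids = annotation.index
    miss = pooled_stats["missingness"].reindex(ids, fill_value=1.0)
    known = (
        annotation["known"].astype(bool)
        if "known" in annotation.columns
        else pd.Series(True, index=ids)
    )
    keep = (miss < max_missingness) & known
    return ids[keep], int((~keep).sum())


def _assemble_estimates(group: pd.DataFrame) -> list[StudyEstimate]:
    return [
        StudyEstimate(cohort=r.cohort, beta=r.beta, se=r.se, n=int(r.n))
        for r in group.itertuples()
    ]


def run_meta(
    cohort_results: pd.DataFrame,
    model_form: str,
    annotation: pd.DataFrame,
    pooled_stats: pd.DataFrame,
    cohort_order: Sequence[str] | None = None,
    max_missingness: float = 0.25,
) -> pd.DataFrame:
    """Meta-analyze per-cohort regression tables into the full results schema.

    ``cohort_results`` is the concatenation of :func:`metabometa.cohort.fit_all`
    outputs over cohorts (columns metabolite, cohort, model_form, beta, se,
    n, p).  Metabolites failing the missingness/known filter are dropped
    before pooling; FDR adjustment spans all retained metabolites within
    this model form.  Cohorts without an estimate for a metabolite appear as
    "?" in ``Cohort_Direction`` and missing per-cohort columns.
    """
    results = cohort_results[cohort_results["model_form"] == model_form]
    if cohort_order is None:
        cohort_order = list(dict.fromkeys(results["cohort"]))
    retained, _ = missingness_filter(annotation, pooled_stats, max_missingness)
    results = results[results["metabolite"].isin(retained)]

    ann_cols = {
        "Method": "method",
        "HMDB_ID": "hmdb_id",
        "super_class": "super_class",
        "class": "class",
        "sub_class": "sub_class",
        "CV": "cv",
    }
    rows = []
    for met, group in results.groupby("metabolite", sort=True):
        estimates = _assemble_estimates(group)
        by_cohort = {e.cohort: e for e in estimates}
        fixed = fixed_effects(estimates)
        q, q_df, q_p = cochran_q(estimates)
        tau2, random = dersimonian_laird(estimates)
        if q_df >= 1:
            h, i2 = h_and_i2(q, q_df)
        else:
            h, i2 = math.nan, math.nan
        row = {
            "Metabolite": met,
            "N_Samples": int(sum(e.n for e in estimates)),
            "N_Studies": len(estimates),
            "Beta_Fixed": fixed.beta,
            "SE_Fixed": fixed.se,
            "Zvalue_Fixed": fixed.z,
            "Pvalue_Fixed": fixed.p,
            "Beta_Random": random.beta,
            "SE_Random": random.se,
            "Zvalue_Random": random.z,
            "Pvalue_Random": random.p,
            "Q": q,
            "Q_df": q_df,
            "Q_Pvalue": q_p,
            "Tau2": tau2,
            "H": h,
            "I2": i2,
        }
        for cohort in cohort_order:
            est = by_cohort.get(cohort)
            row[f"{cohort}_Beta"] = est.beta if est else math.nan
            row[f"{cohort}_SE"] = est.se if est else math.nan
            row[f"{cohort}_Num"] = est.n if est else math.nan
        row["Cohort_Direction"] = "".join(
            "?" if cohort not in by_cohort
            else ("+" if by_cohort[cohort].beta >= 0 else "-")
            for cohort in cohort_order
        )
        ann = annotation.loc[met] if met in annotation.index else None
        for out_col, ann_col in ann_cols.items():
            row[out_col] = (
                ann[ann_col] if ann is not None and ann_col in annotation.columns
                else math.nan
            )
        for col in ("missingness", "zeroness"):
            row[col] = (
                float(pooled_stats.loc[met, col])
                if met in pooled_stats.index
                else math.nan
            )
        rows.append(row)

    cohort_cols = [
        f"{c}_{suffix}" for c in cohort_order for suffix in ("Beta", "SE", "Num")
    ]
    table = pd.DataFrame(rows, columns=META_COLUMNS_CORE + cohort_cols + META_COLUMNS_TAIL)
    if len(table):
        table["Pvalue_Adj_Fixed"] = bh_fdr(table["Pvalue_Fixed"])
        table["Pvalue_Adj_Random"] = bh_fdr(table["Pvalue_Random"])
    return table


def volcano_data(meta_table: pd.DataFrame, which: str = "random") -> pd.DataFrame:
    """Tidy export for a volcano plot: effect size vs −log10 adjusted p.

    ``which`` selects the association analysis ("random", adjusted p) or the
    heterogeneity analysis ("q", nominal Q p-value) for the y axis.
    """
    if which == "random":
        y = -np.log10(meta_table["Pvalue_Adj_Random"])
    elif which == "q":
        y = -np.log10(meta_table["Q_Pvalue"])
    else:
        raise ValueError(f"unknown volcano flavour {which!r}")
    return pd.DataFrame(
        {
            "Metabolite": meta_table["Metabolite"],
            "Beta_Random": meta_table["Beta_Random"],
            "neg_log10_p": y,
            "sub_class": meta_table["sub_class"],
        }
    )
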