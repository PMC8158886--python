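"""End-to-end orchestration: simulate/load → regress → meta-analyze → enrich.

The association analysis meta-analyzes the univariate per-cohort models and
ranks metabolites by the random-effects z-score; the heterogeneity analysis
computes Cochran Q on the covariate-adjusted (full) model estimates and
ranks by Q.  Each stage reads the previous stage's tables, so stages are
independently runnable from files; :func:`run_study` provides the same
pipeline in memory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

import metabometa
from metabometa.cohort import CohortDataset, fit_all, prepare_cohort
from metabometa.enrichment import run_enrichment
from metabometa.errors import ConfigError
from metabometa.io import (
    config_hash,
    read_cohort,
    read_gmt,
    read_json,
    read_table,
    write_cohort,
    write_gmt,
    write_json,
    write_table,
)
from metabometa.meta import pooled_missingness, run_meta, volcano_data
from metabometa.simulate import GeneratorConfig, generate_study

logger = logging.getLogger("metabometa")


@dataclass(frozen=True)
class RunConfig:
    """Options and paths for a full pipeline run."""

    study_dir: str
    out_dir: str
    seed: int = 0
    outlier_k: float = 5.0
    max_missingness: float = 0.25
    n_perm: int = 10_000
    min_set_size: int = 5
    weight_exponent: float = 1.0
    modes: tuple = ("z", "q")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_study(
    cohorts: list[CohortDataset],
    set_db,
    annotation: pd.DataFrame,
    seed: int = 0,
    outlier_k: float = 5.0,
    max_missingness: float = 0.25,
    n_perm: int = 10_000,
    min_set_size: int = 5,
    weight_exponent: float = 1.0,
    modes: tuple = ("z", "q"),
) -> dict:
    """Run the full analysis in memory; returns a dict of result tables.

    Keys: ``meta_univariate``, ``meta_full``, ``enrichment_association``,
    ``enrichment_heterogeneity``, the matching plot-data tables,
    ``volcano_association`` / ``volcano_heterogeneity`` and per-stage
    metadata (excluded subjects, pooled stats).
    """
    t0 = time.perf_counter()
    prepared = [prepare_cohort(c, outlier_k=outlier_k) for c in cohorts]
    cohort_order = [c.name for c in prepared]
    excluded = {c.name: list(c.excluded_subjects) for c in prepared}
    logger.info("prepared %d cohorts (%.1fs)", len(prepared), time.perf_counter() - t0)

    t0 = time.perf_counter()
    results = pd.concat(
        [fit_all(c, form) for c in prepared for form in ("univariate", "full")],
        ignore_index=True,
    )
    logger.info("fitted %d models (%.1fs)", len(results), time.perf_counter() - t0)

    pooled = pooled_missingness(
        {c.name: c.abundance_stats for c in prepared},
        {c.name: c.n_samples for c in prepared},
        annotation.index,
    )

    out: dict = {"excluded_subjects": excluded, "pooled_stats": pooled}
    t0 = time.perf_counter()
    for form in ("univariate", "full"):
        out[f"meta_{form}"] = run_meta(
            results, form, annotation, pooled,
            cohort_order=cohort_order, max_missingness=max_missingness,
        )
    out["regression_results"] = results
    out["volcano_association"] = volcano_data(out["meta_univariate"], "random")
    out["volcano_heterogeneity"] = volcano_data(out["meta_full"], "q")
    logger.info("meta-analysis done (%.1fs)", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if "z" in modes:
        table, plot = run_enrichment(
            out["meta_univariate"], set_db, mode="signed_z",
            n_perm=n_perm, min_size=min_set_size, seed=seed,
            weight_exponent=weight_exponent,
        )
        out["enrichment_association"] = table
        out["enrichment_association_plot"] = plot
    if "q" in modes:
        table, plot = run_enrichment(
            out["meta_full"], set_db, mode="q_stat",
            n_perm=n_perm, min_size=min_set_size, seed=seed,
            weight_exponent=weight_exponent,
        )
        out["enrichment_heterogeneity"] = table
        out["enrichment_heterogeneity_plot"] = plot
    logger.info("enrichment done (%.1fs)", time.perf_counter() - t0)
    return out


def write_study(config: GeneratorConfig, directory) -> dict:
    """Generate a synthetic study and write it as a study directory.

    Emits per-cohort phenotype/abundance TSVs, the shared annotation, the
    subclass GMT, the ground-truth effect ledger and the generator config.
    """
    directory = Path(directory)
    cohorts, set_db, truth = generate_study(config)
    cfg_dict = dataclasses.asdict(config)
    header = {
        "seed": config.seed,
        "config_hash": config_hash(cfg_dict),
        "version": metabometa.__version__,
    }
    write_table(
        cohorts[0].annotation.reset_index(drop=True),
        directory / "annotation.tsv",
        header=header,
    )
    for cohort in cohorts:
        write_cohort(cohort, directory, header=header)
    write_gmt(set_db, directory / "sets.gmt")
    write_json(
        [
            {
                "set_name": t.set_name,
                "member_metabolites": list(t.member_metabolites),
                "beta_per_cohort": t.beta_per_cohort,
                "homogeneous": t.homogeneous,
            }
            for t in truth
        ],
        directory / "truth.json",
    )
    write_json(cfg_dict, directory / "generator_config.json")
    return {"cohorts": [c.name for c in cohorts], "n_metabolites": config.n_metabolites}


def load_study(directory) -> tuple[list[CohortDataset], list, pd.DataFrame]:
    """Load a study directory written by :func:`write_study`."""
    directory = Path(directory)
    annotation, _ = read_table(directory / "annotation.tsv")
    annotation = annotation.set_index("metabolite", drop=False)
    annotation.index.name = None
    names = sorted(
        p.name[len("cohort_"):-len(".phenotypes.tsv")]
        for p in directory.glob("cohort_*.phenotypes.tsv")
    )
    if not names:
        raise ConfigError(f"no cohort tables found under {directory}")
    cohorts = [read_cohort(n, directory, annotation) for n in names]
    set_db = read_gmt(directory / "sets.gmt")
    return cohorts, set_db, annotation


def run_all(config: RunConfig) -> dict:
    """File-level pipeline: load a study directory, analyze, write outputs.

    Writes six result tables (two meta-analysis, two enrichment, two
    volcano exports), the per-cohort regression table, enrichment plot
    data, and a JSON manifest with seed, config hash and row counts.  Two
    runs with the same config are byte-identical.
    """
    study_dir = Path(config.study_dir)
    if not study_dir.exists():
        raise ConfigError(f"study directory {study_dir} does not exist")
    if "z" in config.modes or "q" in config.modes:
        if not (study_dir / "sets.gmt").exists():
            raise ConfigError("enrichment requested but sets.gmt is missing")
    cohorts, set_db, annotation = load_study(study_dir)
    results = run_study(
        cohorts, set_db, annotation,
        seed=config.seed,
        outlier_k=config.outlier_k,
        max_missingness=config.max_missingness,
        n_perm=config.n_perm,
        min_set_size=config.min_set_size,
        weight_exponent=config.weight_exponent,
        modes=config.modes,
    )

    out_dir = Path(config.out_dir)
    header = {
        "seed": config.seed,
        "config_hash": config_hash(config.as_dict()),
        "version": metabometa.__version__,
    }
    table_files = {
        "regression_results": "regression_results.tsv",
        "meta_univariate": "meta_univariate.tsv",
        "meta_full": "meta_full.tsv",
        "enrichment_association": "enrichment_association.tsv",
        "enrichment_heterogeneity": "enrichment_heterogeneity.tsv",
        "enrichment_association_plot": "enrichment_association_plot.tsv",
        "enrichment_heterogeneity_plot": "enrichment_heterogeneity_plot.tsv",
        "volcano_association": "volcano_association.tsv",
        "volcano_heterogeneity": "volcano_heterogeneity.tsv",
    }
    row_counts = {}
    for key, fname in table_files.items():
        if key in results:
            write_table(results[key], out_dir / fname, header=header)
            row_counts[fname] = int(len(results[key]))
    manifest = {
        "version": metabometa.__version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "config_hash": header["config_hash"],
        "row_counts": row_counts,
        "excluded_subjects": results["excluded_subjects"],
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def load_regressions(path) -> pd.DataFrame:
    """Read a regression-results TSV written by :func:`run_all` stage output."""
    table, _ = read_table(path)
    return table
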