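"""Seeded synthetic multi-cohort metabolomics studies.

The generator emulates a multi-cohort weight-loss study: three cohorts of
very different size, outcome scale and covariate mix (a large behavioral
cohort, a mid-size exercise cohort and a small surgical cohort whose
insulin resistance drops far more), each with an LC-MS-style panel of
metabolites organised into taxonomy subclasses.

Key structural features of real data that are reproduced:

* metabolite log-levels are multivariate normal with exchangeable
  within-subclass correlation (lipid species of one class co-vary);
* lipid subclasses are coupled to clinical triglycerides, creating genuine
  covariate confounding for the adjusted model;
* the outcome (%ΔHOMA-IR) is built additively on the percent-change scale
  from planted per-cohort metabolite effects, covariate terms and Gaussian
  noise at the cohort's own scale, so parameter-recovery tests are sharp;
* missingness is injected completely at random, and a configurable number
  of subjects per cohort get outcomes displaced far enough from the mean
  that a >5 SD screening rule flags exactly those subjects;
* planted effects may be homogeneous (equal β in every cohort) or
  cohort-heterogeneous (e.g. sign-flipped in the surgical cohort), giving
  ground truth for both the association and the heterogeneity analyses.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metabometa.cohort import CohortDataset
from metabometa.enrichment import MetaboliteSet
from metabometa.errors import ConfigError

LCMS_METHODS = ("C8-pos", "C18-neg", "HILIC-pos", "HILIC-neg")

#: subclasses treated as lipid-like: coupled to clinical triglycerides and
#: labelled under the lipid superclass
LIPID_SUBCLASS_KEYWORDS = (
    "glycerol", "Glycerophospho", "sphingolipid", "Fatty", "Cholesteryl",
    "Prenol", "Steroid", "Bile",
)


@dataclass(frozen=True)
class CohortSpec:
    """Phenotype-scale parameters for one synthetic cohort.

    ``pct_change_mean_sd`` sets the intercept and the residual noise SD of
    the outcome (%ΔHOMA-IR); planted effects and covariate terms add on top.
    """

    name: str
    n_subjects: int
    homa_ir_baseline_mean_sd: tuple[float, float]
    pct_change_mean_sd: tuple[float, float]
    weight_baseline_mean_sd: tuple[float, float]
    weight_change_mean_sd: tuple[float, float]
    age_mean_sd: tuple[float, float]
    prop_female: float
    race_props: dict = field(default_factory=dict)  # e.g. {"AA": .37, "EA": .62}
    triglycerides_mean_sd: tuple[float, float] = (130.0, 70.0)

    def __post_init__(self):
        if self.n_subjects < 10:
            raise ConfigError(f"{self.name}: need at least 10 subjects")
        for label in ("homa_ir_baseline", "pct_change", "weight_baseline",
                      "weight_change", "age", "triglycerides"):
            sd = getattr(self, f"{label}_mean_sd")[1]
            if not sd > 0:
                raise ConfigError(f"{self.name}: {label} SD must be > 0")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError(f"{self.name}: prop_female outside [0, 1]")
        total = sum(self.race_props.values())
        if any(not 0 <= v <= 1 for v in self.race_props.values()) or total > 1 + 1e-9:
            raise ConfigError(f"{self.name}: race proportions invalid")


@dataclass(frozen=True)
class EffectSpec:
    """A planted metabolite-set effect with per-cohort β values.

    β is in percent-change-of-HOMA-IR per natural-log unit of metabolite
    abundance.  ``homogeneous`` is True iff every cohort shares one β.
    """

    set_name: str
    member_metabolites: tuple
    beta_per_cohort: dict

    def __post_init__(self):
        object.__setattr__(
            self, "member_metabolites", tuple(self.member_metabolites)
        )

    @property
    def homogeneous(self) -> bool:
        betas = list(self.beta_per_cohort.values())
        return all(b == betas[0] for b in betas)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic study; the seed determines everything."""

    seed: int
    n_metabolites: int
    subclass_composition: dict
    cohort_specs: tuple
    effects: tuple = ()
    within_subclass_correlation: float = 0.5
    missingness_rate: float = 0.05
    n_outcome_outliers: int = 2
    tg_coupling: float = 0.5
    weight_effect: float = 0.5  # % HOMA-IR change per % weight change

    def __post_init__(self):
        object.__setattr__(self, "cohort_specs", tuple(self.cohort_specs))
        object.__setattr__(self, "effects", tuple(self.effects))
        if sum(self.subclass_composition.values()) != self.n_metabolites:
            raise ConfigError(
                "subclass composition must sum to n_metabolites "
                f"({sum(self.subclass_composition.values())} != {self.n_metabolites})"
            )
        if not 0.0 <= self.within_subclass_correlation < 1.0:
            raise ConfigError("within-subclass correlation must lie in [0, 1)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ConfigError("missingness rate must lie in [0, 1)")
        if self.n_outcome_outliers < 0:
            raise ConfigError("outlier count must be >= 0")


def _is_lipid(subclass: str) -> bool:
    return any(k.lower() in subclass.lower() for k in LIPID_SUBCLASS_KEYWORDS)


def generate_annotation(config: GeneratorConfig) -> pd.DataFrame:
    """Metabolite annotation table: one row per metabolite.

    Ids are ``<subclass-slug>.<k>``; each metabolite gets an HMDB-style
    accession, a taxonomy placement, an LC-MS method label, a coefficient of
    variation in (0, 0.5] and a per-metabolite mean log abundance reused by
    every cohort.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    rows = []
    idx = 0
    for subclass in sorted(config.subclass_composition):
        count = config.subclass_composition[subclass]
        slug = subclass.replace(" ", "_").replace(",", "")
        for k in range(count):
            idx += 1
            rows.append(
                {
                    "metabolite": f"{slug}.{k + 1:03d}",
                    "hmdb_id": f"HMDB{idx:07d}",
                    "super_class": (
                        "Lipids and lipid-like molecules"
                        if _is_lipid(subclass)
                        else "Organic compounds"
                    ),
                    "class": f"{subclass} (class)",
                    "sub_class": subclass,
                    "method": LCMS_METHODS[idx % len(LCMS_METHODS)],
                    "cv": float(rng.uniform(0.02, 0.5)),
                    "known": True,
                    "log_mean": float(rng.normal(15.0, 2.0)),
                }
            )
    ann = pd.DataFrame(rows).set_index("metabolite", drop=False)
    ann.index.name = None
    return ann


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.normal(*spec.age_mean_sd, n)
    sex = np.where(rng.random(n) < spec.prop_female, "F", "M")
    u = rng.random(n)
    race = np.full(n, "other", dtype=object)
    lo = 0.0
    for level in sorted(spec.race_props):
        hi = lo + spec.race_props[level]
        race[(u >= lo) & (u < hi)] = level
        lo = hi
    tg = np.clip(rng.normal(*spec.triglycerides_mean_sd, n), 20.0, None)
    weight = np.clip(rng.normal(*spec.weight_baseline_mean_sd, n), 40.0, None)
    wchange = rng.normal(*spec.weight_change_mean_sd, n)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "triglycerides_baseline": tg,
            "weight_baseline": weight,
            "pct_change_weight": 100.0 * wchange / weight,
        }
    )


def _displace_outliers(pct: np.ndarray, which: np.ndarray) -> np.ndarray:
    """Push selected outcomes far enough out that a >5 SD rule flags exactly them.

    Displacement starts at 6 pre-displacement SDs and grows geometrically
    until every selected subject exceeds 5 SDs of the *post*-displacement
    sample (displacement inflates the SD, so a fixed 6 SD shove can fall
    short in small cohorts).
    """
    pct = pct.copy()
    base_mean, base_sd = pct.mean(), pct.std(ddof=1)
    signs = np.where(np.arange(len(which)) % 2 == 0, 1.0, -1.0)
    d = 6.0 * base_sd
    for _ in range(60):
        pct[which] = base_mean + signs * d
        mean, sd = pct.mean(), pct.std(ddof=1)
        flagged = np.abs(pct - mean) > 5.0 * sd
        if flagged[which].all() and flagged.sum() == len(which):
            return pct
        d *= 1.4
    raise RuntimeError("could not place outcome outliers beyond the 5 SD rule")


def generate_cohort(
    spec: CohortSpec,
    annotation: pd.DataFrame,
    effects,
    seed,
    within_subclass_correlation: float = 0.5,
    missingness_rate: float = 0.05,
    n_outcome_outliers: int = 0,
    tg_coupling: float = 0.5,
    weight_effect: float = 0.5,
) -> CohortDataset:
    """One cohort's raw dataset (peak-area scale, outliers and missingness in).

    Log abundances are exchangeably correlated within each subclass; lipid
    subclasses additionally load on the subject's standardized clinical
    triglycerides, so the adjusted model has real confounding to remove.
    The outcome is the cohort intercept plus planted metabolite effects on
    centred log abundance, a weight-change term, and Gaussian noise at the
    spec's scale; follow-up HOMA-IR is back-computed from baseline and the
    percent change.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    mets = annotation["metabolite"].to_numpy()
    known = set(mets)
    for eff in effects:
        missing = [m for m in eff.member_metabolites if m not in known]
        if missing:
            raise ConfigError(
                f"effect {eff.set_name!r} references unknown metabolites {missing[:3]!r}"
            )
        if spec.name not in eff.beta_per_cohort:
            raise ConfigError(
                f"effect {eff.set_name!r} has no beta for cohort {spec.name!r}"
            )

    covs = _draw_covariates(spec, rng, n)
    tg_z = (
        covs["triglycerides_baseline"] - spec.triglycerides_mean_sd[0]
    ).to_numpy() / spec.triglycerides_mean_sd[1]

    rho = within_subclass_correlation
    log_x = np.empty((n, len(mets)))
    col = 0
    for subclass, ann_block in annotation.groupby("sub_class", sort=True):
        m = len(ann_block)
        shared = rng.normal(size=n)
        eps = rng.normal(size=(n, m))
        block = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
        if _is_lipid(subclass):
            block = block + tg_coupling * tg_z[:, None]
        log_x[:, col : col + m] = block + ann_block["log_mean"].to_numpy()[None, :]
        col += m
    ordered_ids = [
        mid
        for _, blk in annotation.groupby("sub_class", sort=True)
        for mid in blk["metabolite"]
    ]
    log_df = pd.DataFrame(log_x, columns=ordered_ids)[list(mets)]

    mean_pct, sd_pct = spec.pct_change_mean_sd
    pct = np.full(n, mean_pct)
    for eff in effects:
        beta = eff.beta_per_cohort[spec.name]
        if beta == 0.0:
            continue
        centred = (
            log_df[list(eff.member_metabolites)].to_numpy()
            - annotation.loc[list(eff.member_metabolites), "log_mean"].to_numpy()[None, :]
        )
        pct = pct + beta * centred.sum(axis=1)
    wc = covs["pct_change_weight"].to_numpy()
    pct = pct + weight_effect * (wc - wc.mean())
    pct = pct + rng.normal(0.0, sd_pct, n)

    if n_outcome_outliers > 0:
        which = rng.choice(n, size=n_outcome_outliers, replace=False)
        pct = _displace_outliers(pct, which)

    homa0 = np.clip(rng.normal(*spec.homa_ir_baseline_mean_sd, n), 0.2, None)
    glucose = np.clip(rng.normal(100.0, 12.0, n), 40.0, None)
    insulin = homa0 * 405.0 / glucose
    homa1 = homa0 * (1.0 + pct / 100.0)

    subjects = pd.Index([f"{spec.name}_S{i + 1:04d}" for i in range(n)])
    pheno = pd.DataFrame(
        {
            "glucose_baseline": glucose,
            "insulin_baseline": insulin,
            "homa_ir_baseline": homa0,
            "homa_ir_followup": homa1,
            "pct_change_homa_ir": pct,
            **{c: covs[c].to_numpy() for c in covs.columns},
        },
        index=subjects,
    )

    raw = np.exp(log_df.to_numpy())
    if missingness_rate > 0:
        raw[rng.random(raw.shape) < missingness_rate] = np.nan
    abundance = pd.DataFrame(raw, index=subjects, columns=log_df.columns)
    return CohortDataset(
        name=spec.name,
        phenotypes=pheno,
        abundance=abundance,
        annotation=annotation,
        log_scale=False,
    )


def generate_study(
    config: GeneratorConfig,
) -> tuple[list[CohortDataset], list[MetaboliteSet], list[EffectSpec]]:
    """All cohorts of a study plus the subclass set database and truth ledger.

    Cohorts share one annotation; the set database has one set per taxonomy
    subclass (so the sets partition the panel); the returned effect specs
    echo the planted ground truth for recovery tests.
    """
    if not config.cohort_specs:
        raise ConfigError("need at least one cohort spec")
    annotation = generate_annotation(config)
    cohort_names = {s.name for s in config.cohort_specs}
    for eff in config.effects:
        if not cohort_names <= set(eff.beta_per_cohort):
            raise ConfigError(
                f"effect {eff.set_name!r} does not cover every cohort"
            )
    cohorts = [
        generate_cohort(
            spec,
            annotation,
            config.effects,
            seed=[int(config.seed), 10 + i],
            within_subclass_correlation=config.within_subclass_correlation,
            missingness_rate=config.missingness_rate,
            n_outcome_outliers=config.n_outcome_outliers,
            tg_coupling=config.tg_coupling,
            weight_effect=config.weight_effect,
        )
        for i, spec in enumerate(config.cohort_specs)
    ]
    set_db = [
        MetaboliteSet(name=subclass, members=tuple(block["metabolite"]))
        for subclass, block in annotation.groupby("sub_class", sort=True)
    ]
    return cohorts, set_db, list(config.effects)


# ---------------------------------------------------------------------------
# Ready-made study configurations


def paper_like_cohort_specs() -> tuple[CohortSpec, CohortSpec, CohortSpec]:
    """Three cohorts mirroring the published study's baseline table.

    A large behavioral cohort (n = 443, %ΔHOMA-IR −16 ± 105), a mid-size
    exercise cohort (n = 163, −16 ± 42) and a small surgical cohort
    (n = 125, −71 ± 21) with much larger weight loss and baseline HOMA-IR.
    """
    return (
        CohortSpec(
            name="WLM", n_subjects=443,
            homa_ir_baseline_mean_sd=(2.4, 1.6),
            pct_change_mean_sd=(-16.0, 105.0),
            weight_baseline_mean_sd=(96.0, 16.0),
            weight_change_mean_sd=(-8.5, 3.8),
            age_mean_sd=(56.0, 8.7),
            prop_female=0.62,
            race_props={"AA": 0.37, "EA": 0.62},
            triglycerides_mean_sd=(127.0, 71.0),
        ),
        CohortSpec(
            name="StrridePD", n_subjects=163,
            homa_ir_baseline_mean_sd=(2.0, 1.5),
            pct_change_mean_sd=(-16.0, 42.0),
            weight_baseline_mean_sd=(86.0, 12.0),
            weight_change_mean_sd=(-2.7, 4.0),
            age_mean_sd=(59.0, 7.5),
            prop_female=0.63,
            race_props={"AA": 0.18, "EA": 0.78},
            triglycerides_mean_sd=(123.0, 64.0),
        ),
        CohortSpec(
            name="CBD", n_subjects=125,
            homa_ir_baseline_mean_sd=(9.6, 5.8),
            pct_change_mean_sd=(-71.0, 21.0),
            weight_baseline_mean_sd=(121.0, 22.0),
            weight_change_mean_sd=(-35.0, 16.0),
            age_mean_sd=(42.0, 10.0),
            prop_female=0.82,
            race_props={"AA": 0.50, "EA": 0.49},
            triglycerides_mean_sd=(158.0, 108.0),
        ),
    )


#: 22 taxonomy subclasses, lipid-heavy, summing to a 765-metabolite panel
PAPER_LIKE_COMPOSITION = {
    "Triradylcglycerols": 130,
    "Diradylglycerols": 35,
    "Glycerophosphocholines": 80,
    "Glycerophosphoethanolamines": 25,
    "Phosphosphingolipids": 40,
    "Fatty acid esters": 30,
    "Fatty acids and conjugates": 45,
    "Fatty amides": 10,
    "Cholesteryl esters": 15,
    "Bile acids and derivatives": 15,
    "Steroids and steroid derivatives": 25,
    "Prenol lipids": 10,
    "Amino acids, peptides, and analogues": 110,
    "Carbohydrates and conjugates": 35,
    "Tricarboxylic acids and derivatives": 15,
    "Purines and purine derivatives": 25,
    "Pyrimidines and pyrimidine derivatives": 15,
    "Benzoic acids and derivatives": 20,
    "Indoles and derivatives": 15,
    "Imidazopyrimidines": 10,
    "Organooxygen compounds": 35,
    "Organonitrogen compounds": 25,
}
assert sum(PAPER_LIKE_COMPOSITION.values()) == 765


def _subset_composition(n_metabolites: int) -> dict:
    """Shrink the reference composition proportionally to a smaller panel."""
    if n_metabolites == 765:
        return dict(PAPER_LIKE_COMPOSITION)
    total = 765
    comp = {
        k: max(2, round(v * n_metabolites / total))
        for k, v in PAPER_LIKE_COMPOSITION.items()
    }
    # correct rounding drift on the largest subclass
    largest = max(comp, key=comp.get)
    comp[largest] += n_metabolites - sum(comp.values())
    if comp[largest] < 2:
        raise ConfigError("panel too small for the reference composition")
    return comp


def default_config(
    seed: int,
    n_metabolites: int = 765,
    plant_effects: bool = True,
    homogeneous_effect_size: float = 0.15,
    heterogeneous_effect_size: float = 0.3,
    n_homogeneous_members: int = 30,
    n_heterogeneous_members: int = 14,
    missingness_rate: float = 0.05,
    n_outcome_outliers: int = 2,
    cohort_specs: tuple | None = None,
) -> GeneratorConfig:
    """The standard simulated study.

    Plants a homogeneous negative effect (β = −``homogeneous_effect_size``
    outcome-SDs per metabolite log-SD, identical sign in every cohort) in a
    triacylglycerol-like subset, mimicking the finding that higher baseline
    TAG/DAG levels predict greater HOMA-IR improvement; and a sign-flipped
    effect (positive in the surgical cohort, negative elsewhere) in an
    amino-acid-like subset, mimicking intervention-dependent heterogeneity.
    Effect sizes are expressed per cohort as a fraction of that cohort's
    outcome noise SD, so each cohort contributes comparable evidence.
    """
    specs = cohort_specs if cohort_specs is not None else paper_like_cohort_specs()
    composition = _subset_composition(n_metabolites)

    effects: list[EffectSpec] = []
    if plant_effects:
        ann = generate_annotation(
            GeneratorConfig(
                seed=seed,
                n_metabolites=n_metabolites,
                subclass_composition=composition,
                cohort_specs=specs,
            )
        )
        tag_members = tuple(
            ann.loc[ann["sub_class"] == "Triradylcglycerols", "metabolite"]
            .iloc[:n_homogeneous_members]
        )
        aa_members = tuple(
            ann.loc[
                ann["sub_class"] == "Amino acids, peptides, and analogues",
                "metabolite",
            ].iloc[:n_heterogeneous_members]
        )
        surgical = specs[-1].name
        effects = [
            EffectSpec(
                set_name="Triradylcglycerols",
                member_metabolites=tag_members,
                beta_per_cohort={
                    s.name: -homogeneous_effect_size * s.pct_change_mean_sd[1]
                    for s in specs
                },
            ),
            EffectSpec(
                set_name="Amino acids, peptides, and analogues",
                member_metabolites=aa_members,
                beta_per_cohort={
                    s.name: (
                        heterogeneous_effect_size * s.pct_change_mean_sd[1]
                        if s.name == surgical
                        else -heterogeneous_effect_size * s.pct_change_mean_sd[1]
                    )
                    for s in specs
                },
            ),
        ]

    return GeneratorConfig(
        seed=seed,
        n_metabolites=n_metabolites,
        subclass_composition=composition,
        cohort_specs=specs,
        effects=tuple(effects),
        missingness_rate=missingness_rate,
        n_outcome_outliers=n_outcome_outliers,
    )


def null_config(
    seed: int,
    n_metabolites: int = 200,
    n_subclasses: int = 20,
    cohort_sizes: tuple[int, ...] = (200, 100, 80),
    missingness_rate: float = 0.0,
    within_subclass_correlation: float = 0.0,
) -> GeneratorConfig:
    """A scaled-down study with no planted effects, for null calibration.

    Subclasses are equal-size generic sets; outcome outliers are off so the
    exclusion step is a no-op under the null.  Metabolites are generated
    uncorrelated by default: the membership-permutation null treats ranked
    positions as exchangeable, so calibration is assessed under the
    conditions where that assumption holds (within-set correlation is a
    documented source of anti-conservatism, as in any preranked
    set-enrichment test).
    """
    base, rem = divmod(n_metabolites, n_subclasses)
    composition = {
        f"Nullclass {i + 1:02d}": base + (1 if i < rem else 0)
        for i in range(n_subclasses)
    }
    paper = paper_like_cohort_specs()
    specs = tuple(
        dataclasses.replace(paper[i % 3], name=f"NullCohort{i + 1}", n_subjects=n)
        for i, n in enumerate(cohort_sizes)
    )
    return GeneratorConfig(
        seed=seed,
        n_metabolites=n_metabolites,
        subclass_composition=composition,
        cohort_specs=specs,
        effects=(),
        within_subclass_correlation=within_subclass_correlation,
        missingness_rate=missingness_rate,
        n_outcome_outliers=0,
    )
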