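"""GSEA-style metabolite-set enrichment over a ranked metabolite list.

Metabolites are ranked by a per-metabolite statistic — the signed z-score
from the random-effects meta-analysis (association analysis) or the
nonnegative Cochran Q statistic (heterogeneity analysis).  For each
a-priori set (HMDB taxonomy subclass), a weighted Kolmogorov–Smirnov-like
random walk runs down the list: set members ("hits") add
|s|^w / Σ_hits |s|^w, non-members subtract 1/(N − n).  The enrichment score
(ES) is the signed extremum of the running sum, so sets concentrated at the
top of the list score positive and sets at the bottom negative.

Significance is calibrated by membership permutation: each permutation
draws a uniformly random size-matched subset of the ranked list and records
its ES.  The permutation p-value is one-sided in the direction of the
observed ES against same-sign null scores, with +1 smoothing so p is never
zero; NES normalizes ES by the mean magnitude of same-sign null scores.
Benjamini–Hochberg FDR is applied across all tested sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from metabometa.errors import DataError
from metabometa.meta import bh_fdr

RANKING_MODES = ("signed_z", "q_stat")


@dataclass(frozen=True)
class RankedList:
    """Metabolite ids ordered by statistic, descending; ties by id."""

    ids: tuple
    stats: np.ndarray
    mode: str = "signed_z"

    def __post_init__(self):
        stats = np.asarray(self.stats, dtype=float)
        object.__setattr__(self, "stats", stats)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != len(stats):
            raise DataError("ids and statistics differ in length")
        if len(self.ids) == 0:
            raise DataError("empty ranked list")
        if np.any(np.isnan(stats)):
            raise DataError("ranked list contains missing statistics")
        if np.any(np.diff(stats) > 0):
            raise DataError("statistics must be sorted descending")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MetaboliteSet:
    """Named set of metabolite ids (an HMDB subclass, typically)."""

    name: str
    members: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    ES: float
    NES: float
    pval: float
    padj: float
    nMoreExtreme: int
    size: int


def rank_metabolites(meta_table: pd.DataFrame, mode: str = "signed_z") -> RankedList:
    """Rank a meta-analysis table by signed z (association) or Q (heterogeneity).

    In ``q_stat`` mode, single-cohort metabolites (Q undefined, df = 0) are
    dropped before ranking.  Ties break by lexicographic metabolite id so
    the order is stable across runs.
    """
    if mode not in RANKING_MODES:
        raise ValueError(f"unknown ranking mode {mode!r}")
    if len(meta_table) == 0:
        raise DataError("empty meta-analysis table")
    table = meta_table
    col = "Zvalue_Random" if mode == "signed_z" else "Q"
    if mode == "q_stat":
        table = table[table["N_Studies"] >= 2]
        if len(table) == 0:
            raise DataError("no multi-cohort metabolites to rank by Q")
    sub = table[["Metabolite", col]].copy()
    if sub[col].isna().any():
        raise DataError(f"missing {col} for some metabolites")
    sub = sub.sort_values(
        [col, "Metabolite"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(
        ids=tuple(sub["Metabolite"]), stats=sub[col].to_numpy(float), mode=mode
    )


def _es_from_hits(
    stats: np.ndarray, hits: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray]:
    n_total = len(stats)
    n_hits = int(hits.sum())
    wgt = np.abs(stats) ** weight_exponent
    hit_mass = wgt[hits]
    total = hit_mass.sum()
    if total == 0.0:
        if weight_exponent > 0 and np.all(wgt == 0):
            raise DataError("all statistics are zero; weighted walk is degenerate")
        # hits fall entirely on zero-statistic positions: equal hit mass
        increments = np.where(hits, 1.0 / n_hits, -1.0 / (n_total - n_hits))
    else:
        increments = np.where(hits, wgt / total, -1.0 / (n_total - n_hits))
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def enrichment_score(
    ranked: RankedList,
    metabolite_set: MetaboliteSet | Sequence[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and full running-sum curve for one set against a ranked list.

    The curve starts after the first list position and ends at 0 (hit mass
    and miss mass each total 1); the ES is the point of largest magnitude,
    sign retained.
    """
    members = (
        metabolite_set.members
        if isinstance(metabolite_set, MetaboliteSet)
        else tuple(metabolite_set)
    )
    member_set = set(members)
    hits = np.fromiter((m in member_set for m in ranked.ids), bool, len(ranked))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise DataError("set shares no metabolite with the ranked list")
    if n_hits >= len(ranked):
        raise DataError("set covers the entire ranked list; walk undefined")
    return _es_from_hits(ranked.stats, hits, weight_exponent)


def _null_block(stats, hit_matrix, weight_exponent):
    """ES for a block of size-matched random memberships (rows of hit_matrix)."""
    n_total = stats.shape[0]
    wgt = np.abs(stats) ** weight_exponent
    n_hits = hit_matrix[0].sum()
    hit_mass = hit_matrix * wgt
    totals = hit_mass.sum(axis=1, keepdims=True)
    miss = -1.0 / (n_total - n_hits)
    with np.errstate(invalid="ignore", divide="ignore"):
        increments = np.where(hit_matrix, hit_mass / totals, miss)
    degenerate = totals[:, 0] == 0.0
    if degenerate.any():
        increments[degenerate] = np.where(
            hit_matrix[degenerate], 1.0 / n_hits, miss
        )
    running = np.cumsum(increments, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    seed,
    weight_exponent: float = 1.0,
    exhaustive: bool = False,
    _block: int = 4096,
) -> np.ndarray:
    """Null ES sample from random size-matched memberships.

    Each permutation draws a uniformly random subset of ``set_size``
    positions of the ranked list and records its ES.  The null depends only
    on the ranked statistics and the set size, so one sample is shared by
    every set of equal size.  With ``exhaustive=True`` all C(N, size)
    memberships are enumerated instead (tiny lists only).
    """
    n_total = len(ranked)
    if not 0 < set_size < n_total:
        raise DataError("set size must lie strictly between 0 and the list length")
    stats = ranked.stats
    if exhaustive:
        combos = itertools.combinations(range(n_total), set_size)
        out = np.empty(comb(n_total, set_size))
        pos = 0
        while True:
            block = list(itertools.islice(combos, _block))
            if not block:
                break
            hit = np.zeros((len(block), n_total), dtype=bool)
            rows = np.repeat(np.arange(len(block)), set_size)
            hit[rows, np.concatenate(block)] = True
            out[pos : pos + len(block)] = _null_block(stats, hit, weight_exponent)
            pos += len(block)
        return out
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    pos = 0
    while pos < n_perm:
        b = min(_block, n_perm - pos)
        # smallest `set_size` of B×N uniforms give uniform random subsets
        u = rng.random((b, n_total))
        chosen = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
        hit = np.zeros((b, n_total), dtype=bool)
        hit[np.repeat(np.arange(b), set_size), chosen.ravel()] = True
        out[pos : pos + b] = _null_block(stats, hit, weight_exponent)
        pos += b
    return out


def _same_sign_pool(es: float, null_sample: np.ndarray) -> np.ndarray:
    return null_sample[null_sample >= 0] if es >= 0 else null_sample[null_sample <= 0]


def permutation_pvalue(es: float, null_sample: np.ndarray) -> tuple[float, int]:
    """One-sided permutation p in the direction of the observed ES.

    ``nMoreExtreme`` counts same-sign null scores at least as extreme as the
    observed ES; p = (nMoreExtreme + 1) / (n_same_sign + 1), never zero.
    """
    if len(null_sample) == 0:
        raise DataError("empty null sample")
    pool = _same_sign_pool(es, null_sample)
    n_more = int((pool >= es).sum()) if es >= 0 else int((pool <= es).sum())
    return (n_more + 1) / (len(pool) + 1), n_more


def normalized_es(es: float, null_sample: np.ndarray) -> float:
    """NES = ES / mean |same-sign null ES|; missing if no same-sign nulls."""
    pool = _same_sign_pool(es, null_sample)
    if len(pool) == 0 or np.all(pool == 0):
        warnings.warn("no same-sign null scores; NES undefined", stacklevel=2)
        return float("nan")
    return float(es / np.mean(np.abs(pool)))


def run_enrichment(
    meta_table: pd.DataFrame,
    set_db: Sequence[MetaboliteSet],
    mode: str = "signed_z",
    n_perm: int = 10_000,
    min_size: int = 5,
    seed=0,
    weight_exponent: float = 1.0,
    exhaustive: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every qualifying set against the ranked metabolite list.

    Sets with fewer than ``min_size`` members present in the ranked list are
    not tested.  Null ES samples are shared across sets of equal size and
    are seeded per size, so results do not depend on the ordering of the set
    database.  Returns the per-set results table (columns pathway, pval,
    padj, ES, NES, nMoreExtreme, size, sorted by padj) and a tidy table of
    hit positions/statistics for enrichment ("barcode") plots.
    """
    ranked = rank_metabolites(meta_table, mode=mode)
    id_to_rank = {m: i for i, m in enumerate(ranked.ids)}

    tested = []
    for s in sorted(set_db, key=lambda s: s.name):
        present = [m for m in s.members if m in id_to_rank]
        if len(present) >= min_size and len(present) < len(ranked):
            tested.append((s.name, present))
    if not tested:
        warnings.warn("no set passes the minimum-size filter", stacklevel=2)
        empty = pd.DataFrame(
            columns=["pathway", "pval", "padj", "ES", "NES", "nMoreExtreme", "size"]
        )
        return empty, pd.DataFrame(columns=["pathway", "rank", "Metabolite", "statistic"])

    nulls: dict[int, np.ndarray] = {}
    rows, plot_rows = [], []
    for name, present in tested:
        size = len(present)
        if size not in nulls:
            nulls[size] = permutation_null(
                # per-size child seed keeps the shared null order-independent
                ranked, size, n_perm, [int(seed), size],
                weight_exponent=weight_exponent, exhaustive=exhaustive,
            )
        es, _ = enrichment_score(ranked, present, weight_exponent)
        pval, n_more = permutation_pvalue(es, nulls[size])
        nes = normalized_es(es, nulls[size])
        rows.append(
            {
                "pathway": name,
                "pval": pval,
                "padj": np.nan,
                "ES": es,
                "NES": nes,
                "nMoreExtreme": n_more,
                "size": size,
            }
        )
        for m in present:
            r = id_to_rank[m]
            plot_rows.append(
                {
                    "pathway": name,
                    "rank": r + 1,
                    "Metabolite": m,
                    "statistic": ranked.stats[r],
                }
            )

    table = pd.DataFrame(rows)
    table["padj"] = bh_fdr(table["pval"])
    table = table.sort_values(
        ["padj", "pval", "pathway"], kind="mergesort"
    ).reset_index(drop=True)
    plot_data = pd.DataFrame(plot_rows).sort_values(
        ["pathway", "rank"], kind="mergesort"
    ).reset_index(drop=True)
    return table, plot_data
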