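"""Independent straight-from-formula oracles used to cross-check the package.

Everything here is written directly from textbook definitions (normal
equations, moment formulas, step-up definition, literal random-walk loops)
and deliberately shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.special import gammaincc, stdtr


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """OLS by explicit normal equations with classical t inference.

    Returns (beta vector, se vector, two-sided p vector).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    # two-sided p from the t CDF (stdtr is the regularized incomplete beta)
    pvals = 2.0 * (1.0 - stdtr(n - p, np.abs(t)))
    return beta, se, pvals


def norm_sf2(z: float) -> float:
    """Two-sided normal tail via the complementary error function."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def meta_oracle(betas, ses) -> dict:
    """Fixed effects, Cochran Q, DL tau^2, random effects — all from formulas."""
    betas = [float(b) for b in betas]
    ses = [float(s) for s in ses]
    k = len(betas)
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    beta_f = sum(wi * bi for wi, bi in zip(w, betas)) / sw
    se_f = sw ** -0.5
    z_f = beta_f / se_f
    out = {
        "beta_fixed": beta_f,
        "se_fixed": se_f,
        "z_fixed": z_f,
        "p_fixed": norm_sf2(z_f),
    }
    q = sum(wi * (bi - beta_f) ** 2 for wi, bi in zip(w, betas))
    df = k - 1
    out["Q"] = q
    out["Q_df"] = df
    out["Q_p"] = float(gammaincc(df / 2.0, q / 2.0)) if df >= 1 else math.nan
    if df >= 1:
        denom = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - df) / denom)
        out["H"] = math.sqrt(q / df)
        out["I2"] = 0.0 if q == 0 else max(0.0, (q - df) / q)
    else:
        tau2 = 0.0
        out["H"] = math.nan
        out["I2"] = math.nan
    out["tau2"] = tau2
    ws = [1.0 / (s**2 + tau2) for s in ses]
    sws = sum(ws)
    beta_r = sum(wi * bi for wi, bi in zip(ws, betas)) / sws
    se_r = sws ** -0.5
    z_r = beta_r / se_r
    out.update(
        beta_random=beta_r, se_random=se_r, z_random=z_r, p_random=norm_sf2(z_r)
    )
    return out


def bh_oracle(pvals):
    """Benjamini–Hochberg step-up, literally from the definition."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def es_oracle(stats, hit_positions, weight_exponent=1.0):
    """Enrichment score by a literal element-by-element random walk."""
    stats = [float(s) for s in stats]
    hits = set(int(i) for i in hit_positions)
    n_total = len(stats)
    n_hits = len(hits)
    assert 0 < n_hits < n_total
    nr = sum(abs(stats[i]) ** weight_exponent for i in hits)
    cur, best = 0.0, 0.0
    curve = []
    for i in range(n_total):
        if i in hits:
            cur += (abs(stats[i]) ** weight_exponent / nr) if nr > 0 else 1.0 / n_hits
        else:
            cur -= 1.0 / (n_total - n_hits)
        curve.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, curve


def exhaustive_null_oracle(stats, set_size, weight_exponent=1.0):
    """ES for every size-matched membership, by enumeration."""
    n_total = len(stats)
    return [
        es_oracle(stats, combo, weight_exponent)[0]
        for combo in combinations(range(n_total), set_size)
    ]


def perm_p_oracle(es, null_scores):
    """One-sided same-sign permutation p with +1 smoothing, from definition."""
    if es >= 0:
        pool = [x for x in null_scores if x >= 0]
        n_more = sum(1 for x in pool if x >= es)
    else:
        pool = [x for x in null_scores if x <= 0]
        n_more = sum(1 for x in pool if x <= es)
    return (n_more + 1) / (len(pool) + 1), n_more
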