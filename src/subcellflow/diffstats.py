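"""Empirical-Bayes moderated two-group testing per fraction.

The per-feature residual variances s²_g (d_g residual degrees of freedom)
are assumed to follow a scaled inverse-chi-square prior with d0 degrees of
freedom and scale s0². The posterior variance

    s²_post = (d0·s0² + d_g·s²_g) / (d0 + d_g)

replaces s²_g in the two-sample t statistic, which then follows a t
distribution with d0 + d_g degrees of freedom under the null. (d0, s0²)
are estimated by moment matching on the log residual variances: under the
prior, e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s0² + ψ(d0/2) −
log(d0/2) and excess variance ψ'(d0/2) beyond ψ'(d_g/2), where ψ and ψ'
are the digamma and trigamma functions; d0 follows from inverting the
trigamma function by Newton iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .core import QuantTable

__all__ = ["ModeratedStats", "fit_moderated", "bh_adjust", "squeeze_variances"]

log = logging.getLogger(__name__)

_D0_CAP = 1e6  # "infinite" prior df: complete shrinkage to s0²


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over ranks j >= rank(i) of p_(j)·m/j, capped at 1;
    order-preserving in p. NaN inputs propagate as NaN and do not count
    toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        scaled = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qv, 1.0)
        q[valid] = out
    return q


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0²) from per-feature variances and return
    (d0, s0², posterior variances)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df > 0) & (s2 > 0)
    if ok.sum() < 2:
        # degenerate input (e.g. noiseless data): no information to pool,
        # fall back to unmoderated per-feature variances
        log.warning(
            "squeeze_variances: fewer than 2 positive residual variances; "
            "moderation disabled"
        )
        return 0.0, float("nan"), s2.copy()
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, _D0_CAP)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = _D0_CAP
        s0_sq = float(np.exp(emean))
    s2_post = _posterior_var(s2, df, d0, s0_sq)
    return float(d0), s0_sq, s2_post


def _posterior_var(s2: np.ndarray, df: np.ndarray, d0: float, s0_sq: float):
    if np.isinf(d0) or d0 >= _D0_CAP:
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class ModeratedStats:
    """Result of one two-group contrast in one fraction.

    ``table`` has one row per tested feature with columns mean_a, mean_b,
    logFC (a − b), s2, df_resid, s2_post, t, df_total, p, q, n_a, n_b.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    fraction: int
    condition_a: str
    condition_b: str

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def qvalues(self) -> pd.Series:
        return self.table["q"]


def fit_moderated(
    table: QuantTable,
    condition_a: str,
    condition_b: str,
    fraction: int,
    min_valid: int = 3,
    prior_df: float | None = None,
) -> ModeratedStats:
    """Moderated two-group test of ``condition_a`` versus ``condition_b``
    within one fraction.

    A feature enters the contrast only if it is retained in the fraction
    and at least one of the two groups originally held ``min_valid``
    observed values. logFC is mean(a) − mean(b); the two-sided p comes
    from the t distribution with d0 + d_g degrees of freedom. Pass
    ``prior_df`` to pin d0 (0 disables shrinkage and recovers the ordinary
    pooled-variance t; values >= 1e6 mean complete shrinkage).
    """
    cols_a = list(table.design.samples_for(fraction=fraction, condition=condition_a))
    cols_b = list(table.design.samples_for(fraction=fraction, condition=condition_b))
    cols_a = [c for c in cols_a if c in table.values.columns]
    cols_b = [c for c in cols_b if c in table.values.columns]
    if not cols_a or not cols_b:
        raise ValueError(
            f"fraction {fraction} lacks samples for {condition_a!r} or {condition_b!r}"
        )

    va = table.values[cols_a]
    vb = table.values[cols_b]
    obs_a = table.observed[cols_a].sum(axis=1)
    obs_b = table.observed[cols_b].sum(axis=1)
    eligible = (obs_a >= min_valid) | (obs_b >= min_valid)
    if table.retained is not None and fraction in table.retained.columns:
        eligible &= table.retained[fraction]

    n_a = va.notna().sum(axis=1)
    n_b = vb.notna().sum(axis=1)
    df_resid = (n_a - 1).clip(lower=0) + (n_b - 1).clip(lower=0)
    usable = eligible & (n_a >= 1) & (n_b >= 1) & (df_resid > 0)
    n_dropped = int((eligible & ~usable).sum())
    if n_dropped:
        log.info(
            "fit_moderated: excluded %d features with zero residual df "
            "(fraction %s, %s vs %s)", n_dropped, fraction, condition_a, condition_b,
        )

    va, vb = va.loc[usable], vb.loc[usable]
    n_a, n_b, df_resid = n_a[usable], n_b[usable], df_resid[usable].astype(float)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    ss = ((va.sub(mean_a, axis=0)) ** 2).sum(axis=1) + (
        (vb.sub(mean_b, axis=0)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq, s2_post = squeeze_variances(s2.to_numpy(), df_resid.to_numpy())
    elif prior_df <= 0:
        d0, s0_sq = 0.0, float("nan")
        s2_post = s2.to_numpy().copy()
    else:
        d0 = min(float(prior_df), _D0_CAP)
        # with a pinned d0, s0² still comes from the moment equation
        _, s0_sq, _ = squeeze_variances(s2.to_numpy(), df_resid.to_numpy())
        s2_post = _posterior_var(s2.to_numpy(), df_resid.to_numpy(), d0, s0_sq)

    se = np.sqrt(s2_post) * np.sqrt(1.0 / n_a + 1.0 / n_b)
    logfc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc.to_numpy() / se.to_numpy()
    # total df cannot exceed the information actually pooled across features
    df_pooled = float(df_resid.sum())
    df_total = np.minimum(d0 + df_resid.to_numpy(), max(df_pooled, df_resid.max()))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "logFC": logfc,
            "s2": s2,
            "df_resid": df_resid,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=va.index,
    )
    return ModeratedStats(
        table=out, d0=d0, s0_sq=s0_sq, fraction=fraction,
        condition_a=condition_a, condition_b=condition_b,
    )
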