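"""Differential expression of miRNA probes.

Tissue contrasts use a per-probe two-group linear model with
empirical-Bayes variance moderation: per-probe residual variances s_g^2 on
d degrees of freedom are shrunk toward a common prior s0^2 with prior
degrees of freedom d0, both estimated by the method of moments on
log variances, giving the posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and a moderated t statistic referred to a t distribution on d0 + d degrees
of freedom.  Stage (time-course) comparisons within a tissue use, per
probe, the two-sample Hotelling T^2 for each stage pair — in this
univariate setting the squared pooled-variance t — and rank probes by the
maximum over the three pairs.  Multiple testing is controlled with the
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .io import ValidationError
from .normalize import NormalizedMatrix

__all__ = [
    "DEResult",
    "TimecourseResult",
    "moderated_de",
    "benjamini_hochberg",
    "timecourse_max_t2",
    "top_k_overlap",
    "pca",
    "estimate_variance_prior",
]


@dataclass
class DEResult:
    """Per-probe statistics for one two-group contrast.

    ``table`` is indexed by probe id with columns ``mean_case``,
    ``mean_control``, ``log2fc`` (difference of group means on the input
    scale), ``fold_change`` (2**log2fc), ``t``, ``p``, ``adj_p``.
    """

    table: pd.DataFrame
    label: str
    d0: float
    s0_sq: float
    residual_df: int


@dataclass
class TimecourseResult:
    """Per-probe pairwise Hotelling T^2 across stages within one tissue.

    ``table`` is indexed by probe id with one ``t2_<a>_vs_<b>`` column per
    stage pair, plus ``max_t2`` and ``rank`` (1 = largest max_t2; ties
    broken by probe id).
    """

    table: pd.DataFrame
    tissue: str
    stages: tuple[str, ...]

    def top_k(self, k: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:k])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_variance_prior(s_sq: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from per-probe sample
    variances on ``df`` degrees of freedom.

    Works on e_g = log(s_g^2) - digamma(df/2) + log(df/2), whose mean and
    excess variance over trigamma(df/2) identify the prior.  Returns
    d0 = inf when the observed log-variance spread is at or below the
    sampling noise (no heterogeneity: complete shrinkage).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s_sq[ok])) if ok.any() else 0.0
    e = np.log(s_sq[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no detectable variance heterogeneity: complete shrinkage to the
        # geometric mean of the sample variances, so a matrix of identical
        # per-probe variances is a fixed point (moderated t == pooled t)
        return np.inf, float(np.exp(np.mean(np.log(s_sq[ok]))))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de(
    norm: NormalizedMatrix | pd.DataFrame,
    group_case: Sequence[str],
    group_control: Sequence[str],
    label: str = "",
    prior_df: float | None = None,
) -> DEResult:
    """Two-group moderated-t contrast on a probe-by-sample value matrix.

    ``group_case``/``group_control`` are disjoint sample-id sets with at
    least two members each.  ``prior_df`` overrides the estimated d0
    (``prior_df=0`` disables moderation, recovering the ordinary pooled
    two-sample t).  The ``log2fc`` column is the difference of group means
    on the scale of the input values.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    case = list(group_case)
    control = list(group_control)
    if len(case) < 2 or len(control) < 2:
        raise ValidationError("each group needs at least two samples")
    if set(case) & set(control):
        raise ValidationError("groups overlap")
    x1 = values[case].to_numpy(dtype=float)
    x2 = values[control].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValidationError("non-finite values in input matrix")
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    if df <= 0:
        raise ValidationError("zero residual degrees of freedom")
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = (ss1 + ss2) / df

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s_sq, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s_sq, df)

    if np.isinf(d0):
        post_var = np.full_like(s_sq, s0_sq)
        total_df = np.inf
    else:
        post_var = (d0 * s0_sq + df * s_sq) / (d0 + df)
        total_df = d0 + df

    effect = m1 - m2
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "log2fc": effect,
            "fold_change": np.exp2(effect),
            "t": t,
            "p": p,
            "adj_p": benjamini_hochberg(p),
        },
        index=values.index,
    )
    return DEResult(table=table, label=label, d0=float(d0), s0_sq=float(s0_sq),
                    residual_df=df)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _pooled_t2(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Squared pooled-variance two-sample t, rows = probes.

    A probe with zero pooled variance gets T^2 = 0 when the means agree and
    +inf when they differ (a deterministic difference).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = ss / (n1 + n2 - 2)
    diff = m1 - m2
    denom = pooled * (1.0 / n1 + 1.0 / n2)
    out = np.zeros_like(diff)
    nonzero = denom > 0
    out[nonzero] = diff[nonzero] ** 2 / denom[nonzero]
    out[~nonzero & (diff != 0)] = np.inf
    return out


def timecourse_max_t2(
    norm: NormalizedMatrix, tissue: str, probes: set[str] | None = None
) -> TimecourseResult:
    """Rank probes within one tissue by the maximum pairwise Hotelling T^2
    across the three stage comparisons.

    ``probes`` optionally restricts the ranking to a probe subset (e.g.
    miRNA-class probes only).
    """
    meta = norm.meta.loc[list(norm.values.columns)]
    in_tissue = meta["tissue"].astype(str) == str(tissue)
    if not in_tissue.any():
        raise ValidationError(f"no samples for tissue {tissue!r}")
    stages = sorted(meta.loc[in_tissue, "stage"].astype(str).unique())
    if len(stages) < 3:
        raise ValidationError(
            f"tissue {tissue!r} has stages {stages}; need 3 for the time course"
        )
    values = norm.values
    if probes is not None:
        values = values.loc[sorted(set(probes) & set(values.index))]
    groups = {}
    for st in stages:
        ids = list(meta.index[in_tissue & (meta["stage"].astype(str) == st)])
        if len(ids) < 2:
            raise ValidationError(f"stage {st!r} has fewer than 2 replicates")
        groups[st] = values[ids].to_numpy(dtype=float)
    cols = {}
    for a, b in combinations(stages, 2):
        cols[f"t2_{a}_vs_{b}"] = _pooled_t2(groups[a], groups[b])
    table = pd.DataFrame(cols, index=values.index)
    table["max_t2"] = table.max(axis=1)
    order = sorted(
        table.index, key=lambda pid: (-table.at[pid, "max_t2"], pid)
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    table["rank"] = ranks
    return TimecourseResult(table=table, tissue=str(tissue), stages=tuple(stages))


def top_k_overlap(
    results: Mapping[str, TimecourseResult], k: int
) -> tuple[dict[frozenset, int], pd.DataFrame]:
    """Venn regions of the top-k probe lists of three tissues.

    Returns (region counts keyed by the frozenset of tissues sharing the
    probes, membership table with one boolean column per tissue).  Top-k
    lists use the deterministic (max_t2 desc, probe id asc) order.
    """
    if len(results) < 3:
        raise ValidationError("need time-course results for three tissues")
    tops = {}
    for tissue, res in results.items():
        if k > len(res.table):
            raise ValidationError(f"k={k} exceeds probe count {len(res.table)}")
        order = sorted(
            res.table.index, key=lambda pid: (-res.table.at[pid, "max_t2"], pid)
        )
        tops[tissue] = set(order[:k])
    universe = sorted(set().union(*tops.values()))
    membership = pd.DataFrame(
        {t: [pid in tops[t] for pid in universe] for t in sorted(tops)},
        index=universe,
    )
    regions: dict[frozenset, int] = {}
    for pid in universe:
        key = frozenset(t for t in tops if pid in tops[t])
        regions[key] = regions.get(key, 0) + 1
    return regions, membership


def pca(norm: NormalizedMatrix | pd.DataFrame):
    """Sample-space PCA of the probe-by-sample matrix via SVD.

    Samples are the observations; probes are centered (not scaled).
    Returns (scores, loadings, variance_fractions): scores is samples x
    components, loadings is probes x components, fractions sum to one.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least two samples")
    x = values.to_numpy(dtype=float).T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x != 0):
        raise ValidationError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    ncomp = int(np.sum(s > s[0] * 1e-12))
    comps = [f"PC{i+1}" for i in range(ncomp)]
    scores = pd.DataFrame((u * s)[:, :ncomp], index=values.columns, columns=comps)
    loadings = pd.DataFrame(vt[:ncomp].T, index=values.index, columns=comps)
    return scores, loadings, frac[:ncomp]
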