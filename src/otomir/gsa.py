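"""Annotation-transfer gene-set analysis at the miRNA level.

Pathway -> gene sets are converted into pathway -> miRNA sets through the
target link table (a pathway's miRNA set is every miRNA with at least one
target gene in the pathway).  Each pathway is then scored by a logistic
regression of set membership on the standardized per-miRNA ranking
statistic r across all tested miRNAs; the slope is the reported log odds
ratio (LOR) with a Wald p-value, BH-adjusted across pathways.  A positive
LOR means the pathway's miRNAs carry systematically larger r — more
targeting of the pathway in the case condition than the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .diffexp import DEResult, benjamini_hochberg
from .io import PathwaySets, TargetLinkTable, ValidationError

__all__ = [
    "MirnaAnnotation",
    "GsaResult",
    "transfer_annotations",
    "ranking_index",
    "logistic_gsa",
]


@dataclass
class MirnaAnnotation:
    """pathway id -> transferred miRNA set, with (pathway, miRNA, via-gene)
    provenance rows kept for audit."""

    sets: dict[str, frozenset[str]]
    provenance: pd.DataFrame
    n_dropped_empty: int = 0


@dataclass
class GsaResult:
    """Per-pathway LOR table for one contrast: columns ``lor``, ``p``,
    ``adj_p``, ``set_size``, ``separated``."""

    table: pd.DataFrame
    label: str


def transfer_annotations(
    pathways: PathwaySets, links: TargetLinkTable
) -> MirnaAnnotation:
    """Annotation transfer: pathway's miRNA set = miRNAs targeting >= 1 of
    its genes.  Pathways whose transferred set is empty are dropped (their
    count is recorded)."""
    if len(pathways) == 0 or links.n_links == 0:
        raise ValidationError("need non-empty pathways and links")
    gene_to_mirnas: dict[str, set[str]] = {}
    for m, g in links.links:
        gene_to_mirnas.setdefault(g, set()).add(m)
    sets: dict[str, frozenset[str]] = {}
    prov_rows = []
    dropped = 0
    for pid in pathways.ids():
        members: set[str] = set()
        for g in pathways.genes(pid):
            hit = gene_to_mirnas.get(g)
            if hit:
                members |= hit
                prov_rows.extend((pid, m, g) for m in sorted(hit))
        if members:
            sets[pid] = frozenset(members)
        else:
            dropped += 1
    provenance = pd.DataFrame(prov_rows, columns=["pathway", "mirna", "via_gene"])
    return MirnaAnnotation(sets=sets, provenance=provenance, n_dropped_empty=dropped)


def ranking_index(de: DEResult, transform: str = "t") -> pd.Series:
    """Per-miRNA ranking statistic r for one contrast.

    ``transform="t"`` (default) uses the moderated t statistic;
    ``transform="normal_quantile"`` maps signed p-value ranks through
    standard-normal quantiles (a heavy-tail-robust alternative).
    """
    tab = de.table
    if transform == "t":
        r = tab["t"].astype(float)
    elif transform == "normal_quantile":
        from scipy.stats import norm, rankdata

        signed = np.sign(tab["t"].to_numpy()) * (1.0 - tab["p"].to_numpy())
        u = rankdata(signed) / (len(signed) + 1.0)
        r = pd.Series(norm.ppf(u), index=tab.index)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if not np.all(np.isfinite(r.to_numpy())):
        raise ValidationError("non-finite ranking statistic")
    return r


def _fit_logistic(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    """Slope and Wald p of a logistic fit y ~ 1 + x.

    On perfect separation (or non-convergence) the slope is re-estimated
    with a small L2 ridge and flagged; the p-value is then from the
    penalized Wald statistic and should be read as stabilized, not exact.
    """
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            if np.all(np.isfinite(fit.bse)) and fit.converged \
                    and np.abs(fit.params[1]) < 1e3:
                return float(fit.params[1]), float(fit.pvalues[1]), False
        except (PerfectSeparationWarning, Exception):
            pass
    # ridge-stabilized IRLS fallback
    beta = np.zeros(2)
    lam = 1e-2
    Xd = X
    for _ in range(200):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = Xd.T @ (y - mu) - lam * beta
        hess = Xd.T @ (Xd * w[:, None]) + lam * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]) + lam * np.eye(2))
    se = float(np.sqrt(cov[1, 1]))
    from scipy.stats import norm

    z = beta[1] / se if se > 0 else 0.0
    return float(beta[1]), float(2.0 * norm.sf(abs(z))), True


def logistic_gsa(
    r: pd.Series,
    annotation: MirnaAnnotation,
    size_bounds: tuple[int, int] = (3, 500),
    label: str = "",
) -> GsaResult:
    """Logistic-regression gene-set analysis over all tested miRNAs.

    ``r`` is indexed by miRNA id (the tested universe).  For each pathway
    whose transferred miRNA set, intersected with the tested universe, has
    a size within ``size_bounds``, membership is regressed on standardized
    r; the LOR is the slope per standard deviation of r.
    """
    if r.empty:
        raise ValidationError("empty ranking statistic")
    x = r.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite ranking statistic")
    sd = x.std(ddof=0)
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    tested = set(r.index)
    lo, hi = size_bounds
    rows = []
    for pid, members in sorted(annotation.sets.items()):
        present = members & tested
        if not (lo <= len(present) <= hi):
            continue
        y = np.fromiter((1.0 if m in present else 0.0 for m in r.index),
                        dtype=float, count=len(r))
        if sd == 0:
            rows.append((pid, 0.0, 1.0, len(present), False))
            continue
        slope, p, separated = _fit_logistic(y, z)
        rows.append((pid, slope, min(1.0, p), len(present), separated))
    if not rows:
        raise ValidationError("no pathway within the size bounds")
    table = pd.DataFrame(
        rows, columns=["pathway", "lor", "p", "set_size", "separated"]
    ).set_index("pathway")
    table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    table = table[["lor", "p", "adj_p", "set_size", "separated"]]
    return GsaResult(table=table, label=label)
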