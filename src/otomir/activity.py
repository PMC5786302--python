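"""Per-sample pathway activity from miRNA expression.

miRNA expression is first transferred to gene-level activity: a gene's
activity in a sample is the (sign-adjusted) mean of the normalized values
of the miRNAs that target it — under the default repression sign, high
expression of a gene's miRNAs means low predicted activity of the gene.

Gene sets are then scored per sample with a rank random-walk enrichment
statistic in the GSVA family: each gene's across-sample values are turned
into a Gaussian-kernel cumulative-density estimate, genes are ranked per
sample by that estimate, and a weighted Kolmogorov-Smirnov walk over the
ranking (weight exponent tau, default 1) yields a signed enrichment score
in [-1, 1].  Both the in-set and out-of-set steps are weighted by the
centered-rank statistic, which makes the score of a set's complement the
exact negation of the set's score.

By default the kernel estimate is computed on the within-gene
across-sample fractional ranks (bandwidth = SD of the ranks / 4), so
scores depend on the data only through within-gene orderings and are
invariant under any strictly monotone per-gene transform.  Setting
``kernel_input="values"`` applies the kernel to the raw activity values
(bandwidth = per-gene SD / 4), which is invariant under per-gene affine
transforms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .diffexp import DEResult, moderated_de
from .io import PathwaySets, TargetLinkTable, ValidationError
from .normalize import NormalizedMatrix

__all__ = [
    "GeneActivityMatrix",
    "EnrichmentScoreMatrix",
    "gene_activity_transfer",
    "kernel_cdf_estimate",
    "enrichment_scores",
    "pathway_tissue_test",
]


@dataclass
class GeneActivityMatrix:
    """Genes x samples activity values with the sign convention used."""

    values: pd.DataFrame
    sign: str  # "repression" or "identity"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sign not in ("repression", "identity"):
            raise ValueError(f"unknown sign convention {self.sign!r}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("activity values must be finite")


@dataclass
class EnrichmentScoreMatrix:
    """Pathways x samples enrichment scores plus effective set sizes."""

    values: pd.DataFrame
    set_sizes: pd.Series
    skipped: list[str]
    meta: pd.DataFrame | None = None


def gene_activity_transfer(
    norm: NormalizedMatrix,
    links: TargetLinkTable,
    sign: str = "repression",
    aggregate: str = "mean",
) -> GeneActivityMatrix:
    """Transfer miRNA values to their target genes.

    activity(g, j) = s * agg over distinct miRNAs targeting g of y(m, j),
    with s = -1 under ``sign="repression"`` (default) and +1 under
    ``"identity"``; ``aggregate`` is ``"mean"`` or ``"sum"``.  Genes with
    no targeting miRNA present in the matrix are omitted.
    """
    if links.n_links == 0:
        raise ValidationError("empty link table")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    present = set(norm.values.index)
    gene_to_mirnas: dict[str, set[str]] = {}
    for m, g in links.links:
        if m in present:
            gene_to_mirnas.setdefault(g, set()).add(m)
    if not gene_to_mirnas:
        raise ValidationError("no link miRNA appears in the value matrix")
    s = -1.0 if sign == "repression" else 1.0
    rows = {}
    for g in sorted(gene_to_mirnas):
        block = norm.values.loc[sorted(gene_to_mirnas[g])]
        agg = block.mean(axis=0) if aggregate == "mean" else block.sum(axis=0)
        rows[g] = s * agg
    values = pd.DataFrame(rows).T
    values.columns = norm.values.columns
    return GeneActivityMatrix(values=values, sign=sign, meta=norm.meta)


def kernel_cdf_estimate(
    values: np.ndarray, kernel_input: str = "ranks"
) -> np.ndarray:
    """Across-sample Gaussian-kernel CDF estimate per gene (rows).

    Each entry estimates how high the gene sits in sample j relative to its
    own across-sample distribution.  Bandwidth is SD/4 of the row (of the
    fractional ranks under the default ``kernel_input="ranks"``); a
    constant row has no spread and gets the neutral value 0.5 everywhere.
    """
    if kernel_input not in ("ranks", "values"):
        raise ValueError(f"unknown kernel_input {kernel_input!r}")
    x = np.asarray(values, dtype=float)
    if kernel_input == "ranks":
        x = np.apply_along_axis(rankdata, 1, x)
    sd = x.std(axis=1, ddof=1)
    out = np.full_like(x, 0.5)
    spread = sd > 0
    if np.any(spread):
        xs = x[spread]
        h = (sd[spread] / 4.0)[:, None, None]
        diffs = (xs[:, :, None] - xs[:, None, :]) / h  # gene, eval j, data k
        out[spread] = norm.cdf(diffs).mean(axis=2)
    return out


def _walk_scores(
    order_weights: np.ndarray,
    in_set: np.ndarray,
    tau: float,
    method: str,
) -> float:
    """Signed enrichment score of one (sample, set) from genes already in
    ranking order; ``order_weights`` are the centered-rank magnitudes."""
    w = np.abs(order_weights) ** tau
    w_in = np.where(in_set, w, 0.0)
    w_out = np.where(~in_set, w, 0.0)
    tot_in = w_in.sum()
    tot_out = w_out.sum()
    if tot_in == 0 or tot_out == 0:
        return 0.0
    v = np.cumsum(w_in / tot_in - w_out / tot_out)
    mp, mn = float(v.max()), float(v.min())
    if method == "signed_max":
        return mp if mp >= -mn else mn
    if method == "pos_neg_sum":
        return max(mp, 0.0) + min(mn, 0.0)
    raise ValueError(f"unknown score method {method!r}")


def enrichment_scores(
    activity: GeneActivityMatrix,
    sets: PathwaySets,
    tau: float = 1.0,
    method: str = "signed_max",
    kernel_input: str = "ranks",
    min_set_size: int = 2,
) -> EnrichmentScoreMatrix:
    """Per-sample rank random-walk enrichment score of each gene set.

    Sets are intersected with the available genes; a set with fewer than
    ``min_set_size`` genes present is skipped (recorded in ``skipped``).
    Requires at least 3 samples for the across-sample kernel estimate.
    """
    values = activity.values
    if values.shape[1] < 3:
        raise ValidationError("need at least 3 samples for kernel estimation")
    genes = list(values.index)
    z = kernel_cdf_estimate(values.to_numpy(), kernel_input=kernel_input)
    n_genes, n_samples = z.shape
    # per sample: rank genes by decreasing z, ties broken by gene id
    gene_order = np.argsort(np.array(genes, dtype=object), kind="mergesort")
    score_rows = {}
    sizes = {}
    skipped: list[str] = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    centered = np.abs(np.arange(1, n_genes + 1) - (n_genes + 1) / 2.0)
    order_per_sample = []
    for j in range(n_samples):
        key = -z[:, j]
        order = np.lexsort((np.arange(n_genes)[gene_order].argsort(), key))
        order_per_sample.append(order)
    for pid in sets.ids():
        members = {gene_pos[g] for g in sets.genes(pid) if g in gene_pos}
        if len(members) < min_set_size or len(members) >= n_genes:
            skipped.append(pid)
            continue
        member_mask = np.zeros(n_genes, dtype=bool)
        member_mask[list(members)] = True
        row = np.empty(n_samples)
        for j in range(n_samples):
            order = order_per_sample[j]
            row[j] = _walk_scores(centered, member_mask[order], tau, method)
        score_rows[pid] = row
        sizes[pid] = len(members)
    if not score_rows:
        raise ValidationError("no gene set large enough to score")
    out = pd.DataFrame(score_rows, index=values.columns).T
    return EnrichmentScoreMatrix(
        values=out,
        set_sizes=pd.Series(sizes),
        skipped=skipped,
        meta=activity.meta,
    )


def pathway_tissue_test(
    scores: EnrichmentScoreMatrix,
    group_case: Sequence[str],
    group_control: Sequence[str],
    label: str = "",
) -> DEResult:
    """Moderated-t contrast of pathway scores between two sample groups."""
    return moderated_de(scores.values, group_case, group_control, label=label)
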