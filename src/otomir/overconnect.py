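"""Over-connected gene analysis.

A gene is over-connected when it is targeted by more differentially
expressed miRNAs than expected under hypergeometric sampling of the
miRNA-gene link population.  With N total links among the miRNAs tested in
a contrast, K of them touching the gene, n links emanating from the DE
miRNAs, and k of those touching the gene, the p-value is the upper tail

    p = sum_{j=k..min(K,n)} C(K,j) C(N-K, n-j) / C(N,n)

("targeted at least k times").  Binomial coefficients are evaluated in log
space (log-gamma), so populations of ~1e5 links are exact to double
precision.  DE miRNAs are split by fold-change direction, the test run per
direction, and BH adjustment applied within each (contrast, direction)
gene list; genes pass at adjusted p < 0.10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexp import DEResult, benjamini_hochberg
from .io import TargetLinkTable, ValidationError

__all__ = [
    "OverconnectionResult",
    "hypergeom_upper_tail",
    "hypergeom_point_mass",
    "overconnection_test",
    "split_by_direction",
    "filter_transcription_factors",
    "build_network",
]


@dataclass
class OverconnectionResult:
    """Per-gene over-connection statistics for one direction of one contrast.

    ``table`` is indexed by gene with columns ``K``, ``k``, ``n``, ``N``,
    ``direction``, ``p``, ``adj_p``; ``significant`` is the adjusted-p
    filtered view.
    """

    table: pd.DataFrame
    direction: str
    fdr_threshold: float = 0.10

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < self.fdr_threshold]


def _log_choose(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def hypergeom_point_mass(N: int, K: int, n: int, k: int) -> float:
    """P(exactly k of the gene's K links fall among the n drawn)."""
    num = _log_choose(K, k) + _log_choose(N - K, n - k)
    den = _log_choose(N, n)
    val = num - den
    return float(np.exp(val)) if np.isfinite(val) else 0.0

def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(at least k of the gene's K links fall among the n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"inconsistent hypergeometric instance "
                         f"N={N}, K={K}, n={n}, k={k}")
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    if k > hi:
        return 0.0
    js = np.arange(k, hi + 1)
    log_terms = (_log_choose(K, js) + _log_choose(N - K, n - js)
                 - _log_choose(N, n))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def overconnection_test(
    links: TargetLinkTable,
    de_mirnas: Iterable[str],
    all_mirnas_tested: Iterable[str],
    direction: str = "up",
    fdr_threshold: float = 0.10,
) -> OverconnectionResult:
    """Hypergeometric over-connection of every gene with K >= 1 links.

    The link population is restricted to miRNAs in ``all_mirnas_tested``
    (the miRNAs actually assayed in the contrast); ``de_mirnas`` must be a
    subset of those.
    """
    de = set(de_mirnas)
    tested = set(all_mirnas_tested)
    if not de:
        raise ValidationError("the DE miRNA set is empty")
    if not de <= tested:
        raise ValidationError("DE miRNAs must be a subset of the tested miRNAs")
    pop = links.restrict_mirnas(tested)
    N = pop.n_links
    if N == 0:
        raise ValidationError("no links among the tested miRNAs")
    de_links = [(m, g) for m, g in pop.links if m in de]
    n = len(de_links)
    K_counts = pop.gene_link_counts()
    k_counts = Counter(g for _, g in de_links)
    genes = sorted(K_counts)
    rows = []
    for g in genes:
        K = K_counts[g]
        k = k_counts.get(g, 0)
        rows.append((g, K, k, hypergeom_upper_tail(N, K, n, k)))
    table = pd.DataFrame(rows, columns=["gene", "K", "k", "p"]).set_index("gene")
    table["n"] = n
    table["N"] = N
    table["direction"] = direction
    table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    table = table[["K", "k", "n", "N", "direction", "p", "adj_p"]]
    return OverconnectionResult(table=table, direction=direction,
                                fdr_threshold=fdr_threshold)


def split_by_direction(
    de: DEResult, threshold: float = 0.05
) -> tuple[set[str], set[str]]:
    """(up, down) miRNA sets: raw p below threshold, split by the sign of
    the fold change (up = elevated in the case group)."""
    tab = de.table
    sig = tab["p"] < threshold
    up = set(tab.index[sig & (tab["log2fc"] > 0)])
    down = set(tab.index[sig & (tab["log2fc"] < 0)])
    return up, down


def filter_transcription_factors(
    result: OverconnectionResult,
    annotations: Mapping[str, Iterable[str]],
    pattern: str = "transcription factor",
) -> OverconnectionResult:
    """Keep genes with any annotated term name containing the pattern
    (case-insensitive substring); unannotated genes are dropped."""
    needle = pattern.lower()
    keep = [
        g for g in result.table.index
        if any(needle in str(t).lower() for t in annotations.get(g, ()))
    ]
    return OverconnectionResult(
        table=result.table.loc[keep].copy(),
        direction=result.direction,
        fdr_threshold=result.fdr_threshold,
    )


def build_network(
    result: OverconnectionResult,
    links: TargetLinkTable,
    de_mirnas: Iterable[str],
    significant_only: bool = True,
) -> nx.Graph:
    """Bipartite DE-miRNA / significant-gene targeting graph.

    Gene node ``size`` equals its k (number of DE-miRNA links, counted with
    multiplicity as parallel links collapse to weighted edges).
    """
    de = set(de_mirnas)
    genes = result.significant if significant_only else result.table
    gene_set = set(genes.index)
    if not gene_set:
        raise ValidationError("no significant genes; nothing to draw")
    graph = nx.Graph()
    edge_weight: Counter = Counter()
    for m, g in links.links:
        if m in de and g in gene_set:
            edge_weight[(m, g)] += 1
    for (m, g), w in edge_weight.items():
        graph.add_node(m, bipartite="mirna")
        graph.add_node(g, bipartite="gene", direction=str(genes.at[g, "direction"]))
        graph.add_edge(m, g, weight=w)
    for g in gene_set & set(graph.nodes):
        graph.nodes[g]["size"] = int(
            sum(d["weight"] for _, _, d in graph.edges(g, data=True))
        )
    return graph
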