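"""Redundancy reduction of ontology terms via Lin semantic similarity.

Information content of a term c with corpus occurrence probability p(c) is
IC(c) = -log p(c) (natural log; Lin similarity is base-invariant).  For
terms t1, t2 with most-informative common ancestor MICA (ancestors include
the terms themselves),

    sim(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2))

with sim(t, t) = 1 and sim = 1 by convention when both ICs are zero.

``reduce_terms`` collapses a significant-term list greedily: terms are
visited from most specific (smallest p(c)) to most general, each retained
unless its similarity to an already-retained term exceeds the cutoff C
(default 0.7), in which case it is assigned that retained term as its
representative.  Enrichment p-values are deliberately not used in the
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GoDag

__all__ = ["ReducedTerms", "lin_similarity", "reduce_terms"]


@dataclass
class ReducedTerms:
    """Outcome of the redundancy reduction.

    ``retained`` keeps reduction order; ``representative`` maps every input
    term to its cluster head (itself if retained); ``clusters`` maps each
    retained term to its absorbed terms (head included).
    """

    retained: list[str]
    representative: dict[str, str]
    clusters: dict[str, list[str]]
    cutoff: float

    def to_frame(self, dag: GoDag) -> pd.DataFrame:
        rows = []
        for term, rep in sorted(self.representative.items()):
            rows.append(
                (term, rep, term == rep, dag.p(term), len(self.clusters[rep]))
            )
        return pd.DataFrame(
            rows,
            columns=["term", "representative", "retained", "p_c", "cluster_size"],
        ).set_index("term")


def lin_similarity(dag: GoDag, t1: str, t2: str) -> float:
    """Lin similarity of two terms in [0, 1]."""
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"unknown term {t!r}")
    if t1 == t2:
        return 1.0
    ic1, ic2 = dag.ic(t1), dag.ic(t2)
    if ic1 + ic2 == 0.0:
        return 1.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if not common:
        return 0.0
    mica_ic = max(dag.ic(c) for c in common)
    return max(0.0, min(1.0, 2.0 * mica_ic / (ic1 + ic2)))


def reduce_terms(
    terms: list[str], dag: GoDag, cutoff: float = 0.7
) -> ReducedTerms:
    """Greedy similarity-ceiling reduction of a term list.

    Terms are deduplicated, then sorted by ascending p(c) (rarest, i.e.
    most specific, first; ties by term id).  No retained pair has
    similarity > cutoff, and every dropped term has similarity > cutoff to
    its representative.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1]; got {cutoff}")
    unknown = [t for t in terms if t not in dag]
    if unknown:
        raise KeyError(f"terms not in the ontology: {unknown}")
    ordered = sorted(set(terms), key=lambda t: (dag.p(t), t))
    retained: list[str] = []
    representative: dict[str, str] = {}
    for term in ordered:
        rep = None
        for head in retained:
            if lin_similarity(dag, term, head) > cutoff:
                rep = head
                break
        if rep is None:
            retained.append(term)
            representative[term] = term
        else:
            representative[term] = rep
    clusters: dict[str, list[str]] = {h: [] for h in retained}
    for term, rep in representative.items():
        clusters[rep].append(term)
    for members in clusters.values():
        members.sort()
    return ReducedTerms(
        retained=retained,
        representative=representative,
        clusters=clusters,
        cutoff=cutoff,
    )
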