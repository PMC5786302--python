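"""Readers, writers and validated in-memory containers for every external
format the pipeline touches.

Tabular data (counts, metadata, target links, term probabilities) is plain
UTF-8 TSV; gene sets are GMT; the ontology is OBO (parsed with ``obonet``)
plus a two-column TSV of per-term occurrence probabilities; UTR sequences
are FASTA. Gene and miRNA identifiers are opaque, case-sensitive strings —
no alias resolution is attempted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "CountMatrix",
    "TargetLinkTable",
    "PathwaySets",
    "GoDag",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_target_links",
    "write_target_links",
    "read_gmt",
    "write_gmt",
    "read_obo_subset",
    "read_gene_list",
]

NEG_CONTROL_PREFIX = "ANT"

PROBE_CLASSES = ("miRNA", "negative_control", "process_control")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class CountMatrix:
    """Raw integer counts, probes x samples, with probe classes and sample
    metadata.

    ``counts`` is a DataFrame indexed by probe id with sample-id columns;
    ``probe_class`` maps each probe to one of ``PROBE_CLASSES``; ``meta`` is
    indexed by sample id with columns ``tissue``, ``stage``, ``replicate``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values)):
            raise ValidationError("counts contain non-finite values")
        if np.any(values < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(values != np.floor(values)):
            raise ValidationError("counts must be integral")
        if not self.probe_class.index.equals(self.counts.index):
            raise ValidationError("probe_class index does not match counts")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe class(es): {sorted(bad)}")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(
                f"samples missing metadata: {sorted(missing)}"
            )
        for col in ("tissue", "stage", "replicate"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata lacks column {col!r}")
        if self.meta.loc[list(self.counts.columns)].isna().any().any():
            raise ValidationError("incomplete sample metadata")
        if (self.probe_class == "negative_control").sum() < 1:
            raise ValidationError(
                "at least one negative_control probe is required for QC"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])

    def samples_where(self, tissue: str | None = None, stage: str | None = None) -> list[str]:
        """Sample ids matching the given tissue and/or stage label."""
        meta = self.meta.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=meta.index)
        if tissue is not None:
            mask &= meta["tissue"].astype(str) == str(tissue)
        if stage is not None:
            mask &= meta["stage"].astype(str) == str(stage)
        return list(meta.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return CountMatrix(
            counts=self.counts[keep].copy(),
            probe_class=self.probe_class.copy(),
            meta=self.meta.loc[keep].copy(),
        )


@dataclass
class TargetLinkTable:
    """Multiset of (miRNA, gene) target links.

    Duplicate links are retained: each row of the source table is one link
    object, and the total link count ``n_links`` is the population size N of
    the over-connection test.
    """

    links: list[tuple[str, str]]
    mirna_universe: set[str] = field(default_factory=set)
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.mirna_universe = set(self.mirna_universe) | {m for m, _ in self.links}
        self.gene_universe = set(self.gene_universe) | {g for _, g in self.links}

    @property
    def n_links(self) -> int:
        return len(self.links)

    def gene_link_counts(self) -> Counter:
        return Counter(g for _, g in self.links)

    def genes_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.links if m == mirna}

    def mirnas_of(self, gene: str) -> set[str]:
        return {m for m, g in self.links if g == gene}

    def restrict_mirnas(self, mirnas: Iterable[str]) -> "TargetLinkTable":
        keep = set(mirnas)
        return TargetLinkTable(
            links=[(m, g) for m, g in self.links if m in keep],
            mirna_universe=self.mirna_universe & keep,
        )


@dataclass
class PathwaySets:
    """Named gene sets: pathway id -> (display name, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, pid: str) -> frozenset[str]:
        return self.sets[pid][1]

    def name(self, pid: str) -> str:
        return self.sets[pid][0]

    def ids(self) -> list[str]:
        return sorted(self.sets)


@dataclass
class GoDag:
    """Ontology term DAG with per-term occurrence probabilities p(c).

    ``terms`` maps term id -> (name, parent ids, p).  Roots (terms without
    parents) carry p = 1; p is non-decreasing from child to ancestor, which
    makes information content IC(c) = -log p(c) non-increasing toward the
    root.
    """

    terms: dict[str, tuple[str, tuple[str, ...], float]]

    _MONO_TOL = 1e-9

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        for tid, (_, parents, p) in self.terms.items():
            if not (0.0 < p <= 1.0):
                raise ValidationError(f"term {tid!r} has p={p} outside (0, 1]")
            graph.add_node(tid)
            for parent in parents:
                if parent not in self.terms:
                    raise ValidationError(
                        f"term {tid!r} has unknown parent {parent!r}"
                    )
                graph.add_edge(tid, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValidationError(f"ontology contains a cycle: {cycle}")
        for tid, (_, parents, p) in self.terms.items():
            if not parents and abs(p - 1.0) > self._MONO_TOL:
                raise ValidationError(f"root term {tid!r} must have p = 1")
            for parent in parents:
                if self.terms[parent][2] < p - self._MONO_TOL:
                    raise ValidationError(
                        f"p({tid})={p} exceeds p(parent {parent})="
                        f"{self.terms[parent][2]}"
                    )
        self._graph = graph

    def __contains__(self, tid: str) -> bool:
        return tid in self.terms

    def p(self, tid: str) -> float:
        return self.terms[tid][2]

    def ic(self, tid: str) -> float:
        return -math.log(self.terms[tid][2])

    def ancestors(self, tid: str) -> set[str]:
        """The term itself plus every ancestor reachable through is_a."""
        if tid not in self.terms:
            raise KeyError(tid)
        return {tid} | nx.descendants(self._graph, tid)


# ---------------------------------------------------------------------------
# counts + metadata


def read_counts(
    path: str | Path,
    meta_path: str | Path,
    neg_control_prefix: str = NEG_CONTROL_PREFIX,
    process_control_prefix: str | None = None,
) -> CountMatrix:
    """Read a probe-by-sample raw count TSV plus a sample metadata TSV.

    The counts file has a header row of sample ids and probe ids in the first
    column.  Probes whose id starts with ``neg_control_prefix`` are classed
    ``negative_control`` (and ``process_control_prefix`` likewise, if given);
    everything else is a miRNA probe.
    """
    path, meta_path = Path(path), Path(meta_path)
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse counts TSV {path}: {exc}") from exc
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count values")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    required = {"tissue", "stage", "replicate"}
    if not required <= set(meta.columns):
        raise FormatError(
            f"{meta_path}: metadata needs columns {sorted(required)}"
        )
    cls = []
    for pid in counts.index:
        if pid.startswith(neg_control_prefix):
            cls.append("negative_control")
        elif process_control_prefix and pid.startswith(process_control_prefix):
            cls.append("process_control")
        else:
            cls.append("miRNA")
    probe_class = pd.Series(cls, index=counts.index, name="probe_class")
    cm = CountMatrix(counts=counts, probe_class=probe_class, meta=meta)
    # canonical internal order: by probe id, sample order as given
    order = sorted(cm.counts.index)
    cm.counts = cm.counts.loc[order]
    cm.probe_class = cm.probe_class.loc[order]
    return cm


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    path = Path(path)
    out = cm.counts.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        meta = cm.meta.loc[list(cm.counts.columns)].copy()
        meta.index.name = "sample_id"
        meta.to_csv(Path(meta_path), sep="\t")


# ---------------------------------------------------------------------------
# target links


def read_target_links(path: str | Path) -> TargetLinkTable:
    """Read a two-column (miRNA family, gene symbol) TSV; extra columns are
    ignored and duplicate rows are kept as distinct links."""
    path = Path(path)
    links: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.lower().startswith(("mirna", "#")):
                continue  # optional header
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: malformed link row {line!r}")
            links.append((fields[0].strip(), fields[1].strip()))
    if not links:
        raise FormatError(f"{path}: no target links found")
    return TargetLinkTable(links=links)


def write_target_links(table: TargetLinkTable, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in table.links:
            fh.write(f"{m}\t{g}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> PathwaySets:
    """Read pathway gene sets in the standard GMT dialect
    (name, description, then one gene id per tab-separated field)."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            pid, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if pid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {pid!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            sets[pid] = (desc if desc else pid, genes)
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return PathwaySets(sets=sets)


def write_gmt(pathways: PathwaySets, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for pid in pathways.ids():
            name, genes = pathways.sets[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# ontology


def read_obo_subset(path: str | Path, probabilities: str | Path) -> GoDag:
    """Read an OBO term subset plus a per-term probability TSV into a
    validated :class:`GoDag`.

    The probability file has columns (term id, p). Roots are forced to
    p = 1; a child whose p exceeds an ancestor's (beyond 1e-9) is rejected.
    """
    graph = obonet.read_obo(Path(path))
    probs = pd.read_csv(Path(probabilities), sep="\t", header=None,
                        names=["term", "p"], comment="#", dtype={"term": str})
    pmap = dict(zip(probs["term"], probs["p"].astype(float)))
    terms: dict[str, tuple[str, tuple[str, ...], float]] = {}
    for tid, data in graph.nodes(data=True):
        parents = tuple(sorted(
            parent for _, parent, key in graph.out_edges(tid, keys=True)
            if key == "is_a"
        ))
        if tid not in pmap and parents:
            raise ValidationError(f"no probability for term {tid!r}")
        p = 1.0 if not parents else float(pmap[tid])
        terms[tid] = (data.get("name", tid), parents, p)
    return GoDag(terms=terms)


# ---------------------------------------------------------------------------
# plain-text gene lists


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(Path(path), encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    return genes
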