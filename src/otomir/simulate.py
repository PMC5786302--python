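"""Synthetic inputs with the statistical structure the analysis assumes.

The count generator emulates a nuclease-protection miRNA assay on
laser-microdissected tissue: 27 samples (3 tissues x 3 stages x 3 technical
replicates), ~2,255 miRNA probes plus a handful of negative-control probes,
negative-binomial count noise on top of a log-normal baseline abundance
profile, heterogeneous library sizes, and planted multiplicative
tissue/stage effects (by default a miR-183-family-like trio elevated
+2 log2FC in CVG at stage 13).  Companion generators produce a random
bipartite miRNA-target link table (optionally with hub genes), random
pathway gene sets (optionally with one planted set), a random tree-shaped
ontology with monotone term probabilities, and UTR sequences with planted
seed-match sites.

All generators are pure functions of (config, seed).  The single integer
seed is split into independent streams with ``numpy``'s ``SeedSequence``
via a fixed per-generator stream id, so each stage can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, PathwaySets, GoDag, TargetLinkTable
from .seeds import SeedSite, seed_site_sequences

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "generate_counts",
    "generate_target_db",
    "generate_pathways",
    "generate_godag",
    "generate_utrs",
    "mirna_ids",
    "gene_ids",
]

# fixed stream ids for seed splitting
_STREAM_COUNTS = 1
_STREAM_TARGETS = 2
_STREAM_PATHWAYS = 3
_STREAM_GODAG = 4
_STREAM_UTRS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stream,)))


def mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


def gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative effect on the mean of a probe set in one
    (tissue, stage) cell, expressed as a log2 fold change."""

    probes: tuple[str, ...]
    tissue: str
    stage: str
    log2fc: float


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the count generator.

    Defaults mirror the assayed design: 2,255 miRNA probes, 13
    negative-control probes, three tissues (CVG, NC, OV) x three Carnegie
    stages (13, 14, 15) x three technical replicates.  Library sizes are
    log-normal (median exp(library_size_log_mean) reads); per-probe baseline
    abundances are log-normal with ``baseline_log_sd``; counts are negative
    binomial with variance mu + dispersion * mu^2.  Negative-control probes
    sit at a low, effect-free baseline (``neg_control_level`` times the
    median miRNA baseline weight).
    """

    n_mirna: int = 2255
    n_neg_control: int = 13
    tissues: tuple[str, ...] = ("CVG", "NC", "OV")
    stages: tuple[str, ...] = ("13", "14", "15")
    replicates: int = 3
    library_size_log_mean: float = float(np.log(5e5))
    library_size_log_sd: float = 0.4
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    neg_control_level: float = 0.02
    planted_effects: tuple[PlantedEffect, ...] = (
        PlantedEffect(("miR-0001", "miR-0002", "miR-0003"), "CVG", "13", 2.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna <= 0 or self.n_neg_control <= 0 or self.replicates <= 0:
            raise ValueError("counts must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        known = set(mirna_ids(self.n_mirna))
        for eff in self.planted_effects:
            if not np.isfinite(eff.log2fc):
                raise ValueError("planted log2 fold changes must be finite")
            if eff.tissue not in self.tissues or eff.stage not in self.stages:
                raise ValueError(f"planted effect cell {eff.tissue}/{eff.stage} "
                                 f"not in the design")
            unknown = set(eff.probes) - known
            if unknown:
                raise ValueError(f"planted probes not in design: {sorted(unknown)}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(config: SimulationConfig) -> CountMatrix:
    """Draw one probe-by-sample count matrix from the configured model."""
    rng = _rng(config.seed, _STREAM_COUNTS)
    mirnas = mirna_ids(config.n_mirna)
    negs = [f"ANT-{i:03d}" for i in range(1, config.n_neg_control + 1)]
    probes = mirnas + negs

    base_mir = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd,
                             size=config.n_mirna)
    base_neg = np.full(config.n_neg_control,
                       config.neg_control_level * float(np.median(base_mir)))
    base = np.concatenate([base_mir, base_neg])

    samples, tissue_lab, stage_lab, rep_lab = [], [], [], []
    for tissue in config.tissues:
        for stage in config.stages:
            for rep in range(1, config.replicates + 1):
                samples.append(f"{tissue}_s{stage}_r{rep}")
                tissue_lab.append(tissue)
                stage_lab.append(str(stage))
                rep_lab.append(rep)

    lib = rng.lognormal(mean=config.library_size_log_mean,
                        sigma=config.library_size_log_sd, size=len(samples))

    probe_idx = {p: i for i, p in enumerate(probes)}
    effect = np.ones((len(probes), len(samples)))
    for eff in config.planted_effects:
        mult = 2.0 ** eff.log2fc
        rows = [probe_idx[p] for p in eff.probes]
        cols = [j for j, s in enumerate(samples)
                if tissue_lab[j] == eff.tissue and stage_lab[j] == str(eff.stage)]
        for r in rows:
            effect[r, cols] *= mult

    weights = base[:, None] * effect
    mu = weights / weights.sum(axis=0, keepdims=True) * lib[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=probes, columns=samples, dtype=np.int64)
    probe_class = pd.Series(
        ["miRNA"] * config.n_mirna + ["negative_control"] * config.n_neg_control,
        index=probes, name="probe_class",
    )
    meta = pd.DataFrame(
        {"tissue": tissue_lab, "stage": stage_lab, "replicate": rep_lab},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(counts=counts_df, probe_class=probe_class, meta=meta)


def generate_target_db(
    n_mirna: int,
    n_gene: int,
    mean_targets_per_mirna: float,
    hub_genes: Sequence[str] = (),
    hub_multiplier: float = 1.0,
    seed: int = 0,
) -> TargetLinkTable:
    """Random bipartite miRNA-gene link table (a TargetScan-style multiset).

    Each miRNA draws Poisson(mean_targets_per_mirna) links, genes sampled
    with replacement; genes in ``hub_genes`` have ``hub_multiplier``-fold
    elevated link probability, planting over-connected hubs.
    """
    if n_mirna <= 0 or n_gene <= 0 or mean_targets_per_mirna <= 0:
        raise ValueError("target-db parameters must be positive")
    if hub_multiplier <= 0:
        raise ValueError("hub_multiplier must be positive")
    genes = gene_ids(n_gene)
    unknown = set(hub_genes) - set(genes)
    if unknown:
        raise ValueError(f"hub genes not in gene universe: {sorted(unknown)}")
    rng = _rng(seed, _STREAM_TARGETS)
    weights = np.ones(n_gene)
    hubs = set(hub_genes)
    for i, g in enumerate(genes):
        if g in hubs:
            weights[i] = hub_multiplier
    weights = weights / weights.sum()
    links: list[tuple[str, str]] = []
    for m in mirna_ids(n_mirna):
        k = rng.poisson(mean_targets_per_mirna)
        for gi in rng.choice(n_gene, size=k, replace=True, p=weights):
            links.append((m, genes[int(gi)]))
    return TargetLinkTable(links=links, mirna_universe=set(mirna_ids(n_mirna)),
                           gene_universe=set(genes))


def generate_pathways(
    gene_universe: Sequence[str],
    n_pathways: int,
    size_range: tuple[int, int],
    planted: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> PathwaySets:
    """Random gene sets drawn from the universe, plus an optional planted
    set included verbatim."""
    genes = sorted(set(gene_universe))
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad size_range {size_range}")
    if hi > len(genes):
        raise ValueError(f"size_range {size_range} exceeds universe size {len(genes)}")
    rng = _rng(seed, _STREAM_PATHWAYS)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    if planted is not None:
        pid, members = planted
        members = frozenset(members)
        if not members <= set(genes):
            raise ValueError("planted pathway genes must lie in the universe")
        sets[pid] = (pid, members)
    for i in range(1, n_pathways + 1):
        pid = f"PW{i:04d}"
        if pid in sets:
            continue
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[pid] = (pid, frozenset(genes[int(j)] for j in members))
    return PathwaySets(sets=sets)


def generate_godag(n_terms: int, branching: int = 3, seed: int = 0) -> GoDag:
    """Random tree-shaped term DAG with monotone occurrence probabilities.

    Term i attaches to a uniformly random earlier term among the most recent
    ``branching`` * depth candidates (a simple preferential shape knob);
    p(child) = p(parent) * U(0.3, 0.9), so p is monotone along every path.
    """
    if n_terms < 1 or branching < 1:
        raise ValueError("n_terms and branching must be positive")
    rng = _rng(seed, _STREAM_GODAG)
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    terms: dict[str, tuple[str, tuple[str, ...], float]] = {
        ids[0]: ("root term", (), 1.0)
    }
    probs = {ids[0]: 1.0}
    for i in range(1, n_terms):
        lo = max(0, i - branching * max(1, i // branching))
        parent = ids[int(rng.integers(lo, i))]
        p = probs[parent] * float(rng.uniform(0.3, 0.9))
        terms[ids[i]] = (f"synthetic term {i}", (parent,), p)
        probs[ids[i]] = p
    return GoDag(terms=terms)


def generate_utrs(
    genes: Sequence[str] | int,
    length: int = 500,
    planted_sites: Sequence[tuple[str, str, str]] = (),
    mirna_seqs: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[SeedSite]]:
    """Random DNA 3'UTRs with exact planted seed-match sites.

    ``planted_sites`` entries are (gene, site_type, mirna_id) with the
    miRNA's RNA sequence supplied through ``mirna_seqs``.  Returns the
    gene -> sequence mapping and the planted sites with their recorded
    coordinates.  Planted sites are placed at non-overlapping offsets.
    """
    if isinstance(genes, int):
        genes = gene_ids(genes)
    if length < 1:
        raise ValueError("UTR length must be positive")
    rng = _rng(seed, _STREAM_UTRS)
    alphabet = np.array(list("ACGT"))
    seqs = {
        g: "".join(rng.choice(alphabet, size=length)) for g in genes
    }
    planted: list[SeedSite] = []
    used: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    for gene, site_type, mirna in planted_sites:
        if gene not in seqs:
            raise ValueError(f"planted gene {gene!r} has no UTR")
        if mirna_seqs is None or mirna not in mirna_seqs:
            raise ValueError(f"no sequence for planted miRNA {mirna!r}")
        by_type = seed_site_sequences(mirna_seqs[mirna])
        site = by_type[site_type]
        if len(site) + 2 > length:
            raise ValueError(
                f"planted site longer than UTR allows ({len(site)} nt site "
                f"+ flanks vs length {length})"
            )
        # reserve one flank base on each side so the planted locus cannot be
        # upgraded to a higher-priority class by its random context
        for _ in range(200):
            start = int(rng.integers(1, length - len(site)))
            span = (start, start + len(site))
            guard = (span[0] - 1, span[1] + 1)
            if all(guard[1] <= a or guard[0] >= b for a, b in used[gene]):
                break
        else:  # pragma: no cover - pathological packing
            raise ValueError(f"could not place planted site in UTR of {gene!r}")
        chars = list(seqs[gene])
        chars[span[0] : span[1]] = site
        if site_type in ("7mer-A1", "6mer"):
            m8_base = by_type["7mer-m8"][0]
            if chars[span[0] - 1] == m8_base:
                chars[span[0] - 1] = "A" if m8_base != "A" else "C"
        if site_type in ("7mer-m8", "6mer") and span[1] < length:
            if chars[span[1]] == "A":
                chars[span[1]] = "C"
        seqs[gene] = "".join(chars)
        used[gene].append(guard)
        planted.append(SeedSite(gene, mirna, site_type, span[0], span[1]))
    return seqs, planted


def write_utrs_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(seqs):
            fh.write(f">{gene}\n{seqs[gene]}\n")


# miR-183-family sequences (5'->3' RNA) used for the seed-prediction inputs
MIR183_FAMILY_SEQS = {
    "miR-0001": "UUUGGCACUAGCACAUUUUUGCU",   # miR-96-5p-like
    "miR-0002": "UUUGGCAAUGGUAGAACUCACACU",  # miR-182-5p-like
    "miR-0003": "UAUGGCACUGGUAGAAUUCACU",    # miR-183-5p-like
}


def write_synthetic_inputs(
    out_dir,
    seed: int = 0,
    config: SimulationConfig | None = None,
    n_gene: int = 2000,
    mean_targets_per_mirna: float = 20.0,
    hub_genes: Sequence[str] = ("GENE0001",),
    hub_multiplier: float = 5.0,
    n_pathways: int = 200,
    pathway_size_range: tuple[int, int] = (5, 50),
    n_go_terms: int = 150,
    n_utr_genes: int = 30,
) -> "Path":
    """Write a complete, mutually consistent synthetic input bundle plus a
    pipeline config YAML into ``out_dir`` and return the config path.

    The bundle contains counts + metadata (default study design), a target
    link table with planted hub genes, pathway sets including one planted
    set of trio-targeted genes, a random ontology with term probabilities,
    gene annotations (some naming transcription factors), UTR sequences
    with planted seed sites for the miR-183-family-like trio, and a small
    disease gene list.
    """
    from pathlib import Path
    import yaml

    from .io import write_counts, write_gmt, write_target_links

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SimulationConfig(seed=seed)

    cm = generate_counts(cfg)
    write_counts(cm, out / "counts.tsv", out / "metadata.tsv")

    links = generate_target_db(
        cfg.n_mirna, n_gene, mean_targets_per_mirna,
        hub_genes=hub_genes, hub_multiplier=hub_multiplier, seed=seed,
    )
    write_target_links(links, out / "target_links.tsv")

    trio = [p for eff in cfg.planted_effects for p in eff.probes][:3] or \
        mirna_ids(min(3, cfg.n_mirna))
    trio_targets = sorted(set().union(*(links.genes_of(m) for m in trio)))
    planted_pathway = None
    if len(trio_targets) >= pathway_size_range[0]:
        planted_pathway = ("PW_PLANTED", trio_targets[: pathway_size_range[1]])
    pathways = generate_pathways(
        sorted(links.gene_universe), n_pathways, pathway_size_range,
        planted=planted_pathway, seed=seed,
    )
    write_gmt(pathways, out / "pathways.gmt")

    dag = generate_godag(n_go_terms, seed=seed)
    _write_godag(dag, out / "godag.obo", out / "godag_probs.tsv")

    # ontology-term gene sets (ids = DAG terms) scored by the per-sample
    # enrichment stage; the planted set reappears under the first term id
    go_rng = _rng(seed, _STREAM_PATHWAYS + 100)
    term_ids = sorted(dag.terms)
    universe = sorted(links.gene_universe)
    go_sets: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = pathway_size_range
    for i, tid in enumerate(term_ids):
        if i == 1 and planted_pathway is not None:
            members = frozenset(planted_pathway[1])
        else:
            size = int(go_rng.integers(lo, hi + 1))
            members = frozenset(
                universe[int(j)]
                for j in go_rng.choice(len(universe), size=size, replace=False)
            )
        go_sets[tid] = (dag.terms[tid][0], members)
    write_gmt(PathwaySets(sets=go_sets), out / "go_sets.gmt")

    # gene -> term-name annotations; every 5th gene is a transcription factor
    genes = gene_ids(n_gene)
    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        for i, g in enumerate(genes):
            if i % 5 == 0:
                fh.write(f"{g}\tDNA-binding transcription factor activity\n")
            fh.write(f"{g}\tsynthetic annotation term {i % 7}\n")

    utr_genes = gene_ids(n_utr_genes)
    planted_sites = []
    site_cycle = ("8mer", "7mer-m8", "7mer-A1", "6mer")
    for i, g in enumerate(utr_genes[: len(trio) * 4]):
        planted_sites.append((g, site_cycle[i % 4], trio[i % len(trio)]))
    seqs, planted = generate_utrs(
        utr_genes, length=500, planted_sites=planted_sites,
        mirna_seqs=MIR183_FAMILY_SEQS, seed=seed,
    )
    write_utrs_fasta(seqs, out / "utrs.fasta")
    with open(out / "planted_sites.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tmirna\tsite_type\tstart\tend\n")
        for s in planted:
            fh.write(f"{s.gene}\t{s.mirna}\t{s.site_type}\t{s.start}\t{s.end}\n")
    with open(out / "mirna_seqs.tsv", "w", encoding="utf-8") as fh:
        for mid, seq in sorted(MIR183_FAMILY_SEQS.items()):
            fh.write(f"{mid}\t{seq}\n")
    with open(out / "disease_genes.txt", "w", encoding="utf-8") as fh:
        for g in utr_genes[::3]:
            fh.write(g + "\n")

    config_payload = {
        "counts": str(out / "counts.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "target_links": str(out / "target_links.tsv"),
        "pathways_gmt": str(out / "pathways.gmt"),
        "go_gmt": str(out / "go_sets.gmt"),
        "godag_obo": str(out / "godag.obo"),
        "godag_probs": str(out / "godag_probs.tsv"),
        "annotations": str(out / "annotations.tsv"),
        "utrs_fasta": str(out / "utrs.fasta"),
        "mirna_seqs": str(out / "mirna_seqs.tsv"),
        "disease_genes": str(out / "disease_genes.txt"),
        "out_dir": str(out / "run"),
        "seed": int(seed),
    }
    config_path = out / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_payload, fh, sort_keys=True)
    return config_path


def _write_godag(dag: GoDag, obo_path, probs_path) -> None:
    with open(obo_path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for tid in sorted(dag.terms):
            name, parents, _p = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            for parent in parents:
                fh.write(f"is_a: {parent} ! {dag.terms[parent][0]}\n")
    with open(probs_path, "w", encoding="utf-8") as fh:
        for tid in sorted(dag.terms):
            fh.write(f"{tid}\t{dag.terms[tid][2]:.12g}\n")
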