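"""End-to-end orchestration of the analysis stages.

A single YAML config names the input files and the analysis thresholds
(defaults: DE raw p < 0.05, over-connection FDR < 0.10, pathway
significance p < 0.05, top-k = 100, similarity cutoff C = 0.7, transferred
set sizes 3-500).  ``run_pipeline`` executes

    QC -> tissue DE (per stage) -> time-course DE + top-k overlap -> PCA
       -> over-connection (+ optional TF filter and network)
       -> logistic pathway GSA -> per-sample enrichment + pathway tests
       -> semantic reduction -> seed-target prediction

writing one TSV per artifact into a run directory; every TSV carries a
header comment with the config hash and seed, and a JSON-lines log records
per-stage wall time.  Optional inputs (ontology, annotations, UTRs) simply
switch their stages off when absent.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import diffexp, gsa, normalize, overconnect, seeds, semsim
from .io import (
    ValidationError,
    read_counts,
    read_gene_list,
    read_gmt,
    read_obo_subset,
    read_target_links,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_PATH_KEYS = (
    "counts", "metadata", "target_links", "pathways_gmt", "go_gmt",
    "godag_obo", "godag_probs", "annotations", "utrs_fasta", "mirna_seqs",
    "disease_genes",
)
_REQUIRED_PATHS = ("counts", "metadata")


@dataclass
class PipelineConfig:
    """Typed pipeline configuration; unset optional paths disable stages."""

    counts: str | None = None
    metadata: str | None = None
    target_links: str | None = None
    pathways_gmt: str | None = None
    go_gmt: str | None = None
    godag_obo: str | None = None
    godag_probs: str | None = None
    annotations: str | None = None
    utrs_fasta: str | None = None
    mirna_seqs: str | None = None
    disease_genes: str | None = None
    out_dir: str = "otomir_run"
    de_p: float = 0.05
    overconnection_fdr: float = 0.10
    pathway_p: float = 0.05
    top_k: int = 100
    similarity_cutoff: float = 0.7
    set_size_min: int = 3
    set_size_max: int = 500
    qc_strict: bool = False
    case_tissue: str = "CVG"
    stages: tuple[str, ...] | None = None  # None = all
    seed: int = 0

    _STAGE_NAMES = (
        "qc", "de_tissue", "de_time", "pca", "overconnect", "gsa",
        "sample_enrichment", "semantic_reduction", "seed_targets",
    )

    def stage_enabled(self, name: str) -> bool:
        if name not in self._STAGE_NAMES:
            raise ValueError(f"unknown stage {name!r}")
        return self.stages is None or name in self.stages

    def validate(self) -> list[str]:
        problems = []
        for key in _REQUIRED_PATHS:
            if getattr(self, key) is None:
                problems.append(f"missing required input path {key!r}")
        for key in _PATH_KEYS:
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                problems.append(f"{key}: file not found: {val}")
        if not (0 < self.de_p < 1):
            problems.append(f"de_p={self.de_p} outside (0, 1)")
        if not (0 < self.overconnection_fdr < 1):
            problems.append(f"overconnection_fdr={self.overconnection_fdr} outside (0, 1)")
        if not (0 < self.pathway_p < 1):
            problems.append(f"pathway_p={self.pathway_p} outside (0, 1)")
        if self.top_k < 1:
            problems.append(f"top_k={self.top_k} must be positive")
        if not (0 < self.similarity_cutoff <= 1):
            problems.append(f"similarity_cutoff={self.similarity_cutoff} outside (0, 1]")
        if not (1 <= self.set_size_min <= self.set_size_max):
            problems.append("set size bounds must satisfy 1 <= min <= max")
        if self.stages is not None:
            bad = sorted(set(self.stages) - set(self._STAGE_NAMES))
            if bad:
                problems.append(f"unknown stage name(s) {bad}")
        return problems

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys and every violation
    are reported together."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    problems = [f"unknown config key {k!r}" for k in unknown]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    problems.extend(cfg.validate())
    if problems:
        raise ValidationError(
            f"invalid config {path}:\n  " + "\n  ".join(problems)
        )
    return cfg


class _Run:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.dir = Path(cfg.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.header = (
            f"# otomir run config_hash={cfg.config_hash()} seed={cfg.seed}\n"
        )
        self.log_path = self.dir / "run.log.jsonl"
        self.log_path.write_text("")

    def log(self, stage: str, t0: float, **extra) -> None:
        entry = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 4)}
        entry.update(extra)
        with open(self.log_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")

    def write_tsv(self, frame: pd.DataFrame, name: str) -> Path:
        path = self.dir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.header)
            frame.to_csv(fh, sep="\t", float_format="%.10g")
        return path


def _tissue_pairs(tissues: list[str], case: str) -> list[tuple[str, str]]:
    pairs = [(case, t) for t in tissues if t != case]
    pairs += [p for p in combinations(sorted(t for t in tissues if t != case), 2)]
    return pairs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage the config enables; returns the run directory."""
    problems = cfg.validate()
    if problems:
        raise ValidationError("invalid config:\n  " + "\n  ".join(problems))
    run = _Run(cfg)

    t0 = time.perf_counter()
    cm = read_counts(cfg.counts, cfg.metadata)
    run.log("read_counts", t0, probes=len(cm.probe_ids), samples=len(cm.sample_ids))

    # --- QC on log2(CPM)
    t0 = time.perf_counter()
    cpm = normalize.log2_cpm(cm)
    qc = normalize.spc_qc(cpm)
    if cfg.stage_enabled("qc"):
        run.write_tsv(qc.to_frame(), "qc_report.tsv")
        _qc_chart(qc, run.dir / "qc_chart.png")
    failing = list(qc.passed.index[~qc.passed])
    if cfg.qc_strict and failing:
        cm = cm.subset_samples([s for s in cm.sample_ids if s not in failing])
        cpm = normalize.log2_cpm(cm)
    run.log("qc", t0, failing=failing, dropped=bool(cfg.qc_strict and failing))

    # --- normalization for DE: median-normalized counts on a log2 scale
    t0 = time.perf_counter()
    med = normalize.median_normalize(cm)
    log_med = normalize.NormalizedMatrix(
        values=np.log2(med.values + 0.5), method="median", source=med.source
    )
    run.log("normalize", t0)

    meta = cm.meta.loc[cm.sample_ids]
    tissues = sorted(meta["tissue"].astype(str).unique())
    stages = sorted(meta["stage"].astype(str).unique())
    mir_probes = set(cm.probes_of_class("miRNA"))
    mir_view = log_med.values.loc[sorted(mir_probes)]

    # --- tissue contrasts per stage
    t0 = time.perf_counter()
    de_results: dict[tuple[str, str, str], diffexp.DEResult] = {}
    for stage in stages:
        for case, ctrl in _tissue_pairs(tissues, cfg.case_tissue):
            g1 = cm.samples_where(tissue=case, stage=stage)
            g2 = cm.samples_where(tissue=ctrl, stage=stage)
            if len(g1) < 2 or len(g2) < 2:
                continue
            label = f"{case}_vs_{ctrl}_stage{stage}"
            res = diffexp.moderated_de(mir_view, g1, g2, label=label)
            de_results[(case, ctrl, stage)] = res
            if cfg.stage_enabled("de_tissue"):
                run.write_tsv(res.table, f"de_tissue_{label}.tsv")
    run.log("de_tissue", t0, contrasts=len(de_results))

    # --- time course per tissue + top-k overlap
    t0 = time.perf_counter()
    tc_results: dict[str, diffexp.TimecourseResult] = {}
    for tissue in (tissues if cfg.stage_enabled("de_time") else []):
        try:
            res = diffexp.timecourse_max_t2(log_med, tissue, probes=mir_probes)
        except ValidationError:
            continue
        tc_results[tissue] = res
        run.write_tsv(res.table, f"de_time_{tissue}.tsv")
    overlap12 = None
    if len(tc_results) >= 3:
        k = min(cfg.top_k, len(mir_probes))
        regions, membership = diffexp.top_k_overlap(tc_results, k)
        run.write_tsv(membership.astype(int), "topk_overlap_membership.tsv")
        venn = pd.DataFrame(
            [("+".join(sorted(key)), count) for key, count in sorted(
                regions.items(), key=lambda kv: "+".join(sorted(kv[0])))],
            columns=["region", "count"],
        ).set_index("region")
        run.write_tsv(venn, "topk_overlap_regions.tsv")
        overlap12 = regions.get(frozenset(tc_results), 0)
    run.log("de_time", t0, tissues=list(tc_results), triple_overlap=overlap12)

    # --- PCA on log2(CPM) miRNA values
    t0 = time.perf_counter()
    if cfg.stage_enabled("pca"):
        scores, _loadings, frac = diffexp.pca(cpm.values.loc[sorted(mir_probes)])
        pca_out = scores.copy()
        pca_out["tissue"] = meta["tissue"]
        pca_out["stage"] = meta["stage"]
        run.write_tsv(pca_out, "pca_scores.tsv")
        run.write_tsv(
            pd.DataFrame({"variance_fraction": frac},
                         index=[f"PC{i+1}" for i in range(len(frac))]),
            "pca_variance.tsv",
        )
        run.log("pca", t0)

    links = None
    if cfg.target_links:
        links = read_target_links(cfg.target_links)

    # --- over-connection per contrast and direction
    if links is not None and cfg.stage_enabled("overconnect"):
        t0 = time.perf_counter()
        annotations = _read_annotations(cfg.annotations) if cfg.annotations else None
        tested = mir_probes & links.mirna_universe
        n_tables = 0
        for (case, ctrl, stage), res in de_results.items():
            up, down = overconnect.split_by_direction(res, cfg.de_p)
            for direction, de_set in (("up", up), ("down", down)):
                de_set = de_set & tested
                if not de_set:
                    continue
                oc = overconnect.overconnection_test(
                    links, de_set, tested, direction=direction,
                    fdr_threshold=cfg.overconnection_fdr,
                )
                label = f"{case}_vs_{ctrl}_stage{stage}_{direction}"
                run.write_tsv(oc.table, f"overconnection_{label}.tsv")
                n_tables += 1
                if annotations is not None:
                    tf = overconnect.filter_transcription_factors(oc, annotations)
                    run.write_tsv(tf.table, f"overconnection_tf_{label}.tsv")
                    oc = tf
                sig = oc.significant
                if len(sig):
                    graph = overconnect.build_network(oc, links, de_set)
                    edges = pd.DataFrame(
                        [(m, g, d["weight"]) for m, g, d in graph.edges(data=True)],
                        columns=["mirna", "gene", "n_links"],
                    ).set_index("mirna")
                    run.write_tsv(edges, f"network_{label}.tsv")
        run.log("overconnect", t0, tables=n_tables)

    # --- logistic pathway GSA
    if links is not None and cfg.pathways_gmt and cfg.stage_enabled("gsa"):
        t0 = time.perf_counter()
        pathways = read_gmt(cfg.pathways_gmt)
        annot = gsa.transfer_annotations(pathways, links)
        for (case, ctrl, stage), res in de_results.items():
            r = gsa.ranking_index(res)
            try:
                out = gsa.logistic_gsa(
                    r, annot, (cfg.set_size_min, cfg.set_size_max),
                    label=res.label,
                )
            except ValidationError:
                continue
            run.write_tsv(out.table, f"gsa_{res.label}.tsv")
        run.log("gsa", t0, pathways=len(annot.sets))

    # --- per-sample enrichment + pathway tissue tests
    sig_terms: list[str] = []
    go_sets_path = cfg.go_gmt or cfg.pathways_gmt
    if links is not None and go_sets_path and cfg.stage_enabled("sample_enrichment"):
        t0 = time.perf_counter()
        go_sets = read_gmt(go_sets_path)
        act = activity_mod.gene_activity_transfer(log_med, links)
        es = activity_mod.enrichment_scores(act, go_sets)
        run.write_tsv(es.values, "enrichment_scores.tsv")
        for stage in stages:
            for case, ctrl in _tissue_pairs(tissues, cfg.case_tissue):
                g1 = cm.samples_where(tissue=case, stage=stage)
                g2 = cm.samples_where(tissue=ctrl, stage=stage)
                if len(g1) < 2 or len(g2) < 2:
                    continue
                label = f"{case}_vs_{ctrl}_stage{stage}"
                ptest = activity_mod.pathway_tissue_test(es, g1, g2, label=label)
                run.write_tsv(ptest.table, f"pathway_test_{label}.tsv")
                hits = ptest.table[ptest.table["p"] < cfg.pathway_p]
                sig_terms.extend(hits.index)
        run.log("sample_enrichment", t0, scored_sets=len(es.values))

    # --- semantic reduction of significant ontology terms
    if sig_terms and cfg.godag_obo and cfg.godag_probs \
            and cfg.stage_enabled("semantic_reduction"):
        t0 = time.perf_counter()
        dag = read_obo_subset(cfg.godag_obo, cfg.godag_probs)
        known = [t for t in dict.fromkeys(sig_terms) if t in dag]
        if known:
            red = semsim.reduce_terms(known, dag, cfg.similarity_cutoff)
            run.write_tsv(red.to_frame(dag), "reduced_terms.tsv")
            run.log("semantic_reduction", t0, retained=len(red.retained))

    # --- seed-target prediction
    if cfg.utrs_fasta and cfg.mirna_seqs and cfg.stage_enabled("seed_targets"):
        t0 = time.perf_counter()
        utrs = seeds.read_utrs(cfg.utrs_fasta)
        mirna_seqs = _read_mirna_seqs(cfg.mirna_seqs)
        all_sites: list[seeds.SeedSite] = []
        for mid, seq in sorted(mirna_seqs.items()):
            all_sites.extend(seeds.find_seed_sites(seq, utrs, mirna_id=mid))
        sites = pd.DataFrame(
            [(s.gene, s.mirna, s.site_type, s.start, s.end) for s in all_sites],
            columns=["gene", "mirna", "site_type", "start", "end"],
        ).sort_values(["gene", "start", "mirna"]).set_index("gene")
        run.write_tsv(sites, "seed_sites.tsv")
        if cfg.disease_genes:
            disease = read_gene_list(cfg.disease_genes)
            hits = seeds.intersect_gene_list(all_sites, disease)
            run.write_tsv(
                pd.DataFrame({"gene": sorted(hits)}).set_index("gene"),
                "disease_targets.tsv",
            )
        run.log("seed_targets", t0, sites=len(all_sites))

    return run.dir


def _read_annotations(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV gene -> term name (repeated rows per gene)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                        comment="#", dtype=str)
    out: dict[str, list[str]] = {}
    for gene, term in zip(frame["gene"], frame["term"]):
        out.setdefault(gene, []).append(term)
    return out


def _read_mirna_seqs(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["mirna", "seq"],
                        comment="#", dtype=str)
    return dict(zip(frame["mirna"], frame["seq"]))


def _qc_chart(qc, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = np.arange(len(qc.delta_mean))
    ax.plot(x, qc.delta_mean.to_numpy(), "o-", ms=4)
    for y, style in ((2 * qc.sd, "--"), (-2 * qc.sd, "--"), (0.0, ":")):
        ax.axhline(y, color="grey", linestyle=style, lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(qc.delta_mean.index, rotation=90, fontsize=6)
    ax.set_ylabel("Δmean (negative controls)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
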