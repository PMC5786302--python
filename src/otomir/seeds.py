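"""Canonical miRNA seed-site prediction on 3'UTR sequences.

The seed is miRNA nucleotides 2-8 (5'->3').  On the UTR (DNA, read 5'->3')
the four canonical site classes are

    8mer     reverse complement of seed positions 2-8, followed by A
    7mer-m8  reverse complement of seed positions 2-8
    7mer-A1  reverse complement of positions 2-7, followed by A
    6mer     reverse complement of positions 2-7

When several definitions match at one locus the most specific wins:
8mer > 7mer-m8 > 7mer-A1 > 6mer.  Coordinates are 0-based half-open on the
given UTR strand.  ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "SeedSite",
    "SITE_PRIORITY",
    "seed_site_sequences",
    "find_seed_sites",
    "read_utrs",
    "intersect_gene_list",
]

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True, order=True)
class SeedSite:
    gene: str
    mirna: str
    site_type: str
    start: int  # 0-based, half-open
    end: int


def _check_mirna(mirna_seq: str) -> str:
    seq = mirna_seq.strip().upper()
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(
            f"miRNA sequence must be RNA (ACGU); found {sorted(bad)}"
        )
    return seq


def _revcomp_dna(rna: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(rna))


def seed_site_sequences(mirna_seq: str) -> dict[str, str]:
    """DNA site strings on the UTR for each canonical site class."""
    seq = _check_mirna(mirna_seq)
    seed28 = seq[1:8]  # positions 2-8, 1-based
    seed27 = seq[1:7]  # positions 2-7
    m8site = _revcomp_dna(seed28)
    core6 = _revcomp_dna(seed27)
    return {
        "8mer": m8site + "A",
        "7mer-m8": m8site,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def find_seed_sites(
    mirna_seq: str,
    utrs: Mapping[str, str],
    mirna_id: str = "miRNA",
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA across a set of UTRs.

    ``utrs`` maps gene id -> DNA sequence (ACGTN).  Overlapping site classes
    anchored on the same seed match are collapsed to the highest-priority
    class; the 6mer core occurring at UTR offset ``i`` anchors every class,
    so each core occurrence yields exactly one reported site.
    """
    sites_by_type = seed_site_sequences(mirna_seq)
    core = sites_by_type["6mer"]
    m8 = sites_by_type["7mer-m8"]
    out: list[SeedSite] = []
    for gene, seq in utrs.items():
        s = seq.strip().upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"UTR {gene!r} has non-DNA characters {sorted(bad)}")
        # scan for the 6mer core; classify each occurrence by its context
        start = 0
        while True:
            i = s.find(core, start)
            if i < 0:
                break
            start = i + 1
            has_m8 = i >= 1 and s[i - 1 : i + len(core)] == m8
            has_a1 = s[i + len(core) : i + len(core) + 1] == "A"
            if has_m8 and has_a1:
                out.append(SeedSite(gene, mirna_id, "8mer", i - 1, i + len(core) + 1))
            elif has_m8:
                out.append(SeedSite(gene, mirna_id, "7mer-m8", i - 1, i + len(core)))
            elif has_a1:
                out.append(SeedSite(gene, mirna_id, "7mer-A1", i, i + len(core) + 1))
            else:
                out.append(SeedSite(gene, mirna_id, "6mer", i, i + len(core)))
    return out


def read_utrs(path: str | Path) -> dict[str, str]:
    """Read UTR sequences from FASTA; record ids are gene ids."""
    utrs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in utrs:
            raise ValueError(f"duplicate UTR record {record.id!r}")
        utrs[record.id] = str(record.seq).upper()
    if not utrs:
        raise ValueError(f"{path}: no FASTA records")
    return utrs


def intersect_gene_list(
    predicted: Iterable[SeedSite] | Iterable[str],
    disease_genes: Iterable[str],
) -> set[str]:
    """Genes with at least one predicted site (or link) that also appear in
    the disease list; exact string match after whitespace trimming."""
    genes: set[str] = set()
    for item in predicted:
        genes.add(item.gene if isinstance(item, SeedSite) else str(item).strip())
    listed = {str(g).strip() for g in disease_genes}
    return genes & listed
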