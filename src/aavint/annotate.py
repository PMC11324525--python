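"""Genomic annotation of integration sites and fold-change enrichment over a
random-locus background.

Sites are genic when their coordinate falls inside an annotated gene body;
genic sites are binned by liver expression (nx) into not expressed / low /
medium / high and screened against HCC-associated and mouse-HCC gene lists.
Enrichment per category is the observed fraction divided by the fraction in
computationally generated random loci (10,000 by default); 1 means no
difference from random.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import (
    AnnotatedSite,
    EnrichmentReport,
    EXPRESSION_CATEGORIES,
    GeneModel,
    HostGenome,
    expression_category,
)

ANNOTATION_CATEGORIES = ("intergenic",) + EXPRESSION_CATEGORIES + ("genic_unscored",)


class GeneIndex:
    """Interval lookup over gene bodies with deterministic tie-breaking:
    the smallest containing interval wins, then lexicographic gene_id."""

    def __init__(self, genes: Iterable[GeneModel], flank_bp: int = 0):
        self.trees: dict[str, IntervalTree] = {}
        self.genes: dict[str, GeneModel] = {}
        for g in sorted(genes, key=lambda g: g.gene_id):
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            tree = self.trees.setdefault(g.chrom, IntervalTree())
            tree[max(0, g.start - flank_bp):g.end + flank_bp] = g.gene_id

    def containing_gene(self, chrom: str, coord: int) -> Optional[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = tree[coord]
        if not hits:
            return None
        best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.data))
        return self.genes[best.data]


def annotate_sites(sites: Sequence, genes: Iterable[GeneModel],
                   expression: dict[str, float] | None = None,
                   hcc_list: Iterable[str] = (),
                   mouse_hcc_list: Iterable[str] = (),
                   flank_bp: int = 0) -> list[AnnotatedSite]:
    """Annotate (chrom, coord) sites; accepts IntegrationSiteCall-like
    objects (``chrom``/``coord`` attributes) or (chrom, coord) tuples."""
    index = GeneIndex(genes, flank_bp=flank_bp)
    expression = expression or {}
    hcc = set(hcc_list)
    mouse = set(mouse_hcc_list)
    out: list[AnnotatedSite] = []
    for site in sites:
        chrom, coord = ((site.chrom, site.coord) if hasattr(site, "chrom")
                        else (site[0], site[1]))
        gene = index.containing_gene(chrom, coord)
        if gene is None:
            out.append(AnnotatedSite(chrom, coord, genic=False))
            continue
        nx = expression.get(gene.gene_id)
        out.append(AnnotatedSite(
            chrom, coord, genic=True, gene_id=gene.gene_id,
            category=None if nx is None else expression_category(nx),
            hcc_hit=gene.gene_id in hcc,
            mouse_hcc_hit=gene.gene_id in mouse))
    return out


def site_category(site: AnnotatedSite) -> str:
    if not site.genic:
        return "intergenic"
    return site.category if site.category is not None else "genic_unscored"


def random_loci(host: HostGenome, n: int, seed: int) -> list[tuple[str, int]]:
    """n loci uniform over non-N host positions: chromosome drawn
    proportional to length, position uniform, N positions rejected."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for _, s in host.chromosomes], dtype=float)
    if all(set(seq) == {"N"} for _, seq in host.chromosomes):
        raise ValueError("genome is all N")
    probs = lengths / lengths.sum()
    out: list[tuple[str, int]] = []
    while len(out) < n:
        ci = int(rng.choice(len(lengths), p=probs))
        name, seq = host.chromosomes[ci]
        pos = int(rng.integers(0, len(seq)))
        if seq[pos] == "N":
            continue
        out.append((name, pos))
    return out


def category_fractions(annotated: Sequence[AnnotatedSite]) -> dict[str, float]:
    counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    for site in annotated:
        counts[site_category(site)] += 1
    total = len(annotated)
    return {c: (counts[c] / total if total else 0.0) for c in ANNOTATION_CATEGORIES}


def enrichment(sites_annotated: Sequence[AnnotatedSite],
               background_annotated: Sequence[AnnotatedSite],
               seed: Optional[int] = None) -> EnrichmentReport:
    """Per-category fold change of sites over background.

    Categories absent from the background are reported with fold_change
    None (undefined), never infinity.
    """
    if not background_annotated:
        raise ValueError("background must be non-empty")
    obs = category_fractions(sites_annotated)
    bg = category_fractions(background_annotated)
    cats = {}
    for c in ANNOTATION_CATEGORIES:
        if not sites_annotated:
            fold = None
        elif bg[c] == 0.0:
            fold = None
        else:
            fold = obs[c] / bg[c]
        cats[c] = {"observed_fraction": obs[c],
                   "background_fraction": bg[c],
                   "fold_change": fold}
    return EnrichmentReport(categories=cats, n_sites=len(sites_annotated),
                            n_random=len(background_annotated), seed=seed)


# ---------------------------------------------------------------------------
# Disk I/O


def read_gff3_genes(path) -> list[GeneModel]:
    """Minimal GFF3 gene reader (type == gene, ID attribute)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name")
            genes.append(GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]),
                                   f[6] if f[6] in "+-" else "+"))
    return genes


def write_annotation(annotated: Sequence[AnnotatedSite], report: EnrichmentReport,
                     tsv_path, json_path) -> None:
    import json

    import pandas as pd

    pd.DataFrame([{
        "chrom": a.chrom, "coord": a.coord, "genic": a.genic,
        "gene_id": a.gene_id or "", "category": site_category(a),
        "hcc_hit": a.hcc_hit, "mouse_hcc_hit": a.mouse_hcc_hit,
    } for a in annotated]).to_csv(tsv_path, sep="\t", index=False)
    payload = {"n_sites": report.n_sites, "n_random": report.n_random,
               "seed": report.seed, "categories": report.categories}
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
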