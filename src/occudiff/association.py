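"""Associating peaks with genes and their expression levels.

Each peak is linked to at most one gene: the gene containing the peak summit
if any (preferring it over mere body overlap), otherwise the overlapping gene
with the largest overlap, otherwise the nearest gene within ``max_dist`` with
a strand-aware upstream/downstream relation, otherwise ``intergenic_far``.
Within-gene links can then be tabulated against gene expression quantiles to
ask whether the factor favors highly transcribed genes.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .peaks import Peak, PeakSet
from .synthetic_data import GeneModel

__all__ = [
    "PeakGeneLink",
    "assign_peaks_to_genes",
    "expression_quantile_table",
    "write_quantile_table",
]

RELATIONS = ("within_gene", "upstream", "downstream", "intergenic_far")


@dataclass(frozen=True)
class PeakGeneLink:
    peak: Peak
    gene_id: str | None
    relation: str
    distance: int  # bp between peak and gene body; 0 iff within_gene

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if (self.relation == "within_gene") != (self.distance == 0):
            raise ValueError("within_gene links must (and only they may) have distance 0")


def _relation_for(peak: Peak, gene: GeneModel) -> str:
    """Upstream/downstream of the gene, respecting its strand."""
    if peak.end <= gene.start:  # peak entirely left of the gene
        return "upstream" if gene.strand == "+" else "downstream"
    return "downstream" if gene.strand == "+" else "upstream"


def assign_peaks_to_genes(
    peaks: PeakSet, genes: Sequence[GeneModel], max_dist: int = 1000
) -> list[PeakGeneLink]:
    """Assign each peak to a gene (or to the intergenic bucket).

    Ties between equidistant genes are broken toward the lower-coordinate
    gene, for determinism.  Genes must be sorted by (chrom, start).
    """
    keyed = [(g.chrom, g.start) for g in genes]
    if keyed != sorted(keyed):
        raise ValueError("genes must be sorted by (chrom, start)")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: list[PeakGeneLink] = []
    for p in peaks:
        chrom_genes = by_chrom.get(p.chrom, [])
        summit_gene = None
        best_overlap_gene = None
        best_overlap = 0
        nearest_gene = None
        nearest_dist = None
        for g in chrom_genes:
            if g.start <= p.summit < g.end and summit_gene is None:
                summit_gene = g
            ov = min(g.end, p.end) - max(g.start, p.start)
            if ov > best_overlap:
                best_overlap, best_overlap_gene = ov, g
            if ov <= 0:
                gap = g.start - p.end if g.start >= p.end else p.start - g.end
                # exactly adjacent intervals share no base; floor at 1 bp so
                # distance 0 remains reserved for within-gene links
                dist = max(gap, 1)
                if nearest_dist is None or dist < nearest_dist:
                    nearest_dist, nearest_gene = dist, g
        if summit_gene is not None:
            links.append(PeakGeneLink(p, summit_gene.gene_id, "within_gene", 0))
        elif best_overlap_gene is not None:
            links.append(PeakGeneLink(p, best_overlap_gene.gene_id, "within_gene", 0))
        elif nearest_gene is not None and nearest_dist is not None and nearest_dist <= max_dist:
            links.append(
                PeakGeneLink(p, nearest_gene.gene_id, _relation_for(p, nearest_gene),
                             int(nearest_dist))
            )
        else:
            dist = int(nearest_dist) if nearest_dist is not None else max_dist + 1
            links.append(PeakGeneLink(p, None, "intergenic_far", max(dist, 1)))
    return links


def expression_quantile_table(
    links: Sequence[PeakGeneLink],
    genes: Sequence[GeneModel],
    n_bins: int = 4,
) -> list[dict]:
    """Count within-gene peak links per gene-expression quantile bin.

    Genes are ranked by expression (ties broken by gene id, for determinism)
    and cut into ``n_bins`` near-equal-count bins (sizes differ by at most
    one gene); counts sum exactly to the number of within-gene links whose
    gene is in the list.  All-equal expression degenerates to a single bin,
    with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not genes:
        raise ValueError("need at least one gene")
    exprs = [g.expression for g in genes]
    if len(set(exprs)) == 1:
        warnings.warn(
            "all genes have equal expression; returning a single degenerate bin",
            stacklevel=2,
        )
        n_bins = 1
    ranked = sorted(genes, key=lambda g: (g.expression, g.gene_id))
    chunks = np.array_split(np.arange(len(ranked)), n_bins)
    gene_bin: dict[str, int] = {}
    rows: list[dict] = []
    for bi, idx in enumerate(chunks):
        members = [ranked[i] for i in idx]
        for g in members:
            gene_bin[g.gene_id] = bi
        rows.append(
            {
                "bin_index": bi + 1,
                "expression_lo": min(g.expression for g in members),
                "expression_hi": max(g.expression for g in members),
                "n_genes": len(members),
                "peak_count": 0,
            }
        )
    for link in links:
        if link.relation == "within_gene" and link.gene_id in gene_bin:
            rows[gene_bin[link.gene_id]]["peak_count"] += 1
    return rows


def write_quantile_table(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_index\texpression_range\tn_genes\tpeak_count\n")
        for r in rows:
            fh.write(
                f"{r['bin_index']}\t{r['expression_lo']:.4g}-{r['expression_hi']:.4g}\t"
                f"{r['n_genes']}\t{r['peak_count']}\n"
            )
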