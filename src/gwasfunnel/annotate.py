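"""SNP-to-gene annotation: gene-body containment and nearest-promoter assignment.

A SNP is *intragenic* when its (0-based) point falls inside any gene
body span ``[start, end)`` — introns and UTRs included — and
*intergenic* otherwise.  Every SNP is additionally assigned the gene
whose strand-aware transcription start site (the "promoter", taken as a
point) is closest in absolute base pairs; intergenic SNPs inherit that
gene as their putative target.  Ties are broken toward the
lexicographically smallest gene_id, and a SNP inside several
overlapping genes is hosted by the one with the nearest TSS under the
same tie rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneModel, GwasSnp

logger = logging.getLogger(__name__)

INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    location_class: str
    host_gene: str  # empty when intergenic
    nearest_gene: str  # empty when no gene on the chromosome
    promoter_distance_bp: Optional[int]  # None when no gene on the chromosome


def classify_location(
    snp: GwasSnp, genes: Sequence[GeneModel], upstream_window: int = 0
) -> tuple[str, str]:
    """Classify one SNP against gene bodies; returns (location_class, host_gene).

    ``upstream_window`` optionally widens each gene body upstream of its
    TSS (promoter window); it is 0 by default so "intragenic" means the
    annotated span itself.
    """
    pos0 = snp.pos0
    hosts = []
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        lo, hi = g.start, g.end
        if upstream_window:
            if g.strand == "+":
                lo -= upstream_window
            else:
                hi += upstream_window
        if lo <= pos0 < hi:
            hosts.append(g)
    if not hosts:
        return INTERGENIC, ""
    host = min(hosts, key=lambda g: (abs(pos0 - g.tss), g.gene_id))
    return INTRAGENIC, host.gene_id


def nearest_promoter(
    snp: GwasSnp, genes: Sequence[GeneModel]
) -> Optional[tuple[str, int]]:
    """Gene with the TSS closest to the SNP, with its distance in bp.

    Returns ``None`` (and logs) when the SNP's chromosome carries no gene.
    """
    pos0 = snp.pos0
    same = [g for g in genes if g.chrom == snp.chrom]
    if not same:
        logger.warning("no gene on chromosome %s for SNP %s", snp.chrom, snp.snp_id)
        return None
    best = min(same, key=lambda g: (abs(pos0 - g.tss), g.gene_id))
    return best.gene_id, abs(pos0 - best.tss)


def _index_genes(genes: Sequence[GeneModel]):
    """Per-chromosome arrays sorted by gene_id (so argmin tie-breaks lexicographically)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.gene_id)
        index[chrom] = (
            np.array([g.start for g in glist], dtype=np.int64),
            np.array([g.end for g in glist], dtype=np.int64),
            np.array([g.tss for g in glist], dtype=np.int64),
            [g.gene_id for g in glist],
        )
    return index


def annotate_all(
    snps: Sequence[GwasSnp],
    genes: Sequence[GeneModel],
    upstream_window: int = 0,
) -> list[SnpAnnotation]:
    """Annotate every SNP, preserving input order.

    Vectorized per chromosome; equivalent to calling
    :func:`classify_location` and :func:`nearest_promoter` per SNP.
    """
    index = _index_genes(genes)
    out: list[Optional[SnpAnnotation]] = [None] * len(snps)

    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(snps):
        by_chrom.setdefault(s.chrom, []).append(i)

    missing_chroms = set()
    for chrom, idxs in by_chrom.items():
        if chrom not in index:
            missing_chroms.add(chrom)
            for i in idxs:
                out[i] = SnpAnnotation(snps[i].snp_id, INTERGENIC, "", "", None)
            continue
        starts, ends, tss, gene_ids = index[chrom]
        if upstream_window:
            # widen upstream of the TSS only
            plus = tss == starts
            starts = np.where(plus, starts - upstream_window, starts)
            ends = np.where(~plus, ends + upstream_window, ends)
        pos0 = np.array([snps[i].pos0 for i in idxs], dtype=np.int64)
        dist = np.abs(pos0[:, None] - tss[None, :])
        contains = (pos0[:, None] >= starts[None, :]) & (pos0[:, None] < ends[None, :])
        # argmin over gene_id-sorted columns: first minimum = smallest gene_id
        nearest_col = np.argmin(dist, axis=1)
        masked = np.where(contains, dist, np.iinfo(np.int64).max)
        host_col = np.argmin(masked, axis=1)
        any_host = contains.any(axis=1)
        for row, i in enumerate(idxs):
            hosted = bool(any_host[row])
            out[i] = SnpAnnotation(
                snp_id=snps[i].snp_id,
                location_class=INTRAGENIC if hosted else INTERGENIC,
                host_gene=gene_ids[host_col[row]] if hosted else "",
                nearest_gene=gene_ids[nearest_col[row]],
                promoter_distance_bp=int(dist[row, nearest_col[row]]),
            )
    if missing_chroms:
        logger.warning(
            "no gene models on chromosome(s) %s; SNPs there classified intergenic "
            "with no nearest gene",
            ", ".join(sorted(missing_chroms)),
        )
    return out  # type: ignore[return-value]
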