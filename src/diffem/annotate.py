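"""Mapping HDMSs to genes and genomic features, and correlating epigenetic
with expression dynamics.

A region is assigned to a gene when the region's center falls in the gene's
span extended by a strand-aware promoter flank upstream of the TSS; the
feature class (promoter > coding > exon > intron) is decided by the peak
bin, the bin with the highest dynamics score.  Expression dynamics per gene
is the index of dispersion of its expression across cell types, with the
same empirical p-value scheme used for modification dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hdms import HDMSRegion, empirical_pvalues_from_scores
from .scorers import iod_score
from .signal_io import ExpressionMatrix, GeneModel

__all__ = [
    "AnnotatedHDMS",
    "InsufficientPairsError",
    "assign_hdms_to_gene",
    "classify_feature",
    "annotate_regions",
    "expression_dynamics",
    "correlate_dynamics",
]

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_FLANK = 2000

FEATURE_CLASSES = ("promoter", "coding", "exon", "intron", "intergenic")


class InsufficientPairsError(ValueError):
    """Too few annotated regions of the requested class to correlate."""


@dataclass
class AnnotatedHDMS:
    """An HDMS with its assigned gene (or none) and feature class."""

    region: HDMSRegion
    gene_id: str | None
    feature_class: str

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.feature_class == "intergenic"):
            raise ValueError("gene_id is None exactly for intergenic regions")


def _extended_span(gene: GeneModel, promoter_flank: int) -> tuple[int, int]:
    """Gene span extended by the promoter flank upstream of the TSS."""
    if gene.strand == "+":
        return gene.start - promoter_flank, gene.end
    return gene.start, gene.end + promoter_flank


def assign_hdms_to_gene(
    region: HDMSRegion,
    genes: list[GeneModel],
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> str | None:
    """Gene whose extended span contains the region center, or None.

    Among several qualifying genes the one whose TSS is nearest to the
    center wins (ties: first in sorted order).
    """
    center = region.center
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        lo, hi = _extended_span(g, promoter_flank)
        if lo <= center < hi:
            d = abs(center - g.tss)
            if best is None or d < best[0]:
                best = (d, g.gene_id)
    return None if best is None else best[1]


def _overlaps_any(lo: int, hi: int, intervals) -> bool:
    return any(max(lo, s) < min(hi, e) for s, e in intervals)


def classify_feature(
    region: HDMSRegion,
    gene: GeneModel | None,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> str:
    """Feature class of a region's peak bin relative to its assigned gene.

    Precedence promoter > coding > exon > intron; the promoter is the
    window TSS +/- promoter_flank.  Without an assigned gene the region is
    intergenic.  With a span-only annotation (no CDS) the finest available
    class below promoter is exon.
    """
    if gene is None:
        return "intergenic"
    bin_size = (region.end - region.start) // region.n_bins
    peak_lo = region.start + (region.peak_bin - region.start_bin) * bin_size
    peak_hi = peak_lo + bin_size
    prom_lo, prom_hi = gene.tss - promoter_flank, gene.tss + promoter_flank
    if max(peak_lo, prom_lo) < min(peak_hi, prom_hi):
        return "promoter"
    if gene.cds and _overlaps_any(peak_lo, peak_hi, gene.cds):
        return "coding"
    exons = gene.exons or ((gene.start, gene.end),)  # span-only annotation
    if _overlaps_any(peak_lo, peak_hi, exons):
        return "exon"
    return "intron"


def annotate_regions(
    regions: list[HDMSRegion],
    genes: list[GeneModel],
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> list[AnnotatedHDMS]:
    """Assign every region a gene (center rule) and feature class (peak rule)."""
    by_id = {g.gene_id: g for g in genes}
    out = []
    for r in regions:
        gid = assign_hdms_to_gene(r, genes, promoter_flank)
        cls = classify_feature(r, by_id[gid] if gid else None, promoter_flank)
        out.append(AnnotatedHDMS(region=r, gene_id=gid, feature_class=cls))
    return out


def expression_dynamics(expr: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Expression dynamics per gene: index of dispersion across cell types.

    Returns a frame indexed by gene id with columns ``score`` and
    ``pvalue`` (empirical upper-tail p over the nonzero-score background,
    the same scheme the HDMS caller uses).
    """
    if len(expr.cell_types) < 2:
        raise ValueError("need at least two cell types")
    scores = np.array([iod_score(row, ddof=ddof) for row in expr.values]) if len(
        expr.gene_ids
    ) else np.array([])
    if scores.size and (scores > 0).any():
        pvals = empirical_pvalues_from_scores(scores, np.ones_like(scores, dtype=bool))
    else:
        pvals = np.ones_like(scores)
    return pd.DataFrame({"score": scores, "pvalue": pvals}, index=pd.Index(expr.gene_ids, name="gene_id"))


def correlate_dynamics(
    annotated: list[AnnotatedHDMS],
    expr_dyn: pd.DataFrame,
    feature_class: str,
    region_stat: str = "max",
) -> float:
    """Pearson r between region dynamics and assigned-gene expression dynamics.

    Restricted to regions of ``feature_class`` whose gene has an expression
    dynamics score; a gene hit by several regions contributes once per
    region.  ``region_stat`` picks the per-region score: the peak bin's
    score (max, default), or the sum/mean over significant bins.
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    key = {"max": "rank_score", "sum": "score_sum", "mean": "score_mean"}
    if region_stat not in key:
        raise ValueError("region_stat must be one of max/sum/mean")
    xs, ys = [], []
    for a in annotated:
        if a.feature_class != feature_class or a.gene_id is None:
            continue
        if a.gene_id not in expr_dyn.index:
            continue
        xs.append(getattr(a.region, key[region_stat]))
        ys.append(float(expr_dyn.loc[a.gene_id, "score"]))
    if len(xs) < 3:
        raise InsufficientPairsError(
            f"only {len(xs)} {feature_class} region/gene pairs; need at least 3"
        )
    x, y = np.asarray(xs, float), np.asarray(ys, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientPairsError("zero variance on one side; correlation undefined")
    return float(stats.pearsonr(x, y)[0])
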