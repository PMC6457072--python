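"""Calling highly dynamic modification sites (HDMSs).

Bins with zero dynamics are filtered first; the remaining nonzero retained
bins form the genome background.  Each bin's empirical p-value is the
fraction of background bins scoring at least as high (orientation-aware),
bins with p < alpha are kept and genomically adjacent significant bins are
merged into HDMS regions.  Cross-mark overlap and correlation matrices
summarize how the called sites and the underlying scores agree between
marks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scorers import DynamicsTrack

__all__ = [
    "NoSignalError",
    "HDMSRegion",
    "empirical_pvalues",
    "empirical_pvalues_from_scores",
    "call_hdms",
    "rank_regions",
    "hdms_overlap_matrix",
    "mark_correlation_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class NoSignalError(ValueError):
    """Every retained bin has zero dynamics; no background exists."""


@dataclass
class HDMSRegion:
    """A maximal run of adjacent significant bins.

    ``score`` is the method-native score at the peak bin (the bin with the
    most dynamic value); ``rank_score`` is the same value on the common
    larger-is-more-dynamic scale and is what rankings use.  ``peak_bin`` is
    a global bin index inside [start_bin, end_bin).
    """

    region_id: str
    chrom: str
    start: int
    end: int
    start_bin: int
    end_bin: int
    peak_bin: int
    score: float
    rank_score: float
    score_sum: float
    score_mean: float
    pvalue: float
    mark: str = ""
    method: str = ""

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def empirical_pvalues_from_scores(upper: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Empirical upper-tail p-values against the nonzero background.

    ``upper`` holds scores where larger = more dynamic and 0 = no dynamics;
    ``valid`` flags the bins eligible as background.  Background = valid
    bins with score > 0; p = #(background >= score) / #background.  Zero or
    invalid bins get p = 1.
    """
    upper = np.asarray(upper, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    bg = upper[valid & (upper > 0)]
    if bg.size == 0:
        raise NoSignalError("all dynamics scores are zero: no background to test against")
    srt = np.sort(bg)
    # count of background >= s via position of s in sorted background
    ge = bg.size - np.searchsorted(srt, upper, side="left")
    p = ge / bg.size
    p[~valid | (upper <= 0)] = 1.0
    return p


def empirical_pvalues(track: DynamicsTrack) -> np.ndarray:
    """Per-bin empirical p-values of a dynamics track (orientation-aware)."""
    return empirical_pvalues_from_scores(track.upper_tail_scores(), track.retained_mask)


def call_hdms(
    track: DynamicsTrack,
    alpha: float = DEFAULT_ALPHA,
    pvalues: np.ndarray | None = None,
    merge_gap: int = 0,
) -> list[HDMSRegion]:
    """Call HDMS regions from a dynamics track.

    Bins with p < alpha (strict) are significant; maximal runs of
    consecutive significant bins on one chromosome (allowing up to
    ``merge_gap`` intervening non-significant bins) become regions.  An
    empty call set is a valid outcome.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if pvalues is None:
        pvalues = empirical_pvalues(track)
    upper = track.upper_tail_scores()
    sig = np.flatnonzero((pvalues < alpha) & track.retained_mask)
    if sig.size == 0:
        return []
    chrom_of = track.bins.chrom_of(sig)
    # split where the index gap exceeds merge_gap+1 or the chromosome changes
    brk = np.flatnonzero((np.diff(sig) > merge_gap + 1) | (np.diff(chrom_of) != 0)) + 1
    groups = np.split(sig, brk)
    regions: list[HDMSRegion] = []
    bin_size = track.bins.bin_size
    for i, g in enumerate(groups):
        start_bin, end_bin = int(g[0]), int(g[-1]) + 1
        peak = int(g[np.argmax(upper[g])])
        chrom, start_bp, _ = track.bins.bin_location(start_bin)
        end_bp = start_bp + (end_bin - start_bin) * bin_size
        regions.append(
            HDMSRegion(
                region_id=f"{track.mark or 'mark'}_{track.method}_{i + 1:05d}",
                chrom=chrom,
                start=start_bp,
                end=end_bp,
                start_bin=start_bin,
                end_bin=end_bin,
                peak_bin=peak,
                score=float(track.scores[peak]),
                rank_score=float(upper[peak]),
                score_sum=float(upper[g].sum()),
                score_mean=float(upper[g].mean()),
                pvalue=float(pvalues[g].min()),
                mark=track.mark,
                method=track.method,
            )
        )
    return regions


def rank_regions(regions: list[HDMSRegion], top_k: int | None = None) -> list[HDMSRegion]:
    """Rank regions by dynamics: rank_score desc, then size desc, then
    genomic order; optionally truncate to the top k."""
    ranked = sorted(
        regions,
        key=lambda r: (-r.rank_score, -r.n_bins, r.chrom, r.start),
    )
    return ranked if top_k is None else ranked[:top_k]


# ---------------------------------------------------------------------------
# cross-mark comparisons
# ---------------------------------------------------------------------------

def _overlap_fraction(a: list[HDMSRegion], b: list[HDMSRegion]) -> float:
    """Fraction of regions in ``a`` overlapping (>= 1 bp) any region in ``b``."""
    if not a:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in b:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivs in by_chrom.values():
        ivs.sort()
    hits = 0
    for r in a:
        ivs = by_chrom.get(r.chrom)
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        if np.any((starts < r.end) & (ends > r.start)):
            hits += 1
    return hits / len(a)


def hdms_overlap_matrix(call_sets: dict[str, list[HDMSRegion]]) -> pd.DataFrame:
    """Pairwise HDMS overlap proportions between marks.

    Entry (i, j) = proportion of mark i's HDMSs overlapped by at least one
    HDMS of mark j; not symmetric in general, 0/0 counts as 0.
    """
    if len(call_sets) < 2:
        raise ValueError("need call sets for at least two marks")
    marks = list(call_sets)
    mat = pd.DataFrame(0.0, index=marks, columns=marks)
    for mi in marks:
        for mj in marks:
            mat.loc[mi, mj] = _overlap_fraction(call_sets[mi], call_sets[mj])
    return mat


def mark_correlation_matrix(tracks: dict[str, DynamicsTrack]) -> pd.DataFrame:
    """Pearson correlations between marks' per-bin dynamics scores.

    Each pair is correlated over the bins retained in both marks' masks.
    A pair where either score vector is constant has no defined correlation
    and is reported as NaN (logged).
    """
    marks = list(tracks)
    bins = tracks[marks[0]].bins
    for t in tracks.values():
        if t.bins != bins:
            raise ValueError("all tracks must share one bin grid")
    mat = pd.DataFrame(np.nan, index=marks, columns=marks)
    for i, mi in enumerate(marks):
        for mj in marks[i:]:
            ti, tj = tracks[mi], tracks[mj]
            joint = ti.retained_mask & tj.retained_mask
            x = ti.upper_tail_scores()[joint]
            y = tj.upper_tail_scores()[joint]
            if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s/%s undefined (constant scores)", mi, mj)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            mat.loc[mi, mj] = r
            mat.loc[mj, mi] = r
    return mat
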