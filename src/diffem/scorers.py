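"""Per-bin dynamics scorers: Hamming dynamics score, Shannon-entropy
specificity (QDMR-style) and index of dispersion (IOD).

The Hamming dynamics score of a bin is the sum, over every cell type t, of
the number of cell types whose binary state differs from t's:

    Diff_t = sum_{m != t} |b_t - b_m|        DS = sum_t Diff_t = 2 c (M - c)

with c the number of cell types in state 1.  Each discordant unordered pair
is counted twice (once from each side); that double counting is kept as the
score's definition.  QDMR-style entropy and IOD score the continuous,
depth-normalized signal instead of the binary states and provide the
comparison baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .binarize import BinaryProfile
from .signal_io import GenomeBins

__all__ = [
    "DynamicsTrack",
    "hamming_diff",
    "diffem_score",
    "diffem_score_track",
    "qdmr_entropy",
    "iod_score",
    "normalize_tracks",
    "qdmr_score_track",
    "iod_score_track",
]

logger = logging.getLogger(__name__)


@dataclass
class DynamicsTrack:
    """Per-bin dynamics scores of one mark under one scoring method.

    ``scores`` covers every bin of the grid; only ``retained_mask`` bins are
    meaningful downstream.  ``larger_is_dynamic`` records the method's
    orientation; for smaller-is-dynamic methods ``score_ceiling`` is the
    finite maximum used to flip scores into a common upper-tail scale
    (log2 M for entropy).  No-signal bins may carry NaN.
    """

    mark: str
    method: str
    bins: GenomeBins
    scores: np.ndarray
    retained_mask: np.ndarray
    n_cell_types: int
    larger_is_dynamic: bool = True
    score_ceiling: float | None = None
    diff_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.scores.shape != (self.bins.n_bins,):
            raise ValueError("scores length must equal the bin count")
        if self.retained_mask.shape != self.scores.shape:
            raise ValueError("mask length must equal the bin count")
        if not self.larger_is_dynamic and self.score_ceiling is None:
            raise ValueError("smaller-is-dynamic methods need a score_ceiling")

    def upper_tail_scores(self) -> np.ndarray:
        """Scores on a common scale where larger = more dynamic and 0 = not
        dynamic at all; no-signal (NaN) bins map to 0."""
        if self.larger_is_dynamic:
            out = self.scores.copy()
        else:
            out = self.score_ceiling - self.scores
        out = np.where(np.isnan(out), 0.0, out)
        # numerical floor: tiny negatives from the flip are "not dynamic"
        return np.where(out < 0, 0.0, out)


# ---------------------------------------------------------------------------
# Hamming dynamics
# ---------------------------------------------------------------------------

def hamming_diff(bits: np.ndarray, t: int) -> int:
    """Number of cell types whose binary state differs from cell ``t``'s."""
    bits = np.asarray(bits)
    M = bits.shape[0]
    if M < 2:
        raise ValueError("need at least two cell types for a pairwise comparison")
    if not 0 <= t < M:
        raise IndexError("cell index out of range")
    return int(np.sum(bits != bits[t]))


def diffem_score(bits: np.ndarray) -> int:
    """Dynamics score of one bin: sum of hamming_diff over every cell type.

    Closed form 2*c*(M-c) with c ones among M states; equals the explicit
    double loop because every discordant pair contributes from both sides.
    """
    bits = np.asarray(bits)
    M = bits.shape[0]
    if M < 2:
        raise ValueError("need at least two cell types")
    c = int(np.sum(bits != 0))
    return 2 * c * (M - c)


def diffem_score_track(profile: BinaryProfile, keep_diff: bool = False) -> DynamicsTrack:
    """Vectorized dynamics score over all bins of a binary profile.

    With ``keep_diff`` the per-cell T x N Diff matrix (each cell's disagreement
    count at each bin) is attached to the track.
    """
    M = profile.n_cell_types
    if M < 2:
        raise ValueError("need at least two cell types")
    c = profile.matrix.sum(axis=0).astype(np.int64)
    scores = (2 * c * (M - c)).astype(float)
    diff = None
    if keep_diff:
        # Diff_tn = c_n if bit is 0 else M - c_n, minus the cell's own match
        b = profile.matrix.astype(np.int64)
        diff = np.where(b == 1, M - c, c)
    return DynamicsTrack(
        mark=profile.mark,
        method="diffem",
        bins=profile.bins,
        scores=scores,
        retained_mask=profile.retained_mask.copy(),
        n_cell_types=M,
        larger_is_dynamic=True,
        diff_matrix=diff,
    )


# ---------------------------------------------------------------------------
# entropy and dispersion baselines
# ---------------------------------------------------------------------------

def qdmr_entropy(signal: np.ndarray) -> float:
    """Shannon entropy (bits) of a signal's distribution across cell types.

    Low entropy = cell-type-specific = dynamic.  All-zero signal has no
    distribution; NaN is returned as the no-signal sentinel and handled by
    the p-value stage.
    """
    s = np.asarray(signal, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least two cell types")
    if np.any(s < 0):
        raise ValueError("signal must be non-negative")
    total = s.sum()
    if total == 0:
        return float("nan")
    return float(_shannon_entropy(s / total, base=2))


def iod_score(signal: np.ndarray, ddof: int = 1) -> float:
    """Index of dispersion: variance of the signal divided by its mean.

    Sample variance (ddof=1) by default; ``ddof=0`` gives the population
    variant.  A zero-mean (all-zero) signal scores 0 by convention.
    """
    s = np.asarray(signal, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least two cell types")
    m = s.mean()
    if m == 0:
        return 0.0
    return float(s.var(ddof=ddof) / m)


def normalize_tracks(counts: np.ndarray) -> np.ndarray:
    """Depth-normalize a T x N count matrix: each row divided by its mean.

    Every track ends up with mean 1, removing sequencing-depth differences
    before entropy/IOD scoring.  All-zero tracks are left as zeros (logged).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValueError("expected a T x N matrix with at least one track")
    means = counts.mean(axis=1, keepdims=True)
    zero = means[:, 0] == 0
    if zero.any():
        logger.warning("%d all-zero track(s) left unnormalized", int(zero.sum()))
    safe = np.where(means == 0, 1.0, means)
    return counts / safe


def _stack_counts(tracks) -> tuple[np.ndarray, GenomeBins, str, int]:
    bins = tracks[0].bins
    for t in tracks:
        if t.bins != bins:
            raise ValueError("all tracks must share one bin grid")
    mat = np.stack([np.asarray(t.counts, dtype=float) for t in tracks])
    return mat, bins, tracks[0].mark, mat.shape[0]


def qdmr_score_track(tracks, retained_mask: np.ndarray | None = None) -> DynamicsTrack:
    """Entropy score per bin over a mark's depth-normalized count tracks."""
    mat, bins, mark, M = _stack_counts(tracks)
    if M < 2:
        raise ValueError("need at least two cell types")
    norm = normalize_tracks(mat)
    totals = norm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = norm / totals
        h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=0)
    scores = np.where(totals > 0, h, np.nan)
    mask = np.ones(bins.n_bins, bool) if retained_mask is None else np.asarray(retained_mask, bool)
    return DynamicsTrack(
        mark=mark, method="qdmr", bins=bins, scores=scores, retained_mask=mask,
        n_cell_types=M, larger_is_dynamic=False, score_ceiling=float(np.log2(M)),
    )


def iod_score_track(tracks, retained_mask: np.ndarray | None = None, ddof: int = 1) -> DynamicsTrack:
    """Index-of-dispersion score per bin over depth-normalized count tracks."""
    mat, bins, mark, M = _stack_counts(tracks)
    if M < 2:
        raise ValueError("need at least two cell types")
    norm = normalize_tracks(mat)
    means = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(means > 0, var / means, 0.0)
    mask = np.ones(bins.n_bins, bool) if retained_mask is None else np.asarray(retained_mask, bool)
    return DynamicsTrack(
        mark=mark, method="iod", bins=bins, scores=scores, retained_mask=mask,
        n_cell_types=M, larger_is_dynamic=True,
    )
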