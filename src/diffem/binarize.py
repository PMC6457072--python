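"""Binarization of binned count tracks and removal of unmappable runs.

Each (mark, cell type) track is thresholded at its own genome-wide mean
count: a bin is 1 when its count is strictly higher than the mean, 0
otherwise.  Stacking the binarized tracks of one mark over T cell types
gives the T x N binary matrix the dynamics scores are computed from.
Stretches where every cell type is 0 longer than 5 kb are treated as
unmappable sequence and masked out; runs never span a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .signal_io import BinnedCountTrack, GenomeBins

__all__ = [
    "BinaryProfile",
    "compute_threshold",
    "binarize_track",
    "binarize_profile",
    "filter_unmappable",
]

DEFAULT_MAX_ZERO_RUN_BP = 5000


@dataclass
class BinaryProfile:
    """Binary modification states of one mark across T cell types.

    ``matrix`` is T x N with entries in {0, 1}; ``retained_mask`` flags the
    bins that survive the unmappable-run filter.
    """

    mark: str
    cell_types: list[str]
    bins: GenomeBins
    matrix: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        T, N = self.matrix.shape
        if T != len(self.cell_types):
            raise ValueError("matrix rows must match cell_types")
        if N != self.bins.n_bins or self.retained_mask.shape != (N,):
            raise ValueError("matrix/mask width must match the bin grid")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("binary matrix entries must be 0 or 1")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def subset_cells(self, cell_types: Sequence[str]) -> "BinaryProfile":
        idx = [self.cell_types.index(c) for c in cell_types]
        return replace(self, cell_types=list(cell_types), matrix=self.matrix[idx])


def compute_threshold(track: BinnedCountTrack) -> float:
    """Binarization threshold for one track: total read count / bin count."""
    n = track.bins.n_bins
    if n == 0:
        raise ValueError("track has no bins")
    return float(np.sum(track.counts) / n)


def binarize_track(track: BinnedCountTrack, threshold: float) -> np.ndarray:
    """Binary vector: 1 where the count is strictly higher than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return (track.counts > threshold).astype(np.uint8)


def binarize_profile(
    tracks: Sequence[BinnedCountTrack],
    max_zero_run_bp: int | None = DEFAULT_MAX_ZERO_RUN_BP,
) -> BinaryProfile:
    """Binarize one mark's tracks (per-track mean thresholds) into a profile.

    When ``max_zero_run_bp`` is not None the unmappable-run filter is applied
    immediately; pass None to keep all bins retained.
    """
    if not tracks:
        raise ValueError("at least one track required")
    bins = tracks[0].bins
    mark = tracks[0].mark
    for t in tracks:
        if t.bins != bins:
            raise ValueError("all tracks must share one bin grid")
    matrix = np.stack([binarize_track(t, compute_threshold(t)) for t in tracks])
    profile = BinaryProfile(
        mark=mark,
        cell_types=[t.cell_type for t in tracks],
        bins=bins,
        matrix=matrix,
        retained_mask=np.ones(bins.n_bins, dtype=bool),
    )
    if max_zero_run_bp is not None:
        profile = filter_unmappable(profile, max_zero_run_bp)
    return profile


def _zero_run_mask(all_zero: np.ndarray, bins: GenomeBins, max_zero_run_bp: int) -> np.ndarray:
    """True for bins inside an all-zero run longer than ``max_zero_run_bp``.

    Runs are delimited per chromosome; length is strict (> max, not >=).
    """
    drop = np.zeros(bins.n_bins, dtype=bool)
    offsets = bins.chrom_offsets
    for ci in range(len(bins.chrom_names)):
        lo, hi = int(offsets[ci]), int(offsets[ci + 1])
        z = all_zero[lo:hi]
        if not z.any():
            continue
        # run boundaries via edge detection
        padded = np.concatenate([[False], z, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            if (e - s) * bins.bin_size > max_zero_run_bp:
                drop[lo + s : lo + e] = True
    return drop


def filter_unmappable(
    profile: BinaryProfile, max_zero_run_bp: int = DEFAULT_MAX_ZERO_RUN_BP
) -> BinaryProfile:
    """Mask out runs of bins with no signal in any cell type.

    A run is dropped only when its length strictly exceeds
    ``max_zero_run_bp`` (5 kb default: 25 bins of 200 bp survive, 26 do not).
    The result's mask is the AND of the incoming mask and the run filter.
    """
    all_zero = ~profile.matrix.any(axis=0)
    drop = _zero_run_mask(all_zero, profile.bins, max_zero_run_bp)
    return replace(profile, retained_mask=profile.retained_mask & ~drop)
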