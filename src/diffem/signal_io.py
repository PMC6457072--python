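"""Readers and writers for the on-disk formats used throughout the package.

Counts come in as bin-aligned TSV (bedGraph dialect: chrom, start, end,
count), gene models as BED6 or BED12, expression as a gene-by-cell-type TSV
and region calls go out as BED6.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DataError",
    "GenomeBins",
    "BinnedCountTrack",
    "GeneModel",
    "ExpressionMatrix",
    "read_binned_counts",
    "write_binned_counts",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression",
    "write_expression",
    "write_regions_bed",
    "read_regions_bed",
    "write_score_track",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class DataError(ValueError):
    """A file parses but carries values that violate an invariant."""


# ---------------------------------------------------------------------------
# genome segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBins:
    """A fixed segmentation of the genome into equal-sized bins.

    Bins are contiguous, non-overlapping and sorted within each chromosome;
    a global bin index enumerates them chromosome by chromosome in the
    declared order.

    Parameters
    ----------
    chrom_names:
        Ordered chromosome names.
    chrom_n_bins:
        Number of bins per chromosome, aligned with ``chrom_names``.
    bin_size:
        Bin width in bp (200 by default, the resolution at which binned
        ChIP-seq signal is distributed).
    """

    chrom_names: tuple[str, ...]
    chrom_n_bins: tuple[int, ...]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.chrom_names) != len(self.chrom_n_bins):
            raise ValueError("chrom_names and chrom_n_bins length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(n < 0 for n in self.chrom_n_bins):
            raise ValueError("negative bin count")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_n_bins", tuple(int(n) for n in self.chrom_n_bins))

    @property
    def n_bins(self) -> int:
        return int(sum(self.chrom_n_bins))

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global index of the first bin of each chromosome, plus a final
        sentinel equal to ``n_bins``."""
        return np.concatenate([[0], np.cumsum(self.chrom_n_bins)])

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise FormatError(f"unknown chromosome {chrom!r}") from None

    def global_index(self, chrom: str, start_bp: int) -> int:
        """Global bin index of the bin starting at ``start_bp`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if start_bp % self.bin_size != 0:
            raise FormatError(f"position {start_bp} not on the {self.bin_size} bp grid")
        off = start_bp // self.bin_size
        if not 0 <= off < self.chrom_n_bins[ci]:
            raise FormatError(f"{chrom}:{start_bp} outside the declared segmentation")
        return int(self.chrom_offsets[ci] + off)

    def chrom_of(self, global_index: int | np.ndarray):
        """Chromosome index for one or many global bin indices."""
        return np.searchsorted(self.chrom_offsets, global_index, side="right") - 1

    def bin_location(self, global_index: int) -> tuple[str, int, int]:
        """(chrom, start_bp, end_bp) of a global bin index."""
        ci = int(self.chrom_of(global_index))
        off = int(global_index - self.chrom_offsets[ci])
        s = off * self.bin_size
        return self.chrom_names[ci], s, s + self.bin_size

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        """Half-open global index range of a chromosome."""
        ci = self.chrom_index(chrom)
        off = self.chrom_offsets
        return int(off[ci]), int(off[ci + 1])

    def to_frame(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) table in global order."""
        chroms = np.repeat(self.chrom_names, self.chrom_n_bins)
        starts = np.concatenate(
            [np.arange(n, dtype=np.int64) * self.bin_size for n in self.chrom_n_bins]
        ) if self.n_bins else np.array([], dtype=np.int64)
        return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + self.bin_size})


@dataclass
class BinnedCountTrack:
    """Binned read counts for one mark in one cell type."""

    mark: str
    cell_type: str
    bins: GenomeBins
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.bins.n_bins,):
            raise ValueError("counts length must equal the total bin count")
        if np.any(self.counts < 0):
            raise DataError("negative read count")


# ---------------------------------------------------------------------------
# gene models and expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS, exon and CDS structure.

    Coordinates are 0-based half-open; ``tss`` is ``start`` on the + strand
    and ``end - 1`` on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default=())
    cds: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise DataError(f"gene {self.gene_id}: start must be < end")
        for s, e in (*self.exons, *self.cds):
            if not (self.start <= s < e <= self.end):
                raise DataError(f"gene {self.gene_id}: exon/CDS outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ExpressionMatrix:
    """Non-negative expression values, genes by cell types."""

    gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("values shape must be (n_genes, n_cell_types)")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if self.values.size and np.any(self.values < 0):
            raise DataError("negative expression value")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_cells(self, cell_types: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.cell_types.index(c) for c in cell_types]
        return ExpressionMatrix(list(self.gene_ids), list(cell_types), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)


# ---------------------------------------------------------------------------
# count tracks
# ---------------------------------------------------------------------------

_COUNT_COLS = ["chrom", "start", "end", "count"]


def read_binned_counts(
    path: str | os.PathLike,
    bins: GenomeBins,
    mark: str = "",
    cell_type: str = "",
) -> BinnedCountTrack:
    """Read a bin-aligned count TSV into genome bin order.

    Bins absent from the file are zero-filled, so sparse bedGraph-style
    files that omit empty bins round-trip exactly.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_COUNT_COLS, comment="#",
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_COUNT_COLS)
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    if len(df):
        if df[["start", "end", "count"]].isna().any().any():
            raise FormatError(f"{path}: malformed row")
        starts = df["start"].to_numpy(dtype=np.int64)
        ends = df["end"].to_numpy(dtype=np.int64)
        if np.any(ends - starts != bins.bin_size) or np.any(starts % bins.bin_size):
            raise FormatError(f"{path}: interval not aligned to the {bins.bin_size} bp bin grid")
        vals = df["count"].to_numpy()
        if np.any(vals < 0):
            raise DataError(f"{path}: negative count")
        idx = np.fromiter(
            (bins.global_index(c, int(s)) for c, s in zip(df["chrom"], starts)),
            dtype=np.int64,
            count=len(df),
        )
        counts[idx] = np.asarray(np.rint(vals), dtype=np.int64)
    return BinnedCountTrack(mark=mark, cell_type=cell_type, bins=bins, counts=counts)


def write_binned_counts(
    track: BinnedCountTrack, path: str | os.PathLike, sparse: bool = True
) -> None:
    """Write a count track as a bin-aligned TSV; ``sparse`` omits zero bins."""
    df = track.bins.to_frame()
    df["count"] = track.counts
    if sparse:
        df = df[df["count"] != 0]
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation (BED6 / BED12)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED12 (preferred) or minimal BED6.

    BED6 carries only the gene span: exons default to the whole span and the
    CDS is left empty.  Models come back sorted by (chrom, start).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) not in (6, 12):
                raise FormatError(f"{path}:{ln}: expected 6 or 12 BED columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            if name in seen:
                raise DataError(f"{path}:{ln}: duplicate gene id {name!r}")
            seen.add(name)
            if len(f) == 12:
                thick_s, thick_e = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offs) != n_blocks:
                    raise FormatError(f"{path}:{ln}: block count mismatch")
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
                cds = tuple(
                    (max(s, thick_s), min(e, thick_e))
                    for s, e in exons
                    if max(s, thick_s) < min(e, thick_e)
                )
            else:
                exons = ((start, end),)
                cds = ()
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, strand=strand, start=start,
                          end=end, exons=exons, cds=cds)
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as BED12."""
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
        exons = g.exons or ((g.start, g.end),)
        if g.cds:
            thick_s = min(s for s, _ in g.cds)
            thick_e = max(e for _, e in g.cds)
        else:
            thick_s = thick_e = g.start
        sizes = ",".join(str(e - s) for s, e in exons)
        offs = ",".join(str(s - g.start) for s, _ in exons)
        rows.append(
            "\t".join(
                map(str, [g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                          thick_s, thick_e, 0, len(exons), sizes, offs])
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a gene-by-cell-type expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric expression value") from exc
    if np.isnan(values).any():
        raise DataError(f"{path}: missing or non-numeric expression value")
    if values.size and (values < 0).any():
        raise DataError(f"{path}: negative expression value")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_types=[str(c) for c in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence, path: str | os.PathLike) -> None:
    """Write regions (anything with chrom/start/end/region_id/score) as BED6.

    Output is sorted by (chrom, start); regions from one call set must be
    disjoint, anything else indicates an upstream bug.
    """
    recs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    prev = None
    for r in recs:
        if not r.start < r.end:
            raise RuntimeError(f"region {r.region_id}: empty or inverted interval")
        if prev is not None and prev.chrom == r.chrom and r.start < prev.end:
            raise RuntimeError(
                f"overlapping regions in one call set: {prev.region_id} / {r.region_id}"
            )
        prev = r
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.score:g}\t.\n")


def read_regions_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 region file back into a table (for round-trips and tests)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "region_id", "score", "strand"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "region_id", "score", "strand"])
    return df


def write_score_track(track, path: str | os.PathLike) -> None:
    """Write per-bin scores of a dynamics track as TSV (retained bins only)."""
    df = track.bins.to_frame()
    df["score"] = track.scores
    df = df[track.retained_mask]
    df.to_csv(path, sep="\t", header=False, index=False)
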