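"""Seeded generator of multi-cell-type binned epigenomes with planted
cell-type-subset-specific enriched regions, unmappable runs, gene models
and a coupled expression matrix.

The generator emulates the structure of pre-binned multi-cell-type
ChIP-seq signal: iid Poisson background counts, planted regions where a
random subset of cell types is enriched at a higher Poisson rate, and
stretches of all-zero bins standing in for unmappable sequence.  One gene
is laid over each planted region (in its body or with its promoter on the
region, configurable mix) and that gene's expression is coupled to the
region's active cell subset with multiplicative log-normal noise.  A full
truth table makes every downstream stage testable without real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_io import BinnedCountTrack, ExpressionMatrix, GeneModel, GenomeBins

__all__ = [
    "PlantedRegion",
    "SyntheticTruth",
    "generate_epigenome",
    "generate_annotation",
    "generate_expression",
    "simulate_dataset",
    "recovery_stats",
]

# Study conditions: sizes and rates of the reference synthetic epigenome.
DEFAULTS = dict(
    n_cell_types=10,
    n_bins=50_000,
    lam_bg=0.5,
    lam_hi=8.0,
    n_regions=50,
    region_len_bins=10,
    subset_size_range=(3, 7),
    n_zero_runs=4,
    zero_run_len_bins=30,
    bin_size=200,
    n_chroms=2,
)


@dataclass(frozen=True)
class PlantedRegion:
    """A planted enriched region: global bin interval + active cell subset."""

    chrom: str
    start_bin: int  # global bin index, inclusive
    end_bin: int    # global bin index, exclusive
    active_cells: tuple[int, ...]

    def bp(self, bins: GenomeBins) -> tuple[str, int, int]:
        chrom, s, _ = bins.bin_location(self.start_bin)
        return chrom, s, s + (self.end_bin - self.start_bin) * bins.bin_size


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    bins: GenomeBins
    cell_types: list[str]
    planted_regions: list[PlantedRegion]
    unmappable_runs: list[tuple[str, int, int]]  # (chrom, start_bin, end_bin) global
    dynamic_genes: dict[str, int] = field(default_factory=dict)  # gene_id -> region index
    background_genes: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "chrom_names": list(self.bins.chrom_names),
            "chrom_n_bins": list(self.bins.chrom_n_bins),
            "bin_size": self.bins.bin_size,
            "cell_types": self.cell_types,
            "planted_regions": [asdict(r) for r in self.planted_regions],
            "unmappable_runs": [list(r) for r in self.unmappable_runs],
            "dynamic_genes": self.dynamic_genes,
            "background_genes": self.background_genes,
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _place_intervals(
    rng: np.random.Generator,
    bins: GenomeBins,
    lengths: list[int],
    min_gap_bins: int = 2,
) -> list[tuple[int, int]]:
    """Place non-overlapping global bin intervals that never cross a
    chromosome boundary and keep ``min_gap_bins`` clear bins between any two."""
    placed: list[tuple[int, int]] = []
    offsets = bins.chrom_offsets
    for L in lengths:
        for _ in range(10_000):
            start = int(rng.integers(0, bins.n_bins - L + 1))
            ci = int(bins.chrom_of(start))
            if start + L > offsets[ci + 1]:
                continue
            if any(start < e + min_gap_bins and s - min_gap_bins < start + L for s, e in placed):
                continue
            placed.append((start, start + L))
            break
        else:
            raise RuntimeError("could not place intervals; genome too crowded")
    return placed


def generate_epigenome(
    n_cell_types: int = DEFAULTS["n_cell_types"],
    n_bins: int = DEFAULTS["n_bins"],
    lam_bg: float = DEFAULTS["lam_bg"],
    lam_hi: float = DEFAULTS["lam_hi"],
    n_regions: int = DEFAULTS["n_regions"],
    region_len_bins: int = DEFAULTS["region_len_bins"],
    subset_size_range: tuple[int, int] = DEFAULTS["subset_size_range"],
    n_zero_runs: int = DEFAULTS["n_zero_runs"],
    zero_run_len_bins: int = DEFAULTS["zero_run_len_bins"],
    bin_size: int = DEFAULTS["bin_size"],
    n_chroms: int = DEFAULTS["n_chroms"],
    mark: str = "markA",
    seed: int = 0,
) -> tuple[list[BinnedCountTrack], SyntheticTruth]:
    """Simulate one mark's count tracks across cell types plus ground truth.

    Background counts are iid Poisson(lam_bg); inside each planted region a
    uniformly drawn subset of cell types (size within ``subset_size_range``)
    draws Poisson(lam_hi); planted all-zero runs emulate unmappable
    sequence.  Fully deterministic given ``seed``.
    """
    if not (lam_hi >= lam_bg >= 0):
        raise ValueError("need lam_hi >= lam_bg >= 0")
    lo, hi = subset_size_range
    if not (1 <= lo <= hi < n_cell_types):
        raise ValueError("subset sizes must lie in [1, n_cell_types)")
    if n_regions * region_len_bins > n_bins // 10:
        raise ValueError("planted regions must occupy well under the whole genome")

    per = n_bins // n_chroms
    chrom_n = [per] * (n_chroms - 1) + [n_bins - per * (n_chroms - 1)]
    bins = GenomeBins(
        chrom_names=tuple(f"chr{i + 1}" for i in range(n_chroms)),
        chrom_n_bins=tuple(chrom_n),
        bin_size=bin_size,
    )
    rng = np.random.default_rng(seed)

    intervals = _place_intervals(
        rng, bins, [region_len_bins] * n_regions + [zero_run_len_bins] * n_zero_runs
    )
    region_iv, zero_iv = intervals[:n_regions], intervals[n_regions:]

    counts = rng.poisson(lam_bg, size=(n_cell_types, n_bins))
    regions: list[PlantedRegion] = []
    for s, e in region_iv:
        k = int(rng.integers(lo, hi + 1))
        subset = tuple(sorted(int(c) for c in rng.choice(n_cell_types, size=k, replace=False)))
        counts[np.ix_(list(subset), range(s, e))] = rng.poisson(lam_hi, size=(k, e - s))
        chrom = bins.chrom_names[int(bins.chrom_of(s))]
        regions.append(PlantedRegion(chrom=chrom, start_bin=s, end_bin=e, active_cells=subset))
    for s, e in zero_iv:
        counts[:, s:e] = 0

    cell_types = [f"cell{i + 1:02d}" for i in range(n_cell_types)]
    tracks = [
        BinnedCountTrack(mark=mark, cell_type=ct, bins=bins, counts=counts[i])
        for i, ct in enumerate(cell_types)
    ]
    truth = SyntheticTruth(
        bins=bins,
        cell_types=cell_types,
        planted_regions=regions,
        unmappable_runs=[
            (bins.chrom_names[int(bins.chrom_of(s))], s, e) for s, e in zero_iv
        ],
        parameters=dict(
            n_cell_types=n_cell_types, n_bins=n_bins, lam_bg=lam_bg, lam_hi=lam_hi,
            n_regions=n_regions, region_len_bins=region_len_bins,
            subset_size_range=list(subset_size_range), n_zero_runs=n_zero_runs,
            zero_run_len_bins=zero_run_len_bins, bin_size=bin_size,
            n_chroms=n_chroms, seed=seed,
        ),
    )
    return tracks, truth


def generate_annotation(
    truth: SyntheticTruth,
    promoter_flank: int = 2000,
    body_fraction: float = 0.5,
    gene_margin_bp: int = 4000,
    n_background_genes: int | None = None,
    background_gene_len_bp: int = 3000,
    tight: bool = False,
) -> list[GeneModel]:
    """Lay one gene over each planted region, plus background genes.

    Placement alternates deterministically: a ``body_fraction`` share of the
    coupled genes spans the region with the TSS well outside the promoter
    window (region center in the gene body / CDS); the rest put the TSS at
    the region center so the region sits in the promoter.  With ``tight``
    the gene span equals the region footprint exactly and no background
    genes are emitted.  Updates ``truth.dynamic_genes`` in place.
    """
    bins = truth.bins
    genes: list[GeneModel] = []
    truth.dynamic_genes.clear()
    truth.background_genes = []
    n = len(truth.planted_regions)
    n_body = int(round(body_fraction * n)) if not tight else 0
    for i, reg in enumerate(truth.planted_regions):
        chrom, s_bp, e_bp = reg.bp(bins)
        gid = f"geneR{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        if tight:
            start, end = s_bp, e_bp
            exons = ((start, end),)
            cds = ()
        elif i < n_body:
            # gene body placement: TSS gene_margin_bp upstream of the region
            if strand == "+":
                start, end = s_bp - gene_margin_bp, e_bp + gene_margin_bp // 2
            else:
                start, end = s_bp - gene_margin_bp // 2, e_bp + gene_margin_bp
            exons = ((start, end),)
            cds = ((s_bp - 200, e_bp + 200),)
        else:
            # promoter placement: TSS at the region center
            center = (s_bp + e_bp) // 2
            if strand == "+":
                start, end = center, center + gene_margin_bp
            else:
                start, end = center - gene_margin_bp, center + 1
            exons = ((start, end),)
            cds = ()
        start = max(start, 0)
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end,
                      exons=((start, end),), cds=tuple(
                          (max(cs, start), min(ce, end)) for cs, ce in cds))
        )
        truth.dynamic_genes[gid] = i
    if not tight:
        if n_background_genes is None:
            n_background_genes = n
        occupied = sorted(
            [(r.start_bin, r.end_bin) for r in truth.planted_regions]
            + [(s, e) for _, s, e in truth.unmappable_runs]
        )
        gene_len_bins = max(1, background_gene_len_bp // bins.bin_size)
        placed = 0
        cursor = 0
        spacing = max(gene_len_bins * 4, bins.n_bins // max(n_background_genes * 2, 1))
        while placed < n_background_genes and cursor + gene_len_bins < bins.n_bins:
            s, e = cursor, cursor + gene_len_bins
            ci = int(bins.chrom_of(s))
            if s + gene_len_bins <= bins.chrom_offsets[ci + 1] and not any(
                s < oe + 10 and os_ - 10 < e for os_, oe in occupied
            ):
                chrom, s_bp, _ = bins.bin_location(s)
                e_bp = s_bp + gene_len_bins * bins.bin_size
                gid = f"geneB{placed + 1:04d}"
                genes.append(
                    GeneModel(gene_id=gid, chrom=chrom, strand="+" if placed % 2 == 0 else "-",
                              start=s_bp, end=e_bp, exons=((s_bp, e_bp),))
                )
                truth.background_genes.append(gid)
                placed += 1
            cursor += spacing
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def generate_expression(
    truth: SyntheticTruth,
    base: float = 10.0,
    beta: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression coupled to the planted modification patterns.

    A dynamic gene coupled to region r has expression
    ``base * (1 + beta * 1[cell in active subset]) * exp(eps)`` with
    ``eps ~ Normal(0, noise_sd^2)``; background genes lack the subset term.
    Deterministic given ``seed``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if not truth.dynamic_genes and not truth.background_genes:
        raise ValueError("truth carries no genes; run generate_annotation first")
    rng = np.random.default_rng(seed)
    M = len(truth.cell_types)
    gene_ids = list(truth.dynamic_genes) + list(truth.background_genes)
    values = np.empty((len(gene_ids), M))
    for gi, gid in enumerate(gene_ids):
        eps = rng.normal(0.0, noise_sd, size=M)
        mean = np.full(M, base)
        if gid in truth.dynamic_genes:
            reg = truth.planted_regions[truth.dynamic_genes[gid]]
            mean = base * (1.0 + beta * np.isin(np.arange(M), reg.active_cells))
        values[gi] = mean * np.exp(eps)
    return ExpressionMatrix(gene_ids=gene_ids, cell_types=list(truth.cell_types), values=values)


def recovery_stats(regions, truth: SyntheticTruth) -> dict:
    """Region-level recovery of called regions against the planted truth.

    A truth region is recovered when at least one called region overlaps it
    by >= 1 bp; a called region is a true positive when it overlaps any
    truth region.  Returns recall, precision (NaN when nothing was called),
    and the raw counts, plus the indices of recovered truth regions.
    """
    bins = truth.bins
    truth_iv = [r.bp(bins) for r in truth.planted_regions]
    recovered = set()
    tp = 0
    for reg in regions:
        hit = False
        for i, (chrom, s, e) in enumerate(truth_iv):
            if reg.chrom == chrom and reg.start < e and reg.end > s:
                recovered.add(i)
                hit = True
        tp += hit
    n_called = len(regions)
    n_truth = len(truth_iv)
    return dict(
        recall=len(recovered) / n_truth if n_truth else float("nan"),
        precision=tp / n_called if n_called else float("nan"),
        n_called=n_called,
        n_truth=n_truth,
        n_recovered=len(recovered),
        recovered_indices=sorted(recovered),
    )


def simulate_dataset(
    seed: int = 0,
    beta: float = 2.0,
    noise_sd: float = 0.3,
    base_expression: float = 10.0,
    promoter_flank: int = 2000,
    body_fraction: float = 0.5,
    tight_genes: bool = False,
    n_background_genes: int | None = None,
    **epigenome_kwargs,
):
    """One-call simulation: tracks, truth, gene models and expression.

    Derives independent child seeds for the count and expression draws so
    one integer reproduces the whole dataset.
    """
    ss = np.random.SeedSequence(seed)
    s_counts, s_expr = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    tracks, truth = generate_epigenome(seed=s_counts, **epigenome_kwargs)
    genes = generate_annotation(
        truth, promoter_flank=promoter_flank, body_fraction=body_fraction,
        tight=tight_genes, n_background_genes=n_background_genes,
    )
    expr = generate_expression(truth, base=base_expression, beta=beta, noise_sd=noise_sd, seed=s_expr)
    return tracks, truth, genes, expr
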