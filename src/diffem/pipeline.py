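"""End-to-end pipeline: binarize -> score -> call -> annotate -> correlate
-> benchmark, per cell-type group, driven by one validated configuration.

Groups are named subsets of the declared cell types (e.g. precursor cell
types vs primary tissues vs all).  Every group is analyzed independently:
thresholds, backgrounds and p-values are recomputed on the group's
submatrix, so a group's results equal a full run on a dataset containing
only that group's tracks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import diffem

from .annotate import (
    DEFAULT_PROMOTER_FLANK,
    InsufficientPairsError,
    annotate_regions,
    correlate_dynamics,
    expression_dynamics,
)
from .benchmark import compare_methods
from .binarize import DEFAULT_MAX_ZERO_RUN_BP, binarize_profile
from .hdms import DEFAULT_ALPHA, NoSignalError, call_hdms, empirical_pvalues, rank_regions
from .benchmark import METHODS, score_with_method
from .signal_io import (
    BinnedCountTrack,
    ExpressionMatrix,
    GeneModel,
    write_regions_bed,
    write_score_track,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration.

    ``groups`` maps group names to cell-type subsets (each of size >= 2);
    an empty mapping means one group "all" containing every cell type.
    """

    cell_types: list[str]
    groups: dict[str, list[str]] = field(default_factory=dict)
    methods: tuple[str, ...] = METHODS
    bin_size: int = 200
    max_zero_run_bp: int = DEFAULT_MAX_ZERO_RUN_BP
    alpha: float = DEFAULT_ALPHA
    promoter_flank: int = DEFAULT_PROMOTER_FLANK
    region_stat: str = "max"
    top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.groups:
            self.groups = {"all": list(self.cell_types)}
        declared = set(self.cell_types)
        for name, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(f"group {name!r} must have at least two cell types")
            unknown = set(members) - declared
            if unknown:
                raise ValueError(f"group {name!r} references undeclared cell types {sorted(unknown)}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: d[k] for k in (
            "cell_types", "groups", "methods", "bin_size", "max_zero_run_bp",
            "alpha", "promoter_flank", "region_stat", "top_k", "seed",
        ) if k in d}
        if "methods" in known:
            known["methods"] = tuple(known["methods"])
        return cls(**known)

    def to_dict(self) -> dict:
        return {
            "cell_types": list(self.cell_types),
            "groups": {k: list(v) for k, v in self.groups.items()},
            "methods": list(self.methods),
            "bin_size": self.bin_size,
            "max_zero_run_bp": self.max_zero_run_bp,
            "alpha": self.alpha,
            "promoter_flank": self.promoter_flank,
            "region_stat": self.region_stat,
            "top_k": self.top_k,
            "seed": self.seed,
        }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    tracks_by_mark: dict[str, list[BinnedCountTrack]],
    genes: list[GeneModel],
    expr: ExpressionMatrix,
    out_dir: str | os.PathLike,
) -> Path:
    """Run every stage for every (group, mark, method) and write artifacts.

    Per combination: score TSV, HDMS BED, annotation TSV; per group:
    per-class correlation report and the method-comparison table; plus a
    JSON manifest recording the config hash, seed and library versions.
    Outputs are deterministic: identical config + inputs give identical
    bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for group, members in config.groups.items():
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        try:
            expr_g = expr.subset_cells(members)
        except ValueError as exc:
            raise PipelineError(f"[expression] group {group!r}: {exc}") from exc
        expr_dyn = expression_dynamics(expr_g)
        expr_dyn.to_csv(gdir / "expression_dynamics.tsv", sep="\t")
        corr_rows, bench_frames = [], []
        for mark, tracks in sorted(tracks_by_mark.items()):
            by_cell = {t.cell_type: t for t in tracks}
            missing = [c for c in members if c not in by_cell]
            if missing:
                raise PipelineError(f"[tracks] group {group!r} mark {mark}: missing {missing}")
            sub = [by_cell[c] for c in members]
            try:
                profile = binarize_profile(sub, max_zero_run_bp=config.max_zero_run_bp)
            except ValueError as exc:
                raise PipelineError(f"[binarize] {group}/{mark}: {exc}") from exc
            for method in config.methods:
                track = score_with_method(method, sub, profile=profile)
                write_score_track(track, gdir / f"{mark}.{method}.scores.tsv")
                try:
                    pv = empirical_pvalues(track)
                except NoSignalError:
                    logger.warning("%s/%s/%s: no nonzero scores; empty call set", group, mark, method)
                    regions = []
                else:
                    regions = rank_regions(
                        call_hdms(track, alpha=config.alpha, pvalues=pv), top_k=config.top_k
                    )
                write_regions_bed(regions, gdir / f"{mark}.{method}.hdms.bed")
                annotated = annotate_regions(regions, genes, promoter_flank=config.promoter_flank)
                pd.DataFrame(
                    [
                        dict(region_id=a.region.region_id, chrom=a.region.chrom,
                             start=a.region.start, end=a.region.end,
                             score=a.region.score, rank_score=a.region.rank_score,
                             pvalue=a.region.pvalue, gene_id=a.gene_id or ".",
                             feature_class=a.feature_class)
                        for a in annotated
                    ],
                    columns=["region_id", "chrom", "start", "end", "score", "rank_score",
                             "pvalue", "gene_id", "feature_class"],
                ).to_csv(gdir / f"{mark}.{method}.annotated.tsv", sep="\t", index=False)
                for fc in ("promoter", "coding", "exon", "intron"):
                    try:
                        r = correlate_dynamics(annotated, expr_dyn, fc, region_stat=config.region_stat)
                        n_pairs = sum(
                            1 for a in annotated
                            if a.feature_class == fc and a.gene_id in expr_dyn.index
                        )
                    except InsufficientPairsError:
                        r, n_pairs = np.nan, 0
                    corr_rows.append(dict(mark=mark, method=method, feature_class=fc,
                                          pearson_r=r, n_pairs=n_pairs))
            report, _ = compare_methods(
                sub, expr_g, genes, methods=config.methods, alpha=config.alpha,
                promoter_flank=config.promoter_flank,
                max_zero_run_bp=config.max_zero_run_bp, top_k=config.top_k,
            )
            bench_frames.append(report)
        pd.DataFrame(corr_rows).to_csv(gdir / "correlation_report.tsv", sep="\t", index=False)
        pd.concat(bench_frames, ignore_index=True).to_csv(
            gdir / "comparison_report.tsv", sep="\t", index=False
        )
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "diffem": diffem.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "groups": sorted(config.groups),
        "marks": sorted(tracks_by_mark),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
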