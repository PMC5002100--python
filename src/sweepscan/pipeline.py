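"""Pipeline orchestration: every ordered line comparison, both scans,
per-line merging, method intersection, cross-line consensus, ZHp tables,
haplotype profiles and gene annotation, with a reproducible manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import consensus as cons
from . import xp_clr, xp_ehh, zhp
from .haplotypes import annotate_regions, region_haplotypes
from .io_qc import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, echoed into output headers."""

    # QC (applied upstream of run_all; kept here so the echo is complete)
    call_rate_min: float = 0.90
    mendel_max: float = 0.001
    excluded_chroms: tuple[str, ...] = ()
    # XP-EHH
    xpehh_p_cutoff: float = 0.05
    xpehh_gap_bp: int = 200_000
    ehh_floor: float = 0.05
    two_sided: bool = False
    # XP-CLR-style
    grid_spacing: int = 2_000
    window_cm: float = 0.5
    r_cutoff: float = 0.9
    top_fraction: float = 0.005
    cluster_gap_cm: float = 1.0
    eps: float = 0.02
    # ZHp
    zhp_window: int = 5
    zhp_step: int = 1
    # consensus / annotation
    min_lines: int = 2
    flank: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("call_rate_min", self.call_rate_min, 0, 1),
            ("xpehh_p_cutoff", self.xpehh_p_cutoff, 0, 1),
            ("ehh_floor", self.ehh_floor, 0, 1),
            ("r_cutoff", self.r_cutoff, 0, 1),
            ("top_fraction", self.top_fraction, 0, 1),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo},{hi}]")
        if self.min_lines < 2:
            raise ValueError("min_lines must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    xpehh_tracks: dict[tuple[str, str], pd.DataFrame]
    xpclr_tracks: dict[tuple[str, str], pd.DataFrame]
    xpehh_regions_by_line: dict[str, pd.DataFrame]
    xpclr_regions_by_line: dict[str, pd.DataFrame]
    candidates_by_line: dict[str, pd.DataFrame]
    consensus_regions: pd.DataFrame
    zhp_table: pd.DataFrame
    haplotype_tables: pd.DataFrame
    annotation: pd.DataFrame | None
    coverage_by_line: dict[str, float]
    consensus_coverage: float
    manifest: dict = field(default_factory=dict)


def _write_with_header(frame: pd.DataFrame, path: str, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_all(
    ds: GenotypeDataset,
    config: PipelineConfig | None = None,
    genes: pd.DataFrame | None = None,
    chrom_lengths: dict[str, int] | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Run the full cross-population analysis on a phased, complete dataset.

    Every ordered pair of lines is compared with both scans (K lines give
    K*(K-1) comparisons); per line the four comparison region lists are
    unioned per method, the methods intersected into candidates, and
    candidates shared by >= min_lines lines trimmed to their common overlap.
    """
    config = config or PipelineConfig()
    if not ds.phased:
        raise ValueError("run_all requires a phased, complete dataset")
    if "cM" not in ds.markers.columns:
        raise ValueError("markers need cM positions: interpolate a genetic map first")
    lines = ds.lines()
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(v) for c, v in ds.markers.groupby("chrom", sort=False)["bp"].max().items()
        }
    markers = ds.markers.reset_index(drop=True)
    haps = {line: ds.haplotypes(line) for line in lines}
    t0 = time.time()

    xpehh_tracks: dict[tuple[str, str], pd.DataFrame] = {}
    xpclr_tracks: dict[tuple[str, str], pd.DataFrame] = {}
    ehh_regions: dict[tuple[str, str], pd.DataFrame] = {}
    clr_regions: dict[tuple[str, str], pd.DataFrame] = {}
    for a in lines:
        for b in lines:
            if a == b:
                continue
            label = f"{a}_vs_{b}"
            try:
                track = xp_ehh.xpehh_scan(
                    haps[a], haps[b], markers, ehh_floor=config.ehh_floor,
                    two_sided=config.two_sided, comparison=label,
                )
            except ValueError as exc:
                raise RuntimeError(f"stage xp_ehh failed for {label}: {exc}") from exc
            xpehh_tracks[(a, b)] = track
            sig = track[track["pvalue"] < config.xpehh_p_cutoff]
            reg = xp_ehh.cluster_snps_to_regions(sig, max_gap=config.xpehh_gap_bp)
            reg["comparison"] = label
            ehh_regions[(a, b)] = reg

            ctrack = xp_clr.xpclr_scan(
                haps[a], haps[b], markers, chrom_lengths=chrom_lengths,
                grid_spacing=config.grid_spacing, window_cm=config.window_cm,
                r_cutoff=config.r_cutoff, eps=config.eps, comparison=label,
            )
            xpclr_tracks[(a, b)] = ctrack
            creg = xp_clr.call_xpclr_regions(
                ctrack, top_fraction=config.top_fraction, cluster_gap_cm=config.cluster_gap_cm
            )
            creg["comparison"] = label
            clr_regions[(a, b)] = creg
            logger.info("comparison %s done (%.1fs)", label, time.time() - t0)

    xpehh_by_line = {
        line: cons.merge_comparisons(
            [ehh_regions[(line, b)] for b in lines if b != line], line, "xpehh"
        )
        for line in lines
    }
    xpclr_by_line = {
        line: cons.merge_comparisons(
            [clr_regions[(line, b)] for b in lines if b != line], line, "xpclr"
        )
        for line in lines
    }
    candidates = {
        line: cons.intersect_methods(xpehh_by_line[line], xpclr_by_line[line], line)
        for line in lines
    }
    consensus_regions = cons.cross_line_consensus(candidates, min_lines=config.min_lines)

    zhp_table = zhp.zhp_scan(ds, config.zhp_window, config.zhp_step, set(config.excluded_chroms))

    hap_frames = []
    for row in consensus_regions.itertuples(index=False):
        table = region_haplotypes((str(row.chrom), int(row.start), int(row.end)), ds)
        if table.tables:
            hap_frames.append(table.to_frame())
    haplotype_tables = (
        pd.concat(hap_frames, ignore_index=True)
        if hap_frames
        else pd.DataFrame(columns=["region", "line", "haplotype", "freq", "is_major"])
    )

    annotation = None
    if genes is not None and len(consensus_regions):
        annotation = annotate_regions(consensus_regions, genes, flank=config.flank)

    coverage_by_line = {
        line: cons.genome_coverage(candidates[line], chrom_lengths) if len(candidates[line]) else 0.0
        for line in lines
    }
    consensus_coverage = (
        cons.genome_coverage(consensus_regions, chrom_lengths) if len(consensus_regions) else 0.0
    )

    chash = config.config_hash()
    content = hashlib.sha256()
    for line in lines:
        content.update(candidates[line].to_csv(index=False).encode())
    content.update(consensus_regions.to_csv(index=False).encode())
    manifest = {
        "config_hash": chash,
        "result_hash": content.hexdigest()[:16],
        "n_lines": len(lines),
        "n_comparisons": len(xpehh_tracks),
        "n_snps": ds.n_snps,
        "n_samples": ds.n_samples,
        "counts": {
            "xpehh_regions": int(sum(len(f) for f in xpehh_by_line.values())),
            "xpclr_regions": int(sum(len(f) for f in xpclr_by_line.values())),
            "candidates": int(sum(len(f) for f in candidates.values())),
            "consensus_regions": int(len(consensus_regions)),
            "zhp_windows": int(len(zhp_table)),
        },
        "coverage_by_line": coverage_by_line,
        "consensus_coverage": consensus_coverage,
        "elapsed_s": round(time.time() - t0, 2),
    }

    result = PipelineResult(
        config=config,
        xpehh_tracks=xpehh_tracks,
        xpclr_tracks=xpclr_tracks,
        xpehh_regions_by_line=xpehh_by_line,
        xpclr_regions_by_line=xpclr_by_line,
        candidates_by_line=candidates,
        consensus_regions=consensus_regions,
        zhp_table=zhp_table,
        haplotype_tables=haplotype_tables,
        annotation=annotation,
        coverage_by_line=coverage_by_line,
        consensus_coverage=consensus_coverage,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    chash = result.manifest["config_hash"]
    hdr = [f"config_hash={chash}"]
    clr_hdr = hdr + [f"method={xp_clr.METHOD_LABEL}"]
    for (a, b), track in result.xpehh_tracks.items():
        _write_with_header(track, os.path.join(outdir, f"xpehh_{a}_vs_{b}.tsv"), hdr)
    for (a, b), track in result.xpclr_tracks.items():
        _write_with_header(track, os.path.join(outdir, f"xpclr_{a}_vs_{b}.tsv"), clr_hdr)
    for line, frame in result.candidates_by_line.items():
        _write_with_header(frame, os.path.join(outdir, f"candidates_{line}.tsv"), hdr)
        cons.regions_to_bed(frame[["chrom", "start", "end"]]).to_csv(
            os.path.join(outdir, f"candidates_{line}.bed"), sep="\t", header=False, index=False
        ) if len(frame) else open(os.path.join(outdir, f"candidates_{line}.bed"), "w").close()
    _write_with_header(result.consensus_regions, os.path.join(outdir, "consensus.tsv"), hdr)
    if len(result.consensus_regions):
        cons.regions_to_bed(result.consensus_regions[["chrom", "start", "end"]]).to_csv(
            os.path.join(outdir, "consensus.bed"), sep="\t", header=False, index=False
        )
    _write_with_header(result.zhp_table, os.path.join(outdir, "zhp.tsv"), hdr)
    _write_with_header(result.haplotype_tables, os.path.join(outdir, "haplotypes.tsv"), hdr)
    if result.annotation is not None:
        _write_with_header(result.annotation, os.path.join(outdir, "annotation.tsv"), hdr)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)
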