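"""Genetic-map interpolation.

SNP-array markers come with physical (bp) positions; the haplotype- and
likelihood-based scans need genetic (cM) positions.  Given a set of anchor
markers with known cM positions on a linkage map, every other marker is
assigned a cM position by linear interpolation between the flanking anchors,
i.e. assuming recombination is uniformly distributed within each anchor
interval.  Markers outside the anchored span are extrapolated with the
terminal interval's local cM/bp rate and floored at 0 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnchorSet", "interpolate_map", "read_anchor_tsv", "read_marker_tsv", "write_marker_tsv"]

#: required columns of a marker map frame
MAP_COLUMNS = ["chrom", "id", "bp", "cM"]


@dataclass
class AnchorSet:
    """Per-chromosome sorted (bp, cM) anchor pairs.

    Each chromosome needs at least two anchors with cM non-decreasing in bp;
    equal-cM plateaus (recombination deserts) are allowed.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, chrom: str, bp: np.ndarray, cm: np.ndarray) -> None:
        bp = np.asarray(bp, dtype=np.int64)
        cm = np.asarray(cm, dtype=np.float64)
        order = np.argsort(bp, kind="stable")
        bp, cm = bp[order], cm[order]
        if bp.size < 2:
            raise ValueError(f"chromosome {chrom}: need >=2 anchors, got {bp.size}")
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"chromosome {chrom}: duplicate anchor bp positions")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"chromosome {chrom}: anchor cM must be non-decreasing in bp")
        self.anchors[chrom] = (bp, cm)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnchorSet":
        """Build from a frame with columns chrom, bp, cM."""
        out = cls()
        for chrom, grp in frame.groupby("chrom", sort=False):
            out.add(str(chrom), grp["bp"].to_numpy(), grp["cM"].to_numpy())
        return out

    def chroms(self) -> list[str]:
        return list(self.anchors)


def _interp_chrom(bp_anchor: np.ndarray, cm_anchor: np.ndarray, bp: np.ndarray) -> np.ndarray:
    cm = np.interp(bp, bp_anchor, cm_anchor)
    # np.interp clamps outside the anchored span; extrapolate with the
    # terminal interval's local rate instead, then floor at 0 cM.
    left = bp < bp_anchor[0]
    if np.any(left):
        rate = (cm_anchor[1] - cm_anchor[0]) / (bp_anchor[1] - bp_anchor[0])
        cm[left] = cm_anchor[0] - (bp_anchor[0] - bp[left]) * rate
    right = bp > bp_anchor[-1]
    if np.any(right):
        rate = (cm_anchor[-1] - cm_anchor[-2]) / (bp_anchor[-1] - bp_anchor[-2])
        cm[right] = cm_anchor[-1] + (bp[right] - bp_anchor[-1]) * rate
    return np.maximum(cm, 0.0)


def interpolate_map(anchors: AnchorSet, markers: pd.DataFrame) -> pd.DataFrame:
    """Assign a cM position to every marker.

    Parameters
    ----------
    anchors
        Anchor positions per chromosome.
    markers
        Frame with at least columns ``chrom`` and ``bp`` (an ``id`` column is
        carried through; one is synthesized if absent).

    Returns
    -------
    A marker-map frame with columns ``chrom, id, bp, cM``, in the input row
    order.  Within each chromosome the result is monotone non-decreasing in
    bp and exact at anchor positions.
    """
    missing = sorted(set(markers["chrom"].astype(str)) - set(anchors.anchors))
    if missing:
        raise ValueError(f"no anchors for chromosome(s): {', '.join(missing)}")
    out = markers.copy()
    if "id" not in out.columns:
        out["id"] = [f"snp_{c}_{p}" for c, p in zip(out["chrom"], out["bp"])]
    cm = np.empty(len(out), dtype=np.float64)
    for chrom, grp in out.groupby("chrom", sort=False):
        bp_a, cm_a = anchors.anchors[str(chrom)]
        cm[out.index.get_indexer(grp.index)] = _interp_chrom(bp_a, cm_a, grp["bp"].to_numpy(np.float64))
    out = out.reset_index(drop=True)
    out["cM"] = cm
    return out[MAP_COLUMNS]


def read_anchor_tsv(path: str) -> AnchorSet:
    frame = pd.read_csv(path, sep="\t", header=None, names=["chrom", "bp", "cM"], dtype={"chrom": str})
    return AnchorSet.from_frame(frame)


def read_marker_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=MAP_COLUMNS, dtype={"chrom": str})


def write_marker_tsv(markers: pd.DataFrame, path: str) -> None:
    markers[MAP_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
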