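"""Region calculus: per-line merging, method intersection, cross-line consensus.

Intervals are 1-based inclusive bp internally (BED export converts to
0-based half-open).  The consensus logic mirrors a two-stage design:

1. per line, each scan method's regions from the comparisons against every
   other line are unioned (``merge_comparisons``), and a line's *candidate*
   regions are the XP-CLR-style regions that overlap at least one XP-EHH
   region (``intersect_methods``) — XP-CLR spans being the narrower, they
   define the candidate span;
2. candidates shared by two or more lines become high-confidence consensus
   regions, trimmed to the common overlap (``cross_line_consensus``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "merge_comparisons",
    "intersect_methods",
    "cross_line_consensus",
    "genome_coverage",
    "regions_to_bed",
]

REGION_COLS = ["chrom", "start", "end"]


def _check_regions(frame: pd.DataFrame) -> pd.DataFrame:
    if len(frame) and (frame["start"] > frame["end"]).any():
        raise ValueError("region with start > end")
    return frame


def merge_comparisons(per_comparison: list[pd.DataFrame], line: str, method: str) -> pd.DataFrame:
    """Union a line's regions across its comparisons.

    Overlapping or adjacent (gap <= 1 bp) intervals coalesce; the source
    comparisons of each merged interval are recorded in ``comparisons``.
    Input frames need ``chrom start end`` and may carry a ``comparison``
    column for provenance.
    """
    frames = [f for f in per_comparison if len(f)]
    if not frames:
        return pd.DataFrame(columns=REGION_COLS + ["line", "method", "comparisons"])
    allr = pd.concat(frames, ignore_index=True)
    _check_regions(allr)
    if "comparison" not in allr.columns:
        allr["comparison"] = ""
    records = []
    for chrom, grp in allr.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"])
        cur_s, cur_e, sources = None, None, set()
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, sources = row.start, row.end, {row.comparison}
            elif row.start <= cur_e + 1:  # overlap or adjacency
                cur_e = max(cur_e, row.end)
                sources.add(row.comparison)
            else:
                records.append((chrom, cur_s, cur_e, sorted(sources)))
                cur_s, cur_e, sources = row.start, row.end, {row.comparison}
        if cur_s is not None:
            records.append((chrom, cur_s, cur_e, sorted(sources)))
    out = pd.DataFrame(records, columns=["chrom", "start", "end", "comparisons"])
    out["comparisons"] = out["comparisons"].map(lambda s: ",".join(x for x in s if x))
    out["line"] = line
    out["method"] = method
    return out[REGION_COLS + ["line", "method", "comparisons"]]


def intersect_methods(xpehh_regions: pd.DataFrame, xpclr_regions: pd.DataFrame, line: str) -> pd.DataFrame:
    """Keep each XP-CLR-style region overlapping (>=1 bp) an XP-EHH region.

    Output spans are the XP-CLR spans; a wide XP-EHH region may support
    several XP-CLR regions (multiplicity allowed).  Overlapping XP-EHH
    partner spans are recorded per kept region.
    """
    cols = REGION_COLS + ["line", "xpehh_partners"]
    if len(xpclr_regions) == 0 or len(xpehh_regions) == 0:
        return pd.DataFrame(columns=cols)
    _check_regions(xpehh_regions)
    _check_regions(xpclr_regions)
    records = []
    by_chrom = {c: g for c, g in xpehh_regions.groupby("chrom", sort=False)}
    for row in xpclr_regions.itertuples(index=False):
        ehh = by_chrom.get(row.chrom)
        if ehh is None:
            continue
        hit = ehh[(ehh["start"] <= row.end) & (ehh["end"] >= row.start)]
        if len(hit):
            partners = ";".join(f"{s}-{e}" for s, e in zip(hit["start"], hit["end"]))
            records.append((row.chrom, row.start, row.end, line, partners))
    return pd.DataFrame(records, columns=cols)


def cross_line_consensus(per_line: dict[str, pd.DataFrame], min_lines: int = 2) -> pd.DataFrame:
    """High-confidence regions supported by >= ``min_lines`` lines.

    A sweep over interval breakpoints finds every maximal genomic segment
    covered by the same set of >= min_lines lines; adjacent segments with an
    identical supporting set are merged.  The emitted interval is the common
    overlap, contained in every supporter's own candidate region; untrimmed
    per-line spans are retained in ``provenance``.
    """
    cols = ["chrom", "start", "end", "lines", "n_lines", "provenance"]
    events: dict[str, list[tuple[int, int, str, int, int]]] = {}
    for line, frame in per_line.items():
        if frame is None or len(frame) == 0:
            continue
        _check_regions(frame)
        for row in frame.itertuples(index=False):
            events.setdefault(str(row.chrom), []).append((int(row.start), int(row.end), line, int(row.start), int(row.end)))
    records = []
    for chrom, regs in sorted(events.items()):
        # breakpoints in half-open coordinates [start, end+1)
        points = sorted({s for s, *_ in regs} | {e + 1 for _, e, *_ in regs})
        prev_set: frozenset | None = None
        seg_start = None
        prev_end = None
        for i in range(len(points) - 1):
            lo, hi = points[i], points[i + 1] - 1  # inclusive segment
            covering = frozenset(line for s, e, line, *_ in regs if s <= lo and e >= hi)
            active = covering if len(covering) >= min_lines else None
            if active is not None and active == prev_set and seg_start is not None and lo == prev_end + 1:
                prev_end = hi
            else:
                if prev_set is not None and seg_start is not None:
                    records.append((chrom, seg_start, prev_end, prev_set))
                if active is not None:
                    seg_start, prev_end = lo, hi
                    prev_set = active
                else:
                    seg_start, prev_end, prev_set = None, None, None
        if prev_set is not None and seg_start is not None:
            records.append((chrom, seg_start, prev_end, prev_set))
    rows = []
    for chrom, start, end, lines in records:
        prov = []
        for s, e, line, os_, oe in events[chrom]:
            if line in lines and s <= end and e >= start:
                prov.append(f"{line}:{os_}-{oe}")
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "lines": ",".join(sorted(lines)),
                "n_lines": len(lines),
                "provenance": ";".join(sorted(prov)),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def genome_coverage(regions: pd.DataFrame, chrom_lengths: dict[str, int]) -> float:
    """Fraction of the analyzed genome covered by the (unioned) regions."""
    total = sum(int(v) for v in chrom_lengths.values())
    if total <= 0:
        raise ValueError("empty chromosome-length table")
    if len(regions) == 0:
        return 0.0
    covered = 0
    for chrom, grp in regions.groupby("chrom", sort=False):
        if str(chrom) not in {str(k) for k in chrom_lengths}:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
        length = int(chrom_lengths[str(chrom)])
        if (grp["end"] > length).any():
            raise ValueError(f"region beyond end of chromosome {chrom}")
        cur_s = cur_e = None
        for row in grp.sort_values(["start", "end"]).itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            covered += cur_e - cur_s + 1
    return covered / total


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive regions to BED (0-based half-open)."""
    bed = regions.copy()
    bed["start"] = bed["start"].astype(int) - 1
    bed["end"] = bed["end"].astype(int)
    return bed
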