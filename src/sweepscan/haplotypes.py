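"""Haplotype-frequency profiling and gene annotation of candidate regions.

Within each high-confidence region, haplotypes over the region's informative
SNPs (polymorphic in the pooled sample) are enumerated per line from phase;
regions with fewer than 5 informative SNPs are skipped.  Regions are
annotated with the genes they contain, or — for gene deserts — with the
nearest genes within +/-100 kb of the region edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_qc import GenotypeDataset

__all__ = ["region_haplotypes", "annotate_regions", "read_gene_intervals"]


@dataclass
class RegionHaplotypes:
    """Per-line haplotype frequency table for one region."""

    chrom: str
    start: int
    end: int
    status: str  # "ok" or "below_min_snps"
    n_informative: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)  # line -> (haplotype, freq, is_major)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for line, tab in self.tables.items():
            f = tab.copy()
            f.insert(0, "line", line)
            f.insert(0, "region", f"{self.chrom}:{self.start}-{self.end}")
            frames.append(f)
        if not frames:
            return pd.DataFrame(columns=["region", "line", "haplotype", "freq", "is_major"])
        return pd.concat(frames, ignore_index=True)


def region_haplotypes(
    region: tuple[str, int, int],
    ds: GenotypeDataset,
    min_snps: int = 5,
    informative: str = "pooled",
) -> RegionHaplotypes:
    """Enumerate haplotypes and their frequencies inside one region.

    ``region`` is (chrom, start_bp, end_bp), 1-based inclusive.  Informative
    SNPs are region SNPs polymorphic in the pooled sample (or per line with
    ``informative='per_line'``, in which case the pooled rule is replaced by
    polymorphism in any line).  The major haplotype per line is the most
    frequent one, ties broken lexicographically (smallest string wins).
    Permuting sample order cannot change the table.
    """
    if not ds.phased:
        raise ValueError("unphased dataset: run phasing/imputation first")
    chrom, start, end = region
    in_region = (
        (ds.markers["chrom"].astype(str) == str(chrom))
        & (ds.markers["bp"] >= start)
        & (ds.markers["bp"] <= end)
    ).to_numpy()
    if informative == "pooled":
        freq = ds.allele_frequency()
        poly = (freq > 0) & (freq < 1)
    elif informative == "per_line":
        poly = np.zeros(ds.n_snps, dtype=bool)
        for line in ds.lines():
            f = ds.allele_frequency(line)
            poly |= (f > 0) & (f < 1)
    else:
        raise ValueError("informative must be 'pooled' or 'per_line'")
    cols = np.nonzero(in_region & poly)[0]
    result = RegionHaplotypes(str(chrom), int(start), int(end), "ok", int(cols.size))
    if cols.size < min_snps:
        result.status = "below_min_snps"
        return result
    for line in ds.lines():
        haps = ds.haplotypes(line)[:, cols]
        strings = ["".join(map(str, row)) for row in haps]
        counts = Counter(strings)
        n = len(strings)
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        tab = pd.DataFrame(
            {"haplotype": [h for h, _ in items], "freq": [c / n for _, c in items]}
        )
        tab["is_major"] = False
        tab.loc[0, "is_major"] = True  # sorted: highest count first, lexicographic tie-break
        result.tables[line] = tab
    return result


def read_gene_intervals(path: str) -> pd.DataFrame:
    """Read gene intervals from GFF3 (``gene`` features) or BED (4+ columns).

    Returns a frame ``chrom start end gene_id`` with 1-based inclusive
    coordinates.  Gene ID precedence in GFF3: ``gene_id`` attribute, then
    ``Name``, then ``ID``.
    """
    records = []
    is_gff = path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz"))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff or len(parts) >= 9:
                    if parts[2] != "gene":
                        continue
                    chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("gene_id") or attrs.get("Name") or attrs.get("ID") or f"gene_{lineno}"
                else:
                    if len(parts) < 4:
                        raise ValueError("need >=4 BED columns")
                    chrom = parts[0]
                    start = int(parts[1]) + 1  # BED is 0-based half-open
                    end = int(parts[2])
                    name = parts[3]
                if end < start:
                    raise ValueError("end < start")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed gene interval ({exc})") from None
            records.append((str(chrom), start, end, name))
    return pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"])


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 100_000,
) -> pd.DataFrame:
    """Annotate regions with contained genes or nearby genes within the flank.

    Genes overlapping a region by >= 1 bp are *contained*; a region with none
    is flagged a gene desert and annotated with genes overlapping
    [start - flank, end + flank], each with its signed edge-to-edge distance
    (negative = gene left of the region).  Contained and nearby sets are
    disjoint by construction; strand is ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # interval tree uses half-open ends
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end) + 1, (row.gene_id, int(row.start), int(row.end))
        )
    records = []
    for row in regions.itertuples(index=False):
        tree = trees.get(str(row.chrom), IntervalTree())
        contained = sorted(
            (iv.data for iv in tree.overlap(int(row.start), int(row.end) + 1)),
            key=lambda d: (d[1], d[0]),
        )
        desert = len(contained) == 0
        nearby: list[tuple[str, int]] = []
        if desert:
            for iv in sorted(tree.overlap(int(row.start) - flank, int(row.end) + 1 + flank), key=lambda i: i.begin):
                gene_id, gs, ge = iv.data
                if ge < row.start:
                    dist = ge - int(row.start)
                elif gs > row.end:
                    dist = gs - int(row.end)
                else:  # would be contained
                    continue
                nearby.append((gene_id, dist))
        records.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "contained_genes": ",".join(d[0] for d in contained),
                "n_genes": len(contained),
                "desert": desert,
                "nearby_genes": ",".join(g for g, _ in nearby),
                "distances": ",".join(str(d) for _, d in nearby),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["chrom", "start", "end", "contained_genes", "n_genes", "desert", "nearby_genes", "distances"],
    )
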