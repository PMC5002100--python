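"""Cross-population extended haplotype homozygosity (XP-EHH) scan.

For a core SNP, EHH at distance x is the probability that two haplotypes
drawn at random from the sample are identical-by-state over every marker
between the core and x.  Integrating the EHH decay curve over genetic
distance on both sides of the core gives iHH; the XP-EHH statistic for an
ordered pair of populations (A, B) is

    unstandardized XP-EHH = ln(iHH_A / iHH_B)

Scores are standardized by their genome-wide mean and (population) standard
deviation within each comparison; large positive standardized values mark
haplotypes that stayed long in population A — the footprint of recent
positive selection.  One-sided upper-tail normal P-values are assigned and
significant SNPs are clustered into candidate regions by physical distance.

Both populations are integrated to the SAME truncation boundary per
direction: the curve is cut at the last marker where the EHH of the combined
two-population sample is still at or above ``ehh_floor``.  This keeps
iHH_A / iHH_B comparable between populations.

The per-site functions (:func:`ehh_site`, :func:`ihh`) are a plain-Python
reference path; :func:`xpehh_scan` runs a compiled kernel that is checked
against the reference path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

__all__ = ["EHHCurve", "ehh_site", "ihh", "xpehh_scan", "cluster_snps_to_regions"]


@dataclass
class EHHCurve:
    """EHH decay away from a core marker in one direction.

    ``distances`` are non-negative genetic distances (cM) from the core,
    starting at 0 with the core-site homozygosity; ``ehh`` values lie in
    [0, 1] and are non-increasing.
    """

    distances: np.ndarray
    ehh: np.ndarray
    core: int
    direction: str

    def __len__(self) -> int:
        return len(self.distances)


def _partition_ehh(columns: np.ndarray) -> float:
    """EHH of haplotypes partitioned by identity over the given columns."""
    n = columns.shape[0]
    _, counts = np.unique(columns, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_site(haps: np.ndarray, core: int, direction: str, cm: np.ndarray | None = None) -> EHHCurve:
    """Site EHH decay curve from a core marker over all haplotypes.

    Parameters
    ----------
    haps
        (n_haplotypes, n_markers) 0/1 matrix, complete (no missing).
    core
        Core marker index.
    direction
        ``"left"`` or ``"right"``.
    cm
        Optional cM positions per marker; marker index is used as the
        distance axis when omitted.

    At each marker x in the chosen direction the haplotypes are partitioned
    into groups identical over [core..x] inclusive and EHH(x) is the
    homozygosity of that partition, Σ_g C(n_g,2) / C(n,2).  The curve starts
    at distance 0 with the partition at the core site alone.  A core at the
    chromosome edge yields the single distance-0 point for the empty side.
    """
    haps = np.asarray(haps)
    n, m = haps.shape
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    pos_cm = np.arange(m, dtype=np.float64) if cm is None else np.asarray(cm, dtype=np.float64)
    step = -1 if direction == "left" else 1
    targets = range(core + step, -1, -1) if direction == "left" else range(core + 1, m)
    dists = [0.0]
    vals = [_partition_ehh(haps[:, [core]])]
    for x in targets:
        lo, hi = (x, core) if direction == "left" else (core, x)
        dists.append(abs(pos_cm[x] - pos_cm[core]))
        vals.append(_partition_ehh(haps[:, lo : hi + 1]))
    return EHHCurve(np.array(dists), np.array(vals), core, direction)


def _truncated_trapezoid(curve: EHHCurve, comb: EHHCurve, floor: float) -> float:
    cut = len(comb)
    below = np.nonzero(comb.ehh < floor)[0]
    if below.size:
        cut = int(below[0])
    if cut < 2:
        return 0.0
    return float(np.trapezoid(curve.ehh[:cut], curve.distances[:cut]))


def ihh(
    curve_a_left: EHHCurve,
    curve_a_right: EHHCurve,
    curve_b_left: EHHCurve,
    curve_b_right: EHHCurve,
    curve_comb_left: EHHCurve,
    curve_comb_right: EHHCurve,
    ehh_floor: float = 0.05,
) -> tuple[float, float, bool]:
    """Integrated EHH for populations A and B with a shared truncation.

    Trapezoid integration over genetic distance, left and right summed.  Both
    populations are truncated per direction at the first marker where the
    COMBINED-sample EHH drops below ``ehh_floor`` (that marker excluded), or
    at the chromosome end.  Returns ``(iHH_A, iHH_B, usable)``; ``usable`` is
    False when the integration support is empty on both sides.
    """
    ihh_a = ihh_b = 0.0
    support = False
    for ca, cb, cc in (
        (curve_a_left, curve_b_left, curve_comb_left),
        (curve_a_right, curve_b_right, curve_comb_right),
    ):
        if not (len(ca) == len(cb) == len(cc)):
            raise ValueError("curves must share marker positions")
        a = _truncated_trapezoid(ca, cc, ehh_floor)
        b = _truncated_trapezoid(cb, cc, ehh_floor)
        support = support or a > 0 or b > 0
        ihh_a += a
        ihh_b += b
    return ihh_a, ihh_b, support


@njit(cache=True)
def _scan_chrom_kernel(H, na, cm, floor):  # pragma: no cover - exercised via wrapper
    """iHH_A/iHH_B for every core SNP of one chromosome.

    H is the combined haplotype matrix (A rows first), na the number of A
    haplotypes.  The haplotype partition is refined marker-by-marker outward
    from the core with a stable counting split (O(n) per marker);
    integration stops at the first marker whose combined EHH falls below
    ``floor``.
    """
    n, m = H.shape
    nb = n - na
    out = np.zeros((m, 2))
    pair_c = n * (n - 1)
    pair_a = na * (na - 1)
    pair_b = nb * (nb - 1)
    order = np.empty(n, np.int64)
    grp = np.empty(n, np.int64)
    new_order = np.empty(n, np.int64)
    new_grp = np.empty(n, np.int64)
    ones = np.empty(n, np.int64)
    for core in range(m):
        ihh_a = 0.0
        ihh_b = 0.0
        for dirn in range(2):
            step = -1 if dirn == 0 else 1
            # initial partition by the core-site allele
            p = 0
            for h in range(n):
                if H[h, core] == 0:
                    order[p] = h
                    grp[p] = 0
                    p += 1
            for h in range(n):
                if H[h, core] != 0:
                    order[p] = h
                    grp[p] = 1
                    p += 1
            sc = 0
            sa = 0
            sb = 0
            i = 0
            while i < n:
                j = i
                ca = 0
                while j < n and grp[j] == grp[i]:
                    if order[j] < na:
                        ca += 1
                    j += 1
                cc = j - i
                cb = cc - ca
                sc += cc * (cc - 1)
                sa += ca * (ca - 1)
                sb += cb * (cb - 1)
                i = j
            ehh_a_prev = sa / pair_a if pair_a > 0 else 0.0
            ehh_b_prev = sb / pair_b if pair_b > 0 else 0.0
            d_prev = 0.0
            pos = core + step
            while 0 <= pos < m:
                # stable split of every group by the allele at pos
                q = 0
                gid = 0
                sc = 0
                sa = 0
                sb = 0
                i = 0
                while i < n:
                    j = i
                    while j < n and grp[j] == grp[i]:
                        j += 1
                    n1 = 0
                    cc0 = 0
                    ca0 = 0
                    ca1 = 0
                    for t in range(i, j):
                        r = order[t]
                        if H[r, pos] == 0:
                            new_order[q] = r
                            new_grp[q] = gid
                            q += 1
                            cc0 += 1
                            if r < na:
                                ca0 += 1
                        else:
                            ones[n1] = r
                            n1 += 1
                            if r < na:
                                ca1 += 1
                    if cc0 > 0:
                        gid += 1
                    if n1 > 0:
                        for t in range(n1):
                            new_order[q] = ones[t]
                            new_grp[q] = gid
                            q += 1
                        gid += 1
                    cb0 = cc0 - ca0
                    cb1 = n1 - ca1
                    sc += cc0 * (cc0 - 1) + n1 * (n1 - 1)
                    sa += ca0 * (ca0 - 1) + ca1 * (ca1 - 1)
                    sb += cb0 * (cb0 - 1) + cb1 * (cb1 - 1)
                    i = j
                ehh_c = sc / pair_c
                if ehh_c < floor:
                    break
                tmp = order
                order = new_order
                new_order = tmp
                tmp = grp
                grp = new_grp
                new_grp = tmp
                ehh_a = sa / pair_a if pair_a > 0 else 0.0
                ehh_b = sb / pair_b if pair_b > 0 else 0.0
                d = abs(cm[pos] - cm[core])
                ihh_a += (d - d_prev) * (ehh_a_prev + ehh_a) / 2.0
                ihh_b += (d - d_prev) * (ehh_b_prev + ehh_b) / 2.0
                ehh_a_prev = ehh_a
                ehh_b_prev = ehh_b
                d_prev = d
                pos += step
        out[core, 0] = ihh_a
        out[core, 1] = ihh_b
    return out


def scan_ihh_chrom(haps_a: np.ndarray, haps_b: np.ndarray, cm: np.ndarray, ehh_floor: float = 0.05) -> np.ndarray:
    """(n_snps, 2) array of (iHH_A, iHH_B) for one chromosome."""
    H = np.ascontiguousarray(np.vstack([haps_a, haps_b]).astype(np.uint8))
    return _scan_chrom_kernel(H, haps_a.shape[0], np.asarray(cm, dtype=np.float64), float(ehh_floor))


def xpehh_scan(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    markers: pd.DataFrame,
    ehh_floor: float = 0.05,
    two_sided: bool = False,
    comparison: str = "A_vs_B",
) -> pd.DataFrame:
    """XP-EHH score track for one ordered population comparison.

    Parameters
    ----------
    haps_a, haps_b
        Phased, complete haplotype matrices over the same markers (focal
        population first).
    markers
        Marker map with columns ``chrom, id, bp, cM`` ordered to match the
        haplotype columns.

    Returns a frame with iHH values, the unstandardized log-ratio, the
    genome-wide standardized score and its normal P-value (upper tail by
    default).  SNPs where either iHH is 0 are kept in the frame with NaN
    score and excluded from standardization.
    """
    if haps_a.shape[1] != len(markers) or haps_b.shape[1] != len(markers):
        raise ValueError("haplotype matrices and marker map disagree in SNP count")
    rows = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        vals = scan_ihh_chrom(haps_a[:, idx], haps_b[:, idx], grp["cM"].to_numpy(), ehh_floor)
        rows.append(vals)
    ihh_vals = np.vstack(rows)
    track = markers[["chrom", "id", "bp", "cM"]].copy().reset_index(drop=True)
    track["iHH_A"] = ihh_vals[:, 0]
    track["iHH_B"] = ihh_vals[:, 1]
    usable = (track["iHH_A"] > 0) & (track["iHH_B"] > 0)
    raw = np.full(len(track), np.nan)
    raw[usable] = np.log(track.loc[usable, "iHH_A"] / track.loc[usable, "iHH_B"])
    track["xpehh_raw"] = raw
    if int(usable.sum()) < 2:
        raise ValueError("fewer than 2 scored SNPs: cannot standardize")
    scored = raw[usable.to_numpy()]
    mean, sd = scored.mean(), scored.std()  # population sd, denominator n
    if sd == 0:
        raise ValueError("zero variance of XP-EHH scores: cannot standardize")
    z = (raw - mean) / sd
    track["xpehh_z"] = z
    track["pvalue"] = 2 * norm.sf(np.abs(z)) if two_sided else norm.sf(z)
    track["comparison"] = comparison
    track.attrs["n_excluded_zero_ihh"] = int((~usable).sum())
    return track


def cluster_snps_to_regions(
    significant: pd.DataFrame,
    max_gap: int = 200_000,
) -> pd.DataFrame:
    """Cluster significant SNPs into candidate regions by physical distance.

    Consecutive SNPs on a chromosome closer than ``max_gap`` bp join one
    cluster; the region spans [min bp, max bp] of its members (a singleton
    SNP yields a zero-length region).  ``significant`` needs columns
    ``chrom`` and ``bp``; ``pvalue`` is optional and, when present, the best
    member P-value is reported per region.
    """
    cols = ["chrom", "start", "end", "n_snps", "best_p"]
    if len(significant) == 0:
        return pd.DataFrame(columns=cols)
    has_p = "pvalue" in significant.columns
    records = []
    for chrom, grp in significant.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        bps = grp["bp"].to_numpy()
        pvals = grp["pvalue"].to_numpy() if has_p else np.full(len(grp), np.nan)
        start = 0
        for i in range(1, len(bps) + 1):
            if i == len(bps) or bps[i] - bps[i - 1] >= max_gap:
                members = slice(start, i)
                records.append(
                    {
                        "chrom": chrom,
                        "start": int(bps[members][0]),
                        "end": int(bps[members][-1]),
                        "n_snps": i - start,
                        "best_p": float(np.nanmin(pvals[members])) if has_p else np.nan,
                    }
                )
                start = i
    return pd.DataFrame.from_records(records, columns=cols)
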