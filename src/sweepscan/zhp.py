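"""Pooled-heterozygosity (Hp / ZHp) sliding-window scan.

For each line, sliding windows of 5 SNPs (step 1) are summarized by the
pooled heterozygosity

    Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2

where n_MAJ / n_MIN are the major- and minor-allele counts at each window
SNP within the line (called alleles only).  Hp lies in [0, 0.5]; windows
where all SNPs are fixed give 0 and windows of 50/50 SNPs give the maximum
0.5.  Hp is Z-transformed genome-wide per line (population sd); strongly
negative ZHp marks windows where variation has been swept toward fixation.
Sex chromosomes are excluded; no significance cutoff is imposed — the caller
chooses a threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_qc import GenotypeDataset

__all__ = ["hp_windows", "zhp_transform", "zhp_scan"]


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (major, minor) called-allele counts for one line's calls."""
    called = calls >= 0
    n_called = called.sum(axis=(0, 2))
    n_alt = np.where(called, calls, 0).sum(axis=(0, 2))
    n_ref = n_called - n_alt
    return np.maximum(n_ref, n_alt), np.minimum(n_ref, n_alt)


def hp_windows(
    ds: GenotypeDataset,
    line: str,
    window_size: int = 5,
    step: int = 1,
    excluded_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Sliding-window pooled heterozygosity for one line.

    Chromosomes named in ``excluded_chroms`` (e.g. sex chromosomes) are
    dropped; chromosomes with fewer than ``window_size`` SNPs are skipped
    with a warning.  Returns columns ``line chrom win_start_bp win_end_bp
    sum_maj sum_min hp``.
    """
    excluded = {str(c) for c in (excluded_chroms or set())}
    idx = ds.line_sample_indices(line)
    maj, mino = _allele_counts(ds.calls[idx])
    records = []
    for chrom, grp in ds.markers.groupby("chrom", sort=False):
        if str(chrom) in excluded:
            continue
        if len(grp) < window_size:
            warnings.warn(f"chromosome {chrom}: fewer than {window_size} SNPs, skipped")
            continue
        cols = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        cmaj = np.concatenate([[0], np.cumsum(maj[cols])])
        cmin = np.concatenate([[0], np.cumsum(mino[cols])])
        for start in range(0, len(cols) - window_size + 1, step):
            end = start + window_size
            s_maj = int(cmaj[end] - cmaj[start])
            s_min = int(cmin[end] - cmin[start])
            total = s_maj + s_min
            hp = 2.0 * s_maj * s_min / (total * total) if total > 0 else 0.0
            records.append(
                {
                    "line": line,
                    "chrom": chrom,
                    "win_start_bp": int(bp[start]),
                    "win_end_bp": int(bp[end - 1]),
                    "sum_maj": s_maj,
                    "sum_min": s_min,
                    "hp": hp,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["line", "chrom", "win_start_bp", "win_end_bp", "sum_maj", "sum_min", "hp"],
    )


def zhp_transform(windows: pd.DataFrame) -> pd.DataFrame:
    """Z-transform Hp genome-wide: ZHp = (Hp - mean) / sd (population sd).

    Requires at least two windows with non-identical Hp.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to standardize")
    hp = windows["hp"].to_numpy(np.float64)
    sd = hp.std()
    if np.ptp(hp) == 0 or sd == 0:
        raise ValueError("all Hp values identical: cannot Z-transform")
    out = windows.copy()
    out["zhp"] = (hp - hp.mean()) / sd
    return out


def zhp_scan(
    ds: GenotypeDataset,
    window_size: int = 5,
    step: int = 1,
    excluded_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Hp + ZHp tracks for every line, standardized within each line."""
    frames = [
        zhp_transform(hp_windows(ds, line, window_size, step, excluded_chroms))
        for line in ds.lines()
    ]
    return pd.concat(frames, ignore_index=True)
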