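"""Genotype input and SNP quality control.

The pipeline consumes phased diploid genotypes for several reproductively
isolated lines typed on one SNP array.  This module reads a VCF plus a
sample-to-line table into an in-memory :class:`GenotypeDataset`, computes
per-SNP Mendelian-inconsistency rates from an optional pedigree, applies the
standard array QC filters (excluded chromosomes, Mendelian inconsistency,
ungenotyped SNPs, joint monomorphism, low call rate) in a fixed order so that
every removed SNP is attributed to exactly one category, and offers a naive
within-line frequency imputation as a documented stand-in for statistical
imputation of missing genotypes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeDataset",
    "Pedigree",
    "QCReport",
    "read_phased_vcf",
    "read_line_table",
    "mendel_error_rate",
    "apply_qc",
    "naive_impute",
]

MISSING = -1

#: QC categories in the order they are applied; a SNP is counted in the first
#: category it matches.
QC_CATEGORIES = ("excluded_chrom", "mendel", "ungenotyped", "monomorphic", "low_call_rate")


@dataclass
class GenotypeDataset:
    """Diploid genotype calls for samples grouped into lines.

    ``calls`` has shape (n_samples, n_snps, 2) with alleles coded 0 (REF),
    1 (ALT) or -1 (missing).  ``markers`` is a frame with at least columns
    ``chrom, id, bp`` (``cM`` added once a genetic map is attached; ``ref`` /
    ``alt`` carried as metadata when read from VCF).
    """

    samples: list[str]
    line_of: dict[str, str]
    markers: pd.DataFrame
    calls: np.ndarray
    phased: bool

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        missing_line = [s for s in self.samples if s not in self.line_of]
        if missing_line:
            raise ValueError(f"samples without a line label: {missing_line[:5]}")
        if self.calls.shape != (len(self.samples), len(self.markers), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.phased and np.any(self.calls < 0):
            raise ValueError("phased dataset must not contain missing alleles")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def lines(self) -> list[str]:
        return sorted(set(self.line_of[s] for s in self.samples))

    def line_sample_indices(self, line: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.samples) if self.line_of[s] == line], dtype=np.int64)
        if idx.size == 0:
            raise KeyError(f"no samples for line {line!r}")
        return idx

    def haplotypes(self, line: str) -> np.ndarray:
        """Phased haplotype matrix (2 * n_line_samples, n_snps) for one line."""
        if not self.phased:
            raise ValueError("haplotypes require a phased, complete dataset")
        idx = self.line_sample_indices(line)
        return self.calls[idx].transpose(0, 2, 1).reshape(-1, self.n_snps).astype(np.uint8)

    def allele_frequency(self, line: str | None = None) -> np.ndarray:
        """Per-SNP frequency of allele 1 among called alleles (NaN if none)."""
        calls = self.calls if line is None else self.calls[self.line_sample_indices(line)]
        called = calls >= 0
        n_called = called.sum(axis=(0, 2)).astype(np.float64)
        n_alt = np.where(called, calls, 0).sum(axis=(0, 2)).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_alt / n_called, np.nan)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            samples=list(self.samples),
            line_of=dict(self.line_of),
            markers=self.markers.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask, :],
            phased=self.phased,
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeDataset":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=np.int64)
        return GenotypeDataset(
            samples=list(keep),
            line_of={s: self.line_of[s] for s in keep},
            markers=self.markers,
            calls=self.calls[idx],
            phased=self.phased,
        )


@dataclass
class Pedigree:
    """Trio records (child, sire, dam); '0' or None marks an unknown parent."""

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        cleaned = []
        for child, sire, dam in self.records:
            sire = None if sire in (None, "0", "") else sire
            dam = None if dam in (None, "0", "") else dam
            if child in (sire, dam):
                raise ValueError(f"sample {child!r} listed as its own parent")
            cleaned.append((child, sire, dam))
        self.records = cleaned

    @classmethod
    def from_tsv(cls, path: str) -> "Pedigree":
        frame = pd.read_csv(path, sep="\t", header=None, names=["child", "sire", "dam"], dtype=str)
        return cls(list(frame.itertuples(index=False, name=None)))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QCReport:
    """Accounting of the QC filters: every input SNP lands in exactly one
    category or is retained, so retained + sum(removed) equals the input
    total by construction."""

    input_total: int
    removed: dict[str, int]
    disposition: np.ndarray | None = field(default=None, repr=False)

    @property
    def retained(self) -> int:
        return self.input_total - sum(self.removed.values())

    @classmethod
    def from_counts(cls, input_total: int, removed: dict[str, int]) -> "QCReport":
        if sum(removed.values()) > input_total:
            raise ValueError("removed counts exceed input total")
        return cls(input_total=int(input_total), removed={k: int(v) for k, v in removed.items()})

    def summary(self) -> dict:
        return {
            "input_total": self.input_total,
            "removed": dict(self.removed),
            "retained": self.retained,
        }

    def write(self, tsv_path: str, json_path: str | None = None, markers: pd.DataFrame | None = None) -> None:
        if self.disposition is not None and markers is not None:
            frame = markers[["chrom", "id", "bp"]].copy()
            frame["disposition"] = self.disposition
            frame.to_csv(tsv_path, sep="\t", index=False)
        else:
            pd.DataFrame(
                {"category": list(self.removed) + ["retained"],
                 "count": list(self.removed.values()) + [self.retained]}
            ).to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def read_line_table(path: str) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "line"], dtype=str)
    return dict(zip(frame["sample_id"], frame["line"]))


def read_phased_vcf(path: str, line_table: str | dict[str, str]) -> GenotypeDataset:
    """Read a VCF of biallelic SNPs into a :class:`GenotypeDataset`.

    Multiallelic or non-SNP records are skipped (counted in the log).  Alleles
    are recoded 0=REF / 1=ALT with the original bases kept in the marker
    metadata.  The dataset is flagged phased only if every genotype is phased
    and complete.
    """
    from cyvcf2 import VCF

    line_of = read_line_table(line_table) if isinstance(line_table, str) else dict(line_table)
    vcf = VCF(path)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in line_of]
    if unknown:
        raise ValueError(f"VCF sample(s) missing from line table: {', '.join(unknown)}")

    rows, chroms, ids, bps, refs, alts, skipped = [], [], [], [], [], [], 0
    phased = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        arr = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        if np.any(arr < 0):
            arr[arr < 0] = MISSING
            phased = False
        if not all(g[2] for g in gts):
            phased = False
        rows.append(arr)
        chroms.append(var.CHROM)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        bps.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if skipped:
        logger.info("skipped %d non-SNP/multiallelic records in %s", skipped, path)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    markers = pd.DataFrame({"chrom": chroms, "id": ids, "bp": np.array(bps, dtype=np.int64),
                            "ref": refs, "alt": alts})
    calls = np.stack(rows, axis=1)  # (n_samples, n_snps, 2)
    return GenotypeDataset(samples=samples, line_of=line_of, markers=markers, calls=calls, phased=phased)


def _mendel_tables() -> tuple[np.ndarray, np.ndarray]:
    """Compatibility lookup over genotype dosage codes 0/1/2.

    trio[c, p1, p2] and duo[c, p] are True when the child genotype is
    impossible under Mendelian transmission from the genotyped parent(s).
    """
    genos = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    trio = np.zeros((3, 3, 3), dtype=bool)
    duo = np.zeros((3, 3), dtype=bool)
    for c, (c1, c2) in genos.items():
        for p1, al1 in genos.items():
            duo[c, p1] = not (c1 in al1 or c2 in al1)
            for p2, al2 in genos.items():
                ok = (c1 in al1 and c2 in al2) or (c2 in al1 and c1 in al2)
                trio[c, p1, p2] = not ok
    return trio, duo


_TRIO_BAD, _DUO_BAD = _mendel_tables()


def _dosage(calls: np.ndarray) -> np.ndarray:
    """(n_samples, n_snps) dosage 0/1/2, -1 where either allele is missing."""
    dos = calls.astype(np.int16).sum(axis=2)
    dos[np.any(calls < 0, axis=2)] = MISSING
    return dos


def mendel_error_rate(ds: GenotypeDataset, ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Mendelian-inconsistency rate.

    A check is one (child, SNP) with the child genotyped and at least one
    genotyped parent; it is a violation when the child genotype is impossible
    given the genotyped parent(s).  Returns ``(rate, no_checks_flag)`` where
    SNPs with zero informative checks get rate 0 and the flag set.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree: skip the Mendelian filter instead")
    pos = {s: i for i, s in enumerate(ds.samples)}
    dos = _dosage(ds.calls)
    viol = np.zeros(ds.n_snps, dtype=np.int64)
    checks = np.zeros(ds.n_snps, dtype=np.int64)
    n_usable = 0
    for child, sire, dam in ped.records:
        if child not in pos:
            continue
        c = dos[pos[child]]
        p1 = dos[pos[sire]] if sire in pos else None
        p2 = dos[pos[dam]] if dam in pos else None
        if p1 is None and p2 is None:
            continue
        n_usable += 1
        if p1 is not None and p2 is not None:
            ok = (c >= 0) & (p1 >= 0) & (p2 >= 0)
            viol[ok] += _TRIO_BAD[c[ok], p1[ok], p2[ok]]
            checks[ok] += 1
            # fall back to a duo check where exactly one parent is missing
            for pa, pb in ((p1, p2), (p2, p1)):
                solo = (c >= 0) & (pa >= 0) & (pb < 0)
                viol[solo] += _DUO_BAD[c[solo], pa[solo]]
                checks[solo] += 1
        else:
            pa = p1 if p1 is not None else p2
            ok = (c >= 0) & (pa >= 0)
            viol[ok] += _DUO_BAD[c[ok], pa[ok]]
            checks[ok] += 1
    if n_usable == 0:
        raise ValueError("pedigree references no genotyped child with a genotyped parent")
    no_checks = checks == 0
    with np.errstate(invalid="ignore"):
        rate = np.where(no_checks, 0.0, viol / np.maximum(checks, 1))
    return rate, no_checks


def apply_qc(
    ds: GenotypeDataset,
    ped: Pedigree | None = None,
    call_rate_min: float = 0.90,
    mendel_max: float = 0.001,
    excluded_chroms: set[str] | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the SNP QC filters in a fixed order.

    Order: (1) excluded/unplaced chromosomes, (2) Mendelian inconsistency
    > ``mendel_max`` (skipped with a warning when no pedigree is supplied),
    (3) fully ungenotyped SNPs, (4) SNPs monomorphic jointly across all lines
    pooled, (5) call rate < ``call_rate_min``.  Each SNP is counted in the
    first matching category only.
    """
    if ds.n_snps == 0:
        raise ValueError("empty dataset")
    excluded_chroms = set(excluded_chroms or ())
    known = set(ds.markers["chrom"].astype(str))
    for chrom in excluded_chroms - known:
        warnings.warn(f"excluded chromosome {chrom!r} not present in the data")

    disposition = np.full(ds.n_snps, "retained", dtype=object)
    unassigned = np.ones(ds.n_snps, dtype=bool)

    def take(mask: np.ndarray, category: str) -> int:
        hit = mask & unassigned
        disposition[hit] = category
        unassigned[hit] = False
        return int(hit.sum())

    removed: dict[str, int] = {}
    chrom_mask = ds.markers["chrom"].astype(str).isin(excluded_chroms).to_numpy()
    removed["excluded_chrom"] = take(chrom_mask, "excluded_chrom")

    if ped is not None and len(ped) > 0:
        rate, _ = mendel_error_rate(ds, ped)
        removed["mendel"] = take(rate > mendel_max, "mendel")
    else:
        warnings.warn("no pedigree supplied: Mendelian-inconsistency filter SKIPPED")
        removed["mendel"] = 0

    called = (ds.calls >= 0).all(axis=2)  # (n_samples, n_snps)
    removed["ungenotyped"] = take(~called.any(axis=0), "ungenotyped")

    n_alt = np.where(ds.calls >= 0, ds.calls, 0).sum(axis=(0, 2))
    n_called_alleles = (ds.calls >= 0).sum(axis=(0, 2))
    mono = (n_alt == 0) | (n_alt == n_called_alleles)
    removed["monomorphic"] = take(mono, "monomorphic")

    call_rate = called.mean(axis=0)
    removed["low_call_rate"] = take(call_rate < call_rate_min, "low_call_rate")

    keep = unassigned
    if not keep.any():
        raise ValueError("QC removed every SNP")
    report = QCReport(input_total=ds.n_snps, removed=removed, disposition=disposition)
    return ds.subset_markers(keep), report


def naive_impute(ds: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Fill missing alleles by draws from the within-line allele frequency.

    Each missing allele is drawn Bernoulli(p_line) at its SNP; when a line has
    no called alleles at a SNP the pooled frequency is used (logged).  The
    result is complete; it is flagged phased only if the input was phased.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    pooled = ds.allele_frequency()
    pooled = np.where(np.isnan(pooled), 0.5, pooled)
    n_pooled_fallback = 0
    for line in ds.lines():
        idx = ds.line_sample_indices(line)
        freq = ds.allele_frequency(line)
        fallback = np.isnan(freq)
        n_pooled_fallback += int(fallback.sum())
        freq = np.where(fallback, pooled, freq)
        block = calls[idx]
        miss = block < 0
        if miss.any():
            p = np.broadcast_to(freq[None, :, None], block.shape)
            draws = (rng.random(block.shape) < p).astype(np.int8)
            block[miss] = draws[miss]
            calls[idx] = block
    if n_pooled_fallback:
        logger.info("imputed %d line x SNP cells from the pooled frequency", n_pooled_fallback)
    return GenotypeDataset(
        samples=list(ds.samples), line_of=dict(ds.line_of), markers=ds.markers,
        calls=calls, phased=ds.phased,
    )
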