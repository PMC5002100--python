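"""Forward simulation of isolated breeding lines with optional hard sweeps.

The generator emulates SNP-array data from several purebred lines that split
from one base population and then drifted independently:

* a base population is built from a fixed panel of array-ascertained SNPs
  (allele frequencies drawn from a 1/p-like spectrum with a minor-allele
  frequency floor) whose haplotypes are recombinant mosaics of a limited set
  of founder haplotypes — the mosaic structure is what induces LD;
* each line evolves independently by Wright-Fisher reproduction with
  recombination (Poisson crossovers per Morgan) for G generations; a hard
  sweep in a line seeds the favored allele at a configured start frequency
  and weights parent sampling by (1+s) per favored-allele copy;
* diploid samples are drawn per line and exported as a phased, complete
  dataset plus an "unphased" copy with missing genotypes, optional trios
  with injected Mendelian errors, a marker map, a pedigree, and a
  ground-truth table of the implanted sweeps.

Everything is deterministic given the configuration seed.  There are no new
mutations: the marker panel is fixed in advance, as on a genotyping array.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeDataset, Pedigree

__all__ = [
    "SweepSpec",
    "SimConfig",
    "BasePanel",
    "simulate_base",
    "evolve_lines",
    "sample_and_export",
    "simulate_dataset",
    "write_vcf",
]

DEFAULT_LINES = ("ML1", "ML2", "ML3", "FL1", "FL2")


@dataclass
class SweepSpec:
    """One hard sweep: locus, affected lines, selection coefficient and the
    frequency at which the favored allele is seeded when selection starts."""

    chrom: str
    bp: int
    lines: tuple[str, ...]
    s: float = 0.5
    start_freq: float = 0.05
    #: half-width (cM) of the ancestral haplotype segment shared by the
    #: initial carriers; models selection starting on standing variation
    #: whose carriers descend from one ancestral background at the core
    core_cm: float = 1.5


@dataclass
class SimConfig:
    """Study-scale defaults: 3 chromosomes x 20 Mb at 1 cM/Mb, 3,000
    array-ascertained SNPs, 5 lines of N_e = 250 drifting for 40 generations
    with 24-60 sampled diploids per line."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 20_000_000, "2": 20_000_000, "3": 20_000_000}
    )
    cm_per_mb: float = 1.0
    n_snps: int = 3_000
    n_founders: int = 60
    maf_floor: float = 0.05
    founder_mosaic_depth: float = 10.0  # crossovers per Morgan when tiling founders
    line_names: tuple[str, ...] = DEFAULT_LINES
    ne: int = 250
    generations: int = 40
    samples_per_line: tuple[int, ...] = (24, 60, 38, 48, 36)
    sweeps: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    n_trios_per_line: int = 0
    mendel_error_rate: float = 0.0
    condition_on_establishment: bool = False

    def __post_init__(self) -> None:
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("mendel_error_rate", self.mendel_error_rate),
            ("maf_floor", self.maf_floor),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if len(self.samples_per_line) != len(self.line_names):
            raise ValueError("samples_per_line must match line_names")
        if any(n > self.ne for n in self.samples_per_line):
            raise ValueError("sampled diploids cannot exceed N_e")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not 1 <= sw.bp <= self.chrom_lengths[sw.chrom]:
                raise ValueError(f"sweep locus {sw.bp} outside chromosome {sw.chrom}")
            unknown = set(sw.lines) - set(self.line_names)
            if unknown:
                raise ValueError(f"sweep lines not simulated: {unknown}")

    def to_json(self) -> str:
        d = asdict(self)
        d["sweeps"] = [asdict(s) for s in self.sweeps]
        return json.dumps(d, indent=2, default=str)


@dataclass
class BasePanel:
    """Base-population haplotypes over the fixed marker panel."""

    markers: pd.DataFrame  # chrom, id, bp, cM
    haplotypes: np.ndarray  # (2 * ne, n_snps) uint8
    chrom_slices: dict[str, slice]
    morgans: dict[str, float]


def _chrom_blocks(markers: pd.DataFrame) -> dict[str, slice]:
    blocks = {}
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        blocks[str(chrom)] = slice(int(idx[0]), int(idx[-1]) + 1)
    return blocks


def simulate_base(config: SimConfig) -> BasePanel:
    """Build the marker panel, founder haplotypes and a base population.

    Allele frequencies follow a density proportional to 1/p on
    [maf_floor, 1 - maf_floor] (the floor mimics array ascertainment, which
    discards rare variants).  Founder haplotypes are drawn per SNP
    independently; the base population's haplotypes are then recombinant
    mosaics of the founders (Poisson crossovers at ``founder_mosaic_depth``
    per Morgan), which is what creates linkage disequilibrium.
    """
    if config.maf_floor >= 0.5:
        raise ValueError("maf_floor >= 0.5 leaves no admissible allele frequency")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    total_len = sum(config.chrom_lengths.values())
    rows = []
    for chrom, length in config.chrom_lengths.items():
        n_c = max(2, int(round(config.n_snps * length / total_len)))
        bp = np.sort(rng.choice(np.arange(1, length + 1), size=n_c, replace=False))
        for j, pos in enumerate(bp):
            rows.append((str(chrom), f"snp_{chrom}_{j}", int(pos), pos * config.cm_per_mb / 1e6))
    markers = pd.DataFrame(rows, columns=["chrom", "id", "bp", "cM"])
    m = len(markers)
    lo, hi = config.maf_floor, 1.0 - config.maf_floor
    p = lo * (hi / lo) ** rng.random(m)  # inverse-CDF draw from density ∝ 1/p
    founders = (rng.random((config.n_founders, m)) < p).astype(np.uint8)
    blocks = _chrom_blocks(markers)
    morgans = {}
    n_haps = 2 * config.ne
    haps = np.empty((n_haps, m), dtype=np.uint8)
    for chrom, block in blocks.items():
        cm = markers["cM"].to_numpy()[block]
        cm_len = config.chrom_lengths[chrom] * config.cm_per_mb / 1e6
        morgans[chrom] = cm_len / 100.0
        rate = config.founder_mosaic_depth * morgans[chrom]
        k = rng.poisson(rate, n_haps)
        for h in range(n_haps):
            cuts = np.sort(rng.uniform(0, cm_len, k[h]))
            seg = np.searchsorted(cuts, cm)
            donors = rng.integers(0, config.n_founders, k[h] + 1)
            haps[h, block] = founders[donors[seg], np.arange(block.start, block.stop)]
    # enforce the ascertainment floor on the REALIZED panel: an array would
    # not carry a SNP whose minor allele fell below the floor, so top up the
    # minor-allele count of the few SNPs that drifted under it
    need = int(np.ceil(config.maf_floor * n_haps))
    counts = haps.sum(axis=0).astype(np.int64)
    for j in np.nonzero((counts < need) | (counts > n_haps - need))[0]:
        minor = 1 if counts[j] < need else 0
        carriers = np.nonzero(haps[:, j] != minor)[0]
        deficit = need - (counts[j] if minor == 1 else n_haps - counts[j])
        flip = rng.choice(carriers, size=deficit, replace=False)
        haps[flip, j] = minor
    return BasePanel(markers=markers, haplotypes=haps, chrom_slices=blocks, morgans=morgans)


def _recombine(pop: np.ndarray, parents: np.ndarray, panel: BasePanel, cm: np.ndarray, rng) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices into ``pop``)."""
    n_gam = parents.size
    out = np.empty((n_gam, pop.shape[1]), dtype=np.uint8)
    for chrom, block in panel.chrom_slices.items():
        cm_block = cm[block]
        k = rng.poisson(panel.morgans[chrom], n_gam)
        first = rng.integers(0, 2, n_gam)
        plain = k == 0
        rows = 2 * parents + first
        out[plain, block] = pop[rows[plain], block]
        for g in np.nonzero(~plain)[0]:
            cuts = np.sort(rng.uniform(cm_block[0], cm_block[-1], k[g]))
            choice = (first[g] + np.searchsorted(cuts, cm_block)) % 2
            p0 = pop[2 * parents[g], block]
            p1 = pop[2 * parents[g] + 1, block]
            out[g, block] = np.where(choice == 0, p0, p1)
    return out


def _evolve_one_line(
    panel: BasePanel,
    config: SimConfig,
    line: str,
    sweep_sites: list[tuple[int, float, float, float]],  # (snp, s, start_freq, core_cm)
    seed_seq: np.random.SeedSequence,
) -> tuple[np.ndarray, list[float]]:
    rng = np.random.default_rng(seed_seq)
    ne = config.ne
    cm = panel.markers["cM"].to_numpy()
    rows = rng.choice(panel.haplotypes.shape[0], size=2 * ne, replace=False)
    pop = panel.haplotypes[rows].copy()
    # Hard-sweep seeding: the favored allele starts on ONE ancestral
    # background.  Carriers at the start frequency are copies of a single
    # origin haplotype over a short core segment around the locus — the
    # unbroken ancestral segment of standing variation at that frequency —
    # while their flanking backgrounds stay their own.  Selection then
    # drives the shared core toward fixation.
    chroms_arr = panel.markers["chrom"].to_numpy()
    for snp, _s, start, core_cm in sweep_sites:
        n_car = max(1, int(round(start * 2 * ne)))
        chrom = str(chroms_arr[snp])
        block = panel.chrom_slices[chrom]
        core = np.zeros(pop.shape[1], dtype=bool)
        core[block] = np.abs(cm[block] - cm[snp]) <= core_cm
        origin = int(rng.integers(0, 2 * ne))
        carriers = rng.choice(2 * ne, size=n_car, replace=False)
        origin_core = pop[origin, core].copy()
        pop[:, snp] = 0
        for c in carriers:
            pop[c, core] = origin_core
        pop[carriers, snp] = 1
    for _ in range(config.generations):
        if sweep_sites:
            logw = np.zeros(ne)
            for snp, s, _, _ in sweep_sites:
                copies = pop[0::2, snp].astype(np.float64) + pop[1::2, snp]
                logw += copies * np.log1p(s)
            w = np.exp(logw - logw.max())
            probs = w / w.sum()
        else:
            probs = None
        p1 = rng.choice(ne, size=ne, replace=True, p=probs)
        p2 = rng.choice(ne, size=ne, replace=True, p=probs)
        gam1 = _recombine(pop, p1, panel, cm, rng)
        gam2 = _recombine(pop, p2, panel, cm, rng)
        new = np.empty_like(pop)
        new[0::2] = gam1
        new[1::2] = gam2
        pop = new
    final = [float(pop[:, snp].mean()) for snp, *_ in sweep_sites]
    return pop, final


def evolve_lines(panel: BasePanel, config: SimConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Evolve every line independently; returns panels and the sweep truth.

    The truth table records, per (sweep, line), the marker chosen as the
    selected site and the realized final frequency of the favored allele —
    including losses by drift (flag ``lost``).  With
    ``condition_on_establishment`` a line whose favored allele is lost is
    re-evolved from a fresh random substream (up to 20 tries).
    """
    bp = panel.markers["bp"].to_numpy()
    chroms = panel.markers["chrom"].to_numpy()
    sweep_sites: list[tuple[int, SweepSpec]] = []
    for sw in config.sweeps:
        on_chrom = np.nonzero(chroms == str(sw.chrom))[0]
        snp = int(on_chrom[np.argmin(np.abs(bp[on_chrom] - sw.bp))])
        sweep_sites.append((snp, sw))
    root = np.random.SeedSequence([config.seed, 1])
    streams = root.spawn(len(config.line_names) * 21)
    panels: dict[str, np.ndarray] = {}
    truth_rows = []
    for li, line in enumerate(config.line_names):
        sites = [(snp, sw.s, sw.start_freq, sw.core_cm) for snp, sw in sweep_sites if line in sw.lines]
        tries = 0
        while True:
            pop, final = _evolve_one_line(panel, config, line, sites, streams[li * 21 + tries])
            lost = [f == 0.0 for f in final]
            if not (config.condition_on_establishment and any(lost) and tries < 20):
                break
            tries += 1
        panels[line] = pop
        line_sweeps = [(snp, sw) for snp, sw in sweep_sites if line in sw.lines]
        for ((snp, sw), (_, _, start, _), freq) in zip(line_sweeps, sites, final):
            truth_rows.append(
                {
                    "chrom": str(sw.chrom),
                    "bp": int(bp[snp]),
                    "cM": float(panel.markers["cM"].iloc[snp]),
                    "snp_id": panel.markers["id"].iloc[snp],
                    "line": line,
                    "s": sw.s,
                    "start_freq": start,
                    "final_freq": freq,
                    "lost": freq == 0.0,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "bp", "cM", "snp_id", "line", "s", "start_freq", "final_freq", "lost"],
    )
    return panels, truth


@dataclass
class SimResult:
    phased: GenotypeDataset
    unphased: GenotypeDataset
    pedigree: Pedigree | None
    truth: pd.DataFrame
    config: SimConfig
    n_mendel_injected: int = 0

    @property
    def markers(self) -> pd.DataFrame:
        return self.phased.markers

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.config.chrom_lengths)


def sample_and_export(panels: dict[str, np.ndarray], panel: BasePanel, config: SimConfig) -> SimResult:
    """Draw diploid samples per line and build the exportable datasets.

    Two datasets are produced over the same samples: a phased, complete one
    (the substrate of the scans) and an "unphased" copy with genotype-wise
    missingness at ``missing_rate`` plus, optionally, trio children with
    Mendelian errors injected at sites where a parent is homozygous (so each
    injected error is a detectable violation).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cm = panel.markers["cM"].to_numpy()
    samples: list[str] = []
    line_of: dict[str, str] = {}
    call_rows = []
    sampled_haps: dict[str, tuple[list[str], np.ndarray]] = {}
    for line, n_samp in zip(config.line_names, config.samples_per_line):
        pop = panels[line]
        ne = pop.shape[0] // 2
        if n_samp > ne:
            raise ValueError(f"line {line}: requested {n_samp} samples from N_e={ne}")
        picked = rng.choice(ne, size=n_samp, replace=False)
        names = [f"{line}_{i:03d}" for i in range(n_samp)]
        hap_rows = np.empty((2 * n_samp, pop.shape[1]), dtype=np.uint8)
        for j, d in enumerate(picked):
            hap_rows[2 * j] = pop[2 * d]
            hap_rows[2 * j + 1] = pop[2 * d + 1]
            call_rows.append(np.stack([pop[2 * d], pop[2 * d + 1]], axis=1))
        sampled_haps[line] = (names, hap_rows)
        samples.extend(names)
        line_of.update({s: line for s in names})
    calls = np.stack(call_rows, axis=0).astype(np.int8)
    phased = GenotypeDataset(
        samples=list(samples), line_of=dict(line_of), markers=panel.markers.copy(),
        calls=calls, phased=True,
    )

    # unphased copy: missingness, then optional trio children
    un_calls = calls.copy()
    if config.missing_rate > 0:
        mask = rng.random((un_calls.shape[0], un_calls.shape[1])) < config.missing_rate
        un_calls[mask] = -1
    un_samples = list(samples)
    un_line_of = dict(line_of)
    ped_records: list[tuple[str, str, str]] = []
    n_injected = 0
    if config.n_trios_per_line > 0:
        child_rows = []
        for line, _ in zip(config.line_names, config.samples_per_line):
            names, hap_rows = sampled_haps[line]
            if len(names) < 2:
                continue
            for t in range(config.n_trios_per_line):
                sire_i, dam_i = rng.choice(len(names), size=2, replace=False)
                gam = []
                for par_i in (sire_i, dam_i):
                    pair = hap_rows[2 * par_i : 2 * par_i + 2]
                    gam.append(_recombine(pair, np.array([0]), panel, cm, rng)[0])
                child = np.stack(gam, axis=1).astype(np.int8)  # (n_snps, 2)
                if config.mendel_error_rate > 0:
                    sire_g = hap_rows[2 * sire_i].astype(np.int16) + hap_rows[2 * sire_i + 1]
                    dam_g = hap_rows[2 * dam_i].astype(np.int16) + hap_rows[2 * dam_i + 1]
                    hom_parent = (sire_g % 2 == 0) | (dam_g % 2 == 0)
                    eligible = np.nonzero(hom_parent)[0]
                    hit = eligible[rng.random(eligible.size) < config.mendel_error_rate]
                    for snp in hit:
                        ref_g = sire_g[snp] if sire_g[snp] % 2 == 0 else dam_g[snp]
                        bad = 0 if ref_g == 2 else 1
                        child[snp] = (bad, bad)
                    n_injected += hit.size
                cname = f"{line}_trio{t}_child"
                child_rows.append(child)
                un_samples.append(cname)
                un_line_of[cname] = line
                ped_records.append((cname, names[sire_i], names[dam_i]))
        if child_rows:
            un_calls = np.concatenate([un_calls, np.stack(child_rows, axis=0)], axis=0)
    unphased = GenotypeDataset(
        samples=un_samples, line_of=un_line_of, markers=panel.markers.copy(),
        calls=un_calls, phased=False,
    )
    pedigree = Pedigree(ped_records) if ped_records else None
    return SimResult(
        phased=phased, unphased=unphased, pedigree=pedigree,
        truth=pd.DataFrame(), config=config, n_mendel_injected=n_injected,
    )


def simulate_dataset(config: SimConfig) -> SimResult:
    """Base population -> independent line evolution -> sampled datasets."""
    panel = simulate_base(config)
    panels, truth = evolve_lines(panel, config)
    result = sample_and_export(panels, panel, config)
    result.truth = truth
    return result


def write_vcf(ds: GenotypeDataset, path: str) -> None:
    """Write a minimal VCF; phased datasets use '|', unphased '/' with './.'
    for missing genotypes."""
    sep = "|" if ds.phased else "/"
    chrom_max = ds.markers.groupby("chrom", sort=False)["bp"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulator\n")
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ds.samples) + "\n")
        ref = ds.markers["ref"] if "ref" in ds.markers else pd.Series(["A"] * ds.n_snps)
        alt = ds.markers["alt"] if "alt" in ds.markers else pd.Series(["G"] * ds.n_snps)
        for j in range(ds.n_snps):
            row = ds.markers.iloc[j]
            gts = []
            for i in range(ds.n_samples):
                a, b = ds.calls[i, j]
                gts.append("./." if a < 0 or b < 0 else f"{a}{sep}{b}")
            fh.write(
                f"{row['chrom']}\t{row['bp']}\t{row['id']}\t{ref.iloc[j]}\t{alt.iloc[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def export_all(result: SimResult, outdir: str) -> dict[str, str]:
    """Write VCFs, line table, marker map, pedigree, truth and config echo."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "phased_vcf": os.path.join(outdir, "phased.vcf"),
        "unphased_vcf": os.path.join(outdir, "unphased.vcf"),
        "line_table": os.path.join(outdir, "lines.tsv"),
        "marker_map": os.path.join(outdir, "markers.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    write_vcf(result.phased, paths["phased_vcf"])
    write_vcf(result.unphased, paths["unphased_vcf"])
    pd.DataFrame(
        {"sample": result.unphased.samples,
         "line": [result.unphased.line_of[s] for s in result.unphased.samples]}
    ).to_csv(paths["line_table"], sep="\t", header=False, index=False)
    result.markers[["chrom", "id", "bp", "cM"]].to_csv(paths["marker_map"], sep="\t", header=False, index=False)
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        fh.write(result.config.to_json())
    if result.pedigree is not None:
        paths["pedigree"] = os.path.join(outdir, "pedigree.tsv")
        pd.DataFrame(result.pedigree.records, columns=["child", "sire", "dam"]).fillna("0").to_csv(
            paths["pedigree"], sep="\t", header=False, index=False
        )
    return paths
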