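import numpy as np
import pandas as pd
import pytest

from sweepscan.io_qc import GenotypeDataset
from sweepscan.simulate import SimConfig, SweepSpec, simulate_dataset


def make_markers(n: int, chrom: str = "1", spacing_bp: int = 10_000, cm_per_mb: float = 1.0) -> pd.DataFrame:
    bp = (np.arange(n) + 1) * spacing_bp
    return pd.DataFrame(
        {"chrom": chrom, "id": [f"s{i}" for i in range(n)], "bp": bp, "cM": bp * cm_per_mb / 1e6}
    )


def dataset_from_haplotypes(hap_by_line: dict[str, np.ndarray], markers: pd.DataFrame) -> GenotypeDataset:
    """Build a phased dataset from per-line haplotype matrices (rows paired)."""
    samples, line_of, calls = [], {}, []
    for line, haps in hap_by_line.items():
        assert haps.shape[0] % 2 == 0
        for i in range(haps.shape[0] // 2):
            name = f"{line}_{i}"
            samples.append(name)
            line_of[name] = line
            calls.append(np.stack([haps[2 * i], haps[2 * i + 1]], axis=1))
    return GenotypeDataset(
        samples=samples, line_of=line_of, markers=markers,
        calls=np.stack(calls, axis=0).astype(np.int8), phased=True,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A fast 2-chromosome, 3-line neutral simulation shared across tests."""
    config = SimConfig(
        seed=7,
        chrom_lengths={"1": 5_000_000, "2": 5_000_000},
        n_snps=500,
        line_names=("L1", "L2", "L3"),
        ne=60,
        generations=20,
        samples_per_line=(20, 24, 20),
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_sweep_sim():
    """Small simulation with one hard sweep shared by two of three lines."""
    config = SimConfig(
        seed=11,
        chrom_lengths={"1": 5_000_000, "2": 5_000_000},
        n_snps=500,
        line_names=("L1", "L2", "L3"),
        ne=60,
        generations=20,
        samples_per_line=(20, 24, 20),
        sweeps=[SweepSpec("2", 2_500_000, ("L1", "L2"))],
    )
    return simulate_dataset(config)
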