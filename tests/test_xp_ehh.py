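import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sweepscan.xp_ehh import (
    EHHCurve,
    cluster_snps_to_regions,
    ehh_site,
    ihh,
    scan_ihh_chrom,
    xpehh_scan,
)

from conftest import make_markers


def oracle_ehh(haps, core, direction, cm=None):
    """Exhaustive pair-counting EHH decay (independent of the implementation)."""
    n, m = haps.shape
    pos = np.arange(m, dtype=float) if cm is None else np.asarray(cm, float)
    span = range(core, -1, -1) if direction == "left" else range(core, m)
    dists, vals = [], []
    for x in span:
        lo, hi = min(core, x), max(core, x)
        same = 0
        for i, j in itertools.combinations(range(n), 2):
            if np.array_equal(haps[i, lo : hi + 1], haps[j, lo : hi + 1]):
                same += 1
        dists.append(abs(pos[x] - pos[core]))
        vals.append(same / (n * (n - 1) / 2))
    return np.array(dists), np.array(vals)


def oracle_truncated_ihh(dists, vals, comb_vals, floor):
    """Independent trapezoid with the shared combined-sample cut."""
    cut = len(comb_vals)
    for i, v in enumerate(comb_vals):
        if v < floor:
            cut = i
            break
    total = 0.0
    for i in range(1, cut):
        total += (dists[i] - dists[i - 1]) * (vals[i] + vals[i - 1]) / 2.0
    return total


def random_panel(rng, n_max=12, m_max=10):
    n = rng.integers(2, n_max + 1)
    m = rng.integers(2, m_max + 1)
    return rng.integers(0, 2, size=(n, m)).astype(np.uint8)


class TestEhhSite:
    def test_partition_example(self):
        # 6 haplotypes splitting into groups {3,2,1} two markers out
        haps = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 0], [0, 1, 1]], dtype=np.uint8
        )
        curve = ehh_site(haps, 0, "right")
        assert curve.ehh[-1] == pytest.approx(4 / 15)

    def test_identical_haplotypes_stay_at_one(self):
        haps = np.tile(np.array([0, 1, 0, 1], dtype=np.uint8), (5, 1))
        curve = ehh_site(haps, 1, "right")
        assert (curve.ehh == 1.0).all()

    def test_all_singletons_decay_to_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        curve = ehh_site(haps, 0, "right")
        assert curve.ehh[-1] == 0.0

    def test_matches_exhaustive_oracle_and_monotone(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            haps = random_panel(rng)
            core = int(rng.integers(0, haps.shape[1]))
            for direction in ("left", "right"):
                curve = ehh_site(haps, core, direction)
                dists, vals = oracle_ehh(haps, core, direction)
                np.testing.assert_allclose(curve.distances, dists)
                np.testing.assert_array_equal(curve.ehh, vals)
                assert (np.diff(curve.ehh) <= 1e-15).all()

    def test_edge_core_returns_single_point(self):
        haps = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        curve = ehh_site(haps, 0, "left")
        assert len(curve) == 1 and curve.distances[0] == 0.0

    def test_fewer_than_two_haplotypes_is_an_error(self):
        with pytest.raises(ValueError):
            ehh_site(np.array([[0, 1]], dtype=np.uint8), 0, "right")


def curves_for(haps_a, haps_b, core, cm):
    comb = np.vstack([haps_a, haps_b])
    out = []
    for direction in ("left", "right"):
        out.append(ehh_site(haps_a, core, direction, cm))
        out.append(ehh_site(haps_b, core, direction, cm))
        out.append(ehh_site(comb, core, direction, cm))
    # reorder to (a_l, a_r, b_l, b_r, c_l, c_r)
    return out[0], out[3], out[1], out[4], out[2], out[5]


class TestIhh:
    def test_rectangle_area(self):
        # EHH identically 1 over 0.1 cM per side -> iHH = 0.2
        mk = EHHCurve(np.array([0.0, 0.05, 0.1]), np.ones(3), 0, "left")
        a = ihh(mk, mk, mk, mk, mk, mk, ehh_floor=0.05)
        assert a[0] == pytest.approx(0.2) and a[1] == pytest.approx(0.2)

    def test_identical_panels_give_equal_ihh(self):
        rng = np.random.default_rng(11)
        haps = random_panel(rng, 8, 8)
        cm = np.sort(rng.uniform(0, 1, haps.shape[1]))
        core = haps.shape[1] // 2
        args = curves_for(haps, haps.copy(), core, cm)
        ihh_a, ihh_b, _ = ihh(*args)
        assert ihh_a == ihh_b

    def test_matches_independent_integrator(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            haps_a = random_panel(rng, 6, 8)
            haps_b = rng.integers(0, 2, size=(rng.integers(2, 7), haps_a.shape[1])).astype(np.uint8)
            cm = np.sort(rng.uniform(0, 2, haps_a.shape[1]))
            core = int(rng.integers(0, haps_a.shape[1]))
            comb = np.vstack([haps_a, haps_b])
            ihh_a, ihh_b, _ = ihh(*curves_for(haps_a, haps_b, core, cm))
            expect_a = expect_b = 0.0
            for direction in ("left", "right"):
                d, va = oracle_ehh(haps_a, core, direction, cm)
                _, vb = oracle_ehh(haps_b, core, direction, cm)
                _, vc = oracle_ehh(comb, core, direction, cm)
                expect_a += oracle_truncated_ihh(d, va, vc, 0.05)
                expect_b += oracle_truncated_ihh(d, vb, vc, 0.05)
            assert ihh_a == pytest.approx(expect_a, abs=1e-12)
            assert ihh_b == pytest.approx(expect_b, abs=1e-12)


class TestScanKernel:
    def test_kernel_equals_reference_path(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            haps_a = random_panel(rng, 10, 12)
            haps_b = rng.integers(0, 2, size=(rng.integers(2, 11), haps_a.shape[1])).astype(np.uint8)
            cm = np.sort(rng.uniform(0, 3, haps_a.shape[1]))
            vals = scan_ihh_chrom(haps_a, haps_b, cm, ehh_floor=0.05)
            for core in range(haps_a.shape[1]):
                ihh_a, ihh_b, _ = ihh(*curves_for(haps_a, haps_b, core, cm))
                assert vals[core, 0] == pytest.approx(ihh_a, abs=1e-12)
                assert vals[core, 1] == pytest.approx(ihh_b, abs=1e-12)


class TestXpehhScan:
    def _scan(self, seed=14, n=40, m=60):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, m)
        haps_a = (rng.random((n, m)) < p).astype(np.uint8)
        haps_b = (rng.random((n, m)) < p).astype(np.uint8)
        return haps_a, haps_b, make_markers(m)

    def test_log_ratio_value(self):
        assert np.log(0.2 / 0.1) == pytest.approx(0.6931, abs=1e-4)

    def test_antisymmetry_under_population_swap(self):
        haps_a, haps_b, markers = self._scan()
        fwd = xpehh_scan(haps_a, haps_b, markers)
        rev = xpehh_scan(haps_b, haps_a, markers)
        ok = fwd["xpehh_raw"].notna() & rev["xpehh_raw"].notna()
        np.testing.assert_allclose(
            fwd.loc[ok, "xpehh_raw"], -rev.loc[ok, "xpehh_raw"], atol=1e-12
        )

    def test_standardization_and_pvalues(self):
        haps_a, haps_b, markers = self._scan()
        track = xpehh_scan(haps_a, haps_b, markers)
        z = track["xpehh_z"][track["xpehh_raw"].notna()]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(track["pvalue"], norm.sf(track["xpehh_z"]), atol=1e-12)
        assert norm.sf(1.6449) == pytest.approx(0.05, abs=1e-4)

    def test_too_few_scored_snps_is_an_error(self):
        haps = np.zeros((4, 3), dtype=np.uint8)  # monomorphic -> all iHH equal, sd 0
        with pytest.raises(ValueError):
            xpehh_scan(haps, haps, make_markers(3))


class TestClusterRegions:
    def test_threshold_example(self):
        sig = pd.DataFrame({"chrom": "1", "bp": [1_000_000, 1_100_000, 1_500_000]})
        regions = cluster_snps_to_regions(sig, max_gap=200_000)
        assert [(r.start, r.end) for r in regions.itertuples()] == [
            (1_000_000, 1_100_000),
            (1_500_000, 1_500_000),
        ]

    def test_singleton_and_empty(self):
        one = cluster_snps_to_regions(pd.DataFrame({"chrom": ["3"], "bp": [42]}))
        assert one.iloc[0][["start", "end"]].tolist() == [42, 42]
        assert len(cluster_snps_to_regions(pd.DataFrame(columns=["chrom", "bp"]))) == 0

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(15)
        bp = np.sort(rng.choice(np.arange(1, 50_000_000), size=1000, replace=False))
        sig = pd.DataFrame({"chrom": "1", "bp": bp})
        regions = cluster_snps_to_regions(sig, max_gap=200_000)
        # oracle: split wherever the gap is >= the threshold
        expected = []
        start = bp[0]
        prev = bp[0]
        count = 1
        for x in bp[1:]:
            if x - prev >= 200_000:
                expected.append((start, prev, count))
                start, count = x, 0
            prev = x
            count += 1
        expected.append((start, prev, count))
        got = [(r.start, r.end, r.n_snps) for r in regions.itertuples()]
        assert got == expected
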