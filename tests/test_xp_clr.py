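import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from sweepscan.xp_clr import (
    DEFAULT_SWEEP_SCALES,
    DriftParams,
    _tnorm_pdf,
    call_xpclr_regions,
    clr_score,
    estimate_omega,
    ld_weights,
    make_grid,
    xpclr_scan,
)

from conftest import make_markers


class TestGrid:
    def test_counts(self):
        assert len(make_grid(10_000, 2_000)) == 5
        assert make_grid(10_000, 2_000)[0] == 2_000

    def test_degenerate_length_warns(self):
        with pytest.warns(UserWarning):
            assert len(make_grid(1_999, 2_000)) == 0

    def test_chromosome_scale_closed_form(self):
        length = 62_000_000
        assert len(make_grid(length, 2_000)) == length // 2_000


def oracle_weights(haps, cutoff=0.9):
    """Direct pairwise-correlation enumeration."""
    m = haps.shape[1]
    w = np.empty(m)
    for i in range(m):
        k = 0
        for j in range(m):
            xi, xj = haps[:, i].astype(float), haps[:, j].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) >= cutoff:
                k += 1
        w[i] = 1.0 / max(k, 1)
    return w


class TestLdWeights:
    def test_uncorrelated_snps_weight_one(self):
        rng = np.random.default_rng(20)
        haps = rng.integers(0, 2, size=(200, 5)).astype(np.uint8)
        # with 200 haplotypes random columns are far below |r| = 0.9
        np.testing.assert_array_equal(ld_weights(haps), np.ones(5))

    def test_duplicated_snp_pair(self):
        rng = np.random.default_rng(21)
        col = rng.integers(0, 2, size=20).astype(np.uint8)
        other = rng.integers(0, 2, size=20).astype(np.uint8)
        haps = np.stack([col, col, other], axis=1)
        np.testing.assert_allclose(ld_weights(haps), [0.5, 0.5, 1.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(rng.integers(4, 30), 10)).astype(np.uint8)
            np.testing.assert_allclose(ld_weights(haps), oracle_weights(haps))

    def test_monomorphic_snp_gets_weight_one(self):
        haps = np.zeros((10, 3), dtype=np.uint8)
        haps[:5, 1] = 1
        haps[:5, 2] = 1
        w = ld_weights(haps)
        assert w[0] == 1.0 and w[1] == 0.5 and w[2] == 0.5


class TestOmega:
    def test_equal_frequencies_give_zero(self):
        p = np.linspace(0.1, 0.9, 500)
        drift = estimate_omega(p, p, 10_000_000, 10_000_000)
        assert drift.omega == 0.0

    def test_simulation_recovery(self):
        rng = np.random.default_rng(23)
        m, omega_true = 20_000, 0.02
        p_b = rng.uniform(0.1, 0.9, m)
        sd = np.sqrt(omega_true * p_b * (1 - p_b))
        a, b = (0 - p_b) / sd, (1 - p_b) / sd
        p_a = truncnorm.rvs(a, b, loc=p_b, scale=sd, random_state=rng)
        drift = estimate_omega(p_a, p_b, 10_000_000, 10_000_000)
        assert drift.omega == pytest.approx(omega_true, rel=0.10)

    def test_raw_moment_arithmetic(self):
        with pytest.warns(UserWarning):  # single eligible SNP
            drift = estimate_omega(np.array([0.6]), np.array([0.5]), 10**12, 10**12)
        assert drift.omega == pytest.approx(0.01 / 0.25, abs=1e-9)

    def test_no_eligible_snps_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_omega(np.array([0.5]), np.array([1.0]), 100, 100)


def oracle_clr(p_a, p_b, w, d, omega, n_a, scales, eps=0.02):
    """Straightforward re-evaluation of the drift-vs-sweep mixture."""
    def tn(x, mu, sigma):
        alpha, beta = (0 - mu) / sigma, (1 - mu) / sigma
        return truncnorm.pdf(x, alpha, beta, loc=mu, scale=sigma)

    best = 0.0
    best_s = float("nan")
    for s in scales:
        total = 0.0
        for i in range(len(p_a)):
            if not 0 < p_b[i] < 1:
                continue
            var = omega * p_b[i] * (1 - p_b[i]) + p_b[i] * (1 - p_b[i]) / n_a
            f0 = tn(p_a[i], p_b[i], np.sqrt(var))
            bmix = p_b[i] * tn(p_a[i], 1.0, eps) + (1 - p_b[i]) * tn(p_a[i], 0.0, eps)
            c = 1 - np.exp(-d[i] / s)
            total += w[i] * (np.log(c * f0 + (1 - c) * bmix) - np.log(f0))
        if total > best:
            best, best_s = total, s
    return 2 * best, best_s


class TestClrScore:
    drift = DriftParams(omega=0.05, n_a=60, n_b=60)

    def test_identical_frequencies_score_zero(self):
        p = np.linspace(0.2, 0.8, 12)
        d = np.linspace(0.01, 0.25, 12)
        score, scale = clr_score(p, p, np.ones(12), d, self.drift)
        assert score == 0.0 and np.isnan(scale)

    def test_shifted_window_scores_positive_and_matches_oracle(self):
        rng = np.random.default_rng(24)
        p_b = rng.uniform(0.3, 0.7, 10)
        p_a = np.full(10, 0.99)
        w = rng.uniform(0.5, 1.0, 10)
        d = rng.uniform(0.01, 0.25, 10)
        score, scale = clr_score(p_a, p_b, w, d, self.drift)
        exp_score, exp_scale = oracle_clr(p_a, p_b, w, d, self.drift.omega, self.drift.n_a, DEFAULT_SWEEP_SCALES)
        assert score > 0 and np.isfinite(scale)
        assert score == pytest.approx(exp_score, rel=1e-6)
        assert scale == pytest.approx(exp_scale)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(25)
        p_b = rng.uniform(0.2, 0.8, 8)
        p_a = np.clip(p_b + rng.normal(0, 0.3, 8), 0, 1)
        w = np.ones(8)
        d = rng.uniform(0.01, 0.25, 8)
        full, _ = clr_score(p_a, p_b, w, d, self.drift)
        half, _ = clr_score(p_a, p_b, w / 2, d, self.drift)
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_degenerate_reference_frequencies_score_zero(self):
        p_b = np.array([0.0, 1.0, 1.0])
        score, scale = clr_score(np.array([0.5, 0.5, 0.5]), p_b, np.ones(3), np.full(3, 0.1), self.drift)
        assert score == 0.0 and np.isnan(scale)

    def test_densities_normalize(self):
        x = np.linspace(0, 1, 20_001)
        for mu, sigma in ((0.5, 0.1), (0.0, 0.02), (1.0, 0.02), (0.3, 0.25)):
            area = np.trapezoid(_tnorm_pdf(x, mu, sigma), x)
            assert area == pytest.approx(1.0, abs=1e-6)
        # f1 is a convex mixture of normalized densities, hence normalized
        for c, p_b in ((0.3, 0.4), (0.9, 0.8)):
            f0 = _tnorm_pdf(x, p_b, 0.1)
            bmix = p_b * _tnorm_pdf(x, 1.0, 0.02) + (1 - p_b) * _tnorm_pdf(x, 0.0, 0.02)
            assert np.trapezoid(c * f0 + (1 - c) * bmix, x) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_as_frequencies_approach_fixation(self):
        p_b = np.full(10, 0.5)
        d = np.full(10, 0.05)
        w = np.ones(10)
        scores = []
        for shift in (0.6, 0.7, 0.8, 0.9, 0.99):
            score, _ = clr_score(np.full(10, shift), p_b, w, d, self.drift)
            scores.append(score)
        assert (np.diff(scores) >= 0).all()

    def test_symmetric_under_allele_relabeling(self):
        rng = np.random.default_rng(26)
        p_b = rng.uniform(0.2, 0.8, 10)
        p_a = np.clip(p_b + rng.normal(0, 0.2, 10), 0, 1)
        w = rng.uniform(0.3, 1.0, 10)
        d = rng.uniform(0.01, 0.25, 10)
        s1, _ = clr_score(p_a, p_b, w, d, self.drift)
        s2, _ = clr_score(1 - p_a, 1 - p_b, w, d, self.drift)
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestScan:
    def test_zero_when_focal_equals_reference(self, small_sim):
        ds = small_sim.phased
        haps = ds.haplotypes("L1")
        track = xpclr_scan(haps, haps.copy(), ds.markers, drift=DriftParams(0.05, haps.shape[0], haps.shape[0]))
        scored = track["clr"].dropna()
        assert (scored >= 0).all()
        # near-fixed reference SNPs leave a tiny boundary-component residue
        # (see the methods note); everywhere else the no-sweep model wins
        assert scored.median() == 0.0
        assert scored.max() < 0.1

    def test_scan_matches_per_window_path(self, small_sim):
        ds = small_sim.phased
        haps_a, haps_b = ds.haplotypes("L1"), ds.haplotypes("L2")
        drift = estimate_omega(haps_a.mean(0), haps_b.mean(0), haps_a.shape[0], haps_b.shape[0])
        track = xpclr_scan(haps_a, haps_b, ds.markers, grid_spacing=100_000, drift=drift)
        markers = ds.markers
        p_a, p_b = haps_a.mean(0), haps_b.mean(0)
        rng = np.random.default_rng(27)
        rows = track.dropna(subset=["clr"]).sample(25, random_state=3)
        for row in rows.itertuples():
            grp = markers[markers["chrom"] == row.chrom]
            cm = grp["cM"].to_numpy()
            sel = np.abs(cm - row.grid_cM) <= 0.25
            idx = grp.index.to_numpy()[sel]
            w = ld_weights(haps_b[:, idx])
            score, _ = clr_score(
                p_a[idx], p_b[idx], w, np.abs(cm[sel] - row.grid_cM), drift
            )
            assert row.clr == pytest.approx(score, rel=2e-3, abs=2e-3)

    def test_output_is_labelled(self, small_sim):
        ds = small_sim.phased
        track = xpclr_scan(ds.haplotypes("L1"), ds.haplotypes("L2"), ds.markers, grid_spacing=500_000)
        assert track.attrs["method"] == "XP-CLR-style"


class TestCallRegions:
    def _track(self, clr, cm=None, chrom="1"):
        n = len(clr)
        cm = np.arange(n, dtype=float) / 10 if cm is None else np.asarray(cm, float)
        return pd.DataFrame(
            {"chrom": chrom, "grid_bp": (cm * 1e6).astype(int), "grid_cM": cm,
             "n_snps": 5, "clr": clr, "argmax_scale": 1.0, "comparison": "x"}
        )

    def test_top_half_percent_of_1000(self):
        rng = np.random.default_rng(28)
        clr = rng.permutation(np.arange(1000, dtype=float))
        track = self._track(clr)
        regions = call_xpclr_regions(track)
        assert regions["n_windows"].sum() == 5

    def test_one_cm_cluster_rule(self):
        track = self._track([10.0, 9.0, 8.0], cm=[10.0, 10.4, 12.0])
        regions = call_xpclr_regions(track, top_fraction=1.0, cluster_gap_cm=1.0)
        assert len(regions) == 2
        assert regions.iloc[0][["start", "end"]].tolist() == [10_000_000, 10_400_000]

    def test_matches_quantile_partition_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            clr = rng.exponential(1.0, 400)
            cm = np.sort(rng.uniform(0, 40, 400))
            track = self._track(clr, cm=cm)
            regions = call_xpclr_regions(track, top_fraction=0.02)
            thr = np.quantile(clr, 0.98, method="midpoint")
            kept = np.nonzero(clr >= thr)[0]
            expected = []
            block = [kept[0]]
            for i in kept[1:]:
                if cm[i] - cm[block[-1]] < 1.0:
                    block.append(i)
                else:
                    expected.append(block)
                    block = [i]
            expected.append(block)
            got = [(r.start, r.end, r.n_windows) for r in regions.itertuples()]
            want = [
                (int(cm[b[0]] * 1e6), int(cm[b[-1]] * 1e6), len(b)) for b in expected
            ]
            assert got == want

    def test_all_zero_scores_warn_and_return_empty(self):
        with pytest.warns(UserWarning):
            regions = call_xpclr_regions(self._track([0.0, 0.0, 0.0]))
        assert len(regions) == 0
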