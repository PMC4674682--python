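"""F_ST, LSBL, EHH/iHS, LD pruning and tail flags."""

import numpy as np
import pytest

from popepimeth.selscan import (
    ehh,
    ihs,
    ld_prune,
    lsbl,
    pairwise_r2,
    standardize_ihs,
    top_tail_flags,
    weir_cockerham_fst,
)


def _dosages_from_counts(n_ref, n_alt, n_het, n_dip):
    """Deterministic dosage vector with given allele/het composition."""
    n_hom_alt = (n_alt - n_het) // 2
    n_hom_ref = n_dip - n_het - n_hom_alt
    return np.array([0] * n_hom_ref + [1] * n_het + [2] * n_hom_alt, dtype=float)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        a = np.full((10, 1), 2.0)
        b = np.zeros((10, 1))
        assert weir_cockerham_fst(a, b)[0] == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self, rng):
        g = rng.binomial(2, 0.4, size=(30, 50)).astype(float)
        theta = weir_cockerham_fst(g, g.copy())
        assert np.nanmax(theta) <= 0

    def test_matches_independent_component_formulas(self):
        # population A: 15 diploids, 10 alt alleles, of which 4 heterozygotes;
        # population B: 15 diploids, 22 alt alleles, 6 heterozygotes
        a = _dosages_from_counts(20, 10, 4, 15)[:, None]
        b = _dosages_from_counts(8, 22, 6, 15)[:, None]
        theta = weir_cockerham_fst(a, b)[0]

        # independent long-hand evaluation of the a/b/c variance components
        r, n1, n2 = 2.0, 15.0, 15.0
        p1, p2 = 10 / 30, 22 / 30
        h1, h2 = 4 / 15, 6 / 15
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a_comp = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c_comp = hbar / 2
        assert theta == pytest.approx(a_comp / (a_comp + b_comp + c_comp), abs=1e-12)

    def test_monomorphic_in_both_is_missing(self):
        a = np.zeros((5, 1))
        b = np.zeros((5, 1))
        assert np.isnan(weir_cockerham_fst(a, b)[0])

    def test_balding_nichols_mean_theta(self, rng):
        # mean Weir-Cockerham theta over Balding-Nichols SNPs at F=0.05
        n_snps, n_dip, F = 10_000, 50, 0.05
        p = rng.uniform(0.1, 0.9, n_snps)
        c = (1 - F) / F
        pa = rng.beta(p * c, (1 - p) * c)
        pb = rng.beta(p * c, (1 - p) * c)
        ga = rng.binomial(2, pa, size=(n_dip, n_snps)).astype(float)
        gb = rng.binomial(2, pb, size=(n_dip, n_snps)).astype(float)
        theta = weir_cockerham_fst(ga, gb)
        assert 0.04 <= np.nanmean(theta) <= 0.06


class TestLsbl:
    def test_arithmetic_example(self):
        a, b, c = lsbl(np.array([0.2]), np.array([0.3]), np.array([0.1]))
        assert a[0] == pytest.approx(0.2)
        assert b[0] == pytest.approx(0.0)
        assert c[0] == pytest.approx(0.1)

    def test_symmetric_star(self):
        d = np.array([0.3])
        a, b, c = lsbl(d, d, d)
        for branch in (a, b, c):
            assert branch[0] == pytest.approx(0.15)

    def test_additivity_identity_exact(self, rng):
        f_ab = rng.uniform(0, 0.5, 1000)
        f_ac = rng.uniform(0, 0.5, 1000)
        f_bc = rng.uniform(0, 0.5, 1000)
        a, b, _ = lsbl(f_ab, f_ac, f_bc)
        np.testing.assert_allclose(a + b, f_ab, atol=1e-10)

    def test_missing_propagates(self):
        a, _, _ = lsbl(np.array([np.nan]), np.array([0.1]), np.array([0.1]))
        assert np.isnan(a[0])


class TestEhh:
    def test_focal_point_is_one(self, rng):
        haps = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        haps[:, 15] = np.repeat([0, 1], 10)
        pos = np.arange(30) * 1000.0
        curve = ehh(haps, pos, 15, 1)
        assert curve.left[0, 1] == 1.0
        assert curve.right[0, 1] == 1.0

    def test_four_carrier_example(self):
        # carriers read AB, AB, AC, AB over the two downstream SNPs:
        # after SNP2 only the three AB pairs remain identical -> 3/6
        haps = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, 0, 1],
                [1, 0, 0],
            ],
            dtype=np.int8,
        )
        pos = np.array([0.0, 100.0, 200.0])
        curve = ehh(haps, pos, 0, 1)
        assert curve.right[1, 1] == pytest.approx(1.0)   # after SNP1: all same
        assert curve.right[2, 1] == pytest.approx(0.5)   # 3 of 6 pairs

    def test_identical_carriers_stay_at_one(self):
        haps = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.int8), (6, 1))
        pos = np.arange(5) * 10.0
        curve = ehh(haps, pos, 2, 1)
        assert np.all(curve.left[:, 1] == 1.0)
        assert np.all(curve.right[:, 1] == 1.0)

    def test_monotone_nonincreasing(self, rng):
        haps = rng.integers(0, 2, size=(40, 100)).astype(np.int8)
        haps[:20, 50] = 1
        haps[20:, 50] = 0
        pos = np.sort(rng.choice(100_000, 100, replace=False)).astype(float)
        curve = ehh(haps, pos, 50, 1)
        for arr in (curve.left, curve.right):
            assert np.all(np.diff(arr[:, 1]) <= 1e-12)

    def test_too_few_carriers(self, rng):
        haps = np.zeros((10, 5), dtype=np.int8)
        haps[0, 2] = 1
        with pytest.raises(ValueError, match="carriers"):
            ehh(haps, np.arange(5.0), 2, 1)


class TestIhs:
    def test_symmetric_classes_give_zero(self):
        # ancestral and derived carriers with mirror-identical structure
        block = np.array([[0, 1, 0, 1, 0], [0, 1, 1, 1, 0], [1, 0, 0, 0, 1]],
                         dtype=np.int8)
        haps = np.vstack([block, block])
        haps[:3, 2] = 0
        haps[3:, 2] = 1
        pos = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        out = ihs(haps, pos, ehh_cutoff=0.9, snp_indices=[2])
        val = out["ihs_unstd"].iloc[0]
        if np.isfinite(val):
            assert val == pytest.approx(0.0, abs=1e-12)

    def test_toy_trapezoid_areas(self):
        # hand-checkable panel: 6 haplotypes, 5 SNPs, focal in the middle
        haps = np.array(
            [
                [0, 0, 1, 0, 1],
                [0, 0, 1, 0, 0],
                [1, 0, 1, 1, 0],
                [0, 1, 0, 0, 1],
                [1, 1, 0, 1, 0],
                [0, 0, 0, 1, 0],
            ],
            dtype=np.int8,
        )
        pos = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        out = ihs(haps, pos, ehh_cutoff=0.3, max_gap=1e9, snp_indices=[2])

        def brute_ehh(sub, cols):
            n = sub.shape[0]
            pairs = n * (n - 1) / 2
            same = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if np.array_equal(sub[i, cols], sub[j, cols]):
                        same += 1
            return same / pairs

        derived = haps[haps[:, 2] == 1]
        ancestral = haps[haps[:, 2] == 0]

        def area(sub, direction):
            cols_steps = [[1], [1, 0]] if direction == "left" else [[3], [3, 4]]
            xs, es = [0.0], [1.0]
            for k, cols in enumerate(cols_steps, start=1):
                e = brute_ehh(sub, cols)
                xs.append(100.0 * k)
                es.append(e)
                if e < 0.3:
                    break
            return np.trapezoid(es, xs), es[-1] < 0.3

        ihh = {}
        ok = True
        for name, sub in (("D", derived), ("A", ancestral)):
            aL, okL = area(sub, "left")
            aR, okR = area(sub, "right")
            ihh[name] = aL + aR
            ok &= okL and okR
        if ok:
            expected = np.log(ihh["A"] / ihh["D"])
            assert out["ihs_unstd"].iloc[0] == pytest.approx(expected, abs=1e-10)
        else:
            assert out["reason"].iloc[0] == "ehh-no-decay"

    def test_sweep_inflates_derived_homozygosity(self, rng):
        from popepimeth.simulate import inject_sweep, simulate_haplotypes

        n_snps = 400
        pos = np.arange(1, n_snps + 1) * 1000.0
        haps = simulate_haplotypes(np.full(n_snps, 0.5), 60, pos, 1e-4, rng)
        swept, _ = inject_sweep(haps, pos, 200, 0.5, 100_000, rng)
        out = ihs(swept, pos, snp_indices=[200])
        assert out["ihs_unstd"].iloc[0] < 0  # iHH_D inflated

    def test_monomorphic_skipped_with_reason(self):
        haps = np.zeros((10, 3), dtype=np.int8)
        out = ihs(haps, np.arange(3.0), snp_indices=[1])
        assert out["reason"].iloc[0] == "monomorphic"


class TestStandardize:
    def test_two_score_bin_uses_n_minus_one(self):
        x = np.array([-1.0, 1.0])
        d = np.array([0.5, 0.5])
        out = standardize_ihs(x, d)
        np.testing.assert_allclose(out, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_populated_bins_standardized(self, rng):
        x = rng.normal(size=5000)
        d = rng.uniform(0.01, 0.99, 5000)
        out = standardize_ihs(x, d)
        bins = np.minimum((d / 0.025).astype(int), 39)
        for b in np.unique(bins):
            m = (bins == b) & np.isfinite(out)
            if m.sum() >= 2:
                assert abs(out[m].mean()) < 1e-10
                assert out[m].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_left_closed_bin_boundary(self):
        # DAF exactly 0.025 belongs to the second bin [0.025, 0.05)
        x = np.array([1.0, 2.0, 0.0, -1.0])
        d = np.array([0.025, 0.03, 0.01, 0.02])
        out = standardize_ihs(x, d)
        # first two share a bin, last two share the first bin
        assert out[0] == pytest.approx(-1 / np.sqrt(2))
        assert out[2] == pytest.approx(1 / np.sqrt(2))

    def test_singleton_bin_missing(self):
        out = standardize_ihs(np.array([1.0]), np.array([0.6]))
        assert np.isnan(out[0])


class TestLdPrune:
    def test_identical_snps_keep_first(self, rng):
        g = rng.binomial(2, 0.5, size=(40, 1)).astype(float)
        G = np.hstack([g, g, g])
        keep = ld_prune(G)
        assert keep.tolist() == [True, False, False]

    def test_independent_snps_all_kept(self, rng):
        G = rng.binomial(2, 0.5, size=(200, 30)).astype(float)
        assert ld_prune(G).sum() == 30

    def test_matches_quadratic_reference(self, rng):
        G = rng.binomial(2, 0.4, size=(60, 200)).astype(float)
        # add LD blocks
        for j in range(0, 200, 17):
            if j + 2 < 200:
                G[:, j + 1] = G[:, j]
                flip = rng.random(60) < 0.05
                G[flip, j + 1] = rng.binomial(2, 0.4, flip.sum())
        fast = ld_prune(G, window_snps=50, step_snps=5, r2_threshold=0.8)

        def reference(G, window, step, thr):
            n = G.shape[1]
            keep = np.ones(n, bool)
            start = 0
            while True:
                win = list(range(start, min(start + window, n)))
                for ii, i in enumerate(win):
                    if not keep[i] or np.std(G[:, i]) == 0:
                        continue
                    for j in win[ii + 1:]:
                        if not keep[j] or np.std(G[:, j]) == 0:
                            continue
                        r = np.corrcoef(G[:, i], G[:, j])[0, 1]
                        if r * r > thr:
                            keep[j] = False
                if start + window >= n:
                    break
                start += step
            return keep

        slow = reference(G, 50, 5, 0.8)
        np.testing.assert_array_equal(fast, slow)

    def test_pairwise_r2_helper(self, rng):
        G = rng.binomial(2, 0.5, size=(50, 6)).astype(float)
        rr = pairwise_r2(G, np.array([0, 1]), np.array([2, 3, 4]))
        for i, a in enumerate([0, 1]):
            for j, b in enumerate([2, 3, 4]):
                expected = np.corrcoef(G[:, a], G[:, b])[0, 1] ** 2
                assert rr[i, j] == pytest.approx(expected, abs=1e-12)


class TestTailFlags:
    def test_exactly_five_percent_flagged(self, rng):
        scores = rng.permutation(100).astype(float)
        flags = top_tail_flags(scores, 0.05)
        assert flags.sum() == 5
        assert scores[flags].min() >= np.quantile(scores, 0.95)

    def test_all_equal_all_flagged(self):
        flags = top_tail_flags(np.full(50, 3.0))
        assert flags.all()

    def test_nan_never_flagged(self, rng):
        scores = rng.normal(size=100)
        scores[::10] = np.nan
        flags = top_tail_flags(scores)
        assert not flags[::10].any()

    def test_absolute_mode(self, rng):
        scores = np.concatenate([np.zeros(95), [-10, -9, 8, 9, 10]])
        flags = top_tail_flags(scores, 0.05, absolute=True)
        assert flags[-5:].all() and flags[:95].sum() == 0

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            top_tail_flags(np.arange(10.0))
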