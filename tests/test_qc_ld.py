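"""QC filters, the exact HWE test, the r² engine and the decay fit.

Oracles: HWE against exact-rational full enumeration; r² against direct
haplotype counting on phase-unambiguous constructions; decay fit against
the generating curve.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusemap as fm
from fusemap.ld import IllConditionedFit, r2_for_pairs
from fusemap.qc import EmptyAfterQC, QCParams, apply_qc, hwe_exact_pvalue


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational brute force: enumerate every heterozygote count
    compatible with the allele counts and sum P(config) <= P(observed)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def weight(h):
        # multinomial x 2^h, conditional on allele counts (common factor
        # cancels in the normalization)
        ra = (na - h) // 2
        rb = n - ra - h
        return Fraction(
            2 ** h * comb(n, ra) * comb(n - ra, h)
        )

    hs = [h for h in range(min(na, 2 * n - na) + 1)
          if (na - h) % 2 == 0 and n - (na - h) // 2 - h >= 0]
    ws = {h: weight(h) for h in hs}
    total = sum(ws.values())
    obs = ws[n_ab]
    return float(sum(w for w in ws.values() if w <= obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 0, 0), 1.0),        # no variation
            ((25, 50, 25), 1.0),       # observed het count is modal
        ],
    )
    def test_known_values(self, counts, expected):
        assert hwe_exact_pvalue(*counts) == pytest.approx(expected)

    def test_extreme_het_deficit(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-6

    def test_matches_enumeration_all_small_configs(self):
        """Agreement with the exact-rational oracle for every genotype
        configuration with n <= 20 plus a seeded sample up to n = 50."""
        for n in range(1, 21):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_pvalue(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, rel=1e-9), (
                        n_aa, n_ab, n_bb,
                    )
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(21, 51))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert hwe_exact_pvalue(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-9
            )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def matrix_from_columns(cols):
    cols = [np.asarray(c, dtype=np.int8) for c in cols]
    m = fm.MarkerMap.from_arrays(
        [f"m{k}" for k in range(len(cols))],
        ["1"] * len(cols),
        np.arange(1, len(cols) + 1) * 1000,
    )
    return fm.GenotypeMatrix(
        [f"s{i}" for i in range(len(cols[0]))], m, np.stack(cols, axis=1)
    )


class TestApplyQC:
    def test_filters(self):
        n = 100
        rng = np.random.default_rng(3)
        good = rng.binomial(2, 0.4, size=n)
        low_call = good.copy()
        low_call[:10] = -1                      # 10% missing
        mono = np.zeros(n, dtype=int)           # MAF 0
        hwe_fail = np.array([0] * 50 + [2] * 50)  # (50, 0, 50): no hets
        g = matrix_from_columns([good, low_call, mono, hwe_fail])
        out, report = apply_qc(g, QCParams())
        assert list(out.markers.ids) == ["m0"]
        assert report.n_fail_call_rate == 1
        assert report.n_fail_maf >= 1
        assert report.n_fail_hwe >= 1
        assert set(report.removed_ids) == {"m1", "m2", "m3"}

    def test_strict_inequality_boundary(self):
        # call rate exactly at threshold is removed (strict >)
        col = np.array([1] * 95 + [-1] * 5)
        ok = np.tile([0, 1, 2, 1], 25)
        g = matrix_from_columns([col, ok])
        out, report = apply_qc(g, QCParams(min_call_rate=0.95, hwe_p_min=0.0))
        assert "m0" in report.removed_ids

    def test_empty_after_qc(self):
        g = matrix_from_columns([np.zeros(10, dtype=int)])
        with pytest.raises(EmptyAfterQC):
            apply_qc(g)


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def genotypes_from_haplotype_counts(counts):
    """Build phase-unambiguous diploids from haplotype counts over
    (AB, Ab, aB, ab): pair identical haplotypes so no double hets arise."""
    haps = []
    for h, c in zip([(1, 1), (1, 0), (0, 1), (0, 0)], counts):
        haps += [h] * c
    haps = np.array(haps)
    assert len(haps) % 2 == 0
    g = haps[0::2] + haps[1::2]
    m = fm.MarkerMap.from_arrays(["a", "b"], ["1", "1"], [1000, 2000])
    return fm.GenotypeMatrix(
        [f"s{i}" for i in range(len(g))], m, g.astype(np.int8)
    )


class TestPairwiseR2:
    def test_duplicated_column_gives_one(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.5, 50)
        g = matrix_from_columns([col, col.copy()])
        for est in ("em", "composite"):
            out = fm.pairwise_r2(g, estimator=est)
            assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_haplotype_frequency_example(self):
        """Haplotype frequencies (0.4, 0.1, 0.1, 0.4) give D = 0.15 and
        r² = 0.36, recovered exactly from phase-unambiguous genotypes."""
        # 40 haplotypes: counts 16, 4, 4, 16; identical pairs -> 20 diploids
        g = genotypes_from_haplotype_counts([16, 4, 4, 16])
        out = fm.pairwise_r2(g, estimator="em")
        assert out["r2"].iloc[0] == pytest.approx(0.36, abs=1e-9)

    def test_em_equals_direct_counting_without_double_hets(self):
        """With no double heterozygotes the EM likelihood has no ambiguity:
        r² equals direct haplotype counting."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.multinomial(30, [0.3, 0.2, 0.3, 0.2]) * 2
            haps = []
            for h, c in zip([(1, 1), (1, 0), (0, 1), (0, 0)], counts):
                haps += [h] * c
            haps = np.array(haps)
            f = counts / counts.sum()
            pa, pb = f[0] + f[1], f[0] + f[2]
            if not (0 < pa < 1 and 0 < pb < 1):
                continue
            d = f[0] - pa * pb
            want = d * d / (pa * (1 - pa) * pb * (1 - pb))
            g = genotypes_from_haplotype_counts(list(counts))
            got = fm.pairwise_r2(g, estimator="em")["r2"].iloc[0]
            assert got == pytest.approx(want, abs=1e-8)

    def test_symmetry_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.4, size=(40, 6)).astype(np.int8)
        m = fm.MarkerMap.from_arrays(
            [f"m{k}" for k in range(6)], ["1"] * 3 + ["2"] * 3,
            [1, 2, 3, 1, 2, 3],
        )
        g = fm.GenotypeMatrix([f"s{i}" for i in range(40)], m, calls)
        a = fm.pairwise_r2(g)
        perm = rng.permutation(40)
        b = fm.pairwise_r2(g.subset(sample_idx=perm))
        assert np.allclose(a["r2"], b["r2"], atol=1e-9)
        assert ((a["r2"] >= 0) & (a["r2"] <= 1)).all()
        # each unordered pair appears once
        assert len(a) == 15
        assert (a["i"] < a["j"]).all()

    def test_independent_loci_mean_near_one_over_n(self):
        """Sampling theory: r² between independent loci has mean ~ 1/n."""
        rng = np.random.default_rng(42)
        n, reps = 300, 1000
        calls = rng.binomial(
            2, rng.uniform(0.2, 0.8, size=2 * reps), size=(n, 2 * reps)
        ).astype(np.int8)
        m = fm.MarkerMap.from_arrays(
            [f"m{k}" for k in range(2 * reps)],
            ["1"] * (2 * reps),
            np.arange(2 * reps) + 1,
        )
        g = fm.GenotypeMatrix([f"s{i}" for i in range(n)], m, calls)
        r2 = r2_for_pairs(g, np.arange(0, 2 * reps, 2), np.arange(1, 2 * reps, 2))
        se = r2.std() / np.sqrt(reps)
        assert abs(r2.mean() - 1 / n) < 3 * se + 1e-4

    def test_scope_filters(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.5, size=(30, 4)).astype(np.int8)
        m = fm.MarkerMap.from_arrays(
            ["a", "b", "c", "d"], ["1", "1", "2", "2"], [1, 2, 1, 2]
        )
        g = fm.GenotypeMatrix([f"s{i}" for i in range(30)], m, calls)
        assert len(fm.pairwise_r2(g, scope="intra")) == 2
        assert len(fm.pairwise_r2(g, scope="inter")) == 4
        intra = fm.pairwise_r2(g, scope="intra")
        assert intra["dist_bp"].notna().all()
        inter = fm.pairwise_r2(g, scope="inter")
        assert inter["dist_bp"].isna().all()


# ---------------------------------------------------------------------------
# Hill–Weir expectation and decay fit
# ---------------------------------------------------------------------------

class TestHillWeir:
    def test_hand_value_c0_n100(self):
        # (10/22) * (1 + 36/2200)
        assert fm.expected_r2_hill_weir(0, 100) == pytest.approx(
            0.4619835, abs=1e-6
        )

    def test_large_c_tends_to_one_over_n(self):
        for n in (10, 100, 1000):
            assert fm.expected_r2_hill_weir(1e9, n) == pytest.approx(
                1 / n, rel=1e-3
            )

    def test_monotone_decreasing_in_c_increasing_in_inv_n(self):
        c = np.linspace(0, 1e4, 2000)
        vals = fm.expected_r2_hill_weir(c, 50)
        assert (np.diff(vals) < 0).all()
        assert (
            fm.expected_r2_hill_weir(5.0, 20)
            > fm.expected_r2_hill_weir(5.0, 200)
        )


def pairs_frame(dist, r2):
    import pandas as pd

    return pd.DataFrame(
        {"dist_bp": np.asarray(dist, float), "r2": np.asarray(r2, float)}
    )


class TestDecayFit:
    def test_noiseless_recovery(self):
        beta = 1e-5
        d = np.linspace(1e3, 2e6, 50)
        fit = fm.fit_ld_decay(
            pairs_frame(d, fm.expected_r2_hill_weir(beta * d, 100)), n=100
        )
        assert fit.converged
        assert fit.beta == pytest.approx(beta, rel=1e-8)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(99)
        beta = 1e-5
        d = rng.uniform(1e3, 4e6, 5000)
        r2 = fm.expected_r2_hill_weir(beta * d, 100) + rng.normal(0, 0.05, 5000)
        fit = fm.fit_ld_decay(pairs_frame(d, r2), n=100)
        assert abs(fit.beta - beta) / beta < 0.10

    def test_single_distance_ill_conditioned(self):
        with pytest.raises(IllConditionedFit):
            fm.fit_ld_decay(
                pairs_frame([1000] * 12, [0.5] * 12), n=100
            )

    def test_too_few_pairs_undefined(self):
        assert fm.fit_ld_decay(pairs_frame([1e3, 2e3], [0.4, 0.3]), n=50) is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    p=st.floats(0.1, 0.9),
    q=st.floats(0.1, 0.9),
    seed=st.integers(0, 2**16),
)
def test_r2_allele_flip_invariance(p, q, seed):
    """Flipping the allele labels at either locus never changes r²."""
    rng = np.random.default_rng(seed)
    calls = np.stack(
        [rng.binomial(2, p, 60), rng.binomial(2, q, 60)], axis=1
    ).astype(np.int8)
    m = fm.MarkerMap.from_arrays(["a", "b"], ["1", "1"], [1, 2])
    g = fm.GenotypeMatrix([f"s{i}" for i in range(60)], m, calls)
    base = fm.pairwise_r2(g)["r2"]
    if len(base) == 0:  # monomorphic draw
        return
    for flip in ([0], [1], [0, 1]):
        r = fm.pairwise_r2(g.flip_alleles(np.array(flip)))["r2"]
        assert np.allclose(base, r, atol=1e-9)
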