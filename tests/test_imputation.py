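"""Masking scenarios, fold splits, baseline imputer, accuracy metrics,
ANOVA/Tukey group comparison."""

import numpy as np
import pandas as pd
import pytest

import fusemap as fm
from fusemap.imputation import group_comparison


def linear_map(n, chrom="1", start=1000, step=1000):
    return fm.MarkerMap.from_arrays(
        [f"m{k}" for k in range(n)], [chrom] * n,
        start + step * np.arange(n),
    )


class TestMaskScenarios:
    def test_equidistant_pattern(self):
        m = linear_map(100)
        scens = fm.make_mask_scenarios(m, fractions=(0.10,), seed=0)
        s = scens[0]
        idx = m.index_of(s.retained_marker_ids)
        assert (np.diff(idx) == 10).all()
        assert len(idx) in (10, 11)

    def test_fraction_one_retains_all(self):
        m = linear_map(20)
        s = fm.make_mask_scenarios(m, fractions=(1.0,), seed=3)[0]
        assert len(s.retained_marker_ids) == 20

    def test_deterministic_given_seed(self):
        m = linear_map(50)
        a = fm.make_mask_scenarios(m, seed=5)
        b = fm.make_mask_scenarios(m, seed=5)
        assert all(
            x.retained_marker_ids == y.retained_marker_ids for x, y in zip(a, b)
        )

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            fm.make_mask_scenarios(linear_map(20), fractions=(1.5,), seed=0)


class TestSplitFolds:
    def test_349_samples_fourfold(self):
        """The published 262/87 reference/target split realized as disjoint
        folds: target sizes 88/87/87/87, references the complements."""
        samples = [f"s{i}" for i in range(349)]
        folds = fm.split_folds(samples, n_folds=4, seed=1)
        test_sizes = sorted(len(f.target_samples) for f in folds)
        ref_sizes = sorted(len(f.reference_samples) for f in folds)
        assert test_sizes == [87, 87, 87, 88]
        assert ref_sizes == [261, 262, 262, 262]
        # partition property
        all_test = sum((f.target_samples for f in folds), [])
        assert sorted(all_test) == sorted(samples)
        for f in folds:
            assert not set(f.target_samples) & set(f.reference_samples)

    def test_eight_samples_four_disjoint_pairs(self):
        folds = fm.split_folds([f"s{i}" for i in range(8)], n_folds=4, seed=0)
        assert all(len(f.target_samples) == 2 for f in folds)

    def test_repeated_mode(self):
        folds = fm.split_folds(
            [f"s{i}" for i in range(100)], n_folds=3, seed=0,
            mode="repeated", ref_fraction=0.75,
        )
        assert all(len(f.target_samples) == 25 for f in folds)


class TestBaselineImputer:
    def test_perfect_ld_flanks_recover_truth(self):
        """Masked marker in perfect LD with its flanking markers in the
        reference is imputed exactly for every sample."""
        rng = np.random.default_rng(0)
        n_ref, n_tgt, m = 40, 15, 5
        # two haplotype classes; marker 2 masked, determined by the class
        classes = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], dtype=np.uint8)
        ref = classes[rng.integers(0, 2, 2 * n_ref)]
        tgt_h = classes[rng.integers(0, 2, 2 * n_tgt)]
        markers = linear_map(m)
        reference = fm.HaplotypeSet(ref, markers)
        truth = tgt_h[0::2] + tgt_h[1::2]
        masked = truth.astype(np.int8).copy()
        masked[:, 2] = fm.MISSING
        target = fm.GenotypeMatrix(
            [f"t{i}" for i in range(n_tgt)], markers, masked
        )
        imp = fm.baseline_impute(reference, target, markers)
        assert np.array_equal(imp.calls[:, 2], truth[:, 2])

    def test_monomorphic_reference_marker(self):
        markers = linear_map(3)
        ref = np.array([[0, 1, 0], [0, 0, 0], [0, 1, 0], [0, 0, 0]], np.uint8)
        reference = fm.HaplotypeSet(ref, markers)
        masked = np.array([[fm.MISSING, 1, 0]], dtype=np.int8)
        target = fm.GenotypeMatrix(["t0"], markers, masked)
        imp = fm.baseline_impute(reference, target, markers)
        assert imp.calls[0, 0] == 0

    def test_self_reference_near_perfect(self, small_sim_result):
        """With the target's own haplotypes as reference, window-local
        matching recovers almost every genotype; residual errors are ties
        between haplotypes sharing a flanking window but differing at the
        masked site."""
        haps, geno, truth = small_sim_result
        markers = geno.markers
        masked = geno.calls.copy()
        cols = np.arange(0, geno.n_markers, 7)
        masked[:, cols] = fm.MISSING
        target = fm.GenotypeMatrix(geno.samples, markers, masked)
        imp = fm.baseline_impute(
            fm.HaplotypeSet(haps.haplotypes, markers, haps.samples),
            target, markers,
        )
        r2a, perc = fm.accuracy_metrics(geno, imp, marker_idx=cols)
        assert perc > 0.95 and r2a > 0.85

    def test_empty_reference_errors(self):
        markers = linear_map(2)
        reference = fm.HaplotypeSet(np.empty((0, 2), np.uint8), markers)
        target = fm.GenotypeMatrix(
            ["t"], markers, np.array([[fm.MISSING, 1]], np.int8)
        )
        with pytest.raises(ValueError, match="empty reference"):
            fm.baseline_impute(reference, target, markers)


class TestAccuracyMetrics:
    def make(self, vals):
        vals = np.asarray(vals, dtype=np.int8)[None, :]
        m = linear_map(vals.shape[1])
        return fm.GenotypeMatrix(["s"], m, vals)

    def test_perfect(self):
        t = self.make([0, 1, 2, 1])
        r2a, perc = fm.accuracy_metrics(t, t)
        assert r2a == pytest.approx(1) and perc == pytest.approx(1)

    def test_flipped_homozygotes_separate_the_metrics(self):
        """All-homozygote flip: correlation is sign-blind (r2a = 1) while no
        allele is imputed correctly (PERC = 0)."""
        t = self.make([0, 2, 0, 2])
        i = self.make([2, 0, 2, 0])
        r2a, perc = fm.accuracy_metrics(t, i)
        assert r2a == pytest.approx(1) and perc == pytest.approx(0)

    def test_hand_computed_example(self):
        t = self.make([0, 1, 2, 1])
        i = self.make([0, 1, 1, 1])
        r2a, perc = fm.accuracy_metrics(t, i)
        assert perc == pytest.approx(0.875)  # (2+2+1+2)/8
        want = np.corrcoef([0, 1, 2, 1], [0, 1, 1, 1])[0, 1] ** 2
        assert r2a == pytest.approx(want)

    def test_zero_variance_reported_undefined(self):
        t = self.make([1, 1, 1])
        r2a, perc = fm.accuracy_metrics(t, t)
        assert r2a is None and perc == 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fm.accuracy_metrics(self.make([0, 1]), self.make([0, 1, 2]))

    def test_frequency_random_imputation_perc(self):
        """PERC under frequency-random imputation converges to the mean of
        p^2 + q^2 over masked markers (within 3 SE)."""
        rng = np.random.default_rng(12)
        n, m = 400, 50
        p = rng.uniform(0.1, 0.9, m)
        t = rng.binomial(1, p, size=(n, m)) + rng.binomial(1, p, size=(n, m))
        i = rng.binomial(1, p, size=(n, m)) + rng.binomial(1, p, size=(n, m))
        markers = linear_map(m)
        gt = fm.GenotypeMatrix([f"s{k}" for k in range(n)], markers,
                               t.astype(np.int8))
        gi = fm.GenotypeMatrix([f"s{k}" for k in range(n)], markers,
                               i.astype(np.int8))
        _, perc = fm.accuracy_metrics(gt, gi)
        # closed form for dosage-based PERC of two independent Binomial(2,p)
        # draws: E[1 - |t-i|/2] = 1 - 2pq(p^2+q^2) - 2 p^2 q^2
        q = 1 - p
        want = np.mean(1 - 2 * p * q * (p * p + q * q) - 2 * p * p * q * q)
        se = np.sqrt(want * (1 - want) / (n * m))
        assert abs(perc - want) < 4 * se + 0.01


class TestGroupComparison:
    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame(
            {"g": ["a"] * 4 + ["b"] * 4 + ["c"] * 4, "v": [0.5] * 12}
        )
        res = group_comparison(df, "g", "v")
        assert res["p_value"] == 1.0
        assert len(set(res["letters"].values())) == 1

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "g": ["hi"] * 4 + ["lo"] * 4,
                "v": np.concatenate(
                    [0.95 + rng.normal(0, 0.001, 4), 0.80 + rng.normal(0, 0.001, 4)]
                ),
            }
        )
        res = group_comparison(df, "g", "v")
        # hand ANOVA on two groups: F = t^2, p well below 0.05
        assert res["p_value"] < 1e-6
        assert res["letters"]["hi"] != res["letters"]["lo"]

    def test_two_group_f_matches_hand_anova(self):
        a = np.array([0.95, 0.94, 0.96, 0.95])
        b = np.array([0.80, 0.81, 0.79, 0.80])
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "v": np.r_[a, b]})
        res = group_comparison(df, "g", "v")
        grand = np.r_[a, b].mean()
        ssb = 4 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 6)
        assert res["F"] == pytest.approx(f_hand)

    def test_letters_symmetric_under_relabeling(self):
        rng = np.random.default_rng(1)
        vals = {
            "a": 0.9 + rng.normal(0, 0.01, 4),
            "b": 0.5 + rng.normal(0, 0.01, 4),
            "c": 0.9 + rng.normal(0, 0.01, 4),
        }
        df = pd.DataFrame(
            {"g": sum([[k] * 4 for k in vals], []),
             "v": np.concatenate(list(vals.values()))}
        )
        res = group_comparison(df, "g", "v")
        relab = {"a": "c", "b": "a", "c": "b"}
        df2 = df.assign(g=df["g"].map(relab))
        res2 = group_comparison(df2, "g", "v")

        def share(letters, x, y):
            return bool(set(letters[x]) & set(letters[y]))

        for x in "abc":
            for y in "abc":
                assert share(res["letters"], x, y) == share(
                    res2["letters"], relab[x], relab[y]
                )

    def test_small_group_excluded_with_warning(self):
        df = pd.DataFrame(
            {"g": ["a"] * 4 + ["b"] * 4 + ["tiny"],
             "v": list(np.linspace(0, 1, 8)) + [0.5]}
        )
        res = group_comparison(df, "g", "v")
        assert any("tiny" in n for n in res["notes"])
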