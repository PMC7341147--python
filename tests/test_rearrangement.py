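"""Fusion calling, plan construction, liftover algebra, map comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusemap as fm
from fusemap.rearrange import (
    Arm,
    CoordinateOverflow,
    FusedChromPlan,
    FusionCandidate,
    RearrangementPlan,
)


def pair_table(rows):
    """rows: (chrom_i, pos_i, chrom_j, pos_j, r2)."""
    df = pd.DataFrame(
        rows, columns=["chrom_i", "pos_i", "chrom_j", "pos_j", "r2"]
    )
    df["i"] = np.arange(len(df)) * 2
    df["j"] = df["i"] + 1
    df["marker_i"] = "mi" + df["i"].astype(str)
    df["marker_j"] = "mj" + df["j"].astype(str)
    df["same_chrom"] = df["chrom_i"] == df["chrom_j"]
    df["dist_bp"] = np.where(
        df["same_chrom"], np.abs(df["pos_i"] - df["pos_j"]), np.nan
    )
    return df


class TestInterchromCounts:
    def test_counts_qualifying_pairs(self):
        t = pair_table(
            [("1", 10, "2", 20, 0.5), ("1", 11, "2", 21, 0.3),
             ("1", 12, "2", 22, 0.25), ("1", 13, "1", 23, 0.9)]
        )
        counts = fm.interchrom_ld_counts(t, r2_min=0.2, chrom_order=["1", "2"])
        assert counts.loc["1", "2"] == 3
        assert counts.loc["2", "1"] == 3
        assert counts.loc["1", "1"] == 0

    def test_boundary_r2_excluded(self):
        t = pair_table([("1", 10, "2", 20, 0.20)])
        counts = fm.interchrom_ld_counts(t, r2_min=0.2, chrom_order=["1", "2"])
        assert counts.loc["1", "2"] == 0


class TestDetectFusions:
    def test_single_dominant_pair(self):
        counts = pd.DataFrame(
            0, index=list("123456"), columns=list("123456")
        )
        counts.loc["1", "2"] = counts.loc["2", "1"] = 300
        counts.loc["3", "4"] = counts.loc["4", "3"] = 5
        cands = fm.detect_fusions(counts, min_count=20)
        assert len(cands) == 1
        assert {cands[0].chrom_a, cands[0].chrom_b} == {"1", "2"}
        assert cands[0].n_pairs == 300

    def test_all_background_empty(self):
        counts = pd.DataFrame(
            np.full((4, 4), 5), index=list("1234"), columns=list("1234")
        )
        assert fm.detect_fusions(counts, min_count=20) == []

    def test_greedy_one_fusion_per_chromosome(self):
        counts = pd.DataFrame(0, index=list("1234"), columns=list("1234"))
        counts.loc["1", "2"] = counts.loc["2", "1"] = 300
        counts.loc["2", "3"] = counts.loc["3", "2"] = 250
        cands = fm.detect_fusions(counts, min_count=20)
        assert len(cands) == 1 and cands[0].n_pairs == 300

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 6, size=(5, 5))
        base = base + base.T
        np.fill_diagonal(base, 0)
        base[1, 3] = base[3, 1] = 200
        labels = list("ABCDE")
        counts = pd.DataFrame(base, index=labels, columns=labels)
        cands = fm.detect_fusions(counts, min_count=20)
        perm = ["D", "A", "E", "B", "C"]
        counts2 = counts.loc[perm, perm]
        cands2 = fm.detect_fusions(counts2, min_count=20)
        assert [{c.chrom_a, c.chrom_b} for c in cands] == [
            {c.chrom_a, c.chrom_b} for c in cands2
        ]


class TestLocalizeEnds:
    table = fm.ChromosomeTable({"1": 100_000_000, "2": 40_000_000})

    def test_begin_begin(self):
        rows = [("1", int(p1), "2", int(p2), 0.5)
                for p1 in np.linspace(1e6, 4e6, 5)
                for p2 in np.linspace(1e6, 4e6, 5)]
        cand = FusionCandidate("1", "2", len(rows), 10.0)
        cand = fm.localize_fusion_ends(pair_table(rows), cand, self.table)
        assert cand.resolved and (cand.end_a, cand.end_b) == ("begin", "begin")

    def test_end_call(self):
        rows = [("1", int(p), "2", 1_000_000, 0.5)
                for p in np.linspace(96e6, 99e6, 8)]
        cand = FusionCandidate("1", "2", len(rows), 10.0)
        cand = fm.localize_fusion_ends(pair_table(rows), cand, self.table)
        assert cand.end_a == "end" and cand.end_b == "begin"

    def test_ambiguous_middle_unresolved(self):
        rows = [("1", 50_000_000, "2", 1_000_000, 0.5)] * 6
        cand = FusionCandidate("1", "2", 6, 10.0)
        cand = fm.localize_fusion_ends(pair_table(rows), cand, self.table)
        assert not cand.resolved and "ambiguous" in cand.note


def simple_plan(mode="junction_forward", short_strand="-", long_strand="+"):
    return RearrangementPlan(
        entries=[
            FusedChromPlan(
                name="2;1",
                short_arm=Arm("2", 40_000_000, short_strand, "begin"),
                long_arm=Arm("1", 100_000_000, long_strand, "begin"),
                junction_bp=40_000_000,
                orientation_mode=mode,
            )
        ]
    )


class TestBuildPlan:
    table = fm.ChromosomeTable({"1": 100_000_000, "2": 40_000_000})

    def test_shorter_chromosome_is_short_arm(self):
        cand = FusionCandidate("1", "2", 100, 10.0, "begin", "begin", 1e6, True)
        plan = fm.build_plan([cand], self.table)
        e = plan.entries[0]
        assert e.short_arm.chrom == "2" and e.long_arm.chrom == "1"
        assert e.junction_bp == 40_000_000
        assert e.name == "2;1"
        assert e.short_arm.strand == "-"   # begin fuses -> arm reversed
        assert e.long_arm.strand == "+"

    def test_length_tie_breaks_lexicographically(self):
        table = fm.ChromosomeTable({"a": 1000, "b": 1000})
        cand = FusionCandidate("b", "a", 30, 5.0, "begin", "begin", 100, True)
        plan = fm.build_plan([cand], table)
        assert plan.entries[0].short_arm.chrom == "a"
        assert any("tie" in n for n in plan.notes)


class TestLiftover:
    def test_published_formula_boundaries(self):
        """Short arm: new = shorter_len - pos.  Long arm junction_forward:
        new = junction + pos; literal mode: junction + (longer_len - pos)."""
        m = fm.MarkerMap.from_arrays(
            ["s0", "sj", "l0", "l5"],
            ["2", "2", "1", "1"],
            [0, 40_000_000, 0, 5_000_000],
        )
        fwd = fm.liftover_map(m, simple_plan())
        got = dict(zip(fwd.ids, fwd.pos))
        assert got["s0"] == 40_000_000      # short pos 0 -> junction
        assert got["sj"] == 0               # short telomere
        assert got["l0"] == 40_000_000      # junction_forward: centromeric end
        assert got["l5"] == 45_000_000
        lit = fm.liftover_map(m, simple_plan(mode="literal"))
        got = dict(zip(lit.ids, lit.pos))
        assert got["l0"] == 140_000_000     # literal: far telomere
        assert got["l5"] == 135_000_000
        assert got["s0"] == 40_000_000      # short arm identical in both modes

    def test_non_fused_chromosomes_pass_through(self):
        m = fm.MarkerMap.from_arrays(["x"], ["7"], [123])
        out = fm.liftover_map(m, simple_plan())
        assert out.df.loc[0, "chrom"] == "7" and out.df.loc[0, "pos_bp"] == 123

    def test_overflow_names_marker(self):
        m = fm.MarkerMap.from_arrays(["bad"], ["2"], [40_000_001])
        with pytest.raises(CoordinateOverflow, match="bad"):
            fm.liftover_map(m, simple_plan())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        mode=st.sampled_from(["junction_forward", "literal"]),
    )
    def test_roundtrip_identity_property(self, seed, mode):
        """invert_plan(liftover_map(m)) is the exact integer identity and
        adjacency along each arm is preserved."""
        rng = np.random.default_rng(seed)
        n = 50
        chroms = rng.choice(["1", "2", "9"], size=n)
        pos = np.array(
            [
                rng.integers(0, {"1": 100_000_000, "2": 40_000_000, "9": 1000}[c] + 1)
                for c in chroms
            ]
        )
        m = fm.MarkerMap.from_arrays(
            [f"m{k}" for k in range(n)], chroms, pos
        )
        plan = simple_plan(mode=mode)
        lifted = fm.liftover_map(m, plan)
        back = fm.invert_plan(lifted, plan)
        assert np.array_equal(back.pos, m.pos)
        assert list(back.chrom) == list(m.chrom)
        # order along each arm preserved up to strand: |Dnew| == |Dold|
        for c in ("1", "2"):
            sel = chroms == c
            if sel.sum() > 1:
                old = np.sort(pos[sel])
                order = np.argsort(pos[sel])
                new = lifted.pos[sel][order]
                assert np.array_equal(np.abs(np.diff(new)), np.diff(old))


class TestCompareMaps:
    def make(self, pos, chrom="1"):
        return fm.MarkerMap.from_arrays(
            [f"m{k}" for k in range(len(pos))], [chrom] * len(pos), pos
        )

    def test_identical_maps(self):
        m = self.make([10, 20, 30, 40])
        res = fm.compare_maps(m, m)
        r = res.iloc[0]
        assert r.spearman_rho == 1 and r.ols_slope == pytest.approx(1)
        assert r.ols_intercept_bp == pytest.approx(0) and r.r_squared == pytest.approx(1)
        assert r.orientation_sign == 1

    def test_reversed_map(self):
        m = self.make([10, 20, 30, 40])
        rev = self.make([90, 80, 70, 60])
        r = fm.compare_maps(m, rev).iloc[0]
        assert r.spearman_rho == -1 and r.ols_slope == pytest.approx(-1)
        assert r.orientation_sign == -1

    def test_rank_oracle_hand_listed(self):
        """Spearman rho against a brute-force rank computation."""
        pos_a = [10, 20, 30, 40, 50]
        pos_b = [12, 45, 22, 50, 38]
        r = fm.compare_maps(self.make(pos_a), self.make(pos_b)).iloc[0]
        ra = np.argsort(np.argsort(pos_a)).astype(float)
        rb = np.argsort(np.argsort(pos_b)).astype(float)
        want = np.corrcoef(ra, rb)[0, 1]
        assert r.spearman_rho == pytest.approx(want)

    def test_too_few_shared_markers_skipped(self):
        a = self.make([1, 2])
        b = self.make([1, 2])
        assert len(fm.compare_maps(a, b)) == 0

    def test_identity_liftover_concordance(self):
        """Lifting over an empty plan changes nothing: rho=1, slope=1."""
        m = self.make([5, 10, 15, 20, 25])
        lifted = fm.liftover_map(m, RearrangementPlan())
        r = fm.compare_maps(m, lifted).iloc[0]
        assert r.spearman_rho == pytest.approx(1, abs=1e-12)
        assert r.ols_slope == pytest.approx(1)


class TestMisplacedRule:
    def test_high_local_ld_not_flagged(self):
        """Long-range partners alone do not flag a marker whose local LD is
        healthy (rule conjunction): markers in perfect LD with another
        chromosome AND with their own neighbours stay unflagged."""
        m = fm.MarkerMap.from_arrays(
            [f"m{k}" for k in range(20)],
            ["1"] * 10 + ["2"] * 10,
            list(range(1000, 1010)) + list(range(500_000, 500_010)),
        )
        rng = np.random.default_rng(0)
        shared = rng.binomial(1, 0.5, size=80).astype(np.int8)
        # every marker, on both chromosomes, carries the same genotypes:
        # plenty of high-LD inter-chromosomal partners, but perfect local LD
        calls = (np.repeat(shared[:, None], 20, axis=1) * 2).astype(np.int8)
        g = fm.GenotypeMatrix([f"s{i}" for i in range(80)], m, calls)
        pairs = fm.pairwise_r2(g, scope="all")
        flags = fm.flag_misplaced_snps(pairs, m)
        assert flags == []  # rule conjunction: local LD is healthy


def test_translocated_terminal_run_excluded():
    """A qualifying run at a chromosome terminus is fusion evidence, not a
    translocation."""
    m = fm.MarkerMap.from_arrays(
        [f"m{k}" for k in range(6)],
        ["1"] * 3 + ["2"] * 3,
        [1000, 2000, 3000, 1000, 2000, 3000],
    )
    rows = []
    for k in range(3):
        rows.append(
            {
                "i": k, "j": 3 + k, "marker_i": f"m{k}", "marker_j": f"m{3+k}",
                "chrom_i": "1", "pos_i": m.pos[k],
                "chrom_j": "2", "pos_j": m.pos[3 + k],
                "r2": 0.9, "dist_bp": np.nan, "same_chrom": False,
            }
        )
    pairs = pd.DataFrame(rows)
    table = fm.ChromosomeTable({"1": 1_000_000, "2": 1_000_000})
    segs = fm.detect_translocated_segments(pairs, m, table)
    assert len(segs) == 0  # run at < 25% of chromosome length
    # interior placement is detected
    table2 = fm.ChromosomeTable({"1": 6000, "2": 6000})
    segs2 = fm.detect_translocated_segments(pairs, m, table2)
    assert len(segs2) == 2  # seen from both chromosomes
    assert set(segs2["chrom"]) == {"1", "2"}
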