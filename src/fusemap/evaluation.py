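"""End-to-end recovery evaluation on simulated ground truth.

Each *trial* runs one seeded simulation under the default study conditions
(or a purpose-built variant), pushes it through the full inference pipeline
— QC, pairwise r², fusion detection, end localization, plan building,
liftover, window scans, imputation design — and scores the results against
the simulator's truth.  Trials return flat dicts so batteries over seeds
can be aggregated into recovery rates.

These functions are the substance behind both the acceptance checks and
the reproduction script; they contain no thresholds of their own beyond
the pipeline defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imputation as imp
from . import ld, qc, rearrange, scans, simulate
from .datamodel import GenotypeMatrix, HaplotypeSet


def _fused_name(truth) -> str:
    return truth.plan.entries[0].name


def fusion_recovery_trial(seed: int, run_scans: bool = True,
                          run_imputation: bool = True,
                          fractions=imp.DEFAULT_FRACTIONS) -> dict:
    """One seed of the default scenario: detection, plan, liftover, scans,
    centromeric imputation contrast."""
    cfg = simulate.default_config(seed=seed)
    haps, geno, truth = simulate.simulate_fused_population(cfg)
    # standard panel QC; simulator output already meets the MAF filter, so
    # this mostly exercises the HWE screen
    geno, qc_report = qc.apply_qc(geno)
    kept_idx = truth.split_map.index_of(geno.markers.ids)
    haps = haps.subset_markers(kept_idx)
    truth.split_map = truth.split_map.subset(kept_idx)
    truth.fused_map = truth.fused_map.subset(kept_idx)
    out: dict = {"seed": seed, "n_markers": geno.n_markers,
                 "n_qc_removed": qc_report.n_input - qc_report.n_retained}
    fused_name = _fused_name(truth)
    junction = truth.plan.entries[0].junction_bp

    # --- fusion detection on the split reference -------------------------
    inter = ld.pairwise_r2(geno, scope="inter", r2_min=0.2)
    counts = rearrange.interchrom_ld_counts(
        inter, chrom_order=truth.split_map.chroms()
    )
    cands = rearrange.detect_fusions(counts)
    true_pair = {truth.plan.entries[0].short_arm.chrom,
                 truth.plan.entries[0].long_arm.chrom}
    found_pairs = [{c.chrom_a, c.chrom_b} for c in cands]
    out["fusion_pair_found"] = true_pair in found_pairs
    out["n_false_fusions"] = sum(p != true_pair for p in found_pairs)
    out["ends_ok"] = out["plan_ok"] = False
    if out["fusion_pair_found"]:
        cand = cands[found_pairs.index(true_pair)]
        cand = rearrange.localize_fusion_ends(
            inter, cand, truth.chrom_table_split
        )
        out["ends_ok"] = bool(
            cand.resolved and cand.end_a == "begin" and cand.end_b == "begin"
        )
        if cand.resolved:
            plan = rearrange.build_plan([cand], truth.chrom_table_split)
            e, t = plan.entries[0], truth.plan.entries[0]
            out["plan_ok"] = (
                e.name == t.name
                and e.junction_bp == t.junction_bp
                and e.short_arm.strand == t.short_arm.strand
                and e.long_arm.strand == t.long_arm.strand
            )

    # --- liftover exactness ---------------------------------------------
    split = simulate.project_to_split_reference(truth)
    back = rearrange.liftover_map(split, truth.plan)
    out["liftover_mismatches"] = int(
        (back.pos != truth.fused_map.pos).sum()
        + (back.chrom != truth.fused_map.chrom).sum()
    )

    if run_scans:
        res = junction_scan_trial(haps, geno, truth)
        out.update(res)

    if run_imputation:
        region = np.nonzero(
            (truth.fused_map.chrom == fused_name)
            & (np.abs(truth.fused_map.pos - junction) <= 1e6)
        )[0]
        out["n_region_markers"] = int(len(region))
        if len(region) >= 2:
            results = imp.evaluate_imputation(
                haps, geno,
                {"arranged": truth.fused_map, "non_arranged": truth.split_map},
                region, fractions=fractions, seed=seed,
            )
            out["imputation"] = results
    return out


def junction_scan_trial(haps: HaplotypeSet, geno: GenotypeMatrix, truth) -> dict:
    """Windowed LD peak and haplotype-diversity trough on the arranged map."""
    fused_name = _fused_name(truth)
    junction = truth.plan.entries[0].junction_bp
    n = geno.n_samples
    geno_f = GenotypeMatrix(geno.samples, truth.fused_map, geno.calls)
    pairs = ld.pairwise_r2(
        geno_f, scope="intra", max_dist_bp=4e6, chroms=[fused_name]
    )
    scan = scans.window_ld_scan(
        pairs, truth.fused_map, n=n,
        chrom_table=truth.chrom_table_fused, chroms=[fused_name],
    )
    out: dict = {}
    d = scan[scan["defined"]]
    mid = ((d["window_start_bp"] + d["window_end_bp"]) / 2).to_numpy()
    out["ld_argmax_mid_bp"] = float(mid[int(np.argmax(d["stat"].to_numpy()))])
    out["ld_argmax_hit"] = bool(abs(out["ld_argmax_mid_bp"] - junction) <= 2e6)
    near = np.abs(mid - junction) <= 2e6
    out["ld_junction_stat"] = float(d["stat"].to_numpy()[near].max()) if near.any() else np.nan
    # unbiased single-window statistic (nearest window midpoint): the
    # max/min over the +-2 Mb neighbourhood is selection-biased and must
    # not be used for null comparisons
    out["ld_stat_at_junction"] = float(
        d["stat"].to_numpy()[int(np.argmin(np.abs(mid - junction)))]
    )
    out["ld_arm_median"] = float(
        np.median(d["stat"].to_numpy()[np.abs(mid - junction) > 10e6])
    )
    haps_f = HaplotypeSet(haps.haplotypes, truth.fused_map, haps.samples)
    div = scans.haplotype_diversity_scan(
        haps_f, truth.fused_map,
        chrom_table=truth.chrom_table_fused, chroms=[fused_name],
    )
    dd = div[div["defined"]]
    midd = ((dd["window_start_bp"] + dd["window_end_bp"]) / 2).to_numpy()
    out["div_argmin_mid_bp"] = float(midd[int(np.argmin(dd["stat"].to_numpy()))])
    out["div_argmin_hit"] = bool(abs(out["div_argmin_mid_bp"] - junction) <= 2e6)
    neard = np.abs(midd - junction) <= 2e6
    out["div_junction_stat"] = (
        float(dd["stat"].to_numpy()[neard].min()) if neard.any() else np.nan
    )
    out["div_stat_at_junction"] = float(
        dd["stat"].to_numpy()[int(np.argmin(np.abs(midd - junction)))]
    )
    out["div_arm_median"] = float(
        np.median(dd["stat"].to_numpy()[np.abs(midd - junction) > 10e6])
    )
    out["ld_scan"] = scan
    out["div_scan"] = div
    return out


def suppression_null_trial(seed: int) -> dict:
    """Default scenario with suppression factor 1 (no suppression): junction
    windows should not be systematically elevated/depressed."""
    cfg = simulate.default_config(seed=seed)
    f = cfg.fusions[0]
    f.suppression_factor = 1.0
    haps, geno, truth = simulate.simulate_fused_population(cfg)
    out = junction_scan_trial(haps, geno, truth)
    return {
        "seed": seed,
        "ld_junction_minus_arm": out["ld_stat_at_junction"] - out["ld_arm_median"],
        "div_junction_minus_arm": out["div_stat_at_junction"] - out["div_arm_median"],
        "ld_argmax_hit": out["ld_argmax_hit"],
        "div_argmin_hit": out["div_argmin_hit"],
    }


# ---------------------------------------------------------------------------
# misassembly fixtures: planted misplacements / translocated segment
# ---------------------------------------------------------------------------

def _misassembly_config(seed: int, misplacements) -> simulate.SimConfig:
    """Two 40 Mb chromosomes at real-panel marker density (~18/Mb
    surviving), no fusion: the test bed for map-corruption diagnostics."""
    return simulate.SimConfig(
        n_samples=200, ne=200, n_generations=300,
        recomb_rate_per_bp=1e-8,
        fusions=[],
        decoy_chroms={"1": 40_000_000, "2": 40_000_000},
        n_markers=2700,
        misplacements=misplacements,
        seed=seed,
    )


def misplacement_trial(seed: int, n_planted: int = 1) -> dict:
    """Plant stray markers in the map; score flag recovery and false flags."""
    cfg = _misassembly_config(
        seed, simulate.MisplacementSpec(n_single_markers=n_planted)
    )
    haps, geno, truth = simulate.simulate_fused_population(cfg)
    pairs = ld.pairwise_r2(geno, scope="all")
    flags = rearrange.flag_misplaced_snps(pairs, truth.split_map)
    planted = {
        r["marker_id"]: r["true_chrom"]
        for r in truth.planted["single_markers"]
    }
    flagged = {f.marker_id: f for f in flags}
    hits = [
        m for m, true_chrom in planted.items()
        if m in flagged and flagged[m].best_alternative_chrom == true_chrom
    ]
    false_flags = [m for m in flagged if m not in planted]
    return {
        "seed": seed,
        "n_planted": len(planted),
        "n_recovered": len(hits),
        "n_false_flags": len(false_flags),
        "n_markers": geno.n_markers,
    }


def segment_trial(seed: int, seg_len_bp: int = 700_000) -> dict:
    """Plant an interior translocated segment; score bound recovery."""
    rng = np.random.default_rng((seed, 77))
    for _ in range(10):
        src_start = int(rng.integers(12_000_000, 26_000_000))
        dest_start = int(rng.integers(12_000_000, 26_000_000))
        cfg = _misassembly_config(
            seed,
            simulate.MisplacementSpec(
                segment_src_chrom="1", segment_start_bp=src_start,
                segment_len_bp=seg_len_bp, segment_dest_chrom="2",
                segment_dest_start_bp=dest_start,
            ),
        )
        haps, geno, truth = simulate.simulate_fused_population(cfg)
        # a window that drifted to fixation leaves nothing to plant; redraw
        if len(truth.planted["segment"]["marker_ids"]) >= 3:
            break
    pairs = ld.pairwise_r2(geno, scope="inter", r2_min=0.2)
    segs = rearrange.detect_translocated_segments(
        pairs, truth.split_map, truth.chrom_table_split
    )
    planted = truth.planted["segment"]
    planted_ids = set(planted["marker_ids"])
    # detected bounds are marker-position spans, so truth is the span of
    # the planted markers (the window edges overshoot by ~half a spacing)
    moved = np.isin(truth.split_map.ids, list(planted_ids))
    true_start = int(truth.split_map.pos[moved].min())
    true_end = int(truth.split_map.pos[moved].max())
    # typical spacing near the planted window on the corrupted map
    on2 = np.sort(
        truth.split_map.pos[truth.split_map.chrom == planted["fake_chrom"]]
    )
    spacing = float(np.median(np.diff(on2)))
    hit = False
    start_err = end_err = np.nan
    found = segs[segs["chrom"] == planted["fake_chrom"]]
    for _, s in found.iterrows():
        overlap = min(s["end_bp"], true_end) - max(s["start_bp"], true_start)
        if overlap > 0:
            start_err = abs(s["start_bp"] - true_start)
            end_err = abs(s["end_bp"] - true_end)
            hit = start_err <= spacing and end_err <= spacing
            break
    n_extra = len(segs) - (1 if len(found) else 0)
    return {
        "seed": seed,
        "recovered": bool(hit),
        "start_err_bp": float(start_err),
        "end_err_bp": float(end_err),
        "spacing_bp": spacing,
        "n_extra_segments": int(max(n_extra, 0)),
    }


def false_flag_trial(seed: int) -> dict:
    """No planted corruption: the misplacement flag false-positive budget."""
    cfg = _misassembly_config(seed, None)
    haps, geno, truth = simulate.simulate_fused_population(cfg)
    pairs = ld.pairwise_r2(geno, scope="all")
    flags = rearrange.flag_misplaced_snps(pairs, truth.split_map)
    segs = rearrange.detect_translocated_segments(
        pairs, truth.split_map, truth.chrom_table_split
    )
    return {
        "seed": seed,
        "n_false_flags": len(flags),
        "n_false_segments": int(len(segs)),
        "n_markers": geno.n_markers,
    }


def pool_imputation_results(trials: list[dict]) -> pd.DataFrame:
    """Per-(seed, scenario, variant, metric) fold-mean table pooled over a
    battery of fusion-recovery trials."""
    frames = []
    for t in trials:
        if "imputation" not in t:
            continue
        df = t["imputation"].copy()
        df["seed"] = t["seed"]
        frames.append(df)
    allr = pd.concat(frames, ignore_index=True)
    return (
        allr.groupby(["seed", "scenario", "map_variant", "metric"])["value"]
        .mean()
        .reset_index()
    )
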