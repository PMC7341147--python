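"""Imputation-accuracy experimental design and metrics.

Masking scenarios retain an equidistant-in-rank subset of markers
(10–30% by default), cross-validation splits samples into reference and
target sets (a disjoint fourfold scheme by default, matching a 262/87
split of 349 animals), a deliberately simple haplotype-matching baseline
imputer fills the masked genotypes, and accuracy is scored by

* ``r2a`` — squared Pearson correlation between true and imputed allele
  counts over all (sample, masked marker) cells, and
* ``PERC`` — the proportion of correctly imputed alleles (a one-dosage
  genotype error counts one of its two alleles correct).

The baseline imputer exists so the evaluation pipeline is testable end to
end; it is not a reimplementation of production phasing/imputation
software, and externally imputed genotypes can be imported (VCF) and scored
with the same metrics.  Group comparisons across map variants use a one-way
F-test with Tukey HSD letters, the presentation used for centromeric-region
accuracy tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap

DEFAULT_FRACTIONS = (0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class MaskScenario:
    retained_fraction: float
    retained_marker_ids: list[str]
    seed: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_marker_ids)


@dataclass
class FoldSpec:
    fold: int
    reference_samples: list[str]
    target_samples: list[str]


def make_mask_scenarios(markers: MarkerMap, fractions=DEFAULT_FRACTIONS,
                        seed: int = 0) -> list[MaskScenario]:
    """Equidistant-in-rank retention scenarios.

    For retained fraction f, every k-th marker in map order is kept with
    ``k = round(1/f)``, starting at a seeded random offset in [0, k).
    Deterministic given the seed.
    """
    if len(markers) < 10:
        raise ValueError("need at least 10 markers")
    ids = markers.sorted().ids
    out = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        rng = np.random.default_rng((seed, int(round(frac * 1000))))
        k = max(int(round(1 / frac)), 1)
        offset = int(rng.integers(0, k))
        out.append(
            MaskScenario(
                retained_fraction=float(frac),
                retained_marker_ids=list(ids[offset::k]),
                seed=seed,
            )
        )
    return out


def split_folds(samples, n_folds: int = 4, seed: int = 0,
                mode: str = "disjoint", ref_fraction: float | None = None) -> list[FoldSpec]:
    """Reference/target sample splits.

    ``disjoint`` (default): one seeded shuffle partitioned into ``n_folds``
    near-equal test sets, each fold's reference being the complement —
    349 samples give target sizes 88/87/87/87.  ``repeated``: ``n_folds``
    independent random splits holding out ``1 - ref_fraction`` of samples.
    """
    samples = [str(s) for s in samples]
    if len(samples) < n_folds:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    out = []
    if mode == "disjoint":
        perm = rng.permutation(len(samples))
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            test = sorted(chunk)
            ref = np.setdiff1d(np.arange(len(samples)), chunk)
            out.append(
                FoldSpec(
                    fold=f,
                    reference_samples=[samples[i] for i in ref],
                    target_samples=[samples[i] for i in test],
                )
            )
    elif mode == "repeated":
        if ref_fraction is None:
            raise ValueError("repeated mode requires ref_fraction")
        n_test = int(round((1 - ref_fraction) * len(samples)))
        for f in range(n_folds):
            perm = rng.permutation(len(samples))
            test, ref = perm[:n_test], perm[n_test:]
            out.append(
                FoldSpec(
                    fold=f,
                    reference_samples=[samples[i] for i in sorted(ref)],
                    target_samples=[samples[i] for i in sorted(test)],
                )
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# baseline imputer
# ---------------------------------------------------------------------------

def baseline_impute(
    reference: HaplotypeSet,
    target: GenotypeMatrix,
    markers: MarkerMap,
    flank_k: int = 4,
    impute_marker_idx=None,
) -> GenotypeMatrix:
    """Impute masked genotypes by flanking-haplotype matching.

    For each fully masked marker, each target sample is matched against every
    reference haplotype on a window of the nearest ``flank_k`` retained
    markers each side (map order within the chromosome); the imputed dosage
    is the sum of the two best-matching haplotypes' alleles at the masked
    site.  The first haplotype minimizes the genotype-to-haplotype distance
    (0 at heterozygous flanks, mismatches against homozygous flanks); the
    second minimizes the distance to the residual genotype after the first
    pick, so a heterozygous flank consumed by the first haplotype demands
    the complementary allele.  Ties break by reference haplotype-window
    frequency, then haplotype index — fully deterministic.

    ``impute_marker_idx`` restricts imputation to those marker columns
    (others stay missing); by default every all-missing column is imputed.
    """
    if reference.haplotypes.shape[0] == 0:
        raise ValueError("empty reference panel")
    if reference.n_markers != target.n_markers:
        raise ValueError("reference and target marker dimensions differ")
    calls = target.calls.copy()
    masked_cols = np.nonzero((calls == MISSING).all(axis=0))[0]
    if impute_marker_idx is not None:
        masked_cols = np.intersect1d(masked_cols, np.asarray(impute_marker_idx))
    order = markers.argsort_positional()
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    chrom_arr = markers.chrom
    H = reference.haplotypes
    masked_set = set((calls == MISSING).all(axis=0).nonzero()[0])

    for m in masked_cols:
        same = np.nonzero(chrom_arr == chrom_arr[m])[0]
        retained = np.array([k for k in same if k not in masked_set])
        if len(retained) == 0:
            # no informative flank: impute the reference modal dosage
            freq = H[:, m].mean()
            calls[:, m] = int(round(2 * freq))
            continue
        left = retained[rank[retained] < rank[m]]
        right = retained[rank[retained] > rank[m]]
        left = left[np.argsort(rank[left])][-flank_k:]
        right = right[np.argsort(rank[right])][:flank_k]
        flank = np.concatenate([left, right])
        Hw = H[:, flank].astype(np.float32)              # (2R, F)
        G = calls[:, flank]                              # (T, F)
        a0 = (G == 0).astype(np.float32)
        a2 = (G == 2).astype(np.float32)
        D = a0 @ Hw.T + a2 @ (1.0 - Hw).T                # (T, 2R)
        # haplotype-window frequency for tie-breaks
        _, inv, cnt = np.unique(
            H[:, flank], axis=0, return_inverse=True, return_counts=True
        )
        freq = cnt[inv]
        alleles = H[:, m].astype(np.int8)
        idx = np.arange(H.shape[0])
        for t in range(calls.shape[0]):
            ordr = np.lexsort((idx, -freq, D[t]))
            h1 = ordr[0]
            # second pick: distance to the residual genotype given h1
            het = G[t] == 1
            if het.any():
                want = 1.0 - Hw[h1, het]
                d2 = D[t] + np.abs(Hw[:, het] - want[None, :]).sum(axis=1)
            else:
                d2 = D[t]
            ordr2 = np.lexsort((idx, -freq, d2))
            calls[t, m] = alleles[h1] + alleles[ordr2[0]]
    return GenotypeMatrix(list(target.samples), markers, calls)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy_metrics(true: GenotypeMatrix, imputed: GenotypeMatrix,
                     marker_idx=None, per_marker: bool = False):
    """(r2a, perc) over the (sample, marker) cells of the subset.

    ``r2a`` is the squared Pearson correlation of true vs imputed dosages
    pooled over cells (``per_marker=True`` averages per-marker r² instead);
    it is ``None`` when either side has zero variance.  ``perc`` counts
    correctly imputed alleles: a one-dosage error is half right.
    """
    if true.calls.shape != imputed.calls.shape:
        raise ValueError("dimension mismatch between true and imputed")
    if marker_idx is None:
        marker_idx = np.arange(true.n_markers)
    marker_idx = np.asarray(marker_idx)
    if marker_idx.size == 0:
        raise ValueError("empty marker subset")
    t = true.calls[:, marker_idx].astype(np.float64)
    i = imputed.calls[:, marker_idx].astype(np.float64)
    ok = (t != MISSING) & (i != MISSING)
    perc = float((2.0 - np.abs(t[ok] - i[ok])).sum() / (2.0 * ok.sum()))
    if per_marker:
        vals = []
        for c in range(t.shape[1]):
            okc = ok[:, c]
            tc, ic = t[okc, c], i[okc, c]
            if tc.std() > 0 and ic.std() > 0:
                vals.append(np.corrcoef(tc, ic)[0, 1] ** 2)
        r2a = float(np.mean(vals)) if vals else None
    else:
        tv, iv = t[ok], i[ok]
        if tv.std() > 0 and iv.std() > 0:
            r2a = float(np.corrcoef(tv, iv)[0, 1] ** 2)
        else:
            r2a = None
    return r2a, perc


# ---------------------------------------------------------------------------
# group comparison (F-test + Tukey letters)
# ---------------------------------------------------------------------------

def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different (insert-and-absorb)."""
    letters: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letters:
            if all(frozenset((g, o)) in not_different for o in s):
                s.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb subsets
    letters = [
        s for k, s in enumerate(letters)
        if not any(s < o for o in letters[:k] + letters[k + 1:])
    ]
    out = {g: "" for g in groups}
    for tag, s in zip("abcdefghijklmnopqrstuvwxyz", letters):
        for g in s:
            out[g] += tag
    return out


def group_comparison(values: pd.DataFrame, group_col: str, value_col: str,
                     alpha: float = 0.05):
    """One-way ANOVA across groups plus Tukey HSD letters.

    ``values`` holds one replicate per row.  Groups with fewer than 2
    replicates are excluded (with a warning note in the result).  Returns a
    dict with the F statistic, p-value, per-group means, Tukey table and
    compact letters at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    notes = []
    counts = values.groupby(group_col)[value_col].count()
    small = list(counts[counts < 2].index)
    if small:
        notes.append(f"excluded groups with <2 replicates: {small}")
        values = values[~values[group_col].isin(small)]
    groups = sorted(values[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates")
    arrays = [values.loc[values[group_col] == g, value_col].to_numpy()
              for g in groups]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        # no variation anywhere: nothing is significant
        return {
            "F": 0.0, "p_value": 1.0,
            "means": {g: float(a.mean()) for g, a in zip(groups, arrays)},
            "letters": {g: "a" for g in groups},
            "tukey": None, "notes": notes + ["all values identical"],
        }
    F, p = stats.f_oneway(*arrays)
    tuk = pairwise_tukeyhsd(
        pooled,
        np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)]),
        alpha=alpha,
    )
    not_diff = set()
    res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    for _, r in res.iterrows():
        if not r["reject"]:
            not_diff.add(frozenset((str(r["group1"]), str(r["group2"]))))
    letters = _compact_letters([str(g) for g in groups], not_diff)
    return {
        "F": float(F), "p_value": float(p),
        "means": {g: float(a.mean()) for g, a in zip(groups, arrays)},
        "letters": letters, "tukey": res, "notes": notes,
    }


def region_group_comparison(results: pd.DataFrame, alpha: float = 0.05,
                            pool_scenarios: bool = False) -> pd.DataFrame:
    """Compare map variants on per-fold accuracy, per (scenario, metric).

    ``results`` is the tidy table produced by :func:`evaluate_imputation`
    (columns scenario, fold, region, map_variant, metric, value).  With
    ``pool_scenarios=True`` the scenarios are treated as replicates of a
    single comparison per metric.
    """
    rows = []
    keys = ["metric"] if pool_scenarios else ["scenario", "metric"]
    for key, grp in results.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        cmp = group_comparison(grp, "map_variant", "value", alpha=alpha)
        rows.append(
            dict(
                zip(keys, key),
                F=cmp["F"],
                p_value=cmp["p_value"],
                **{f"mean_{g}": v for g, v in cmp["means"].items()},
                **{f"letter_{g}": v for g, v in cmp["letters"].items()},
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def evaluate_imputation(
    haps: HaplotypeSet,
    geno: GenotypeMatrix,
    maps: dict[str, MarkerMap],
    region_marker_idx,
    fractions=DEFAULT_FRACTIONS,
    n_folds: int = 4,
    seed: int = 0,
    flank_k: int = 4,
) -> pd.DataFrame:
    """Run the masking x folds x map-variant design on one dataset.

    ``maps`` gives the marker map per variant (e.g. ``{"arranged": fused,
    "non_arranged": split}``); marker columns are shared across variants.
    ``region_marker_idx`` selects the evaluation region (e.g. junction
    ±1 Mb).  Only the region's masked markers are imputed — the flanking
    evidence still comes from all retained markers of the variant's map.

    Returns a tidy frame: scenario, fold, region, map_variant, metric, value.
    """
    region_marker_idx = np.asarray(region_marker_idx)
    base_map = next(iter(maps.values()))
    scenarios = make_mask_scenarios(base_map, fractions, seed=seed)
    folds = split_folds(geno.samples, n_folds=n_folds, seed=seed)
    sample_pos = {s: k for k, s in enumerate(geno.samples)}
    rows = []
    for scen in scenarios:
        retained_idx = base_map.index_of(scen.retained_marker_ids)
        retained = np.zeros(geno.n_markers, dtype=bool)
        retained[retained_idx] = True
        eval_idx = region_marker_idx[~retained[region_marker_idx]]
        if eval_idx.size == 0:
            continue
        for fold in folds:
            ref_rows = np.array([sample_pos[s] for s in fold.reference_samples])
            tgt_rows = np.array([sample_pos[s] for s in fold.target_samples])
            ref_haps = haps.subset_individuals(ref_rows)
            true_tgt = geno.subset(sample_idx=tgt_rows)
            masked_calls = true_tgt.calls.copy()
            masked_calls[:, ~retained] = MISSING
            for variant, vmap in maps.items():
                tgt = GenotypeMatrix(true_tgt.samples, vmap, masked_calls.copy())
                imp = baseline_impute(
                    HaplotypeSet(ref_haps.haplotypes, vmap, ref_haps.samples),
                    tgt, vmap, flank_k=flank_k, impute_marker_idx=eval_idx,
                )
                truth_region = GenotypeMatrix(true_tgt.samples, vmap, true_tgt.calls)
                r2a, perc = accuracy_metrics(truth_region, imp, marker_idx=eval_idx)
                for metric, value in (("r2a", r2a), ("perc", perc)):
                    rows.append(
                        {
                            "scenario": scen.retained_fraction,
                            "fold": fold.fold,
                            "region": "junction",
                            "map_variant": variant,
                            "metric": metric,
                            "value": value,
                            "n_markers": int(eval_idx.size),
                        }
                    )
    return pd.DataFrame(rows)
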