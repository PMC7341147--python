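"""Windowed LD and haplotype-diversity profiles along chromosomes.

The LD scan fits the Hill–Weir decay curve inside each sliding window
(default 4 Mb windows stepping 1 Mb) and summarizes the window by the fitted
expectation evaluated at a fixed reference distance ``d_ref`` (default
100 kb).  Evaluating the curve at one distance makes windows with different
marker spacing comparable and adjusts the raw mean r² for the within-window
distance distribution; the raw mean is reported alongside.

The diversity scan computes the unbiased haplotype diversity
``H = (M/(M-1)) (1 - sum p_i^2)`` over complete-window haplotype classes in
1 Mb windows stepping 0.5 Mb, with ``M`` the number of haplotype
observations (2N for diploids; a literal mode using N is switchable).

On a fused chromosome, recombination suppression around the junction
(centromere) leaves a signature: elevated windowed LD and depressed
haplotype diversity.  :func:`centromere_profile` measures the peak and its
extent, and :func:`rank_fusion_age` orders fused chromosomes by a staging
heuristic — small centromeric LD extent marks old fusions, large extent
recent ones — with the peak height as tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ChromosomeTable, HaplotypeSet, MarkerMap
from .ld import IllConditionedFit, expected_r2_hill_weir, fit_ld_decay


def _windows(length: int, window_bp: float, step_bp: float) -> np.ndarray:
    starts = np.arange(0, max(length - 1, 1), step_bp, dtype=np.int64)
    return np.stack([starts, np.minimum(starts + int(window_bp), length)], axis=1)


def window_ld_scan(
    pairs: pd.DataFrame,
    markers: MarkerMap,
    n: int,
    chrom_table: ChromosomeTable | None = None,
    window_bp: float = 4e6,
    step_bp: float = 1e6,
    d_ref: float = 1e5,
    min_pairs: int = 10,
    chroms=None,
) -> pd.DataFrame:
    """Decay-adjusted windowed LD profile.

    ``pairs`` must be intra-chromosomal rows with distances.  Per window,
    :func:`~fusemap.ld.fit_ld_decay` runs on pairs with both markers inside
    the window; ``stat`` is the fitted expectation at ``d_ref`` and windows
    with undefined fits carry ``defined=False``.
    """
    intra = pairs[pairs["same_chrom"]]
    if chroms is None:
        chroms = list(dict.fromkeys(intra["chrom_i"]))
    rows = []
    for chrom in chroms:
        sub = intra[intra["chrom_i"] == chrom]
        length = (
            chrom_table[chrom]
            if chrom_table is not None and chrom in chrom_table
            else int(markers.df.loc[markers.chrom == chrom, "pos_bp"].max())
        )
        lo = np.minimum(sub["pos_i"].to_numpy(), sub["pos_j"].to_numpy())
        hi = np.maximum(sub["pos_i"].to_numpy(), sub["pos_j"].to_numpy())
        for start, end in _windows(length, window_bp, step_bp):
            inside = sub[(lo >= start) & (hi < end)]
            stat = np.nan
            beta = np.nan
            mean_r2 = float(inside["r2"].mean()) if len(inside) else np.nan
            defined = False
            try:
                fit = fit_ld_decay(inside, n=n, min_pairs=min_pairs)
            except IllConditionedFit:
                fit = None
            if fit is not None:
                beta = fit.beta
                stat = float(expected_r2_hill_weir(fit.beta * d_ref, n))
                defined = True
            rows.append(
                {
                    "chrom": chrom,
                    "window_start_bp": int(start),
                    "window_end_bp": int(end),
                    "stat": stat,
                    "mean_r2": mean_r2,
                    "beta": beta,
                    "n_items": int(len(inside)),
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def haplotype_diversity_scan(
    haps: HaplotypeSet,
    markers: MarkerMap | None = None,
    chrom_table: ChromosomeTable | None = None,
    window_bp: float = 1e6,
    step_bp: float = 5e5,
    correction: str = "observations",
    min_markers: int = 5,
    chroms=None,
) -> pd.DataFrame:
    """Sliding-window haplotype diversity over phased haplotypes.

    ``H = (M/(M-1)) (1 - sum p_i^2)`` with haplotype classes defined by the
    complete window haplotype.  ``correction="observations"`` uses M = number
    of haplotypes (2N); ``correction="individuals"`` uses N, the literal
    reading of the published estimator.  Windows holding fewer than
    ``min_markers`` markers are reported with ``defined=False``: a
    one-marker "haplotype block" measures allele diversity, not haplotype
    diversity, and would contaminate along-chromosome comparisons.
    """
    markers = markers if markers is not None else haps.markers
    if markers is None:
        raise ValueError("marker map required")
    if correction not in ("observations", "individuals"):
        raise ValueError(f"unknown correction {correction!r}")
    h = haps.haplotypes
    m_obs = h.shape[0] if correction == "observations" else haps.n_individuals
    if m_obs < 2:
        raise ValueError("need at least 2 haplotype observations")
    factor = m_obs / (m_obs - 1)
    chrom_arr = markers.chrom
    pos = markers.pos
    if chroms is None:
        chroms = list(dict.fromkeys(chrom_arr))
    rows = []
    for chrom in chroms:
        on = np.nonzero(chrom_arr == chrom)[0]
        length = (
            chrom_table[chrom]
            if chrom_table is not None and chrom in chrom_table
            else int(pos[on].max())
        )
        for start, end in _windows(length, window_bp, step_bp):
            idx = on[(pos[on] >= start) & (pos[on] < end)]
            if len(idx) < min_markers:
                rows.append(
                    {
                        "chrom": chrom,
                        "window_start_bp": int(start),
                        "window_end_bp": int(end),
                        "stat": np.nan,
                        "n_items": 0,
                        "n_classes": 0,
                        "defined": False,
                    }
                )
                continue
            block = h[:, idx]
            _, counts = np.unique(block, axis=0, return_counts=True)
            p = counts / counts.sum()
            hdiv = factor * (1.0 - float(np.sum(p * p)))
            rows.append(
                {
                    "chrom": chrom,
                    "window_start_bp": int(start),
                    "window_end_bp": int(end),
                    "stat": float(np.clip(hdiv, 0.0, 1.0)),
                    "n_items": int(h.shape[0]),
                    "n_classes": int(len(counts)),
                    "defined": True,
                }
            )
    return pd.DataFrame(rows)


def haplotype_diversity(block: np.ndarray, correction: str = "observations") -> float:
    """Diversity of one haplotype block (rows = haplotypes)."""
    _, counts = np.unique(np.asarray(block), axis=0, return_counts=True)
    m = block.shape[0] if correction == "observations" else block.shape[0] // 2
    p = counts / counts.sum()
    return float(np.clip(m / (m - 1) * (1 - np.sum(p * p)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# centromere characterization
# ---------------------------------------------------------------------------

@dataclass
class CentromereProfile:
    chrom: str
    junction_bp: int
    peak_value: float
    baseline_value: float
    extent_bp: int
    peak_window: tuple[int, int]


def centromere_profile(
    scan: pd.DataFrame,
    junction_bp: int,
    near_bp: float = 2e6,
    baseline_min_dist_bp: float = 10e6,
    min_baseline_windows: int = 5,
    sign: int = +1,
) -> CentromereProfile:
    """Summarize a window scan around a known junction.

    ``peak_value`` is the extreme ``stat`` among defined windows whose
    midpoint lies within ``near_bp`` of the junction (maximum for LD scans;
    pass ``sign=-1`` for diversity scans, where the signature is a trough).
    ``baseline_value`` is the median of defined windows whose midpoints are
    more than ``baseline_min_dist_bp`` away.  ``extent_bp`` is the width of
    the contiguous block of windows around the peak whose stat stays on the
    peak side of ``baseline + 0.5 (peak - baseline)``.
    """
    df = scan[scan["defined"]].copy()
    if df["chrom"].nunique() > 1:
        raise ValueError("profile expects a single-chromosome scan")
    mid = (df["window_start_bp"] + df["window_end_bp"]) / 2
    df = df.assign(mid=mid).sort_values("window_start_bp").reset_index(drop=True)
    near = df[np.abs(df["mid"] - junction_bp) <= near_bp]
    base = df[np.abs(df["mid"] - junction_bp) > baseline_min_dist_bp]
    if len(near) < 1:
        raise ValueError("no defined window within reach of the junction")
    if len(base) < min_baseline_windows:
        raise ValueError(
            f"only {len(base)} baseline windows (need {min_baseline_windows})"
        )
    s = sign * df["stat"].to_numpy()
    near_idx = near.index.to_numpy()
    peak_local = near_idx[int(np.argmax(s[near_idx]))]
    peak = float(df.loc[peak_local, "stat"])
    baseline = float(np.median(sign * base["stat"].to_numpy()) * sign)
    half = sign * baseline + 0.5 * (sign * peak - sign * baseline)
    above = s >= half
    k0 = k1 = peak_local
    while k0 - 1 >= 0 and above[k0 - 1]:
        k0 -= 1
    while k1 + 1 < len(df) and above[k1 + 1]:
        k1 += 1
    extent = int(df.loc[k1, "window_end_bp"] - df.loc[k0, "window_start_bp"])
    return CentromereProfile(
        chrom=str(df["chrom"].iloc[0]),
        junction_bp=int(junction_bp),
        peak_value=peak,
        baseline_value=baseline,
        extent_bp=extent,
        peak_window=(
            int(df.loc[peak_local, "window_start_bp"]),
            int(df.loc[peak_local, "window_end_bp"]),
        ),
    )


def rank_fusion_age(profiles: list[CentromereProfile]) -> pd.DataFrame:
    """Order fused chromosomes oldest -> newest from centromeric LD profiles.

    Heuristic staging: the centromeric high-LD region of an old fusion has
    relaxed toward equilibrium from the outside in, leaving a narrow extent;
    a recent fusion still carries a broad elevated region.  Ranking is by
    ascending ``extent_bp``, then descending ``peak_value``, then chromosome
    label (ties flagged).  Stage labels are assigned by the (peak, extent)
    quadrant relative to the profile medians.  This is a heuristic ordering,
    annotated as such in the output.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to rank")
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in profiles],
            "peak_value": [p.peak_value for p in profiles],
            "extent_bp": [p.extent_bp for p in profiles],
        }
    )
    med_peak = df["peak_value"].median()
    med_ext = df["extent_bp"].median()

    def stage(row):
        high_peak = row.peak_value >= med_peak
        large_ext = row.extent_bp >= med_ext
        if high_peak and not large_ext:
            return "stage5_old_sharp"
        if high_peak and large_ext:
            return "stage3_established"
        if not high_peak and large_ext:
            return "stage2_recent_broad"
        return "stage4_relaxing"

    df["stage"] = df.apply(stage, axis=1)
    df = df.sort_values(
        ["extent_bp", "peak_value", "chrom"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank_oldest_first"] = np.arange(1, len(df) + 1)
    df["tied"] = df.duplicated(["extent_bp", "peak_value"], keep=False)
    df["note"] = "heuristic ordering from centromeric LD profile"
    return df
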