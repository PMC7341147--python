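"""From inter-chromosomal LD evidence to fusion calls and new coordinates.

A centric (Robertsonian) fusion joins two acrocentric chromosomes at their
centromeric ends.  When the genotyped species carries the fused chromosome
but its markers are mapped on the split (acrocentric) reference, marker
pairs spanning the junction show high r² *between* reference chromosomes.
This module turns those counts into fusion candidates, orients and orders
the arms, produces an exact invertible coordinate liftover onto the fused
chromosome, and provides map-concordance and misassembly diagnostics.

Fused coordinates run from the short-arm telomere (position 0), through the
junction at ``junction_bp`` (= short-arm length), to the long-arm telomere:

* short arm, source position ``p`` -> ``junction_bp - p``
* long arm, ``junction_forward`` mode (default): ``junction_bp + p`` when
  the fusing end is the chromosome's beginning;
* long arm, ``literal`` mode: ``junction_bp + (long_len - p)``, the
  verbatim published formula, which places the long arm's fusing end at the
  far telomere.  Both conventions are exact bijections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ChromosomeTable, MarkerMap

DEFAULT_R2_MIN = 0.2


# ---------------------------------------------------------------------------
# fusion candidates
# ---------------------------------------------------------------------------

@dataclass
class FusionCandidate:
    chrom_a: str
    chrom_b: str
    n_pairs: int
    background_score: float
    end_a: str | None = None          # "begin" | "end"
    end_b: str | None = None
    junction_breadth_bp: float | None = None
    resolved: bool = False
    note: str = ""


def interchrom_ld_counts(pairs: pd.DataFrame, r2_min: float = DEFAULT_R2_MIN,
                         chrom_order=None) -> pd.DataFrame:
    """Symmetric chromosome-pair matrix of inter-chromosomal high-LD counts.

    Entry (a, b) counts marker pairs with ``r2 > r2_min`` (strict), one
    marker on each chromosome.
    """
    inter = pairs[~pairs["same_chrom"] & (pairs["r2"] > r2_min)]
    if chrom_order is None:
        # note: a pre-thresholded table only names chromosomes that survive;
        # pass the full chromosome list so zero-count pairs enter the
        # background statistics
        chrom_order = sorted(
            set(pairs["chrom_i"]).union(pairs["chrom_j"]), key=str
        )
    chrom_order = [str(c) for c in chrom_order]
    mat = pd.DataFrame(0, index=chrom_order, columns=chrom_order, dtype=np.int64)
    if len(inter):
        grouped = (
            inter.assign(
                a=np.minimum(inter["chrom_i"], inter["chrom_j"]),
                b=np.maximum(inter["chrom_i"], inter["chrom_j"]),
            )
            .groupby(["a", "b"])
            .size()
        )
        for (a, b), cnt in grouped.items():
            mat.loc[a, b] += cnt
            mat.loc[b, a] += cnt
    return mat


def detect_fusions(counts: pd.DataFrame, min_count: int = 20,
                   k_mad: float = 10.0) -> list[FusionCandidate]:
    """Call fused chromosome pairs from the inter-chromosomal count matrix.

    A pair qualifies when its count exceeds
    ``max(min_count, median + k_mad * MAD)`` over all inter-chromosomal
    counts; qualifying pairs are accepted greedily by descending count with
    each chromosome used at most once (a centric fusion consumes both
    partners).
    """
    chroms = list(counts.index)
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes")
    iu = np.triu_indices(len(chroms), k=1)
    vals = counts.to_numpy()[iu].astype(float)
    med = float(np.median(vals))
    mad = float(stats.median_abs_deviation(vals))
    thr = max(float(min_count), med + k_mad * mad)
    order = np.argsort(-vals, kind="stable")
    used: set[str] = set()
    out: list[FusionCandidate] = []
    for k in order:
        v = vals[k]
        if v <= thr:
            break
        a, b = chroms[iu[0][k]], chroms[iu[1][k]]
        if a in used or b in used:
            continue
        score = (v - med) / mad if mad > 0 else np.inf
        out.append(FusionCandidate(a, b, int(v), float(score)))
        used.update((a, b))
    return out


def localize_fusion_ends(
    pairs: pd.DataFrame,
    candidate: FusionCandidate,
    chrom_table: ChromosomeTable,
    r2_min: float = DEFAULT_R2_MIN,
    terminal_fraction: float = 0.25,
) -> FusionCandidate:
    """Decide which end of each chromosome fuses, from supporting markers.

    The median position of a chromosome's supporting markers must fall in
    the first (``begin``) or last (``end``) ``terminal_fraction`` of the
    chromosome; a median in the middle zone marks the candidate
    unresolvable rather than silently placing it.  ``junction_breadth_bp``
    records the 5th–95th percentile span of supporting-marker positions
    (the wider of the two chromosomes).
    """
    a, b = candidate.chrom_a, candidate.chrom_b
    sup = pairs[
        ~pairs["same_chrom"]
        & (pairs["r2"] > r2_min)
        & (
            ((pairs["chrom_i"] == a) & (pairs["chrom_j"] == b))
            | ((pairs["chrom_i"] == b) & (pairs["chrom_j"] == a))
        )
    ]
    ends = {}
    breadths = []
    for chrom in (a, b):
        pos = np.concatenate(
            [
                sup.loc[sup["chrom_i"] == chrom, "pos_i"].to_numpy(),
                sup.loc[sup["chrom_j"] == chrom, "pos_j"].to_numpy(),
            ]
        ).astype(float)
        if len(pos) == 0:
            candidate.resolved = False
            candidate.note = f"no supporting markers on {chrom}"
            return candidate
        frac = np.median(pos) / chrom_table[chrom]
        if frac < terminal_fraction:
            ends[chrom] = "begin"
        elif frac > 1 - terminal_fraction:
            ends[chrom] = "end"
        else:
            candidate.resolved = False
            candidate.note = (
                f"ambiguous junction on {chrom}: median at fraction {frac:.2f}"
            )
            return candidate
        breadths.append(float(np.quantile(pos, 0.95) - np.quantile(pos, 0.05)))
    candidate.end_a = ends[a]
    candidate.end_b = ends[b]
    candidate.junction_breadth_bp = max(breadths)
    candidate.resolved = True
    return candidate


# ---------------------------------------------------------------------------
# rearrangement plan and liftover
# ---------------------------------------------------------------------------

@dataclass
class Arm:
    chrom: str
    length_bp: int
    strand: str               # '+' / '-' relative to fused coordinates
    fused_end: str            # which source end abuts the junction


@dataclass
class FusedChromPlan:
    name: str
    short_arm: Arm
    long_arm: Arm
    junction_bp: int
    orientation_mode: str = "junction_forward"


@dataclass
class RearrangementPlan:
    entries: list[FusedChromPlan] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def by_source(self) -> dict[str, tuple[FusedChromPlan, str]]:
        out = {}
        for e in self.entries:
            out[e.short_arm.chrom] = (e, "short")
            out[e.long_arm.chrom] = (e, "long")
        return out

    def fused_lengths(self) -> dict[str, int]:
        return {
            e.name: e.short_arm.length_bp + e.long_arm.length_bp
            for e in self.entries
        }

    def to_frame(self) -> pd.DataFrame:
        """Chain-style table: one row per arm."""
        rows = []
        for e in self.entries:
            for role in ("short", "long"):
                arm = e.short_arm if role == "short" else e.long_arm
                rows.append(
                    {
                        "source_chrom": arm.chrom,
                        "source_start": 0,
                        "source_end": arm.length_bp,
                        "strand": arm.strand,
                        "target_chrom": e.name,
                        "target_start": 0 if role == "short" else e.junction_bp,
                        "role": role,
                        "junction_bp": e.junction_bp,
                        "orientation_mode": e.orientation_mode,
                    }
                )
        return pd.DataFrame(rows)


class CoordinateOverflow(ValueError):
    pass


def build_plan(
    candidates: list[FusionCandidate],
    chrom_table: ChromosomeTable,
    orientation_mode: str = "junction_forward",
    name_sep: str = ";",
) -> RearrangementPlan:
    """Turn resolved fusion candidates into an invertible rearrangement plan.

    The shorter source chromosome becomes the short arm and the fused
    coordinate origin is the short-arm telomere; the junction sits at the
    short-arm length.  Length ties break to the lexicographically smaller
    label (logged in ``plan.notes``).
    """
    if orientation_mode not in ("junction_forward", "literal"):
        raise ValueError(f"unknown orientation mode {orientation_mode!r}")
    plan = RearrangementPlan()
    seen: set[str] = set()
    for cand in candidates:
        if not cand.resolved:
            plan.notes.append(
                f"skipped unresolved candidate {cand.chrom_a}/{cand.chrom_b}: {cand.note}"
            )
            continue
        if cand.chrom_a in seen or cand.chrom_b in seen:
            plan.notes.append(
                f"skipped {cand.chrom_a}/{cand.chrom_b}: chromosome already used"
            )
            continue
        len_a, len_b = chrom_table[cand.chrom_a], chrom_table[cand.chrom_b]
        ends = {cand.chrom_a: cand.end_a, cand.chrom_b: cand.end_b}
        if len_a < len_b:
            short, long_ = cand.chrom_a, cand.chrom_b
        elif len_b < len_a:
            short, long_ = cand.chrom_b, cand.chrom_a
        else:
            short, long_ = sorted((cand.chrom_a, cand.chrom_b))
            plan.notes.append(
                f"length tie {cand.chrom_a}/{cand.chrom_b}: "
                f"{short} taken as short arm (lexicographic)"
            )
        junction = int(chrom_table[short])
        # short arm: fused = junction - p if begin fuses, junction - (len - p) if end
        short_strand = "-" if ends[short] == "begin" else "+"
        if orientation_mode == "literal":
            long_strand = "-"
        else:
            long_strand = "+" if ends[long_] == "begin" else "-"
        plan.entries.append(
            FusedChromPlan(
                name=f"{short}{name_sep}{long_}",
                short_arm=Arm(short, int(chrom_table[short]), short_strand, ends[short]),
                long_arm=Arm(long_, int(chrom_table[long_]), long_strand, ends[long_]),
                junction_bp=junction,
                orientation_mode=orientation_mode,
            )
        )
        seen.update((cand.chrom_a, cand.chrom_b))
    return plan


def _forward_positions(pos: np.ndarray, entry: FusedChromPlan, role: str) -> np.ndarray:
    arm = entry.short_arm if role == "short" else entry.long_arm
    j = entry.junction_bp
    if role == "short":
        if arm.fused_end == "begin":
            return j - pos
        return j - (arm.length_bp - pos)
    if entry.orientation_mode == "literal":
        return j + (arm.length_bp - pos)
    if arm.fused_end == "begin":
        return j + pos
    return j + (arm.length_bp - pos)


def _inverse_positions(fpos: np.ndarray, entry: FusedChromPlan):
    """Map fused positions back to (source chrom, source pos)."""
    j = entry.junction_bp
    short, long_ = entry.short_arm, entry.long_arm
    is_short = fpos < j
    src_chrom = np.where(is_short, short.chrom, long_.chrom)
    src_pos = np.empty_like(fpos)
    if short.fused_end == "begin":
        src_pos[is_short] = j - fpos[is_short]
    else:
        src_pos[is_short] = short.length_bp - (j - fpos[is_short])
    rest = ~is_short
    if entry.orientation_mode == "literal":
        src_pos[rest] = long_.length_bp - (fpos[rest] - j)
    elif long_.fused_end == "begin":
        src_pos[rest] = fpos[rest] - j
    else:
        src_pos[rest] = long_.length_bp - (fpos[rest] - j)
    return src_chrom, src_pos


def liftover_map(markers: MarkerMap, plan: RearrangementPlan) -> MarkerMap:
    """Rewrite marker coordinates onto the fused chromosomes.

    Markers on chromosomes absent from the plan pass through unchanged.
    Raises :class:`CoordinateOverflow` naming the first offending marker
    whose position exceeds its arm length.
    """
    by_src = plan.by_source()
    df = markers.df.copy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos_bp"].to_numpy().copy()
    new_chrom = chrom.astype(object)
    for src, (entry, role) in by_src.items():
        sel = chrom == src
        if not sel.any():
            continue
        arm = entry.short_arm if role == "short" else entry.long_arm
        p = pos[sel]
        bad = (p < 0) | (p > arm.length_bp)
        if bad.any():
            mid = df.loc[np.nonzero(sel)[0][np.nonzero(bad)[0][0]], "marker_id"]
            raise CoordinateOverflow(
                f"marker {mid!r} at {p[bad][0]} bp exceeds arm length "
                f"{arm.length_bp} of {src}"
            )
        pos[sel] = _forward_positions(p, entry, role)
        new_chrom[sel] = entry.name
    df["chrom"] = new_chrom.astype(str)
    df["pos_bp"] = pos
    return MarkerMap(df)


def invert_plan(markers: MarkerMap, plan: RearrangementPlan) -> MarkerMap:
    """Inverse liftover: fused coordinates back to the split reference.

    ``invert_plan(liftover_map(m, plan), plan)`` is the exact integer
    identity on every marker.
    """
    df = markers.df.copy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos_bp"].to_numpy().copy()
    new_chrom = chrom.astype(object)
    for entry in plan.entries:
        sel = chrom == entry.name
        if not sel.any():
            continue
        src_chrom, src_pos = _inverse_positions(pos[sel], entry)
        new_chrom[sel] = src_chrom
        pos[sel] = src_pos
    df["chrom"] = new_chrom.astype(str)
    df["pos_bp"] = pos
    return MarkerMap(df)


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

def compare_maps(map_a: MarkerMap, map_b: MarkerMap,
                 outlier_threshold: float = 3.0) -> pd.DataFrame:
    """Per-chromosome concordance between two maps sharing marker ids.

    Markers are paired by id; for each chromosome of ``map_a`` with >= 3
    shared markers the Spearman rank correlation, the OLS fit of
    ``pos_b ~ pos_a`` (slope, intercept, R²), the orientation sign
    (sign of the slope) and outliers with absolute externally studentized
    residual above ``outlier_threshold`` are reported.  Chromosomes with
    fewer shared markers are skipped.
    """
    import statsmodels.api as sm

    a = map_a.df.set_index("marker_id")
    b = map_b.df.set_index("marker_id")
    shared = a.index.intersection(b.index)
    a = a.loc[shared]
    b = b.loc[shared]
    rows = []
    for chrom, grp in a.groupby("chrom", sort=False):
        if len(grp) < 3:
            continue
        x = grp["pos_bp"].to_numpy(dtype=float)
        y = b.loc[grp.index, "pos_bp"].to_numpy(dtype=float)
        rho = float(stats.spearmanr(x, y).statistic)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        slope = float(model.params[1])
        intercept = float(model.params[0])
        if len(grp) > 3 and model.df_resid > 1 and model.ssr > 1e-12:
            resid = model.get_influence().resid_studentized_external
            out_ids = list(grp.index[np.abs(resid) > outlier_threshold])
        else:
            out_ids = []
        rows.append(
            {
                "chrom": chrom,
                "spearman_rho": rho,
                "ols_slope": slope,
                "ols_intercept_bp": intercept,
                "r_squared": float(model.rsquared),
                "orientation_sign": int(np.sign(slope)) or 1,
                "n_markers": len(grp),
                "outlier_marker_ids": out_ids,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# misplaced SNPs and translocated segments
# ---------------------------------------------------------------------------

@dataclass
class MisplacedFlag:
    marker_id: str
    evidence: str                 # "interchrom_ld" | "longrange_ld"
    n_discordant_pairs: int
    best_alternative_chrom: str | None
    mean_local_r2: float


def flag_misplaced_snps(
    pairs: pd.DataFrame,
    markers: MarkerMap,
    flag_r2: float = DEFAULT_R2_MIN,
    min_discordant: int = 3,
    far_dist_bp: float = 10e6,
    near_k: int = 5,
    local_r2_max: float = 0.05,
) -> list[MisplacedFlag]:
    """Flag markers whose LD pattern contradicts their map position.

    A marker is flagged when it has at least ``min_discordant`` partners at
    ``r2 > flag_r2`` on another chromosome or beyond ``far_dist_bp`` on its
    own, AND its mean r² to its ``near_k`` nearest mapped neighbours is
    below ``local_r2_max``.  ``pairs`` must not be truncated below
    ``flag_r2`` and must contain the local-neighbour pairs (pass an
    unthresholded table).
    """
    m = len(markers)
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    same = pairs["same_chrom"].to_numpy()
    dist = pairs["dist_bp"].to_numpy()

    discord = (r2 > flag_r2) & (~same | (same & (dist > far_dist_bp)))
    n_disc = np.zeros(m, dtype=np.int64)
    np.add.at(n_disc, i[discord], 1)
    np.add.at(n_disc, j[discord], 1)

    # modal partner chromosome of discordant inter-chromosomal pairs
    chrom_arr = markers.chrom
    partner_chrom: dict[int, dict[str, int]] = {}
    inter_disc = discord & ~same
    for a, b in zip(i[inter_disc], j[inter_disc]):
        partner_chrom.setdefault(a, {}).setdefault(chrom_arr[b], 0)
        partner_chrom[a][chrom_arr[b]] += 1
        partner_chrom.setdefault(b, {}).setdefault(chrom_arr[a], 0)
        partner_chrom[b][chrom_arr[a]] += 1

    # local r2 lookup
    r2_lookup: dict[tuple[int, int], float] = {
        (int(a), int(b)): float(v) for a, b, v in zip(i, j, r2)
    }

    pos = markers.pos
    order = markers.argsort_positional()
    flags: list[MisplacedFlag] = []
    chrom_sorted = chrom_arr[order]
    for k in np.nonzero(n_disc >= min_discordant)[0]:
        sel = order[chrom_sorted == chrom_arr[k]]
        sel = sel[sel != k]
        if len(sel) == 0:
            mean_local = 0.0
        else:
            nearest = sel[np.argsort(np.abs(pos[sel] - pos[k]), kind="stable")[:near_k]]
            vals = [
                r2_lookup.get((min(k, o), max(k, o)), np.nan) for o in nearest
            ]
            vals = [v for v in vals if np.isfinite(v)]
            mean_local = float(np.mean(vals)) if vals else 0.0
        if mean_local < local_r2_max:
            alt = None
            evidence = "longrange_ld"
            if k in partner_chrom:
                alt = max(partner_chrom[k].items(), key=lambda kv: (kv[1], kv[0]))[0]
                evidence = "interchrom_ld"
            flags.append(
                MisplacedFlag(
                    marker_id=str(markers.ids[k]),
                    evidence=evidence,
                    n_discordant_pairs=int(n_disc[k]),
                    best_alternative_chrom=alt,
                    mean_local_r2=mean_local,
                )
            )
    return flags


def detect_translocated_segments(
    pairs: pd.DataFrame,
    markers: MarkerMap,
    chrom_table: ChromosomeTable,
    r2_min: float = DEFAULT_R2_MIN,
    min_run: int = 3,
    terminal_fraction: float = 0.25,
    max_gap: int = 1,
) -> pd.DataFrame:
    """Find interior runs of markers whose LD points at another chromosome.

    A segment is a maximal run of >= ``min_run`` consecutive mapped markers
    each having at least one inter-chromosomal partner at ``r2 > r2_min`` on
    the same partner chromosome; up to ``max_gap`` consecutive markers
    without a qualifying partner are tolerated inside a run (a single weak
    marker otherwise splits a real segment in two).  Segment bounds span
    the qualifying markers only.  Runs lying entirely within
    ``terminal_fraction`` of their own chromosome are excluded — terminal
    runs are fusion evidence, not translocations.
    """
    inter = pairs[~pairs["same_chrom"] & (pairs["r2"] > r2_min)]
    chrom_arr = markers.chrom
    pos = markers.pos
    # partner chromosomes (and partner positions) per marker
    partners: dict[int, dict[str, list[int]]] = {}
    for a, b, ca, cb, pa, pb in zip(
        inter["i"].to_numpy(), inter["j"].to_numpy(),
        inter["chrom_i"], inter["chrom_j"],
        inter["pos_i"].to_numpy(), inter["pos_j"].to_numpy(),
    ):
        partners.setdefault(int(a), {}).setdefault(str(cb), []).append(int(pb))
        partners.setdefault(int(b), {}).setdefault(str(ca), []).append(int(pa))

    order = markers.argsort_positional()
    chrom_sorted = chrom_arr[order]
    rows = []
    for chrom in dict.fromkeys(chrom_sorted):
        idx = order[chrom_sorted == chrom]
        part_chroms = set()
        for k in idx:
            part_chroms.update(partners.get(int(k), {}))
        for pchrom in sorted(part_chroms):
            has = np.array([pchrom in partners.get(int(k), {}) for k in idx])
            # maximal runs of True, tolerating gaps of up to max_gap Falses
            k0 = 0
            while k0 < len(has):
                if not has[k0]:
                    k0 += 1
                    continue
                k1 = k0
                while k1 + 1 < len(has):
                    if has[k1 + 1]:
                        k1 += 1
                        continue
                    nxt = k1 + 1
                    while nxt < len(has) and not has[nxt]:
                        nxt += 1
                    if nxt < len(has) and (nxt - k1 - 1) <= max_gap:
                        k1 = nxt
                    else:
                        break
                run = idx[k0 : k1 + 1][has[k0 : k1 + 1]]
                k0 = k1 + 1
                if len(run) < min_run:
                    continue
                start, end = int(pos[run].min()), int(pos[run].max())
                L = chrom_table[chrom] if chrom in chrom_table else int(pos[idx].max())
                if end <= terminal_fraction * L or start >= (1 - terminal_fraction) * L:
                    continue
                ppos = np.concatenate(
                    [partners[int(k)][pchrom] for k in run]
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "start_bp": start,
                        "end_bp": end,
                        "partner_chrom": pchrom,
                        "partner_start_bp": int(ppos.min()),
                        "partner_end_bp": int(ppos.max()),
                        "n_support": int(sum(
                            len(partners[int(k)][pchrom]) for k in run
                        )),
                        "n_markers": int(len(run)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "partner_chrom",
            "partner_start_bp", "partner_end_bp", "n_support", "n_markers",
        ],
    )
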