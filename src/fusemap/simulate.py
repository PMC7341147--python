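"""Forward Wright–Fisher simulator of a fused-chromosome genotype panel.

The simulated species carries one or more submetacentric chromosomes formed
by centric fusion of two acrocentric ancestors, with recombination
suppressed around the junction (the centromere).  Markers are SNPs with
founder frequencies drawn from a panel-ascertainment-like law
(Uniform(0.05, 0.95) by default) and a sample-MAF ascertainment filter at
output, emulating a commercial genotyping panel.  The marker map is also
projected onto the split "ancestral acrocentric" reference — the coordinate
system in which the fused chromosome appears as two chromosomes joined at
their beginnings — which is the input the rearrangement inference expects.

Model choices:

* diploid Wright–Fisher population of ``ne`` monoecious individuals, random
  mating, discrete generations; no mutation, no selection (founder variation
  only), no crossover interference;
* recombination by a Poisson crossover process on the genetic map; the
  genetic length of an interval is recombination rate x physical length,
  multiplied by the suppression factor where the interval overlaps the
  suppressed radius around a junction;
* a fusion that happened ``fusion_time`` generations before present: in
  earlier generations its two arms segregate as independent linkage groups
  (no suppression); afterwards they form one group with junction
  suppression;
* genotypes sampled without replacement from the final generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import ChromosomeTable, GenotypeMatrix, HaplotypeSet, MarkerMap
from .rearrange import (
    Arm,
    FusedChromPlan,
    RearrangementPlan,
    invert_plan,
    liftover_map,
)


@dataclass
class FusionSpec:
    """A single centric fusion: two ancestral acrocentrics joined head-on."""

    short_chrom: str
    short_len_bp: int
    long_chrom: str
    long_len_bp: int
    fusion_time: int                      # generations before present
    suppression_factor: float = 0.01      # multiplies recomb rate near junction
    suppression_radius_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.short_len_bp > self.long_len_bp:
            raise ValueError("short arm longer than long arm")
        if not 0 < self.suppression_factor <= 1:
            raise ValueError("suppression factor must be in (0, 1]")

    @property
    def name(self) -> str:
        return f"{self.short_chrom};{self.long_chrom}"

    @property
    def junction_bp(self) -> int:
        return self.short_len_bp

    @property
    def fused_len_bp(self) -> int:
        return self.short_len_bp + self.long_len_bp


@dataclass
class MisplacementSpec:
    """Planted map corruptions written into the split reference map."""

    n_single_markers: int = 0
    segment_src_chrom: str | None = None      # split-reference labels
    segment_start_bp: int | None = None
    segment_len_bp: int | None = None
    segment_dest_chrom: str | None = None
    segment_dest_start_bp: int | None = None


@dataclass
class SimConfig:
    n_samples: int = 300
    ne: int = 300
    n_generations: int = 300
    recomb_rate_per_bp: float = 1e-8
    fusions: list[FusionSpec] = field(default_factory=list)
    decoy_chroms: dict[str, int] = field(default_factory=dict)
    n_markers: int = 3600                  # requested, pre-ascertainment
    markers_per_chrom: dict[str, int] | None = None
    marker_spacing: str = "panel"          # "panel" (even + jitter) | "uniform"
    founder_freq_law: str = "uniform"      # "uniform" | "beta"
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    founder_beta_ab: tuple[float, float] = (0.5, 0.5)
    maf_ascertainment: float = 0.05
    misplacements: MisplacementSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples > self.ne:
            raise ValueError("cannot sample more individuals than the population")
        for f in self.fusions:
            if f.fusion_time > self.n_generations:
                raise ValueError("fusion time exceeds total generations")
        if not self.fusions and not self.decoy_chroms:
            raise ValueError("no chromosomes configured")


@dataclass
class TruthSet:
    fused_map: MarkerMap                  # true coordinates on the fused genome
    split_map: MarkerMap                  # same markers on the split reference
    plan: RearrangementPlan
    chrom_table_split: ChromosomeTable
    chrom_table_fused: ChromosomeTable
    planted: dict = field(default_factory=dict)
    recomb_intensity: "pd.DataFrame | None" = None


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Default study conditions: one 40/100 Mb centric fusion among 4 decoys.

    The fusion is present for the whole simulated history (350 generations
    at Ne = 300, ~0.6 coalescent units): long enough for the suppressed
    junction to develop the centromeric signature — elevated LD, depressed
    haplotype diversity — yet short enough that the junction block retains
    segregating panel markers through the MAF ascertainment (a fully
    coalesced block would carry no markers at all, since the model has no
    mutation to replenish centromeric variation).  The recombination rate
    (1.5 cM/Mb) is mid-range for mammals.  ~3000 markers survive the
    MAF > 0.05 panel ascertainment.
    """
    cfg = dict(
        n_samples=300,
        ne=300,
        n_generations=350,
        recomb_rate_per_bp=1.5e-8,
        fusions=[
            FusionSpec(
                short_chrom="2", short_len_bp=40_000_000,
                long_chrom="1", long_len_bp=100_000_000,
                fusion_time=350,
            )
        ],
        decoy_chroms={"3": 25_000_000, "4": 25_000_000,
                      "5": 25_000_000, "6": 25_000_000},
        n_markers=5800,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _truth_plan(cfg: SimConfig) -> RearrangementPlan:
    plan = RearrangementPlan()
    for f in cfg.fusions:
        plan.entries.append(
            FusedChromPlan(
                name=f.name,
                short_arm=Arm(f.short_chrom, f.short_len_bp, "-", "begin"),
                long_arm=Arm(f.long_chrom, f.long_len_bp, "+", "begin"),
                junction_bp=f.junction_bp,
                orientation_mode="junction_forward",
            )
        )
    return plan


def _marker_layout(cfg: SimConfig, rng: np.random.Generator):
    """Physical layout: per linkage entity (fused chrom or decoy), sorted
    unique marker positions in fused coordinates."""
    entities = []  # (chrom_name, length, is_fusion, FusionSpec | None)
    for f in cfg.fusions:
        entities.append((f.name, f.fused_len_bp, f))
    for name, length in cfg.decoy_chroms.items():
        entities.append((str(name), int(length), None))
    total_len = sum(e[1] for e in entities)
    layout = []
    for name, length, fspec in entities:
        if cfg.markers_per_chrom and name in cfg.markers_per_chrom:
            m = cfg.markers_per_chrom[name]
        else:
            m = int(round(cfg.n_markers * length / total_len))
        layout.append(
            (name, length, fspec,
             _sample_positions(rng, length, m, cfg.marker_spacing))
        )
    return layout


def _sample_positions(rng: np.random.Generator, length: int, m: int,
                      spacing: str = "panel") -> np.ndarray:
    """m distinct sorted marker positions in [1, length-1].

    ``panel`` emulates array design: near-equidistant sites with +-35%
    jitter of the spacing, as commercial panels are engineered for even
    genome coverage.  ``uniform`` draws positions uniformly at random
    (clumpier than any designed panel).
    """
    if m >= length - 1:
        return np.arange(1, length)
    if spacing == "panel":
        step = length / m
        base = (np.arange(m) + 0.5) * step
        pos = base + rng.uniform(-0.35, 0.35, size=m) * step
        pos = np.clip(np.round(pos).astype(np.int64), 1, length - 1)
        pos = np.unique(pos)
        spacing = "uniform" if len(pos) < m else "done"
        if spacing == "done":
            return pos
        m_left = m - len(pos)
        extra = np.setdiff1d(rng.integers(1, length, size=4 * m_left), pos)
        return np.sort(np.concatenate([pos, extra[:m_left]]))
    pos = np.unique(rng.integers(1, length, size=2 * m))
    while len(pos) < m:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length, size=m)]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def _interval_recomb_prob(pos, length, rate, fspec: FusionSpec | None, fused: bool):
    """Per-interval recombination probabilities (Haldane) between adjacent
    markers, suppression applied when the fusion is in effect."""
    left = pos[:-1].astype(np.float64)
    right = pos[1:].astype(np.float64)
    d = (right - left) * rate
    if fspec is not None and fused:
        lo = fspec.junction_bp - fspec.suppression_radius_bp
        hi = fspec.junction_bp + fspec.suppression_radius_bp
        overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0, None)
        d = d - overlap * rate * (1 - fspec.suppression_factor)
    return d  # genetic length in Morgans per interval


def _gametes(pop: np.ndarray, parent_idx: np.ndarray, unit_slices, unit_maps,
             rng: np.random.Generator) -> np.ndarray:
    """Form one gamete per parent index by Poisson-crossover meiosis.

    ``unit_slices`` are (start, stop) marker index ranges of independently
    segregating linkage units; ``unit_maps`` the cumulative genetic position
    of each marker within its unit.
    """
    n_gam = len(parent_idx)
    m = pop.shape[1]
    parity = np.zeros((n_gam, m), dtype=np.uint8)
    for (s0, s1), cum in zip(unit_slices, unit_maps):
        width = s1 - s0
        total = float(cum[-1])
        phase = rng.integers(0, 2, size=n_gam, dtype=np.uint8)
        if total > 0:
            k = rng.poisson(total, size=n_gam)
            tot_events = int(k.sum())
            if tot_events:
                u = rng.random(tot_events) * total
                owner = np.repeat(np.arange(n_gam), k)
                # crossover between markers at-1 and at within the unit
                at = np.searchsorted(cum, u, side="right")
                seg = parity[:, s0:s1]
                np.add.at(seg, (owner, np.clip(at, 1, width - 1)), 1)
                np.cumsum(seg, axis=1, dtype=np.uint8, out=seg)
                np.bitwise_and(seg, 1, out=seg)
        parity[:, s0:s1] ^= phase[:, None]
    # pick hap_a where parity 0, hap_b where 1:  a ^ ((a ^ b) & parity)
    hap_a = pop[2 * parent_idx]
    out = pop[2 * parent_idx + 1]
    np.bitwise_xor(out, hap_a, out=out)
    np.bitwise_and(out, parity, out=out)
    np.bitwise_xor(out, hap_a, out=out)
    return out


def simulate_fused_population(cfg: SimConfig):
    """Run the simulation.

    Returns ``(HaplotypeSet, GenotypeMatrix, TruthSet)``.  Fully
    deterministic given ``cfg.seed``.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    layout = _marker_layout(cfg, rng)

    # global marker arrays (fused coordinates)
    names, lengths, fspecs, positions = zip(*layout)
    chrom_arr = np.concatenate(
        [np.repeat(n, len(p)) for n, p in zip(names, positions)]
    )
    pos_arr = np.concatenate(positions)
    m_total = len(pos_arr)
    marker_ids = np.array([f"M{k:05d}" for k in range(m_total)])

    # founder haplotypes
    if cfg.founder_freq_law == "uniform":
        lo, hi = cfg.founder_freq_range
        freqs = rng.uniform(lo, hi, size=m_total)
    elif cfg.founder_freq_law == "beta":
        a, b = cfg.founder_beta_ab
        freqs = np.clip(rng.beta(a, b, size=m_total), 1e-3, 1 - 1e-3)
    else:
        raise ValueError(f"unknown founder law {cfg.founder_freq_law!r}")
    pop = (rng.random((2 * cfg.ne, m_total)) < freqs).astype(np.uint8)

    # linkage-unit structure per epoch.  A fused chromosome contributes one
    # unit after its fusion and two (its arms, unsuppressed) before.
    slices = {}
    off = 0
    for name, length, fspec, p in layout:
        slices[name] = (off, off + len(p))
        off += len(p)

    def units_for_generation(gens_before_present: int):
        unit_slices, unit_maps = [], []
        for name, length, fspec, p in layout:
            s0, s1 = slices[name]
            if fspec is None or gens_before_present <= fspec.fusion_time:
                fused = fspec is not None
                d = _interval_recomb_prob(
                    p, length, cfg.recomb_rate_per_bp, fspec, fused=fused
                )
                if fspec is None:
                    cum = np.concatenate([[0.0], np.cumsum(d)])
                    unit_slices.append((s0, s1))
                    unit_maps.append(cum)
                else:
                    cum = np.concatenate([[0.0], np.cumsum(d)])
                    unit_slices.append((s0, s1))
                    unit_maps.append(cum)
            else:
                # pre-fusion: arms segregate independently, no suppression
                cut = int(np.searchsorted(p, fspec.junction_bp))
                d = (np.diff(p) * cfg.recomb_rate_per_bp).astype(np.float64)
                for a0, a1 in ((s0, s0 + cut), (s0 + cut, s1)):
                    if a1 > a0:
                        local = d[a0 - s0 : a1 - s0 - 1]
                        cum = np.concatenate([[0.0], np.cumsum(local)])
                        unit_slices.append((a0, a1))
                        unit_maps.append(cum)
        return unit_slices, unit_maps

    epochs: dict[int, tuple] = {}
    for g in range(cfg.n_generations, 0, -1):
        key = tuple(g <= f.fusion_time for f in cfg.fusions)
        if key not in epochs:
            epochs[key] = units_for_generation(g)

    for g in range(cfg.n_generations, 0, -1):
        key = tuple(g <= f.fusion_time for f in cfg.fusions)
        unit_slices, unit_maps = epochs[key]
        parents = rng.integers(0, cfg.ne, size=2 * cfg.ne)
        gametes = _gametes(pop, parents, unit_slices, unit_maps, rng)
        new_pop = np.empty_like(pop)
        new_pop[0::2] = gametes[: cfg.ne]      # maternal gametes
        new_pop[1::2] = gametes[cfg.ne :]      # paternal gametes
        pop = new_pop

    chosen = rng.choice(cfg.ne, size=cfg.n_samples, replace=False)
    rows = np.empty(2 * cfg.n_samples, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    sample_haps = pop[rows]
    geno = sample_haps[0::2].astype(np.int8) + sample_haps[1::2]

    # panel ascertainment on the sampled genotypes (0 disables the filter
    # entirely, keeping even fixed markers)
    p_hat = geno.mean(axis=0) / 2
    maf = np.minimum(p_hat, 1 - p_hat)
    if cfg.maf_ascertainment > 0:
        keep = maf > cfg.maf_ascertainment
    else:
        keep = np.ones(len(maf), dtype=bool)
    if not keep.any():
        raise ValueError(
            "all markers lost to MAF ascertainment; lower maf_ascertainment"
        )
    sample_haps = sample_haps[:, keep]
    geno = geno[:, keep]
    chrom_arr = chrom_arr[keep]
    pos_arr = pos_arr[keep]
    marker_ids = marker_ids[keep]

    fused_map = MarkerMap.from_arrays(marker_ids, chrom_arr, pos_arr)
    plan = _truth_plan(cfg)
    split_map = invert_plan(fused_map, plan)

    fused_table = ChromosomeTable(
        {f.name: f.fused_len_bp for f in cfg.fusions}
        | {str(k): int(v) for k, v in cfg.decoy_chroms.items()}
    )
    split_table = ChromosomeTable(
        {f.short_chrom: f.short_len_bp for f in cfg.fusions}
        | {f.long_chrom: f.long_len_bp for f in cfg.fusions}
        | {str(k): int(v) for k, v in cfg.decoy_chroms.items()}
    )

    # per-interval true recombination intensity (present-day map)
    intensity = []
    for name, length, fspec, p in layout:
        d = _interval_recomb_prob(p, length, cfg.recomb_rate_per_bp, fspec, True)
        intensity.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "start_bp": p[:-1],
                    "end_bp": p[1:],
                    "morgans": d,
                }
            )
        )
    truth = TruthSet(
        fused_map=fused_map,
        split_map=split_map,
        plan=plan,
        chrom_table_split=split_table,
        chrom_table_fused=fused_table,
        recomb_intensity=pd.concat(intensity, ignore_index=True),
    )

    # planted misplacements rewrite the split map (the analysis input)
    if cfg.misplacements is not None:
        corrupted, truth.planted, drop_idx = _plant_misplacements(
            truth.split_map, split_table, cfg.misplacements, rng
        )
        keep_idx = np.setdiff1d(np.arange(len(fused_map)), drop_idx)
        sample_haps = sample_haps[:, keep_idx]
        geno = geno[:, keep_idx]
        truth.fused_map = fused_map.subset(keep_idx)
        truth.split_map = corrupted.subset(keep_idx)

    samples = [f"S{k:03d}" for k in range(cfg.n_samples)]
    haps = HaplotypeSet(sample_haps, truth.split_map, samples)
    gmat = GenotypeMatrix(samples, truth.split_map, geno)
    return haps, gmat, truth


def _plant_misplacements(split_map: MarkerMap, table: ChromosomeTable,
                         spec: MisplacementSpec, rng: np.random.Generator):
    """Corrupt the split map: stray single markers and/or a translocated
    segment.  Returns (corrupted map with all rows kept, planted-truth dict,
    row indices the caller must drop from every companion array)."""
    df = split_map.df.copy()
    planted: dict = {"single_markers": [], "segment": None}
    drop_idx = np.array([], dtype=np.int64)

    chroms = list(dict.fromkeys(df["chrom"]))
    if spec.n_single_markers:
        cand = rng.choice(len(df), size=spec.n_single_markers, replace=False)
        for k in cand:
            true_chrom = df.at[k, "chrom"]
            others = [c for c in chroms if c != true_chrom]
            dest = others[rng.integers(0, len(others))]
            new_pos = int(rng.integers(int(0.3 * table[dest]), int(0.7 * table[dest])))
            planted["single_markers"].append(
                {
                    "marker_id": df.at[k, "marker_id"],
                    "true_chrom": str(true_chrom),
                    "true_pos_bp": int(df.at[k, "pos_bp"]),
                    "fake_chrom": str(dest),
                    "fake_pos_bp": new_pos,
                }
            )
            df.at[k, "chrom"] = dest
            df.at[k, "pos_bp"] = new_pos

    if spec.segment_src_chrom is not None:
        src = str(spec.segment_src_chrom)
        dest = str(spec.segment_dest_chrom)
        s0 = int(spec.segment_start_bp)
        s1 = s0 + int(spec.segment_len_bp)
        d0 = int(spec.segment_dest_start_bp)
        in_seg = (
            (df["chrom"] == src) & (df["pos_bp"] >= s0) & (df["pos_bp"] < s1)
        ).to_numpy()
        # clear the destination window so the planted markers are consecutive
        clash = (
            (df["chrom"] == dest)
            & (df["pos_bp"] >= d0)
            & (df["pos_bp"] < d0 + int(spec.segment_len_bp))
        ).to_numpy()
        drop_idx = np.nonzero(clash)[0]
        seg_ids = list(df.loc[in_seg, "marker_id"])
        new_pos = d0 + (df.loc[in_seg, "pos_bp"].to_numpy() - s0)
        df.loc[in_seg, "chrom"] = dest
        df.loc[in_seg, "pos_bp"] = new_pos
        planted["segment"] = {
            "marker_ids": seg_ids,
            "true_chrom": src,
            "true_start_bp": s0,
            "true_end_bp": s1,
            "fake_chrom": dest,
            "fake_start_bp": d0,
            "fake_end_bp": d0 + int(spec.segment_len_bp),
        }

    return MarkerMap(df), planted, drop_idx


def project_to_split_reference(truth: TruthSet) -> MarkerMap:
    """Re-express the true fused map on the ancestral acrocentric reference.

    Round trip with :func:`~fusemap.rearrange.liftover_map` is the exact
    integer identity.
    """
    return invert_plan(truth.fused_map, truth.plan)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture(haps: HaplotypeSet, geno: GenotypeMatrix, truth: TruthSet,
                  out_dir, formats=("plink-text", "vcf")) -> dict[str, str]:
    """Write a standard-format fixture with machine-readable ground truth."""
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for fmt in formats:
        if fmt == "vcf":
            path = out_dir / "genotypes.vcf"
            fio.write_vcf(geno, path, haplotypes=haps,
                          chrom_table=truth.chrom_table_split)
            written["vcf"] = str(path)
        else:
            prefix = out_dir / "genotypes"
            fio.write_genotypes(geno, str(prefix), fmt)
            written[fmt] = str(prefix)
    fio.write_chrom_table(truth.chrom_table_split, out_dir / "chrom_lengths.tsv")
    written["chrom_table"] = str(out_dir / "chrom_lengths.tsv")
    fio.write_marker_map(truth.fused_map, out_dir / "true_fused_map.tsv")
    truth_json = {
        "plan": truth.plan.to_frame().to_dict(orient="records"),
        "planted": truth.planted,
        "chrom_lengths_split": truth.chrom_table_split.lengths,
        "chrom_lengths_fused": truth.chrom_table_fused.lengths,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    written["truth"] = str(out_dir / "truth.json")
    return written
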