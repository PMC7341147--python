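# Methods

## The inference problem and its signal

A centric fusion joins two acrocentric chromosomes at their centromeric
ends.  If the genotyped population carries the fused chromosome but its
markers are annotated on a split reference, then marker pairs that span
the junction are physically linked yet nominally inter-chromosomal.  Around
a centromere, recombination is strongly suppressed, so these pairs stay in
high LD; the count of inter-chromosomal pairs with r² above a threshold is
therefore a direct fusion signal, and the positions of the supporting
markers identify which chromosome ends fuse.

## r² estimation

r² = D²/(p_A q_A p_B q_B) with haplotype frequencies estimated from
unphased genotypes.  Only the double heterozygote is phase-ambiguous; the
default estimator resolves it by maximum likelihood (EM, tolerance 1e-8,
at most 100 iterations, initialized at the covariance-based composite D
clipped to the admissible range).  Pairs where EM does not converge fall
back to the composite estimator (squared Pearson correlation of dosage
columns), which is also selectable outright.  The two estimators are
*not* identical even without double heterozygotes — haplotype-frequency r²
weights the 2N gametes, the composite weights N genotypes — but they agree
exactly on fully homozygous data and closely under Hardy–Weinberg
proportions.  Missing genotypes are handled by pairwise deletion; a pair
whose complete-case subset is monomorphic at either locus is skipped and
tallied.  All pair blocks are computed from nine indicator-matrix products,
so memory scales with the block and the output, not with pairs × samples.

Thresholds follow the printed QC and LD rules strictly: call rate > 0.95,
MAF > 0.05, exact-test HWE p > 1e-6 (Wigginton-style conditional test on
the heterozygote count), and "high LD" means r² > 0.2 — a pair at exactly
0.2 is excluded.

## LD decay and windowed scans

Expected r² under drift–recombination balance is the Hill–Weir function of
C = 4·Ne·c and sample size n.  `fit_ld_decay` estimates a single per-bp
coefficient β (C = β·distance) by bounded 1-D least squares: a log10 grid
of 20 multi-starts over β ∈ [1e-12, 1] plus a β = 0 evaluation, polished
with bounded scalar minimization on the log scale — the curve is monotone
but the squared-error surface can be flat, and the grid avoids its local
minima.  Fewer than `min_pairs` (10) pairs → an undefined fit (`None`),
which window scans report as `defined=False`; pairs at a single distance →
an ill-conditioned error.

The windowed LD scan (4 Mb windows, 1 Mb step) fits β per window and
reports the fitted expectation at a fixed reference distance d_ref =
100 kb, alongside the raw window mean.  Evaluating at one distance makes
windows with different marker spacing comparable; d_ref sits near the
median intra-window pair distance of a ~10 markers/Mb panel.

Haplotype diversity is Ĥ = (M/(M−1))(1 − Σ p_i²) over complete-window
haplotype classes in 1 Mb windows stepping 0.5 Mb.  M defaults to the
number of haplotype observations (2N); a literal mode using N individuals
is switchable.  Windows with fewer than 5 markers are reported undefined:
a 1–2 marker "haplotype" measures allele diversity, and such windows
otherwise dominate the low tail of along-chromosome comparisons.

`centromere_profile` summarizes a scan around a known junction: the peak
(or trough, `sign=-1`) within 2 Mb, the baseline median beyond 10 Mb, and
the extent of the contiguous half-height region.  `rank_fusion_age` orders
fused chromosomes oldest→newest by ascending extent then descending peak:
a long-suppressed junction has relaxed toward its narrow equilibrium
profile, while a recent fusion still carries a broad, lower-contrast
elevation.  The ordering is a heuristic and is annotated as such.

## Rearrangement

Fusion candidates are chromosome pairs whose high-LD count exceeds
max(20, median + 10·MAD) of all inter-chromosomal counts, accepted
greedily by descending count with each chromosome used once.  Ends are
called from the median position of supporting markers (terminal quarter =
`begin`/`end`; the middle half marks the candidate unresolvable).  The
shorter chromosome becomes the short arm (ties break lexicographically,
logged), the fused origin is the short-arm telomere and the junction sits
at the short-arm length.  Two long-arm conventions are implemented:
`junction_forward` (default; the long arm runs forward from the junction,
so the junction is the LD/diversity landmark, consistent with the
arranged-assembly scans) and `literal` (the verbatim published
formula, which places the long arm's fusing end at the far telomere).
Both are exact integer bijections with `invert_plan` as inverse.

Misplaced-marker flags implement the spirit of long-range-LD misassembly
screens: ≥ 3 partners at r² > 0.2 on another chromosome (or > 10 Mb away)
AND mean r² < 0.05 to the 5 nearest mapped neighbours; the modal partner
chromosome is reported as the likely true home.  Translocated segments are
maximal runs of ≥ 3 consecutive markers sharing an inter-chromosomal
partner chromosome, excluding terminal runs (those are fusion evidence).

## Imputation-accuracy design

Masking scenarios retain every k-th marker (k = round(1/fraction), seeded
offset) for fractions 10–30%.  Sample splits default to disjoint 4-fold
cross-validation (349 samples → 88/87/87/87 targets, mirroring a 262/87
reference/target split); independent repeated splits are available.  The
built-in imputer is a deliberately simple deterministic baseline — each
masked genotype is the sum of the two reference haplotypes best matching
the target's flanking genotypes (4 retained markers each side; the second
haplotype matches the residual after the first; ties break by haplotype
frequency then index).  It exists so the evaluation design is testable end
to end and is not a stand-in for production imputation software, whose
output can be imported from VCF and scored with the same metrics.
r²a pools cells by default (per-marker averaging switchable); PERC counts
alleles, so a one-dosage error is half right.  Map variants are compared
by one-way ANOVA on per-fold means with Tukey HSD compact letters at
α = 0.05.

## The simulator

Forward Wright–Fisher: Ne monoecious diploids, discrete generations,
random mating with selfing, no mutation, no selection, no interference.
Gametes recombine by a Poisson crossover process on the genetic map;
interval genetic lengths are rate × physical length, scaled by the
suppression factor where the interval overlaps the suppressed radius
around a fusion junction.  Before its fusion time a fusion's arms
segregate as independent unsuppressed linkage groups.  Founder haplotypes
draw allele frequencies from Uniform(0.05, 0.95) (panel-like; Beta
switchable) independently across loci.  Markers are placed near-evenly
with ±35% jitter, emulating array design (uniform-random placement is
switchable but clumpier than any engineered panel).  At output, samples
are drawn without replacement and markers with sample MAF ≤ 0.05 are
dropped — panel ascertainment; 0 disables the filter.

Default study conditions (used by the acceptance batteries): one fusion of
40 Mb + 100 Mb arms among four 25 Mb decoys; 300 samples; Ne = 300;
350 generations with the fusion present throughout; 1.5 cM/Mb;
suppression factor 0.01 within 1 Mb of the junction; 5800 requested
markers, ~3000 surviving ascertainment.  The fusion age (~0.6 coalescent
units) balances two opposing needs: the junction block must be old enough
to show elevated LD and depressed diversity, yet young enough to retain
segregating panel markers — with no mutation to replenish centromeric
variation, a fully coalesced junction carries no markers at all.  This is
also the model's main departure from real data: a real centromere is
orders of magnitude older and owes its residual marker variation to
mutation, so the simulated diversity trough is far shallower relative to
arm fluctuations than the real one.  Consequences are measured honestly by
the acceptance battery: fusion detection, plan recovery, liftover
exactness and the windowed-LD peak localize reliably, while the global
argmin of the 1 Mb diversity scan lands on the junction in only roughly
half the seeds — sparse or drift-frozen arm windows can undercut a
moderate junction trough.  Passing scan tests therefore demonstrate
correct machinery and the qualitative signature, not real-data effect
sizes.

Sizes of the batteries: the test suite runs 20 seeds for the
default-scenario battery (detection, liftover, scans, imputation
contrast) and 10 seeds each for the suppression-factor-1 null, the
planted-misplacement, the planted-segment and the no-corruption
false-positive batteries; the reproduction script runs the same code at
10 / 5 / 8 / 8 / 8 seeds respectively.

## Numerical and degenerate-input choices

Positions are 1-based externally; liftover may produce position 0 at the
short-arm telomere.  A fused position exactly at the junction belongs to
the long arm on inversion.  Genotype counts are computed in float32 matrix
products (exact for counts < 2²⁴) and promoted to float64 before EM.
ANOVA on identical values reports p = 1 with a single Tukey letter.  HWE
on monomorphic counts returns 1.  Empty-after-QC raises rather than
returning an empty matrix.  Window tiling starts at 0 and steps uniformly;
the final windows truncate at the chromosome end.

## Known limitations

* The baseline imputer is window-local: haplotypes identical across a
  flanking window but different at the masked site tie, so even imputing a
  sample against its own haplotypes is only near-perfect.
* The misplacement screen's thresholds are exposed configuration, not a
  reimplementation of any specific published recipe.
* No D′, no LD pruning, no dosage data, no sex chromosomes, no
  multi-break rearrangements beyond the segment detector.
* `rank_fusion_age` compresses a multi-stage relaxation process into two
  numbers; with staggered simulated fusions it recovers the true order in
  most but not all seeds.
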