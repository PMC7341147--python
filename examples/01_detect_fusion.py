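"""Detect a chromosome fusion from inter-chromosomal LD.

Simulates genotypes of a population carrying a 40+100 Mb fused chromosome
whose markers are mapped on the split (acrocentric) reference, counts
marker pairs in high LD between reference chromosomes, and calls the
fusion with its ends and coordinate plan.
"""

import fusemap as fm
from fusemap import ld, rearrange

haps, geno, truth = fm.simulate_fused_population(fm.default_config(seed=3))
print(f"{geno.n_samples} samples, {geno.n_markers} markers on "
      f"{len(geno.markers.chroms())} split-reference chromosomes")

pairs = ld.pairwise_r2(geno, scope="inter", r2_min=0.2)
counts = rearrange.interchrom_ld_counts(
    pairs, chrom_order=geno.markers.chroms()
)
print("\ninter-chromosomal pairs with r^2 > 0.2:")
print(counts)

cands = rearrange.detect_fusions(counts)
cand = rearrange.localize_fusion_ends(pairs, cands[0], truth.chrom_table_split)
print(f"\nfusion call: {cand.chrom_a} + {cand.chrom_b} "
      f"({cand.n_pairs} supporting pairs, ends {cand.end_a}/{cand.end_b})")

plan = rearrange.build_plan([cand], truth.chrom_table_split)
entry = plan.entries[0]
print(f"plan: fused chromosome {entry.name}, junction at "
      f"{entry.junction_bp:,} bp (= short-arm length)")
print("matches simulated truth:", entry.name == truth.plan.entries[0].name
      and entry.junction_bp == truth.plan.entries[0].junction_bp)
# The supporting-pair count stands far above the zero background of the
# decoy chromosome pairs; both fusing ends are the chromosomes' beginnings,
# as expected for a centric fusion annotated on an acrocentric reference.
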