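"""Imputation accuracy around the centromere: arranged vs split map.

Runs the masking/cross-validation design (retain 10–30% of markers, 4-fold
sample splits, baseline haplotype-matching imputer) on the junction ±1 Mb
region under both marker maps, and compares the map variants by F-test
with Tukey letters.
"""

import numpy as np

import fusemap as fm
from fusemap import imputation

haps, geno, truth = fm.simulate_fused_population(fm.default_config(seed=3))
junction = truth.plan.entries[0].junction_bp
fused_name = truth.plan.entries[0].name

region = np.nonzero(
    (truth.fused_map.chrom == fused_name)
    & (np.abs(truth.fused_map.pos - junction) <= 1e6)
)[0]
print(f"evaluation region: {len(region)} markers within 1 Mb of the junction")

results = imputation.evaluate_imputation(
    haps, geno,
    {"arranged": truth.fused_map, "non_arranged": truth.split_map},
    region, seed=3,
)
print(results.groupby(["map_variant", "metric"])["value"].mean().round(4))

cmp = imputation.region_group_comparison(results, pool_scenarios=True)
print(cmp.to_string(index=False))
# Under the split map the imputer cannot use flanking markers from the
# other side of the junction, so centromeric accuracy drops; groups not
# sharing a Tukey letter differ at alpha = 0.05.
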