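"""Genotype quality control: call rate, MAF and Hardy–Weinberg filters.

Markers are retained when call rate > ``min_call_rate`` AND minor-allele
frequency > ``min_maf`` AND exact Hardy–Weinberg p-value > ``hwe_p_min``
(all strict inequalities).  The HWE test is the exact conditional test on
the heterozygote count given the allele counts (Wigginton-style): the
p-value sums the probabilities of all heterozygote counts no more probable
than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeMatrix


@dataclass
class QCParams:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_hwe: int
    removed_ids: list[str] = field(default_factory=list)


class EmptyAfterQC(ValueError):
    pass


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (of matching parity) whose probability does not
    exceed that of the observed count.  Monomorphic data give 1.0.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no observations")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # unnormalised probabilities over all het counts with the parity of n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    probs = np.empty(len(hets), dtype=np.float64)
    # recurrence: P(h+2)/P(h) = h_homr * h_homc * 4 / ((h+2)(h+1))  (in counts)
    mid = len(hets) // 2
    probs[mid] = 1.0
    for k in range(mid, len(hets) - 1):
        h = hets[k]
        homr = (n_rare - h) // 2
        homc = n - homr - h
        probs[k + 1] = probs[k] * 4.0 * homr * homc / ((h + 2.0) * (h + 1.0))
    for k in range(mid, 0, -1):
        h = hets[k]
        homr = (n_rare - h) // 2
        homc = n - homr - h
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (homr + 1.0) * (homc + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def genotype_counts(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker genotype counts: array (markers, 3) of (n0, n1, n2)."""
    out = np.empty((g.n_markers, 3), dtype=np.int64)
    for k in range(3):
        out[:, k] = (g.calls == k).sum(axis=0)
    return out


def apply_qc(g: GenotypeMatrix, params: QCParams | None = None):
    """Filter markers; returns ``(filtered GenotypeMatrix, QCReport)``.

    Raises :class:`EmptyAfterQC` when no marker survives.
    """
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    params = params or QCParams()
    counts = genotype_counts(g)
    n_obs = counts.sum(axis=1)
    call_rate = n_obs / g.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = (counts[:, 1] + 2 * counts[:, 2]) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(p_b, 1 - p_b)
    hwe_p = np.array(
        [
            hwe_exact_pvalue(c0, c1, c2) if nob > 0 else 0.0
            for (c0, c1, c2), nob in zip(counts, n_obs)
        ]
    )
    pass_cr = call_rate > params.min_call_rate
    pass_maf = maf > params.min_maf
    pass_hwe = hwe_p > params.hwe_p_min
    keep = pass_cr & pass_maf & pass_hwe
    report = QCReport(
        n_input=g.n_markers,
        n_retained=int(keep.sum()),
        n_fail_call_rate=int((~pass_cr).sum()),
        n_fail_maf=int((~pass_maf).sum()),
        n_fail_hwe=int((~pass_hwe).sum()),
        removed_ids=list(g.markers.ids[~keep]),
    )
    if not keep.any():
        raise EmptyAfterQC(
            f"no markers left after QC (of {g.n_markers}: "
            f"{report.n_fail_call_rate} fail call rate, "
            f"{report.n_fail_maf} fail MAF, {report.n_fail_hwe} fail HWE)"
        )
    return g.subset(marker_idx=np.nonzero(keep)[0]), report
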