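"""Pairwise r-squared engine and the Hill–Weir decay model.

The r² statistic between two biallelic loci is ``D^2 / (pA qA pB qB)`` with
``D`` the deviation of the AB haplotype frequency from independence.  For
unphased genotypes the haplotype frequencies are not observable directly:
only the double heterozygote is phase-ambiguous, and the default estimator
resolves it by maximum likelihood (EM).  A composite estimator — the squared
Pearson correlation of the two genotype-dosage columns — is available as a
fallback and is used automatically for pairs where EM fails to converge.

All pair computations are chunked into marker blocks: the nine genotype
cross-count tables of a block are obtained as indicator-matrix products, so
memory grows with the block size and the output table, never with
(markers)^2 x samples.

The expected r² under drift–recombination balance follows Hill & Weir's
formula in ``C = 4 Ne c`` (scaled recombination) and the sample size ``n``;
:func:`fit_ld_decay` estimates the per-base-pair ``beta`` (``C = beta *
distance``) by bounded one-dimensional nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datamodel import MISSING, GenotypeMatrix

__all__ = [
    "pairwise_r2",
    "r2_for_pairs",
    "expected_r2_hill_weir",
    "fit_ld_decay",
    "DecayFit",
    "IllConditionedFit",
]

_EM_TOL = 1e-8
_EM_MAX_ITER = 100


class IllConditionedFit(ValueError):
    """Decay fit attempted on pairs spanning a single distance."""


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def _indicator_counts(gi: np.ndarray, gj: np.ndarray):
    """Nine cross-count tables for all (column of gi) x (column of gj) pairs.

    Returns a dict ``counts[(a, b)]`` of shape (cols_i, cols_j), plus the
    complete-case sample count per pair.
    """
    counts = {}
    ind_i = [np.ascontiguousarray((gi == a), dtype=np.float32) for a in (0, 1, 2)]
    ind_j = [np.ascontiguousarray((gj == b), dtype=np.float32) for b in (0, 1, 2)]
    for a in range(3):
        for b in range(3):
            # float32 matmul is exact for integer counts < 2^24; promote to
            # float64 so the EM iterations run at full precision
            counts[(a, b)] = (ind_i[a].T @ ind_j[b]).astype(np.float64)
    n = sum(counts.values())
    return counts, n


def _em_r2_from_counts(counts, n):
    """Vectorized EM haplotype-frequency r² from 3x3 genotype count tables.

    Returns (r2, converged, valid) arrays of the pair-block shape; ``valid``
    is False where a locus is monomorphic in the complete-case subset.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.where(n > 0, n, 1.0)
        # marginal allele-1 frequencies from the table
        gi_dose = (
            counts[(1, 0)] + counts[(1, 1)] + counts[(1, 2)]
            + 2 * (counts[(2, 0)] + counts[(2, 1)] + counts[(2, 2)])
        )
        gj_dose = (
            counts[(0, 1)] + counts[(1, 1)] + counts[(2, 1)]
            + 2 * (counts[(0, 2)] + counts[(1, 2)] + counts[(2, 2)])
        )
        p1 = gi_dose / (2 * n_safe)
        p2 = gj_dose / (2 * n_safe)
        valid = (n > 0) & (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1)

        # phase-resolved haplotype contributions (dose of allele 1 at each locus)
        c11k = 2 * counts[(2, 2)] + counts[(2, 1)] + counts[(1, 2)]
        c10k = 2 * counts[(2, 0)] + counts[(2, 1)] + counts[(1, 0)]
        c01k = 2 * counts[(0, 2)] + counts[(0, 1)] + counts[(1, 2)]
        c00k = 2 * counts[(0, 0)] + counts[(0, 1)] + counts[(1, 0)]
        dh = counts[(1, 1)]  # double heterozygotes: ambiguous

        # initialise at the composite (covariance-based) D, clipped to bounds
        mean_i = gi_dose / n_safe
        mean_j = gj_dose / n_safe
        cross = sum(
            a * b * counts[(a, b)] for a in (1, 2) for b in (1, 2)
        )
        cov = cross / n_safe - mean_i * mean_j
        d0 = cov / 2.0
        lo = np.maximum(-p1 * p2, -(1 - p1) * (1 - p2)) + 1e-6
        hi = np.minimum(p1 * (1 - p2), (1 - p1) * p2) - 1e-6
        d0 = np.clip(d0, lo, np.maximum(lo, hi))
        f11 = p1 * p2 + d0

        two_n = 2 * n_safe
        converged = np.zeros(f11.shape, dtype=bool)
        for _ in range(_EM_MAX_ITER):
            f10 = p1 - f11
            f01 = p2 - f11
            f00 = 1 - p1 - p2 + f11
            num = f11 * f00
            den = num + f10 * f01
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
            f11_new = (c11k + dh * w) / two_n
            f11_new = np.clip(f11_new, 0.0, np.minimum(p1, p2))
            delta = np.abs(f11_new - f11)
            f11 = f11_new
            newly = delta < _EM_TOL
            converged |= newly
            if newly.all():
                break

        d = f11 - p1 * p2
        denom = p1 * (1 - p1) * p2 * (1 - p2)
        r2 = np.where(valid, d * d / np.where(valid, denom, 1.0), np.nan)

        # composite fallback where EM did not converge
        var_i = cross_var(counts, (1, 2), axis=0, n=n_safe, mean=mean_i)
        var_j = cross_var(counts, (1, 2), axis=1, n=n_safe, mean=mean_j)
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = np.where(
                (var_i > 0) & (var_j > 0), cov * cov / (var_i * var_j), np.nan
            )
        r2 = np.where(converged, r2, comp)
    return np.clip(r2, 0.0, 1.0, out=r2), converged, valid


def cross_var(counts, doses, axis, n, mean):
    """Genotype variance per pair from the count tables (population form)."""
    if axis == 0:
        sq = sum(a * a * sum(counts[(a, b)] for b in (0, 1, 2)) for a in (1, 2))
    else:
        sq = sum(b * b * sum(counts[(a, b)] for a in (0, 1, 2)) for b in (1, 2))
    return sq / n - mean * mean


def _composite_r2_from_counts(counts, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.where(n > 0, n, 1.0)
        gi_dose = sum(a * sum(counts[(a, b)] for b in (0, 1, 2)) for a in (1, 2))
        gj_dose = sum(b * sum(counts[(a, b)] for a in (0, 1, 2)) for b in (1, 2))
        mean_i = gi_dose / n_safe
        mean_j = gj_dose / n_safe
        cross = sum(a * b * counts[(a, b)] for a in (1, 2) for b in (1, 2))
        cov = cross / n_safe - mean_i * mean_j
        var_i = cross_var(counts, (1, 2), 0, n_safe, mean_i)
        var_j = cross_var(counts, (1, 2), 1, n_safe, mean_j)
        valid = (n > 0) & (var_i > 0) & (var_j > 0)
        r2 = np.where(valid, cov * cov / np.where(valid, var_i * var_j, 1.0), np.nan)
    return np.clip(r2, 0.0, 1.0, out=r2), valid


def _block_r2(gi, gj, estimator):
    counts, n = _indicator_counts(gi, gj)
    if estimator == "em":
        r2, _, valid = _em_r2_from_counts(counts, n)
    elif estimator == "composite":
        r2, valid = _composite_r2_from_counts(counts, n)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return r2, valid, n


def pairwise_r2(
    g: GenotypeMatrix,
    scope: str = "all",
    r2_min: float | None = None,
    estimator: str = "em",
    max_dist_bp: float | None = None,
    chroms=None,
    block: int = 512,
) -> pd.DataFrame:
    """Compute r² for every unordered marker pair in scope.

    Parameters
    ----------
    scope:
        ``"all"``, ``"intra"`` (same chromosome) or ``"inter"``.
    r2_min:
        When given, pairs with ``r2 <= r2_min`` are omitted (strict ``>``).
    estimator:
        ``"em"`` (maximum-likelihood haplotype frequencies, default) or
        ``"composite"`` (squared genotype correlation).
    max_dist_bp:
        Restrict intra-chromosomal pairs to at most this distance (useful for
        windowed scans); ignored for inter-chromosomal pairs.
    chroms:
        Restrict to markers on these chromosomes.

    Returns
    -------
    pandas.DataFrame
        Columns ``i, j`` (marker row indices into ``g.markers``),
        ``marker_i, marker_j, chrom_i, pos_i, chrom_j, pos_j, r2, dist_bp,
        same_chrom``.  ``dist_bp`` is NaN for inter-chromosomal pairs.
        ``df.attrs["n_skipped_monomorphic"]`` tallies pairs skipped because a
        locus was monomorphic in the complete-case subset.
    """
    if scope not in ("all", "intra", "inter"):
        raise ValueError(f"unknown scope {scope!r}")
    if g.n_markers < 2:
        raise ValueError("need at least 2 markers")

    mdf = g.markers.df
    sel = np.arange(g.n_markers)
    if chroms is not None:
        chroms = {str(c) for c in chroms}
        sel = sel[mdf["chrom"].isin(chroms).to_numpy()]
    chrom_codes = pd.factorize(mdf["chrom"].to_numpy()[sel])[0]
    pos = mdf["pos_bp"].to_numpy()[sel].astype(np.float64)
    calls = g.calls[:, sel]

    out = {k: [] for k in ("i", "j", "r2")}
    n_skipped = 0
    nsel = len(sel)
    for b0 in range(0, nsel, block):
        bi = np.arange(b0, min(b0 + block, nsel))
        for b1 in range(b0, nsel, block):
            bj = np.arange(b1, min(b1 + block, nsel))
            same = chrom_codes[bi][:, None] == chrom_codes[bj][None, :]
            keep = np.ones((len(bi), len(bj)), dtype=bool)
            if scope == "intra":
                keep &= same
            elif scope == "inter":
                keep &= ~same
            if max_dist_bp is not None:
                dist = np.abs(pos[bi][:, None] - pos[bj][None, :])
                keep &= ~same | (dist <= max_dist_bp)
            # upper triangle only
            keep &= bi[:, None] < bj[None, :]
            if not keep.any():
                continue
            r2, valid, _ = _block_r2(calls[:, bi], calls[:, bj], estimator)
            n_skipped += int((keep & ~valid).sum())
            keep &= valid
            if r2_min is not None:
                keep &= r2 > r2_min
            ii, jj = np.nonzero(keep)
            out["i"].append(bi[ii])
            out["j"].append(bj[jj])
            out["r2"].append(r2[ii, jj])

    if out["i"]:
        i_loc = np.concatenate(out["i"])
        j_loc = np.concatenate(out["j"])
        r2v = np.concatenate(out["r2"])
    else:
        i_loc = j_loc = np.empty(0, dtype=np.int64)
        r2v = np.empty(0)
    i_glob, j_glob = sel[i_loc], sel[j_loc]
    same = chrom_codes[i_loc] == chrom_codes[j_loc]
    dist = np.where(same, np.abs(pos[i_loc] - pos[j_loc]), np.nan)
    ids = mdf["marker_id"].to_numpy()
    chrom_arr = mdf["chrom"].to_numpy()
    pos_arr = mdf["pos_bp"].to_numpy()
    df = pd.DataFrame(
        {
            "i": i_glob,
            "j": j_glob,
            "marker_i": ids[i_glob],
            "marker_j": ids[j_glob],
            "chrom_i": chrom_arr[i_glob],
            "pos_i": pos_arr[i_glob],
            "chrom_j": chrom_arr[j_glob],
            "pos_j": pos_arr[j_glob],
            "r2": r2v,
            "dist_bp": dist,
            "same_chrom": same,
        }
    )
    df.attrs["n_skipped_monomorphic"] = n_skipped
    df.attrs["estimator"] = estimator
    return df


def r2_for_pairs(g: GenotypeMatrix, idx_i, idx_j, estimator: str = "em") -> np.ndarray:
    """r² for an explicit list of marker-index pairs (diagonal of the block)."""
    idx_i = np.asarray(idx_i)
    idx_j = np.asarray(idx_j)
    out = np.empty(len(idx_i))
    step = 2048
    for s in range(0, len(idx_i), step):
        ii, jj = idx_i[s : s + step], idx_j[s : s + step]
        gi = g.calls[:, ii]
        gj = g.calls[:, jj]
        counts = {}
        for a in range(3):
            ia = (gi == a).astype(np.float64)
            for b in range(3):
                counts[(a, b)] = np.einsum("sk,sk->k", ia, (gj == b).astype(np.float64))
        n = sum(counts.values())
        if estimator == "em":
            r2, _, _ = _em_r2_from_counts(counts, n)
        else:
            r2, _ = _composite_r2_from_counts(counts, n)
        out[s : s + step] = r2
    return out


def write_ld_table(df: pd.DataFrame, path) -> None:
    """TSV layout column-compatible with the common inter-chromosome r² table."""
    cols = ["marker_i", "marker_j", "chrom_i", "pos_i", "chrom_j", "pos_j", "r2"]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hill–Weir expectation and decay fit
# ---------------------------------------------------------------------------

def expected_r2_hill_weir(C, n):
    """Expected r² at scaled recombination ``C = 4 Ne c`` for sample size n.

    ``E(r2) = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]``

    Tends to ``1/n`` as C grows (finite-sample floor) and to ``10/22`` plus a
    small sample term as C -> 0.
    """
    C = np.asarray(C, dtype=np.float64)
    if np.any(C < 0):
        raise ValueError("C must be nonnegative")
    if n < 2:
        raise ValueError("sample size must be >= 2")
    a = (10 + C) / ((2 + C) * (11 + C))
    b = 1 + ((3 + C) * (12 + 12 * C + C * C)) / (n * (2 + C) * (11 + C))
    out = a * b
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Result of the one-parameter LD decay fit."""

    beta: float          # 4*Ne*c per base pair, so C = beta * dist_bp
    n: int               # sample size used in the expectation
    rss: float
    n_pairs: int
    converged: bool

    def expected(self, dist_bp):
        return expected_r2_hill_weir(self.beta * np.asarray(dist_bp, float), self.n)


def fit_ld_decay(
    pairs: pd.DataFrame,
    n: int,
    min_pairs: int = 10,
    beta_bounds=(0.0, 1.0),
    n_grid: int = 20,
) -> DecayFit | None:
    """Least-squares fit of the Hill–Weir curve to observed (distance, r²).

    ``pairs`` must be intra-chromosomal rows with finite ``dist_bp``.  Returns
    ``None`` (undefined fit, not an exception) with fewer than ``min_pairs``
    pairs so window scans can emit missing values; raises
    :class:`IllConditionedFit` when all pairs sit at one distance.

    The 1-D optimum is located on a log10 multi-start grid and polished with
    bounded scalar minimization, which avoids the local minima of the
    nonlinear curve.
    """
    d = pairs["dist_bp"].to_numpy(dtype=np.float64)
    r2 = pairs["r2"].to_numpy(dtype=np.float64)
    ok = np.isfinite(d) & np.isfinite(r2)
    d, r2 = d[ok], r2[ok]
    if len(d) < min_pairs:
        return None
    if np.unique(d).size < 2:
        raise IllConditionedFit(
            f"all {len(d)} pairs at a single distance {d[0]:.0f} bp"
        )

    def rss_of_beta(beta):
        return float(np.sum((r2 - expected_r2_hill_weir(beta * d, n)) ** 2))

    lo = max(beta_bounds[0], 1e-12)
    hi = beta_bounds[1]
    grid = np.concatenate(
        [[beta_bounds[0]], np.logspace(np.log10(lo), np.log10(hi), n_grid)]
    )
    vals = [rss_of_beta(b) for b in grid]
    k = int(np.argmin(vals))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, len(grid) - 1)]
    converged = True
    if left == right:
        best = left
    elif grid[k] <= lo:
        best_beta = grid[k]
        res = minimize_scalar(
            rss_of_beta, bounds=(beta_bounds[0], right), method="bounded",
            options={"xatol": 1e-15},
        )
        best = res.x if res.fun <= rss_of_beta(best_beta) else best_beta
        converged = bool(res.success)
    else:
        # polish on log scale around the bracketing grid points
        res = minimize_scalar(
            lambda t: rss_of_beta(10.0 ** t),
            bounds=(np.log10(max(left, 1e-13)), np.log10(right)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = 10.0 ** res.x
        converged = bool(res.success)
    return DecayFit(
        beta=float(best), n=int(n), rss=rss_of_beta(best),
        n_pairs=int(len(d)), converged=converged,
    )
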