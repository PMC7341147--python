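"""Shared data model for the pipeline.

Four containers travel through every stage:

* :class:`MarkerMap` — ordered SNP markers with chromosome label, base-pair
  position and allele codes.  This is the object the rearrangement rewrites.
* :class:`ChromosomeTable` — chromosome lengths, needed to orient arms and to
  tile windows.
* :class:`GenotypeMatrix` — samples x markers counts of the B allele
  (0/1/2, ``-1`` for missing).
* :class:`HaplotypeSet` — phased binary haplotypes, two rows per individual.

Positions are 1-based externally (PLINK/VCF convention); internal arithmetic
that needs half-open intervals converts at the boundary.  Liftover formulas
may produce position 0 for a marker exactly at the short-arm telomere, so the
model tolerates ``pos_bp >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING = -1

MAP_COLUMNS = ("marker_id", "chrom", "pos_bp", "allele_a", "allele_b")


class DataModelError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class MarkerMap:
    """Ordered marker map.

    ``df`` has columns ``marker_id, chrom, pos_bp, allele_a, allele_b``;
    allele codes are single characters, ``"0"`` for unknown.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataModelError(f"marker map missing columns: {missing}")
        df = self.df.loc[:, list(MAP_COLUMNS)].reset_index(drop=True)
        df["marker_id"] = df["marker_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        self.df = df

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        marker_id,
        chrom,
        pos_bp,
        allele_a=None,
        allele_b=None,
    ) -> "MarkerMap":
        n = len(marker_id)
        return cls(
            pd.DataFrame(
                {
                    "marker_id": list(marker_id),
                    "chrom": list(chrom),
                    "pos_bp": np.asarray(pos_bp, dtype=np.int64),
                    "allele_a": ["A"] * n if allele_a is None else list(allele_a),
                    "allele_b": ["B"] * n if allele_b is None else list(allele_b),
                }
            )
        )

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def chroms(self) -> list[str]:
        """Chromosome labels in first-appearance order."""
        return list(dict.fromkeys(self.df["chrom"]))

    def sorted(self) -> "MarkerMap":
        """Copy sorted by (chrom, pos_bp); stable within ties."""
        return MarkerMap(
            self.df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(
                drop=True
            )
        )

    def argsort_positional(self) -> np.ndarray:
        """Indices that sort markers by (chrom, pos_bp), stable."""
        return np.lexsort((self.pos, self.chrom))

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def index_of(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataModelError(f"unknown marker id {exc}") from exc

    def validate(self, chrom_table: "ChromosomeTable | None" = None) -> None:
        ids = self.df["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DataModelError(f"duplicate marker id {dup!r}")
        if (self.df["pos_bp"] < 0).any():
            raise DataModelError("negative base-pair position in marker map")
        if chrom_table is not None:
            known = set(chrom_table.lengths)
            unknown = set(self.chroms()) - known
            if unknown:
                raise DataModelError(
                    f"marker chromosomes missing from chromosome table: {sorted(unknown)}"
                )
            for c, g in self.df.groupby("chrom"):
                if g["pos_bp"].max() > chrom_table.lengths[c]:
                    raise DataModelError(
                        f"marker beyond length of chromosome {c}"
                    )

    def equals(self, other: "MarkerMap") -> bool:
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


@dataclass
class ChromosomeTable:
    """Chromosome lengths in base pairs."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.lengths = {str(k): int(v) for k, v in self.lengths.items()}
        for c, length in self.lengths.items():
            if length <= 0:
                raise DataModelError(f"non-positive length for chromosome {c}")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[str(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return str(chrom) in self.lengths

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.lengths), "length_bp": list(self.lengths.values())}
        )


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-B dosage matrix (0/1/2; -1 missing)."""

    samples: list[str]
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise DataModelError("calls must be 2-D (samples x markers)")
        if calls.shape != (len(self.samples), len(self.markers)):
            raise DataModelError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DataModelError("genotype calls outside {0,1,2,missing}")
        self.calls = calls.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx]
            samples = [self.samples[i] for i in sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            calls = calls[:, marker_idx]
            markers = self.markers.subset(marker_idx)
        return GenotypeMatrix(samples, markers, calls.copy())

    def flip_alleles(self, marker_idx) -> "GenotypeMatrix":
        """Swap allele_a/allele_b labels at the given markers (g -> 2-g)."""
        marker_idx = np.atleast_1d(np.asarray(marker_idx))
        calls = self.calls.copy()
        block = calls[:, marker_idx]
        obs = block != MISSING
        block[obs] = 2 - block[obs]
        calls[:, marker_idx] = block
        df = self.markers.df.copy()
        a = df.loc[marker_idx, "allele_a"].copy()
        df.loc[marker_idx, "allele_a"] = df.loc[marker_idx, "allele_b"].to_numpy()
        df.loc[marker_idx, "allele_b"] = a.to_numpy()
        return GenotypeMatrix(list(self.samples), MarkerMap(df), calls)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.markers.equals(other.markers)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: 2 rows per individual, markers in columns.

    Row ``2i`` / ``2i+1`` are the two haplotypes of individual ``i`` in the
    companion sample ordering.
    """

    haplotypes: np.ndarray
    markers: MarkerMap | None = None
    samples: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.ndim != 2 or h.shape[0] % 2:
            raise DataModelError("haplotypes must be a (2N x M) array")
        if not np.isin(h, (0, 1)).all():
            raise DataModelError("haplotype alleles must be 0/1")
        if self.markers is not None and h.shape[1] != len(self.markers):
            raise DataModelError("haplotype width inconsistent with marker map")
        self.haplotypes = h.astype(np.uint8)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def to_genotypes(self, samples=None, markers: MarkerMap | None = None) -> GenotypeMatrix:
        g = self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
        if samples is None:
            samples = self.samples or [f"S{i}" for i in range(self.n_individuals)]
        markers = markers if markers is not None else self.markers
        if markers is None:
            markers = MarkerMap.from_arrays(
                [f"M{j}" for j in range(self.n_markers)],
                ["1"] * self.n_markers,
                np.arange(1, self.n_markers + 1),
            )
        return GenotypeMatrix(list(samples), markers, g)

    def subset_individuals(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        samples = [self.samples[i] for i in idx] if self.samples else None
        return HaplotypeSet(self.haplotypes[rows], self.markers, samples)

    def subset_markers(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        markers = self.markers.subset(idx) if self.markers is not None else None
        return HaplotypeSet(self.haplotypes[:, idx], markers, self.samples)
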