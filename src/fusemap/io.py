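"""Readers and writers for the genotype/marker formats the pipeline touches.

Supported formats
-----------------
* PLINK text (``.ped`` + ``.map``)
* PLINK 1 binary (``.bed`` + ``.bim`` + ``.fam``), SNP-major v1.00
* VCF v4.2 (plain text; read through cyvcf2, written directly).  A fully
  phased VCF additionally yields a :class:`~fusemap.datamodel.HaplotypeSet`.
* chromosome-length table as a two-column TSV
* a plain tab-separated marker map (``chrom  marker_id  pos_bp``)

Genotypes are coded as counts of ``allele_b``; in VCF terms ``allele_a`` is
REF and ``allele_b`` is ALT, in bim terms ``allele_b`` is the A1 column and
``allele_a`` A2, so the bed code ``00`` (homozygous A1) reads as dosage 2.
Multi-allelic VCF records are rejected: the method is biallelic-SNP based.

For ``.ped`` input, which carries no allele declaration, allele codes are
assigned per marker in lexicographic order of the observed alleles
(``allele_a < allele_b``); a monomorphic marker gets ``allele_b = "0"``.
Read-then-write is the identity for maps that follow the same convention;
the binary and VCF formats preserve allele order natively.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    ChromosomeTable,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
)


class ParseError(ValueError):
    """Malformed record in an input file."""


class ConsistencyError(ValueError):
    """Companion files disagree (sample/marker counts, payload size)."""


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# bed 2-bit code -> allele-B (=A1) dosage
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_genotypes(prefix_or_path, fmt: str):
    """Read genotypes in the given format.

    Parameters
    ----------
    prefix_or_path:
        For ``plink-text``/``plink-bed``: the file-set prefix (``prefix.ped``
        etc.).  For ``vcf``: the VCF path.
    fmt:
        ``"plink-text"``, ``"plink-bed"`` or ``"vcf"``.

    Returns
    -------
    (GenotypeMatrix, MarkerMap, HaplotypeSet | None)
        The haplotype set is populated only for a fully phased VCF.
    """
    if fmt == "plink-text":
        g = read_ped(prefix_or_path)
        return g, g.markers, None
    if fmt == "plink-bed":
        g = read_bed(prefix_or_path)
        return g, g.markers, None
    if fmt == "vcf":
        g, haps = read_vcf(prefix_or_path)
        return g, g.markers, haps
    raise ValueError(f"unknown format {fmt!r}")


def write_genotypes(data: GenotypeMatrix, prefix_or_path, fmt: str,
                    haplotypes: HaplotypeSet | None = None) -> list[Path]:
    """Write genotypes; returns the list of files produced."""
    if fmt == "plink-text":
        return write_ped(data, prefix_or_path)
    if fmt == "plink-bed":
        return write_bed(data, prefix_or_path)
    if fmt == "vcf":
        return [write_vcf(data, prefix_or_path, haplotypes=haplotypes)]
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# PLINK text (ped/map)
# ---------------------------------------------------------------------------

def _read_map_file(path) -> MarkerMap:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{ln}: expected 3 or 4 columns")
            chrom, mid = parts[0], parts[1]
            pos = parts[-1]
            try:
                pos = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: bad position {pos!r}") from exc
            rows.append((mid, chrom, pos))
    return MarkerMap.from_arrays(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows],
        allele_a=["0"] * len(rows), allele_b=["0"] * len(rows),
    )


def read_ped(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    markers = _read_map_file(prefix + ".map")
    m = len(markers)
    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ConsistencyError(
                    f"{prefix}.ped:{ln}: {len(parts)} fields, expected {6 + 2 * m} "
                    f"for {m} markers"
                )
            samples.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U8").reshape(m, 2))
    if allele_rows:
        alleles = np.stack(allele_rows)            # (n, m, 2)
    else:
        alleles = np.empty((0, m, 2), dtype="U8")

    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    allele_a = ["0"] * m
    allele_b = ["0"] * m
    for j in range(m):
        col = alleles[:, j, :]
        obs = col != "0"
        uniq = sorted(np.unique(col[obs]))
        if len(uniq) > 2:
            raise ParseError(
                f"{prefix}.ped: marker {markers.ids[j]!r} has >2 alleles {uniq}"
            )
        if uniq:
            allele_a[j] = uniq[0]
        if len(uniq) == 2:
            allele_b[j] = uniq[1]
        full = obs.all(axis=1)
        if len(uniq) == 2:
            calls[full, j] = (col[full] == uniq[1]).sum(axis=1)
        else:
            calls[full, j] = 0
    df = markers.df
    df["allele_a"] = allele_a
    df["allele_b"] = allele_b
    return GenotypeMatrix(samples, MarkerMap(df), calls)


def write_ped(data: GenotypeMatrix, prefix) -> list[Path]:
    prefix = str(prefix)
    mdf = data.markers.df
    for col in ("allele_a", "allele_b"):
        bad = mdf[col].astype(str).str.len() != 1
        if len(mdf) and bad.any():
            raise ValueError(
                f"unsupported allele code {mdf.loc[bad, col].iloc[0]!r} for ped output"
            )
    map_path, ped_path = Path(prefix + ".map"), Path(prefix + ".ped")
    with open(map_path, "w") as fh:
        for _, r in mdf.iterrows():
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.pos_bp}\n")
    a = mdf["allele_a"].to_numpy()
    b = mdf["allele_b"].to_numpy()
    # allele pair per dosage: 0 -> a a, 1 -> a b, 2 -> b b, missing -> 0 0
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(data.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            row = data.calls[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a[j], a[j]]
                elif g == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


# ---------------------------------------------------------------------------
# PLINK binary (bed/bim/fam)
# ---------------------------------------------------------------------------

def read_bed(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    markers = MarkerMap.from_arrays(
        bim["marker_id"], bim["chrom"], bim["pos_bp"],
        allele_a=bim["a2"], allele_b=bim["a1"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic (expect SNP-major v1.00)")
    bpm = (n + 3) // 4
    payload = raw[3:]
    if payload.size != bpm * m:
        raise ConsistencyError(
            f"{prefix}.bed: payload {payload.size} bytes, expected {bpm * m} "
            f"for {n} samples x {m} markers"
        )
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    block = payload.reshape(m, bpm)
    for shift in range(4):
        codes[:, shift::4] = (block >> (2 * shift)) & 0b11
    calls = _BED_DECODE[codes[:, :n]].T.copy()
    return GenotypeMatrix(list(fam["iid"]), markers, calls)


def write_bed(data: GenotypeMatrix, prefix) -> list[Path]:
    prefix = str(prefix)
    mdf = data.markers.df
    bim_path, fam_path, bed_path = (
        Path(prefix + ".bim"), Path(prefix + ".fam"), Path(prefix + ".bed"))
    with open(bim_path, "w") as fh:
        for _, r in mdf.iterrows():
            fh.write(
                f"{r.chrom}\t{r.marker_id}\t0\t{r.pos_bp}\t{r.allele_b}\t{r.allele_a}\n"
            )
    with open(fam_path, "w") as fh:
        for sid in data.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n, m = data.n_samples, data.n_markers
    bpm = (n + 3) // 4
    code_lut = np.zeros(256, dtype=np.uint8)
    for g, c in _BED_ENCODE.items():
        code_lut[g & 0xFF] = c
    codes = np.zeros((m, bpm * 4), dtype=np.uint8)
    codes[:, :n] = code_lut[data.calls.T.astype(np.uint8)]
    packed = np.zeros((m, bpm), dtype=np.uint8)
    for shift in range(4):
        packed |= codes[:, shift::4] << (2 * shift)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)
    return [bed_path, bim_path, fam_path]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path):
    """Read a biallelic-SNP VCF.

    Returns ``(GenotypeMatrix, HaplotypeSet | None)``; the haplotype set is
    present only when every genotype in the file is phased and non-missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, ref, alt = [], [], [], [], []
    geno_cols, hap_cols = [], []
    phased_all = True
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ParseError(
                f"{path}: record {v.CHROM}:{v.POS} is not biallelic "
                f"(ALT={v.ALT}); the method is biallelic-SNP based"
            )
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gts = v.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        hap = np.zeros((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(gts):
            a = gt[:-1]
            if len(a) != 2:
                raise ParseError(f"{path}: non-diploid call at {v.CHROM}:{v.POS}")
            if a[0] < 0 or a[1] < 0:
                col[i] = MISSING
                phased_all = False
            else:
                col[i] = a[0] + a[1]
                hap[i] = a
                if not gt[-1]:
                    phased_all = False
        geno_cols.append(col)
        hap_cols.append(hap)
    markers = MarkerMap.from_arrays(ids, chroms, poss, allele_a=ref, allele_b=alt)
    calls = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    g = GenotypeMatrix(samples, markers, calls)
    haps = None
    if phased_all and geno_cols:
        h = np.stack(hap_cols, axis=1)  # (n, m, 2)
        arr = np.empty((2 * len(samples), len(markers)), dtype=np.uint8)
        arr[0::2] = h[:, :, 0]
        arr[1::2] = h[:, :, 1]
        haps = HaplotypeSet(arr, markers, list(samples))
    return g, haps


def write_vcf(data: GenotypeMatrix, path, haplotypes: HaplotypeSet | None = None,
              chrom_table: ChromosomeTable | None = None) -> Path:
    """Write a VCF v4.2 with GT only; phased bars when haplotypes given."""
    path = Path(path)
    mdf = data.markers.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fusemap\n")
        if chrom_table is not None:
            for c, length in chrom_table.lengths.items():
                fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.samples) + "\n"
        )
        order = np.lexsort((mdf["pos_bp"].to_numpy(), mdf["chrom"].to_numpy()))
        for j in order:
            r = mdf.iloc[j]
            ref = r.allele_a if r.allele_a != "0" else "N"
            alt = r.allele_b if r.allele_b != "0" else "N"
            if haplotypes is not None:
                h0 = haplotypes.haplotypes[0::2, j]
                h1 = haplotypes.haplotypes[1::2, j]
                gts = [f"{int(a)}|{int(b)}" for a, b in zip(h0, h1)]
            else:
                lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [lut[int(g)] for g in data.calls[:, j]]
            fh.write(
                f"{r.chrom}\t{r.pos_bp}\t{r.marker_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# marker map / chromosome table TSV
# ---------------------------------------------------------------------------

def write_marker_map(markers: MarkerMap, path) -> Path:
    """Serialize a marker map as ``chrom  marker_id  pos_bp`` (sorted)."""
    markers.validate()
    path = Path(path)
    out = markers.sorted().df
    out[["chrom", "marker_id", "pos_bp"]].to_csv(
        path, sep="\t", header=True, index=False
    )
    return path


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker_id": str})
    return MarkerMap.from_arrays(
        df["marker_id"], df["chrom"], df["pos_bp"],
        allele_a=["0"] * len(df), allele_b=["0"] * len(df),
    )


def write_chrom_table(table: ChromosomeTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_chrom_table(path) -> ChromosomeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return ChromosomeTable(dict(zip(df["chrom"], df["length_bp"])))
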