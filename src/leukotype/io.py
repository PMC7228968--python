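"""Readers/writers for 10x-style matrices, GMT gene sets, mutation tables and
tri-state allele-call matrices."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix
from .simulate import ALT, NO_COVERAGE, REF, AlleleCallMatrix


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


MTX_HEADER = "%%MatrixMarket matrix coordinate integer general"


def write_tenx_like(counts: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (uncompressed).

    features.tsv carries (gene_id, gene_symbol); barcodes.tsv one barcode per
    line; sample labels go to samples.tsv so the round trip is lossless.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(counts.values),
                     field="integer")
    pd.DataFrame({"gene_id": counts.gene_ids, "gene_symbol": counts.gene_symbols}) \
        .to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_barcodes).to_csv(out / "barcodes.tsv", header=False,
                                           index=False)
    pd.Series(counts.sample_of_cell).to_csv(out / "samples.tsv", header=False,
                                            index=False)


def _dedupe(symbols: np.ndarray) -> np.ndarray:
    """Disambiguate duplicate symbols deterministically with .1, .2 suffixes."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        seen[s] = k + 1
    return np.array(out, dtype=object)


def read_tenx_like(in_dir) -> CountMatrix:
    """Read a directory written by :func:`write_tenx_like` (or 10x-shaped)."""
    d = Path(in_dir)
    mtx = d / "matrix.mtx"
    with open(mtx) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("%%MatrixMarket"):
        raise FormatError(f"{mtx}, line 1: missing MatrixMarket header: {first!r}")
    try:
        values = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    except ValueError as exc:  # scipy reports malformed size/entry lines
        raise FormatError(f"{mtx}: {exc}") from exc
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None, dtype=str)
    if features.shape[1] < 2:
        raise FormatError(f"{d / 'features.tsv'}: expected gene_id and gene_symbol "
                          "columns")
    barcodes = _read_lines(d / "barcodes.tsv")
    samples_path = d / "samples.tsv"
    if samples_path.exists():
        samples = _read_lines(samples_path)
    else:
        samples = np.full(len(barcodes), "sample", dtype=object)
    if values.shape[0] != len(features):
        raise FormatError(f"{mtx}: {values.shape[0]} rows but "
                          f"{len(features)} features")
    if values.shape[1] != len(barcodes):
        raise FormatError(f"{mtx}: {values.shape[1]} columns but "
                          f"{len(barcodes)} barcodes")
    return CountMatrix(
        values=values,
        gene_ids=features.iloc[:, 0].to_numpy(dtype=object),
        gene_symbols=_dedupe(features.iloc[:, 1].to_numpy(dtype=object)),
        cell_barcodes=np.asarray(barcodes, dtype=object),
        sample_of_cell=np.asarray(samples, dtype=object),
    )


def _read_lines(path) -> np.ndarray:
    if os.path.getsize(path) == 0:
        return np.empty(0, dtype=object)
    return pd.read_csv(path, header=None, dtype=str).iloc[:, 0].to_numpy(dtype=object)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: tab-separated set name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}, line {lineno}: GMT rows need "
                                  "name, description and >= 1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_mutation_table(path) -> pd.DataFrame:
    """Somatic mutation table from TSV or a minimal VCF.

    Returns columns variant_id, chromosome, position, ref, alt, vaf (and
    annotation if present). TSV needs a header with those names; VCF rows use
    CHROM/POS/REF/ALT and an INFO ``VAF=`` key.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        return _read_minimal_vcf(path)
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "chromosome", "position", "ref", "alt", "vaf"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    _check_vaf(df, path)
    return df


def _read_minimal_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}, line {lineno}: VCF row has "
                                  f"{len(parts)} fields, expected >= 8")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            info = dict(kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv)
            if "VAF" not in info:
                raise FormatError(f"{path}, line {lineno}: INFO lacks VAF")
            rows.append(
                {"variant_id": vid if vid != "." else f"{chrom}:{pos}:{ref}>{alt}",
                 "chromosome": chrom, "position": int(pos), "ref": ref, "alt": alt,
                 "vaf": float(info["VAF"]),
                 "annotation": info.get("ANN", "")})
    df = pd.DataFrame(rows)
    if len(df):
        _check_vaf(df, path)
    return df


def _check_vaf(df: pd.DataFrame, path) -> None:
    bad = df[(df["vaf"] < 0) | (df["vaf"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: VAF outside [0, 1] for "
                          f"{bad['variant_id'].iloc[0]}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise FormatError(f"{path}: duplicate variant_id {dup}")


def write_allele_calls(calls: AlleleCallMatrix, out_dir) -> None:
    """Sparse MTX-style allele calls (1 = ref, 2 = alt, absent = no coverage)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(calls.codes)
    scipy.io.mmwrite(str(out / "alleles.mtx"), coo, field="integer")
    pd.Series(calls.variant_ids).to_csv(out / "variants.tsv", header=False, index=False)
    pd.Series(calls.cell_barcodes).to_csv(out / "barcodes.tsv", header=False,
                                          index=False)
    pd.Series(calls.sample_of_cell).to_csv(out / "samples.tsv", header=False,
                                           index=False)


def read_allele_calls(in_dir) -> AlleleCallMatrix:
    d = Path(in_dir)
    codes = np.asarray(sp.csr_matrix(scipy.io.mmread(str(d / "alleles.mtx"))).todense())
    if not np.isin(codes, [NO_COVERAGE, REF, ALT]).all():
        raise FormatError(f"{d / 'alleles.mtx'}: entries must be 1 (ref) or 2 (alt)")
    return AlleleCallMatrix(
        codes=codes.astype(np.int8),
        variant_ids=_read_lines(d / "variants.tsv"),
        cell_barcodes=_read_lines(d / "barcodes.tsv"),
        sample_of_cell=_read_lines(d / "samples.tsv"),
    )


def read_rp_gene_list(path) -> list[str]:
    """Ribosomal-protein gene list, one symbol per line."""
    symbols = [s for s in _read_lines(path)]
    if not symbols:
        raise FormatError(f"{path}: empty RP gene list")
    return list(dict.fromkeys(symbols))
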