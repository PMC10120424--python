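"""Readers and writers for the package's file formats.

Formats handled:

* variant tables — VCF v4.x (via cyvcf2; only CHROM/POS/REF/ALT and an
  optional ``LABEL`` INFO key are consumed) or headered TSV with columns
  ``chrom  pos  ref  alt  [label]``;
* feature matrices — headered TSV, missing cells marked by a sentinel
  token (default ``NA``);
* feature metadata — YAML mapping feature name -> {category, imputation};
* cytoband intervals — BED-like 4-column file (chrom, start, end, name);
* score tracks — see :class:`remmlite.datamodel.ScoreTrack`;
* VCF annotation — scores emitted into the INFO field under key ``REMM``.

Only single-nucleotide substitutions survive variant reading; indels and
symbolic alleles are dropped, mirroring the SNV-only training sets the
scoring model is built on. Mitochondrial records can be excluded with a
flag. Chromosome names are never rewritten.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import FeatureMatrix, FeatureMeta, CytobandMap, ScoreTrack, VariantRecord

__all__ = [
    "MITO_NAMES",
    "read_variants",
    "write_variants",
    "read_feature_metadata",
    "write_feature_metadata",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_cytobands",
    "write_cytobands",
    "write_score_track",
    "read_score_track",
    "annotate_vcf",
]

#: Common spellings of the mitochondrial contig.
MITO_NAMES = frozenset({"MT", "M", "chrM", "chrMT"})


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != alt and alt.isalpha()


def read_variants(
    path: str | os.PathLike,
    format: str | None = None,
    exclude_mito: bool = False,
) -> list[VariantRecord]:
    """Read a variant table, keeping only SNVs, in file order.

    ``format`` is ``"vcf"`` or ``"tsv"``; inferred from the suffix when
    omitted. Multi-allelic VCF records contribute one record per SNV
    alternate allele. ``exclude_mito`` drops records on mitochondrial
    contigs (any spelling in :data:`MITO_NAMES`).
    """
    path = os.fspath(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        records = _read_vcf(path)
    elif format == "tsv":
        records = _read_variant_tsv(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    if exclude_mito:
        records = [v for v in records if v.chrom not in MITO_NAMES]
    return records


def _read_vcf(path: str) -> list[VariantRecord]:
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    vcf = VCF(path)
    try:
        for rec in vcf:
            label = rec.INFO.get("LABEL")
            if label is not None:
                label = int(label)
            for alt in rec.ALT:
                if not _is_snv(rec.REF, alt):
                    continue
                out.append(
                    VariantRecord(rec.CHROM, rec.POS, rec.REF, alt, label=label)
                )
    finally:
        vcf.close()
    return out


def _read_variant_tsv(path: str) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "pos", "ref", "alt"]
        if header[: len(required)] != required:
            raise ValueError(
                f"{path}:1: header must start with {required}, got {header}"
            )
        has_label = len(header) > 4 and header[4] == "label"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            chrom, pos_s, ref, alt = parts[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if not _is_snv(ref, alt):
                continue
            label = None
            if has_label and len(parts) > 4 and parts[4] != "":
                try:
                    label = int(parts[4])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad label {parts[4]!r}") from None
            out.append(VariantRecord(chrom, pos, ref, alt, label=label))
    return out


def write_variants(variants: Sequence[VariantRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\n")
        for v in variants:
            label = "" if v.label is None else str(v.label)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{label}\n")


def read_feature_metadata(path: str | os.PathLike) -> list[FeatureMeta]:
    """Read feature metadata from YAML: ``{features: {name: {category, imputation}}}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    feats = doc["features"] if isinstance(doc, dict) and "features" in doc else doc
    return [
        FeatureMeta(name, spec["category"], spec["imputation"])
        for name, spec in feats.items()
    ]


def write_feature_metadata(metadata: Sequence[FeatureMeta], path: str | os.PathLike) -> None:
    doc = {
        "features": {
            m.name: {"category": m.category, "imputation": m.imputation}
            for m in metadata
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_feature_matrix(
    path: str | os.PathLike,
    metadata: Sequence[FeatureMeta],
    na_token: str = "NA",
) -> FeatureMatrix:
    """Read a headered TSV feature matrix against declared metadata.

    Every header column must be declared in ``metadata`` and vice versa;
    columns are re-ordered to metadata order. Cells equal to ``na_token``
    become missing; all other cells must parse as finite floats.
    """
    df = pd.read_csv(
        os.fspath(path),
        sep="\t",
        na_values=[na_token],
        keep_default_na=False,
        dtype=float,
    )
    names = [m.name for m in metadata]
    unknown = [c for c in df.columns if c not in names]
    if unknown:
        raise ValueError(f"feature column {unknown[0]!r} not declared in metadata")
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"feature column {missing[0]!r} absent from {path}")
    df = df[names]
    mask = df.isna().to_numpy()
    values = df.to_numpy(dtype=float)
    values = np.where(mask, 0.0, values)
    return FeatureMatrix(values, mask, metadata)


def write_feature_matrix(
    matrix: FeatureMatrix, path: str | os.PathLike, na_token: str = "NA"
) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df = df.mask(pd.DataFrame(matrix.mask, columns=matrix.feature_names))
    df.to_csv(os.fspath(path), sep="\t", index=False, na_rep=na_token)


def read_cytobands(path: str | os.PathLike) -> CytobandMap:
    """Read a BED-like 4-column cytoband file (0-based half-open)."""
    records: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad interval bounds") from None
    return CytobandMap(records)


def write_cytobands(bands: CytobandMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in bands.records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_score_track(
    records, path: str | os.PathLike, precision: int = 3
) -> ScoreTrack:
    """Sort, validate and write ``(chrom, pos, score)`` records; returns the track."""
    track = records if isinstance(records, ScoreTrack) else ScoreTrack.from_records(records)
    track.write(path, precision=precision)
    return track


def read_score_track(path: str | os.PathLike) -> ScoreTrack:
    return ScoreTrack.read(path)


def annotate_vcf(
    vcf_in: str | os.PathLike,
    vcf_out: str | os.PathLike,
    track: ScoreTrack,
    info_key: str = "REMM",
) -> int:
    """Annotate a VCF with per-position scores from a prescored track.

    Adds ``info_key`` to the header and writes the looked-up score into the
    INFO field of every record whose position has one. Returns the number of
    records annotated.
    """
    from cyvcf2 import VCF, Writer

    vcf = VCF(os.fspath(vcf_in))
    vcf.add_info_to_header(
        {
            "ID": info_key,
            "Number": "1",
            "Type": "Float",
            "Description": "Regulatory pathogenicity score (0=benign, 1=pathogenic)",
        }
    )
    writer = Writer(os.fspath(vcf_out), vcf)
    n = 0
    try:
        for rec in vcf:
            hits = track.lookup(rec.CHROM, rec.POS, rec.POS)
            if hits:
                rec.INFO[info_key] = float(hits[0][1])
                n += 1
            writer.write_record(rec)
    finally:
        writer.close()
        vcf.close()
    return n
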