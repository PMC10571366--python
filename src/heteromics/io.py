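"""Readers and writers for the on-disk formats.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based closed)
and Bismark-style CX reports (1-based positions) are converted at this
boundary and converted back exactly on write.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .intervals import AnnotationSet, FEATURE_COLUMNS, TE_CLASSES

__all__ = [
    "read_annotation", "write_annotation_gff3", "read_counts", "write_counts",
    "read_cx_report", "write_cx_report", "read_bed_reads", "write_bed",
    "write_bedgraph", "read_allele_counts", "read_pair_table",
]

CX_CONTEXTS = ("CG", "CHG", "CHH")

_GFF_TYPE_MAP = {
    "gene": "gene", "exon": "exon", "intron": "intron",
    "transposable_element": "TE", "TE": "TE",
    "promoter": "promoter", "flank": "flank",
}
_GFF_TYPE_OUT = {v: k for k, v in _GFF_TYPE_MAP.items() if k != "TE"}
_GFF_TYPE_OUT["TE"] = "transposable_element"


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().strip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_annotation(path: str | os.PathLike) -> AnnotationSet:
    """Read a GFF3 (.gff/.gff3) or BED (.bed) annotation file.

    GFF3 coordinates (1-based closed) become ``[start-1, end)``; BED is taken
    as is. BED lines may carry three optional extra columns after BED6:
    feature_type, subgenome, te_class. Parse failures raise
    :class:`ParseError` naming the offending line.
    """
    path = os.fspath(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    if path.endswith(".bed"):
        return _read_bed_annotation(path)
    raise ValueError(f"cannot infer annotation format from {path!r}")


def _read_gff3(path: str) -> AnnotationSet:
    rows = []
    chrom_sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) == 4:
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end < start")
            if ftype not in _GFF_TYPE_MAP:
                raise ParseError(f"{path}:{lineno}: unknown feature type {ftype!r}")
            try:
                a = _parse_gff_attributes(attrs)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            te_class = a.get("te_class", "none")
            if te_class not in TE_CLASSES:
                raise ParseError(f"{path}:{lineno}: unknown te_class {te_class!r}")
            rows.append((
                seqid, start_i - 1, end_i, strand if strand in "+-" else ".",
                _GFF_TYPE_MAP[ftype], a.get("subgenome", "unknown"), te_class,
                a.get("ID", f"feat{lineno}"), a.get("Parent", ""),
            ))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return AnnotationSet(df, chrom_sizes=chrom_sizes or None)


def _read_bed_annotation(path: str) -> AnnotationSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"feat{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            ftype = fields[6] if len(fields) > 6 else "gene"
            subgenome = fields[7] if len(fields) > 7 else "unknown"
            te_class = fields[8] if len(fields) > 8 else "none"
            if te_class not in TE_CLASSES:
                raise ParseError(f"{path}:{lineno}: unknown te_class {te_class!r}")
            rows.append((chrom, start, end, strand, ftype, subgenome, te_class, name, ""))
    return AnnotationSet(pd.DataFrame(rows, columns=FEATURE_COLUMNS))


def write_annotation_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write an :class:`AnnotationSet` as GFF3 (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in sorted(annotation.chrom_sizes.items()):
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for row in annotation.features.itertuples(index=False):
            attrs = [f"ID={row.id}"]
            if row.parent:
                attrs.append(f"Parent={row.parent}")
            if row.subgenome != "unknown":
                attrs.append(f"subgenome={row.subgenome}")
            if row.te_class != "none":
                attrs.append(f"te_class={row.te_class}")
            fh.write(
                f"{row.chrom}\theteromics\t{_GFF_TYPE_OUT[row.feature_type]}\t"
                f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{';'.join(attrs)}\n"
            )


def read_counts(path: str | os.PathLike, design: dict | pd.DataFrame) -> ExpressionMatrix:
    """Read a TSV count matrix (first column gene ids, header sample names).

    ``design`` maps each sample name to ``(genotype, replicate)`` (dict) or is
    a DataFrame indexed by sample with genotype/replicate columns; it must
    cover every sample column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(design, dict):
        meta = pd.DataFrame(
            {s: {"genotype": g, "replicate": r} for s, (g, r) in design.items()}
        ).T
        meta.index.name = "sample"
    else:
        meta = design.copy()
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    meta = meta.loc[df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError("non-numeric count encountered")
    if (numeric.to_numpy() < 0).any():
        raise ValueError("negative count encountered")
    counts = numeric.round().astype(np.int64)
    return ExpressionMatrix(counts=counts, sample_meta=meta)


def write_counts(em: ExpressionMatrix, path: str | os.PathLike) -> None:
    em.counts.to_csv(path, sep="\t", index_label="gene")


def read_cx_report(path: str | os.PathLike, genotype: str | None = None) -> pd.DataFrame:
    """Read a Bismark-style CX cytosine report.

    Columns: chrom, 1-based position, strand, count methylated, count
    unmethylated, context (CG/CHG/CHH), trinucleotide. Positions are converted
    to 0-based; a ``total`` column is added. Unknown contexts are an error.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
        dtype={"chrom": str, "pos": np.int64, "strand": str,
               "meth": np.int64, "unmeth": np.int64, "context": str, "tri": str},
    )
    if len(df) == 0:
        df = df.assign(total=pd.Series(dtype=np.int64))
        return df
    bad = set(df["context"]) - set(CX_CONTEXTS)
    if bad:
        raise ValueError(f"unknown cytosine context(s): {sorted(bad)}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError("negative counts in CX report")
    df["pos"] = df["pos"] - 1
    df["total"] = df["meth"] + df["unmeth"]
    if genotype is not None:
        df["genotype"] = genotype
    return df


def write_cx_report(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write CX records (0-based ``pos``) back to the 1-based report dialect."""
    out = records[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_reads(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file of read (or cluster) intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "score": str, "strand": str},
    )
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        raise ValueError("invalid BED interval (need 0 <= start < end)")
    return df


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a BED6 file; missing name/score/strand columns are filled."""
    df = intervals.copy()
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str | os.PathLike) -> None:
    """Write chrom/start/end plus one value column as bedGraph."""
    out = df[["chrom", "start", "end", value_col]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_allele_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read the allele-count table: gene, F, M, HF, HM, fpkm_min."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "F", "M", "HF", "HM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    for col in ("F", "M", "HF", "HM"):
        if (df[col] < 0).any():
            raise ValueError(f"negative allele counts in column {col}")
    return df


def read_pair_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the homoeolog pair table: an_gene, dn_gene."""
    df = pd.read_csv(path, sep="\t")
    missing = {"an_gene", "dn_gene"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return df
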