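"""Genomic intervals and the feature annotation container.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Conversion to/from 1-based closed dialects (GFF3, CX reports) happens only at
the I/O boundary (:mod:`heteromics.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_TYPES = frozenset({"gene", "exon", "intron", "TE", "promoter", "flank"})
SUBGENOMES = frozenset({"An", "Dn", "unknown"})
TE_CLASSES = frozenset({"DNA", "LTR-copia", "LTR-gypsy", "LINE", "SINE", "none"})

#: Columns of the annotation feature table.
FEATURE_COLUMNS = [
    "chrom", "start", "end", "strand",
    "feature_type", "subgenome", "te_class", "id", "parent",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class AnnotationSet:
    """Gene/TE/exon annotation held as a validated feature table.

    Parameters
    ----------
    features : pandas.DataFrame
        Must carry :data:`FEATURE_COLUMNS`. ``parent`` links exons/introns to
        their gene id (empty string otherwise).
    chrom_sizes : dict, optional
        Chromosome lengths; required only by simulators and flank clipping.
    """

    def __init__(self, features: pd.DataFrame, chrom_sizes: dict[str, int] | None = None):
        df = features.copy().reset_index(drop=True)
        if "parent" not in df.columns:
            df["parent"] = ""
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        df = df[FEATURE_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self._validate(df)
        self.features = df
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval [{bad['start']}, {bad['end']}) for feature {bad['id']!r}"
            )
        unknown_type = set(df["feature_type"]) - FEATURE_TYPES
        if unknown_type:
            raise ValueError(f"unknown feature types: {sorted(unknown_type)}")
        unknown_te = set(df["te_class"]) - TE_CLASSES
        if unknown_te:
            raise ValueError(f"unknown te_class values: {sorted(unknown_te)}")
        unknown_sg = set(df["subgenome"]) - SUBGENOMES
        if unknown_sg:
            raise ValueError(f"unknown subgenome values: {sorted(unknown_sg)}")
        # ids unique within a feature type
        dup = df.groupby("feature_type")["id"].apply(lambda s: s.duplicated().any())
        if dup.any():
            raise ValueError(
                f"duplicate ids within feature type(s): {list(dup[dup].index)}"
            )
        # exons lie within their gene
        genes = df[df["feature_type"] == "gene"].set_index("id")
        sub = df[df["feature_type"].isin(["exon", "intron"])]
        for _, row in sub.iterrows():
            if row["parent"] not in genes.index:
                raise ValueError(f"{row['feature_type']} {row['id']!r} has no parent gene")
            g = genes.loc[row["parent"]]
            if row["start"] < g["start"] or row["end"] > g["end"] or row["chrom"] != g["chrom"]:
                raise ValueError(
                    f"{row['feature_type']} {row['id']!r} extends outside gene {row['parent']!r}"
                )

    def subset(self, feature_type: str) -> pd.DataFrame:
        return self.features[self.features["feature_type"] == feature_type]

    @property
    def genes(self) -> pd.DataFrame:
        return self.subset("gene")

    @property
    def tes(self) -> pd.DataFrame:
        return self.subset("TE")

    def __len__(self) -> int:
        return len(self.features)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.features.equals(other.features)


def overlap_lengths(
    query: pd.DataFrame, targets: pd.DataFrame
) -> np.ndarray:
    """Total overlap (bp) of each query interval with the union of targets.

    Both frames need ``chrom``/``start``/``end`` columns. Overlapping target
    intervals are merged per chromosome first so shared basepairs are not
    double counted.
    """
    out = np.zeros(len(query), dtype=np.int64)
    if len(targets) == 0 or len(query) == 0:
        return out
    for chrom, tgt in targets.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        merged_s, merged_e = merge_intervals(
            tgt["start"].to_numpy(), tgt["end"].to_numpy()
        )
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        # cumulative covered bp up to each merged-interval end
        cum = np.concatenate([[0], np.cumsum(merged_e - merged_s)])
        ov = np.zeros(len(qs), dtype=np.int64)
        # for each query, sum of clip(min(e, me)-max(s, ms), 0) over merged
        i0 = np.searchsorted(merged_e, qs, side="right")
        i1 = np.searchsorted(merged_s, qe, side="left")
        for j, (s, e, a, b) in enumerate(zip(qs, qe, i0, i1)):
            if a >= b:
                continue
            ov[j] = (
                cum[b] - cum[a]
                - max(0, s - merged_s[a])
                - max(0, merged_e[b - 1] - e)
            )
        out[mask] = ov
    return out


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into a sorted disjoint set."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [], []
    cur_s, cur_e = None, None
    for a, b in zip(s, e):
        if cur_s is None:
            cur_s, cur_e = a, b
        elif a <= cur_e:
            cur_e = max(cur_e, b)
        else:
            keep_s.append(cur_s)
            keep_e.append(cur_e)
            cur_s, cur_e = a, b
    if cur_s is not None:
        keep_s.append(cur_s)
        keep_e.append(cur_e)
    return np.asarray(keep_s, dtype=np.int64), np.asarray(keep_e, dtype=np.int64)


def any_overlap(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean: does each query interval overlap >=1 bp of any target."""
    return overlap_lengths(query, targets) > 0


def gene_flanks(
    genes: pd.DataFrame, flank: int, chrom_sizes: dict[str, int] | None = None,
    which: str = "both",
) -> pd.DataFrame:
    """Strand-aware flanking intervals of genes.

    ``which`` selects "up" (upstream of TSS), "down" (downstream of TES) or
    "both". Upstream/downstream follow gene strand; "." is treated as "+".
    """
    rows = []
    for _, g in genes.iterrows():
        minus = g["strand"] == "-"
        size = (chrom_sizes or {}).get(g["chrom"], np.iinfo(np.int64).max)
        up = (max(0, g["start"] - flank), g["start"]) if not minus else (
            g["end"], min(size, g["end"] + flank))
        down = (g["end"], min(size, g["end"] + flank)) if not minus else (
            max(0, g["start"] - flank), g["start"])
        if which in ("up", "both") and up[0] < up[1]:
            rows.append((g["chrom"], up[0], up[1], g["strand"], g["id"], "up"))
        if which in ("down", "both") and down[0] < down[1]:
            rows.append((g["chrom"], down[0], down[1], g["strand"], g["id"], "down"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene", "side"])
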