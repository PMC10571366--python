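"""24-nt siRNA cluster calling, quantification and genomic annotation.

Clusters are discovered on the pooled reads of all samples with a single
linear sweep (a new cluster opens when a read starts more than ``max_gap``
bp past the current cluster end), then quantified per sample against the
final intervals so every genotype shares one coordinate set. Cluster
abundance (reads per million 24-nt reads) is tested against the mid-parent
value with the expression engine; clusters are annotated by precedence
TE > gene-body > flank > intergenic with a minimum overlap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .diffexpr import DEThresholds, test_de
from .intervals import AnnotationSet, gene_flanks, overlap_lengths

__all__ = [
    "ClusterParams", "call_clusters", "quantify_clusters", "cluster_rpm",
    "de_clusters_vs_mpv", "annotate_clusters", "te_expression_change",
]

READ_LENGTH = 24


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 100
    min_reads: int = 10
    min_span: int = 50


def _filter_24nt(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    keep = (reads["end"] - reads["start"]) == READ_LENGTH
    return reads[keep], int((~keep).sum())


def call_clusters(
    reads: dict[str, pd.DataFrame], params: ClusterParams = ClusterParams()
) -> tuple[pd.DataFrame, int]:
    """Call clusters on pooled samples and re-tally per-sample counts.

    ``reads`` maps sample name -> BED-like frame of 24-nt intervals. Returns
    (clusters, n_skipped) where clusters carry chrom/start/end/span plus one
    ``reads_<sample>`` column each, and n_skipped counts non-24-nt reads.
    """
    skipped = 0
    pooled = []
    filtered = {}
    for sample, df in reads.items():
        ok, bad = _filter_24nt(df)
        skipped += bad
        filtered[sample] = ok
        pooled.append(ok[["chrom", "start", "end"]])
    pool = pd.concat(pooled, ignore_index=True) if pooled else pd.DataFrame(
        columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in pool.groupby("chrom", sort=True):
        starts = np.sort(grp["start"].to_numpy())
        ends = starts + READ_LENGTH
        if len(starts) == 0:
            continue
        # sweep: break where a read's start exceeds the running cluster end
        # by more than max_gap
        run_end = np.maximum.accumulate(ends)
        brk = np.flatnonzero(starts[1:] - run_end[:-1] > params.max_gap) + 1
        bounds = np.concatenate([[0], brk, [len(starts)]])
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            s, e = int(starts[lo]), int(run_end[hi - 1])
            n = int(hi - lo)
            if n >= params.min_reads and e - s >= params.min_span:
                rows.append({"chrom": chrom, "start": s, "end": e,
                             "span": e - s, "reads_pooled": n})
    clusters = pd.DataFrame(rows, columns=["chrom", "start", "end", "span", "reads_pooled"])
    clusters = quantify_clusters(clusters, filtered)
    return clusters, skipped


def quantify_clusters(clusters: pd.DataFrame, reads: dict[str, pd.DataFrame]
                      ) -> pd.DataFrame:
    """Per-sample read counts against fixed cluster intervals.

    A read is assigned to a cluster when its start lies inside the cluster
    interval (clusters are disjoint by construction).
    """
    out = clusters.copy()
    for sample, df in reads.items():
        counts = np.zeros(len(out), dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=False):
            mask = (out["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            cs = out.loc[mask, "start"].to_numpy()
            ce = out.loc[mask, "end"].to_numpy()
            pos = np.sort(grp["start"].to_numpy())
            counts[mask] = np.searchsorted(pos, ce, side="left") - np.searchsorted(
                pos, cs, side="left")
        out[f"reads_{sample}"] = counts
    return out


def cluster_rpm(clusters: pd.DataFrame, library_sizes: dict[str, int]) -> pd.DataFrame:
    """Reads per million aligned 24-nt reads, per sample."""
    out = clusters.copy()
    for sample, lib in library_sizes.items():
        if lib <= 0:
            raise ValueError(f"library size for {sample} must be positive")
        out[f"rpm_{sample}"] = out[f"reads_{sample}"] * 1e6 / lib
    return out


def de_clusters_vs_mpv(
    clusters: pd.DataFrame,
    samples: dict[str, list[str]],
    fc: float = 1.5, q_max: float = 0.05,
    pseudocount: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Hybrid-vs-MPV differential test of cluster RPM.

    ``samples`` maps genotype F/M/H to its sample-name lists (paired by
    replicate order). MPV pseudo-replicates are (F_i + M_i)/2 on the RPM
    scale; the expression engine runs on log2(rpm + 0.01) with the
    |fold change| >= fc and BH q <= q_max gate. Returns the annotated table
    and a summary (fractions above/below MPV among DE clusters, skewness of
    log2(H/MPV)).
    """
    f = clusters[[f"rpm_{s}" for s in samples["F"]]].to_numpy()
    m = clusters[[f"rpm_{s}" for s in samples["M"]]].to_numpy()
    h = clusters[[f"rpm_{s}" for s in samples["H"]]].to_numpy()
    if f.shape[1] != m.shape[1]:
        raise ValueError("unequal parental replicate counts")
    mpv = (f + m) / 2.0
    thresholds = DEThresholds(fc_min=float(np.log2(fc)), p_max=1.0, q_max=q_max)
    res = test_de(mpv, h, thresholds=thresholds, pseudocount=pseudocount)
    out = clusters.copy()
    out["log2fc_mpv"] = res["log2fc"].to_numpy(dtype=float)
    out["p"] = res["p"].to_numpy(dtype=float)
    out["q"] = res["q"].to_numpy(dtype=float)
    out["de_status"] = res["status"].to_numpy()
    de = out[out["de_status"] != "ns"]
    n_de = len(de)
    lfc = out["log2fc_mpv"].to_numpy()
    summary = {
        "fraction_de": n_de / len(out) if len(out) else float("nan"),
        "fraction_above_mpv": float((de["de_status"] == "up").mean()) if n_de else float("nan"),
        "fraction_below_mpv": float((de["de_status"] == "down").mean()) if n_de else float("nan"),
        "skewness_log2fc": float(_sps.skew(lfc)) if len(out) > 2 else float("nan"),
    }
    return out, summary


def annotate_clusters(
    clusters: pd.DataFrame, annotation: AnnotationSet,
    flank: int = 2000, min_frac: float = 0.5,
) -> tuple[pd.Series, dict]:
    """Label clusters TE / gene-body / flank-up / flank-down / intergenic.

    Precedence TE > gene-body > flank (strand-aware up/down) > intergenic; a
    label needs >= min_frac of the cluster length overlapping the region.
    Returns (labels, summary with the TE-colocalized fraction).
    """
    q = clusters[["chrom", "start", "end"]]
    length = (q["end"] - q["start"]).to_numpy()
    genes = annotation.genes
    up = gene_flanks(genes, flank, annotation.chrom_sizes or None, which="up")
    down = gene_flanks(genes, flank, annotation.chrom_sizes or None, which="down")
    te_ov = overlap_lengths(q, annotation.tes)
    gene_ov = overlap_lengths(q, genes)
    up_ov = overlap_lengths(q, up)
    down_ov = overlap_lengths(q, down)
    need = min_frac * length
    label = np.select(
        [te_ov >= need, gene_ov >= need, up_ov >= need, down_ov >= need],
        ["TE", "gene-body", "flank-up", "flank-down"],
        default="intergenic",
    )
    labels = pd.Series(label, index=clusters.index, name="annotation")
    summary = {
        "te_fraction": float((labels == "TE").mean()) if len(labels) else float("nan"),
        "by_label": labels.value_counts().to_dict(),
    }
    return labels, summary


def te_expression_change(
    te_means: pd.DataFrame, fc: float = 1.5,
    sirna_te_ids=None,
) -> tuple[pd.Series, dict]:
    """Up/down/ns call per TE from normalized genotype means vs MPV.

    ``te_means`` needs columns mean_F, mean_M, mean_H indexed by TE id; a TE
    is up when H/MPV > fc and down when H/MPV < 1/fc. ``sirna_te_ids``
    optionally marks the TEs bearing 24-nt siRNA clusters, adding the
    fraction of those that are down to the summary.
    """
    mpv = (te_means["mean_F"] + te_means["mean_M"]) / 2.0
    ratio = (te_means["mean_H"] + 1e-9) / (mpv + 1e-9)
    status = pd.Series(
        np.where(ratio > fc, "up", np.where(ratio < 1.0 / fc, "down", "ns")),
        index=te_means.index, name="status",
    )
    lfc = np.log2(ratio)
    summary = {
        "n_up": int((status == "up").sum()),
        "n_down": int((status == "down").sum()),
        "log2fc": pd.Series(lfc, index=te_means.index),
    }
    if sirna_te_ids is not None:
        bearing = status.index.isin(set(sirna_te_ids))
        sub = status[bearing]
        summary["sirna_te_down_fraction"] = (
            float((sub == "down").mean()) if len(sub) else float("nan"))
    return status, summary
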