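"""Methylome analysis: context levels, site calls, metaplots, DMRs, patterns.

Per-cytosine calls (CG/CHG/CHH contexts; H = A, C or T) are aggregated into
100-bp windows per genotype. DMRs between genotypes come from Fisher's exact
test on pooled window counts with BH control per context, a context-specific
minimum methylation difference (CG 0.4, CHG 0.2, CHH 0.1), and merging of
adjacent same-direction windows. Hybrid windows are additionally tested
against the mid-parent value (MPV, rounded half-sums of parental counts):
significant hybrid-vs-MPV differences are "interactive" DMRs, split into
trans-chromosomal methylation (TCM, hybrid above MPV) and demethylation
(TCdM, hybrid below). Single positions are called methylated with a one-sided
binomial test against the residual non-conversion rate, which also drives the
eight-way (F, M, H) parental patterning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_stepup, fisher_exact_many
from .intervals import AnnotationSet, gene_flanks, overlap_lengths

__all__ = [
    "DMRParams", "make_windows", "context_levels", "call_methylated_site",
    "call_methylated_sites", "metaplot", "call_dmrs", "classify_vs_mpv",
    "pattern_id_from_states", "PATTERN_NAMES", "parental_pattern",
    "annotate_dmrs", "identify_dmgs", "expression_quartile_methylation",
]

CONTEXTS = ("CG", "CHG", "CHH")
GENOTYPES = ("F", "M", "H")


@dataclass(frozen=True)
class DMRParams:
    """Window/DMR calling parameters (all configurable)."""

    window: int = 100
    min_cytosines: dict = field(default_factory=lambda: {"CG": 4, "CHG": 4, "CHH": 6})
    min_reads: int = 10                 # per genotype per window
    q_max: float = 0.05
    min_delta: dict = field(default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1})
    merge_gap: int = 200
    mpv_q_max: float = 0.01             # interactive (TCM/TCdM) gate


def make_windows(records: dict[str, pd.DataFrame], window: int = 100) -> pd.DataFrame:
    """Aggregate per-genotype CX records into fixed windows per context.

    Returns one row per (chrom, start, context) carrying, for each genotype,
    ``meth_G``, ``total_G``, ``n_G`` (cytosines with coverage) and ``level_G``.
    """
    pieces = []
    for geno, df in records.items():
        g = df.copy()
        g["start"] = (g["pos"] // window) * window
        g["covered"] = (g["total"] > 0).astype(np.int64)
        agg = (
            g.groupby(["chrom", "start", "context"], sort=True)
            .agg(meth=("meth", "sum"), total=("total", "sum"), n=("covered", "sum"))
            .rename(columns=lambda c: f"{c}_{geno}")
        )
        pieces.append(agg)
    out = pd.concat(pieces, axis=1).fillna(0).reset_index()
    out["end"] = out["start"] + window
    for geno in records:
        for col in (f"meth_{geno}", f"total_{geno}", f"n_{geno}"):
            out[col] = out[col].astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"level_{geno}"] = out[f"meth_{geno}"] / out[f"total_{geno}"]
    cols = ["chrom", "start", "end", "context"]
    return out[cols + [c for c in out.columns if c not in cols]]


def call_methylated_site(methylated, total, error_rate: float = 0.006) -> np.ndarray:
    """One-sided exact binomial p-value P(X >= methylated | total, error_rate)."""
    methylated = np.asarray(methylated, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    return stats.binom.sf(methylated - 1, total, error_rate)


def call_methylated_sites(
    records: pd.DataFrame, error_rate: float = 0.006,
    min_cov: int = 4, q_max: float = 0.01,
) -> pd.DataFrame:
    """Binomial site calls with BH across sites per context.

    Sites below ``min_cov`` are excluded. Returns the covered records with
    ``p``, ``q`` and boolean ``methylated`` columns.
    """
    covered = records[records["total"] >= min_cov].copy()
    covered["p"] = call_methylated_site(covered["meth"], covered["total"], error_rate)
    covered["q"] = 1.0
    for ctx in CONTEXTS:
        mask = covered["context"] == ctx
        if mask.any():
            covered.loc[mask, "q"] = bh_stepup(covered.loc[mask, "p"].to_numpy())
    covered["methylated"] = covered["q"] <= q_max
    return covered


def context_levels(records: pd.DataFrame, error_rate: float = 0.006,
                   min_cov: int = 4) -> pd.DataFrame:
    """Per-context weighted methylation level and methylated-site proportion.

    The weighted level is sum(meth)/sum(total) over all covered sites; the
    proportion is the fraction of sites with coverage >= min_cov that the
    binomial caller flags methylated.
    """
    rows = []
    called = call_methylated_sites(records, error_rate, min_cov)
    for ctx in CONTEXTS:
        sub = records[(records["context"] == ctx) & (records["total"] > 0)]
        csub = called[called["context"] == ctx]
        level = (sub["meth"].sum() / sub["total"].sum()) if len(sub) else np.nan
        prop = csub["methylated"].mean() if len(csub) else np.nan
        rows.append({"context": ctx, "level": level,
                     "mc_proportion": prop, "n_sites": len(sub)})
    return pd.DataFrame(rows)


def metaplot(
    records: pd.DataFrame, features: pd.DataFrame,
    flank: int = 2000, body_bins: int = 20, flank_bins: int = 30,
) -> tuple[pd.DataFrame, int]:
    """Coverage-weighted methylation profile over scaled bodies and flanks.

    Bins 0..flank_bins-1 are the upstream flank (5' of the feature, strand
    aware), then body_bins relative body bins, then the downstream flank.
    Returns (profile, n_skipped) where profile has one row per (context, bin)
    with the pooled level, and n_skipped counts features shorter than
    ``body_bins``.
    """
    n_bins = 2 * flank_bins + body_bins
    sums = {ctx: np.zeros((n_bins, 2)) for ctx in CONTEXTS}  # (meth, total)
    n_skipped = 0
    by_chrom = {c: g.sort_values("pos") for c, g in records.groupby("chrom")}
    for feat in features.itertuples():
        length = feat.end - feat.start
        if length < body_bins:
            n_skipped += 1
            continue
        sub = by_chrom.get(feat.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, feat.start - flank, side="left")
        hi = np.searchsorted(pos, feat.end + flank, side="left")
        window = sub.iloc[lo:hi]
        p = window["pos"].to_numpy()
        minus = getattr(feat, "strand", "+") == "-"
        bin_idx = np.empty(len(p), dtype=np.int64)
        left = p < feat.start            # 5' flank on the + orientation
        right = p >= feat.end
        body = ~left & ~right
        # flank bins are absolute-width; body bins relative
        bin_idx[left] = (p[left] - (feat.start - flank)) * flank_bins // flank
        bin_idx[body] = flank_bins + (p[body] - feat.start) * body_bins // length
        bin_idx[right] = flank_bins + body_bins + (p[right] - feat.end) * flank_bins // flank
        if minus:
            bin_idx = n_bins - 1 - bin_idx
        meth = window["meth"].to_numpy()
        total = window["total"].to_numpy()
        ctx_arr = window["context"].to_numpy()
        for ctx in CONTEXTS:
            m = ctx_arr == ctx
            if m.any():
                np.add.at(sums[ctx], bin_idx[m], np.column_stack([meth[m], total[m]]))
    rows = []
    for ctx in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            levels = sums[ctx][:, 0] / sums[ctx][:, 1]
        for b in range(n_bins):
            rows.append({"context": ctx, "bin": b, "level": levels[b],
                         "meth": sums[ctx][b, 0], "total": sums[ctx][b, 1]})
    return pd.DataFrame(rows), n_skipped


def _fisher_windows(windows: pd.DataFrame, a: str, b: str) -> np.ndarray:
    tables = np.column_stack([
        windows[f"meth_{a}"], windows[f"total_{a}"] - windows[f"meth_{a}"],
        windows[f"meth_{b}"], windows[f"total_{b}"] - windows[f"meth_{b}"],
    ])
    return fisher_exact_many(tables)


def _testable(windows: pd.DataFrame, genos: tuple[str, str], params: DMRParams
              ) -> pd.DataFrame:
    min_cyt = windows["context"].map(params.min_cytosines)
    keep = np.ones(len(windows), dtype=bool)
    for g in genos:
        keep &= (windows[f"n_{g}"] >= min_cyt) & (windows[f"total_{g}"] >= params.min_reads)
    return windows[keep]


def call_dmrs(
    windows: pd.DataFrame,
    contrast: tuple[str, str] = ("F", "H"),
    params: DMRParams = DMRParams(),
) -> pd.DataFrame:
    """Fisher-exact DMRs for one genotype contrast (delta = B minus A).

    Windows passing the per-context coverage gates are tested, BH-adjusted
    per context, and kept when q <= q_max and |delta| >= the context minimum.
    Adjacent same-direction DMR windows within ``merge_gap`` bp are merged;
    merged rows carry pooled counts and the minimum q of their windows.
    """
    a, b = contrast
    out = []
    for ctx in CONTEXTS:
        sub = _testable(windows[windows["context"] == ctx], (a, b), params).copy()
        if len(sub) == 0:
            continue
        sub["p"] = _fisher_windows(sub, a, b)
        sub["q"] = bh_stepup(sub["p"].to_numpy())
        sub["delta"] = sub[f"level_{b}"] - sub[f"level_{a}"]
        hit = sub[(sub["q"] <= params.q_max)
                  & (sub["delta"].abs() >= params.min_delta[ctx])].copy()
        if len(hit) == 0:
            continue
        hit["direction"] = np.where(hit["delta"] > 0, "hyper", "hypo")
        out.append(_merge_dmr_windows(hit, params.merge_gap))
    if not out:
        return _empty_dmr_frame(windows)
    res = pd.concat(out, ignore_index=True)
    res["contrast"] = f"{a}-vs-{b}"
    return res.sort_values(["chrom", "start", "context"], kind="stable").reset_index(drop=True)


def _empty_dmr_frame(windows: pd.DataFrame) -> pd.DataFrame:
    cols = (["chrom", "start", "end", "context", "direction", "q", "delta",
             "n_windows", "contrast"]
            + [c for c in windows.columns if c.startswith(("meth_", "total_"))])
    return pd.DataFrame(columns=cols)


def _merge_dmr_windows(hits: pd.DataFrame, merge_gap: int) -> pd.DataFrame:
    hits = hits.sort_values(["chrom", "start"], kind="stable")
    count_cols = [c for c in hits.columns if c.startswith(("meth_", "total_", "n_"))]
    merged = []
    cur = None
    for row in hits.to_dict("records"):
        if (cur is not None and row["chrom"] == cur["chrom"]
                and row["direction"] == cur["direction"]
                and row["start"] - cur["end"] <= merge_gap):
            cur["end"] = row["end"]
            cur["q"] = min(cur["q"], row["q"])
            cur["n_windows"] += 1
            for c in count_cols:
                cur[c] += row[c]
            cur["_deltas"].append(row["delta"])
        else:
            if cur is not None:
                merged.append(cur)
            cur = dict(row)
            cur["n_windows"] = 1
            cur["_deltas"] = [row["delta"]]
    if cur is not None:
        merged.append(cur)
    out = pd.DataFrame(merged)
    out["delta"] = [float(np.mean(d)) for d in out["_deltas"]]
    out = out.drop(columns=["_deltas", "p"], errors="ignore")
    keep = ["chrom", "start", "end", "context", "direction", "q", "delta", "n_windows"]
    return out[keep + [c for c in count_cols]]


def classify_vs_mpv(table: pd.DataFrame, q_max: float = 0.01) -> pd.DataFrame:
    """Interactive / noninteractive and TCM / TCdM classification vs MPV.

    ``table`` needs pooled meth/total columns for F, M and H. MPV counts are
    element-wise rounded half-sums of the parental counts; Fisher H-vs-MPV
    p-values are BH-adjusted over the table. Interactive rows (q <= q_max)
    are TCM when the hybrid level exceeds the MPV level, TCdM when below.
    """
    out = table.copy()
    if len(out) == 0:
        out["class"] = pd.Series(dtype=str)
        out["trans_class"] = pd.Series(dtype=str)
        return out
    meth_mpv = np.round((out["meth_F"] + out["meth_M"]) / 2.0).astype(np.int64)
    total_mpv = np.round((out["total_F"] + out["total_M"]) / 2.0).astype(np.int64)
    meth_mpv = np.minimum(meth_mpv, total_mpv)
    tables = np.column_stack([
        out["meth_H"], out["total_H"] - out["meth_H"],
        meth_mpv, total_mpv - meth_mpv,
    ])
    p = fisher_exact_many(tables)
    q = bh_stepup(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        level_h = out["meth_H"] / out["total_H"]
        level_mpv = meth_mpv / total_mpv
    interactive = q <= q_max
    out["mpv_p"] = p
    out["mpv_q"] = q
    out["level_MPV"] = level_mpv
    out["class"] = np.where(interactive, "interactive", "noninteractive")
    out["trans_class"] = np.where(
        interactive & (level_h > level_mpv), "TCM",
        np.where(interactive & (level_h < level_mpv), "TCdM", "n/a"),
    )
    return out


#: pattern ids for the 2^3 (F, M, H) methylation states
PATTERN_NAMES = {
    1: "conserved",                # (1,1,1)
    2: "hybrid-loss",              # (1,1,0)
    3: "F-maintained",             # (1,0,1)
    4: "M-maintained",             # (0,1,1)
    5: "F-lost",                   # (1,0,0)
    6: "M-lost",                   # (0,1,0)
    7: "de-novo",                  # (0,0,1)
    8: "unmethylated",             # (0,0,0)
}
_PATTERN_IDS = {
    (1, 1, 1): 1, (1, 1, 0): 2, (1, 0, 1): 3, (0, 1, 1): 4,
    (1, 0, 0): 5, (0, 1, 0): 6, (0, 0, 1): 7, (0, 0, 0): 8,
}


def pattern_id_from_states(f: int, m: int, h: int) -> int:
    """Pattern id (1..8) for the (F, M, H) methylated-state triple."""
    return _PATTERN_IDS[(int(f), int(m), int(h))]


def parental_pattern(
    records: dict[str, pd.DataFrame],
    error_rate: float = 0.006, min_cov: int = 4, q_max: float = 0.01,
) -> pd.DataFrame:
    """Eight-way (F, M, H) methylation patterning of shared loci.

    Loci (chrom, pos, context) covered >= min_cov in all three genotypes are
    site-called per genotype and assigned one of the 8 pattern ids; the
    ``de-novo`` pattern is (0, 0, 1) — methylated only in the hybrid.
    """
    calls = {}
    for geno in GENOTYPES:
        called = call_methylated_sites(records[geno], error_rate, min_cov, q_max)
        calls[geno] = called.set_index(["chrom", "pos", "context"])["methylated"]
    idx = calls["F"].index
    for geno in ("M", "H"):
        idx = idx.intersection(calls[geno].index)
    states = pd.DataFrame({
        f"state_{g}": calls[g].loc[idx].astype(int) for g in GENOTYPES
    }, index=idx)
    states["pattern_id"] = [
        pattern_id_from_states(f, m, h)
        for f, m, h in zip(states["state_F"], states["state_M"], states["state_H"])
    ]
    states["pattern"] = states["pattern_id"].map(PATTERN_NAMES)
    return states.reset_index()


def annotate_dmrs(dmrs: pd.DataFrame, annotation: AnnotationSet,
                  promoter: int = 2000, min_frac: float = 0.5) -> pd.Series:
    """Region label per DMR: promoter > intragenic > intergenic.

    The promoter is ``promoter`` bp upstream of the TSS (strand aware); a
    label requires >= min_frac of the DMR length to overlap the region.
    """
    if len(dmrs) == 0:
        return pd.Series(dtype=str, name="region")
    genes = annotation.genes
    promoters = gene_flanks(genes, promoter, annotation.chrom_sizes or None, which="up")
    q = dmrs[["chrom", "start", "end"]]
    length = (q["end"] - q["start"]).to_numpy()
    prom_ov = overlap_lengths(q, promoters)
    gene_ov = overlap_lengths(q, genes)
    label = np.where(
        prom_ov >= min_frac * length, "promoter",
        np.where(gene_ov >= min_frac * length, "intragenic", "intergenic"),
    )
    return pd.Series(label, index=dmrs.index, name="region")


def identify_dmgs(
    nonadditive_genes, dmrs: pd.DataFrame, annotation: AnnotationSet,
    updown: int = 1000,
) -> pd.DataFrame:
    """Flag nonadditive DEGs with a DMR in the 1-kb upstream, 1-kb downstream
    or coding region (>= 1 bp overlap)."""
    genes = annotation.genes.set_index("id")
    rows = []
    for gid in nonadditive_genes:
        if gid not in genes.index:
            continue
        g = genes.loc[gid]
        gdf = pd.DataFrame([g]).assign(id=gid)
        up = gene_flanks(gdf, updown, annotation.chrom_sizes or None, which="up")
        down = gene_flanks(gdf, updown, annotation.chrom_sizes or None, which="down")
        body = pd.DataFrame([{"chrom": g["chrom"], "start": g["start"], "end": g["end"]}])
        flags = {}
        for name, region in (("up1kb", up), ("down1kb", down), ("body", body)):
            if len(region) == 0:
                flags[name] = False
                continue
            ov = overlap_lengths(region[["chrom", "start", "end"]], dmrs)
            flags[name] = bool((ov > 0).any())
        rows.append({"gene": gid, **flags})
    out = pd.DataFrame(rows, columns=["gene", "up1kb", "down1kb", "body"])
    return out


def expression_quartile_methylation(
    em, records: pd.DataFrame, annotation: AnnotationSet,
    flank: int = 2000, body_bins: int = 20, flank_bins: int = 30,
) -> dict[str, pd.DataFrame]:
    """Gene-body metaplots for expression quartiles of the hybrid.

    Genes are ranked by mean normalized hybrid expression (ties broken by
    gene id) and split into four equal groups, remainder going to the lower
    quartiles; returns quartile name -> metaplot profile.
    """
    genes = annotation.genes
    norm = em.normalized()
    h_mean = norm[em.samples_of("H")].mean(axis=1)
    expressed = [g for g in genes["id"] if g in h_mean.index]
    if len(expressed) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    ranked = sorted(expressed, key=lambda g: (h_mean.loc[g], g))
    n = len(ranked)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    names = ["low", "mid-low", "mid-high", "high"]
    out = {}
    start = 0
    for name, size in zip(names, sizes):
        ids = set(ranked[start:start + size])
        start += size
        feats = genes[genes["id"].isin(ids)]
        profile, _ = metaplot(records, feats, flank, body_bins, flank_bins)
        out[name] = profile
    return out
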