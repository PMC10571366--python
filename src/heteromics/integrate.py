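"""Cross-layer statistics: siRNA x methylome x expression, and heterosis.

Associates 24-nt siRNA clusters with TCM/TCdM DMRs, contrasts methylation
levels inside vs outside siRNA-covered regions (label-permutation test),
attributes the hybrid's methylation increase to the four parental-state
categories crossed with siRNA presence, and computes the phenotype heterosis
metrics MPH% = (F1 - MP)/MP * 100 and BPH = (F1 - BP)/BP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import any_overlap
from .methylome import CONTEXTS, call_methylated_sites

__all__ = [
    "sirna_dmr_overlap", "methylation_by_sirna_presence",
    "increase_attribution", "heterosis_metrics",
]


def sirna_dmr_overlap(dmrs: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Fraction of TCM and TCdM DMRs containing >= 1 siRNA cluster, per context.

    Containment is >= 1 bp overlap. ``dmrs`` needs chrom/start/end/context and
    ``trans_class`` columns; rows whose trans_class is not TCM/TCdM are
    ignored.
    """
    rows = []
    for trans_class in ("TCM", "TCdM"):
        sub_all = dmrs[dmrs["trans_class"] == trans_class]
        for ctx in CONTEXTS + ("all",):
            sub = sub_all if ctx == "all" else sub_all[sub_all["context"] == ctx]
            if len(sub) == 0:
                frac = float("nan")
            elif len(clusters) == 0:
                frac = 0.0
            else:
                frac = float(any_overlap(sub[["chrom", "start", "end"]], clusters).mean())
            rows.append({"trans_class": trans_class, "context": ctx,
                         "n_dmrs": len(sub), "fraction_with_cluster": frac})
    return pd.DataFrame(rows)


def methylation_by_sirna_presence(
    records: pd.DataFrame, clusters: pd.DataFrame,
    window: int = 100, n_permutations: int = 1000, seed: int = 0,
) -> pd.DataFrame:
    """Weighted methylation level inside vs outside siRNA clusters, per context.

    Sites are pooled into ``window``-bp windows; each window is labeled
    covered when it overlaps >= 1 bp of a cluster. Significance of the
    inside-minus-outside difference comes from permuting the window labels
    (one-sided: inside higher), seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if len(clusters) == 0:
        for ctx in CONTEXTS:
            rows.append({"context": ctx, "level_inside": float("nan"),
                         "level_outside": float("nan"), "difference": float("nan"),
                         "p_permutation": float("nan"), "n_windows_inside": 0})
        return pd.DataFrame(rows)
    recs = records.copy()
    recs["wstart"] = (recs["pos"] // window) * window
    win = (recs.groupby(["chrom", "wstart", "context"], sort=True)
           .agg(meth=("meth", "sum"), total=("total", "sum")).reset_index())
    win["start"] = win["wstart"]
    win["end"] = win["wstart"] + window
    covered = any_overlap(win[["chrom", "start", "end"]], clusters)
    for ctx in CONTEXTS:
        sub = win[(win["context"] == ctx) & (win["total"] > 0)]
        inside = covered[win.index.get_indexer(sub.index)]
        meth = sub["meth"].to_numpy(dtype=float)
        total = sub["total"].to_numpy(dtype=float)
        n_in = int(inside.sum())
        if n_in == 0 or n_in == len(sub):
            rows.append({"context": ctx, "level_inside": float("nan"),
                         "level_outside": float("nan"), "difference": float("nan"),
                         "p_permutation": float("nan"), "n_windows_inside": n_in})
            continue
        def _diff(lbl):
            li = meth[lbl].sum() / total[lbl].sum()
            lo = meth[~lbl].sum() / total[~lbl].sum()
            return li - lo
        obs = _diff(inside)
        hits = 0
        lbl = inside.copy()
        for _ in range(n_permutations):
            rng.shuffle(lbl)
            if _diff(lbl) >= obs:
                hits += 1
        rows.append({
            "context": ctx,
            "level_inside": meth[inside].sum() / total[inside].sum(),
            "level_outside": meth[~inside].sum() / total[~inside].sum(),
            "difference": obs,
            "p_permutation": (hits + 1) / (n_permutations + 1),
            "n_windows_inside": n_in,
        })
    return pd.DataFrame(rows)


def increase_attribution(
    records: dict[str, pd.DataFrame], clusters: pd.DataFrame,
    error_rate: float = 0.006, min_cov: int = 4, q_max: float = 0.01,
) -> pd.DataFrame:
    """Attribute the hybrid methylation increase to parental-state categories.

    Positions covered in all three genotypes are assigned to (F>M, M>F,
    F=M>0, F=M=0) by the binomial site calls, crossed with 24-nt siRNA
    presence (>= 1 bp cluster overlap). Each cell sums the positive part of
    the hybrid increase, max(0, level_H - (level_F + level_M)/2); fractions
    are of the grand total, so cells partition the total increase exactly.
    """
    keyed = {}
    for geno in ("F", "M", "H"):
        called = call_methylated_sites(records[geno], error_rate, min_cov, q_max)
        keyed[geno] = called.set_index(["chrom", "pos", "context"])
    idx = keyed["F"].index
    for geno in ("M", "H"):
        idx = idx.intersection(keyed[geno].index)
    f = keyed["F"].loc[idx]
    m = keyed["M"].loc[idx]
    h = keyed["H"].loc[idx]
    lf = (f["meth"] / f["total"]).to_numpy()
    lm = (m["meth"] / m["total"]).to_numpy()
    lh = (h["meth"] / h["total"]).to_numpy()
    increase = np.maximum(0.0, lh - (lf + lm) / 2.0)
    sf = f["methylated"].to_numpy()
    sm = m["methylated"].to_numpy()
    category = np.select(
        [sf & ~sm, ~sf & sm, sf & sm],
        ["F>M", "M>F", "F=M>0"],
        default="F=M=0",
    )
    pos_df = pd.DataFrame(
        {"chrom": [t[0] for t in idx], "start": [t[1] for t in idx]})
    pos_df["end"] = pos_df["start"] + 1
    with_sirna = (any_overlap(pos_df, clusters) if len(clusters)
                  else np.zeros(len(pos_df), dtype=bool))
    total = increase.sum()
    rows = []
    for cat in ("F>M", "M>F", "F=M>0", "F=M=0"):
        for label, mask in (("with-siRNA", with_sirna), ("without-siRNA", ~with_sirna)):
            cell = increase[(category == cat) & mask].sum()
            rows.append({
                "category": cat, "sirna": label,
                "increase": float(cell),
                "fraction": float(cell / total) if total > 0 else 0.0,
                "n_positions": int(((category == cat) & mask).sum()),
            })
    return pd.DataFrame(rows)


def heterosis_metrics(traits: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent and better-parent heterosis per trait.

    ``traits`` needs columns trait, F1, F, M and optionally
    ``higher_is_better`` (default True). MP = (F + M)/2 must be nonzero.
    MPH_percent = (F1 - MP)/MP * 100; BPH = (F1 - BP)/BP (as a ratio, not a
    percentage).
    """
    rows = []
    for t in traits.itertuples():
        mp = (t.F + t.M) / 2.0
        if mp == 0:
            raise ValueError(f"mid-parent value is zero for trait {t.trait!r}")
        higher = getattr(t, "higher_is_better", True)
        bp = max(t.F, t.M) if higher else min(t.F, t.M)
        rows.append({
            "trait": t.trait, "F1": t.F1, "MP": mp, "BP": bp,
            "MPH_percent": (t.F1 - mp) / mp * 100.0,
            "BPH": (t.F1 - bp) / bp,
        })
    return pd.DataFrame(rows)
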