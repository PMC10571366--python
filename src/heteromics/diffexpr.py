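"""Normalization and differential expression against the mid-parent value.

The hybrid (H) is compared with the expected mid-parent value (MPV), built as
paired pseudo-replicates ``(F_i + M_i) / 2`` of the normalized parental
replicates, and the two parents are compared with each other (M-F DEGs).
Significance combines a per-gene two-sample t test on log2(x + pseudocount)
with gene-set-wide Benjamini-Hochberg control and a fold-change gate.

The default gate is the stringent one used for mRNA (|log2FC| >= 2,
p <= 0.01, FDR q <= 0.01); miRNA count tables reuse the same machinery with
the looser (|log2FC| >= 1, p <= 0.01, q <= 0.05) gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_stepup

__all__ = [
    "DEThresholds", "ExpressionMatrix", "size_factors", "mpv_expression",
    "test_de", "de_table", "bh_fdr", "classify_additivity", "fpkm",
    "MRNA_THRESHOLDS", "MIRNA_THRESHOLDS",
]

GENOTYPES = ("F", "M", "H")


@dataclass(frozen=True)
class DEThresholds:
    """Joint significance gate: |log2fc| >= fc_min, p <= p_max, BH q <= q_max."""

    fc_min: float = 2.0
    p_max: float = 0.01
    q_max: float = 0.01


#: mRNA gate (|log2FC| >= 2, p <= 0.01, FDR <= 0.01).
MRNA_THRESHOLDS = DEThresholds(2.0, 0.01, 0.01)
#: miRNA gate (p <= 0.01, FDR <= 0.05, |log2FC| >= 1).
MIRNA_THRESHOLDS = DEThresholds(1.0, 0.01, 0.05)


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts with genotype/replicate labels.

    ``counts`` is a DataFrame indexed by gene id with one column per sample;
    ``sample_meta`` is indexed by sample name with columns ``genotype``
    (in {F, M, H}) and ``replicate`` (1-based int).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match count matrix columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.sample_meta["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        reps = self.sample_meta.groupby("genotype").size()
        if (reps < 2).any():
            raise ValueError("need >=2 replicates per genotype")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def samples_of(self, genotype: str) -> list[str]:
        meta = self.sample_meta[self.sample_meta["genotype"] == genotype]
        return list(meta.sort_values("replicate").index)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors (computing them if unset)."""
        sf = self.size_factors
        if sf is None:
            sf = size_factors(self.counts)
            self.size_factors = sf
        return self.counts / sf

    def genotype_matrix(self, genotype: str, normalized: bool = True) -> np.ndarray:
        """(genes x replicates) array for one genotype, replicate-ordered."""
        data = self.normalized() if normalized else self.counts
        return data[self.samples_of(genotype)].to_numpy(dtype=float)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed on
    genes with a nonzero count in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; median-of-ratios is "
            "undefined (consider a pseudo-reference with a pseudocount)"
        )
    ref = np.exp(np.log(mat[nonzero]).mean(axis=1))
    factors = np.median(mat[nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def mpv_expression(em: ExpressionMatrix) -> pd.DataFrame:
    """Mid-parent pseudo-replicates: MPV_i = (F_i + M_i)/2, normalized scale.

    Replicates are paired by replicate index; unequal parental replicate
    counts are an error.
    """
    f = em.genotype_matrix("F")
    m = em.genotype_matrix("M")
    if f.shape[1] != m.shape[1]:
        raise ValueError(
            "unequal parental replicate counts; MPV pairing by replicate "
            "index requires the same number of F and M replicates"
        )
    mpv = (f + m) / 2.0
    cols = [f"MPV{i + 1}" for i in range(mpv.shape[1])]
    return pd.DataFrame(mpv, index=em.counts.index, columns=cols)


def _log_means_and_t(
    a: np.ndarray, b: np.ndarray, pseudocount: float, engine: str
) -> tuple[np.ndarray, np.ndarray]:
    """log2fc (B over A) and p from a two-sample t on log2(x + pseudocount)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >=2 replicates per group")
    log2fc = np.log2(b.mean(axis=1) + pseudocount) - np.log2(a.mean(axis=1) + pseudocount)
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if engine == "student":
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    elif engine == "welch":
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    else:
        raise ValueError(f"unknown DE engine {engine!r}")
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate: zero variance in both groups -> p=1 when equal, p=0 when not
    va = la.var(axis=1)
    vb = lb.var(axis=1)
    degen = (va == 0) & (vb == 0)
    p[degen & (log2fc == 0)] = 1.0
    p[degen & (log2fc != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return log2fc, p


def test_de(
    group_a: np.ndarray,
    group_b: np.ndarray,
    thresholds: DEThresholds = MRNA_THRESHOLDS,
    pseudocount: float = 1.0,
    engine: str = "student",
) -> pd.DataFrame:
    """Per-gene differential test of group B against group A.

    Returns a frame with ``log2fc``, ``p``, ``q`` (BH over the supplied gene
    set) and ``status`` in {up, down, ns}. ``log2fc`` is
    ``log2((mean_B + pc) / (mean_A + pc))``; positive means B above A.
    """
    log2fc, p = _log_means_and_t(group_a, group_b, pseudocount, engine)
    q = bh_fdr(p)
    status = np.where(
        (np.abs(log2fc) >= thresholds.fc_min)
        & (p <= thresholds.p_max)
        & (q <= thresholds.q_max),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame({"log2fc": log2fc, "p": p, "q": q, "status": status})


def de_table(
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_ids,
    thresholds: DEThresholds = MRNA_THRESHOLDS,
    pseudocount: float = 1.0,
    engine: str = "student",
) -> pd.DataFrame:
    """:func:`test_de` with a gene-id index."""
    out = test_de(group_a, group_b, thresholds, pseudocount, engine)
    out.index = pd.Index(gene_ids, name="gene")
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserved, capped at 1)."""
    return bh_stepup(np.asarray(pvalues, dtype=float))


def classify_additivity(de_result: pd.DataFrame) -> pd.Series:
    """Map a hybrid-vs-MPV DE table to additive / nonadditive-up / -down."""
    mapping = {"up": "nonadditive-up", "down": "nonadditive-down", "ns": "additive"}
    return de_result["status"].map(mapping).rename("additivity")


def fpkm(em: ExpressionMatrix, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million, on size-factor-scaled libraries.

    ``fpkm[g, s] = (counts[g, s] / sf_s) * 1e9 / (L * length_g)`` where L is
    the mean size-factor-scaled library size. Used only for the allele-specific
    expression filter.
    """
    norm = em.normalized()
    lib = norm.sum(axis=0).mean()
    lengths = gene_lengths.reindex(norm.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise ValueError(f"gene lengths missing for {missing}...")
    return norm.mul(1e9 / lib).div(lengths, axis=0)
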