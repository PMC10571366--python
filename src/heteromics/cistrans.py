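"""Cis/trans classification of allele-specific expression in the hybrid.

For each gene with allele-resolved counts (F, M in the parents; HF, HM for the
two parental alleles inside the hybrid), two chi-square p-values are computed:

* ``PA`` — homogeneity of the parental ratio F:M against the hybrid allelic
  ratio HF:HM (2x2 table, df=1, no continuity correction). A significant PA
  (<= 0.05) means the allelic ratio changed between generations: a trans
  effect.
* ``PB`` — goodness of fit of (HF, HM) against a 1:1 split (df=1). A
  significant PB (<= 0.05) means the two alleles are unequally expressed
  inside the same hybrid nucleus: a cis effect.

Exact tests replace the chi-square where it is unreliable (any expected cell
< 5 for PA -> Fisher exact; HF+HM < 25 for PB -> exact binomial). The four
regulatory categories follow from the (PA <= a, PB <= a) pair at a = 0.05,
with no multiple-testing correction applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_exact_two_sided

__all__ = [
    "filter_ase_genes", "chi2_homogeneity_pa", "chi2_balance_pb",
    "classify_cistrans", "cistrans_table",
]

ALLELE_COLUMNS = ["F", "M", "HF", "HM"]


def filter_ase_genes(
    records: pd.DataFrame, min_fpkm: float = 2.0, min_allelic_reads: int = 20
) -> pd.DataFrame:
    """Drop genes with low expression or low SNP-resolved coverage.

    Keeps records with ``fpkm_min >= min_fpkm`` and at least
    ``min_allelic_reads`` allelic reads in both the parents (F+M) and the
    hybrid (HF+HM).
    """
    keep = (
        (records["fpkm_min"] >= min_fpkm)
        & (records["F"] + records["M"] >= min_allelic_reads)
        & (records["HF"] + records["HM"] >= min_allelic_reads)
    )
    return records[keep]


def chi2_homogeneity_pa(f: int, m: int, hf: int, hm: int) -> float:
    """PA: homogeneity of F:M vs HF:HM on the 2x2 table [[F, M], [HF, HM]].

    Pearson chi-square with df=1 and no continuity correction; Fisher exact
    (two-sided) when any expected cell is below 5. Degenerate margins give
    PA = 1.
    """
    table = np.array([[f, m], [hf, hm]], dtype=float)
    n = table.sum()
    if n == 0:
        return 1.0
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 1.0
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        return fisher_exact_two_sided(int(f), int(m), int(hf), int(hm))
    chi2 = ((table - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def chi2_balance_pb(hf: int, hm: int, small_total: int = 25) -> float:
    """PB: goodness of fit of (HF, HM) against an equal split.

    Chi-square with df=1 against expected (n/2, n/2); exact two-sided binomial
    when HF+HM < ``small_total``. HF+HM = 0 gives PB = 1.
    """
    n = hf + hm
    if n == 0:
        return 1.0
    if n < small_total:
        return float(stats.binomtest(int(hf), int(n), 0.5).pvalue)
    e = n / 2.0
    chi2 = (hf - e) ** 2 / e + (hm - e) ** 2 / e
    return float(stats.chi2.sf(chi2, df=1))


def classify_cistrans(pa: float, pb: float, alpha: float = 0.05) -> str:
    """Map (PA, PB) to one of the four regulatory categories."""
    a_sig, b_sig = pa <= alpha, pb <= alpha
    if a_sig and b_sig:
        return "cis+trans"
    if a_sig:
        return "trans-only"
    if b_sig:
        return "cis-only"
    return "none"


def cistrans_table(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_fpkm: float = 2.0,
    min_allelic_reads: int = 20,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Filter, test and classify a table of allele-count records.

    ``records`` needs columns gene, F, M, HF, HM and (unless ``prefiltered``)
    fpkm_min. Returns one row per retained gene with PA, PB and category.
    """
    recs = records if prefiltered else filter_ase_genes(records, min_fpkm, min_allelic_reads)
    pa = np.array([
        chi2_homogeneity_pa(r.F, r.M, r.HF, r.HM) for r in recs.itertuples()
    ])
    pb = np.array([chi2_balance_pb(r.HF, r.HM) for r in recs.itertuples()])
    category = [classify_cistrans(a, b, alpha) for a, b in zip(pa, pb)]
    out = pd.DataFrame({"PA": pa, "PB": pb, "category": category})
    if "gene" in recs.columns:
        out.insert(0, "gene", recs["gene"].to_numpy())
    return out
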