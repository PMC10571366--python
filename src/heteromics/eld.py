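"""Expression-level dominance: the 12-class (F, H, M) classification.

Each expressed gene's genotype triple is reduced to three pairwise relations
(F vs M, H vs F, H vs M), each called ``<``, ``=`` or ``>`` with a looser
gate than the DEG test (default p <= 0.05 and |log2FC| >= 1), and the
relation triple is mapped through a fixed lookup table:

======  ==============================  ====================  ============
class   pattern                         category              parent level
======  ==============================  ====================  ============
1       F < H < M                       additive              n/a
2       F > H > M                       additive              n/a
3       H = F, F > M                    ELD-F                 high
4       H = F, F < M                    ELD-F                 low
5       H = M, M > F                    ELD-M                 high
6       H = M, M < F                    ELD-M                 low
7-9     H above both (F<M, F=M, F>M)    transgressive-up      n/a
10-12   H below both (F<M, F=M, F>M)    transgressive-down    n/a
======  ==============================  ====================  ============

Triples that fit none of the rows (including the all-equal, untested triple)
are class ``none``. High-parent ELD genes are classes 3 and 5; low-parent ELD
genes are classes 4 and 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEThresholds, test_de

__all__ = [
    "ELD_THRESHOLDS", "ELD_LOOKUP", "pairwise_relations", "classify_eld",
    "classify_eld_calls", "summarize_eld", "class_metadata",
]

#: Equality gate for pairwise relations (looser than the DEG gate on purpose:
#: a 4-fold gate would over-call equality). q_max=1 disables the FDR gate —
#: relations are per-pair decisions, not a gene-set discovery.
ELD_THRESHOLDS = DEThresholds(fc_min=1.0, p_max=0.05, q_max=1.0)

# (rel_FM, rel_HF, rel_HM) -> class id; relations read "F <rel> M" etc.
ELD_LOOKUP: dict[tuple[str, str, str], int] = {
    ("<", ">", "<"): 1,   # F < H < M
    (">", "<", ">"): 2,   # F > H > M
    (">", "=", ">"): 3,   # H = F, F > M   (ELD-F, high)
    ("<", "=", "<"): 4,   # H = F, F < M   (ELD-F, low)
    ("<", ">", "="): 5,   # H = M, M > F   (ELD-M, high)
    (">", "<", "="): 6,   # H = M, M < F   (ELD-M, low)
    ("<", ">", ">"): 7,   # transgressive-up, F < M
    ("=", ">", ">"): 8,   # transgressive-up, F = M
    (">", ">", ">"): 9,   # transgressive-up, F > M
    ("<", "<", "<"): 10,  # transgressive-down, F < M
    ("=", "<", "<"): 11,  # transgressive-down, F = M
    (">", "<", "<"): 12,  # transgressive-down, F > M
}

_CATEGORY = {
    1: "additive", 2: "additive",
    3: "ELD-F", 4: "ELD-F", 5: "ELD-M", 6: "ELD-M",
    7: "transgressive-up", 8: "transgressive-up", 9: "transgressive-up",
    10: "transgressive-down", 11: "transgressive-down", 12: "transgressive-down",
}
_PARENT_LEVEL = {3: "high", 4: "low", 5: "high", 6: "low"}


def class_metadata(class_id: int) -> tuple[str, str]:
    """(category, parent_level) for a class id (0 = none)."""
    if class_id == 0:
        return "none", "n/a"
    return _CATEGORY[class_id], _PARENT_LEVEL.get(class_id, "n/a")


def _relation(a: np.ndarray, b: np.ndarray, thresholds: DEThresholds,
              engine: str) -> np.ndarray:
    """Vector of relations 'a vs b' in {<, =, >} (a significantly above b -> '>')."""
    res = test_de(b, a, thresholds=thresholds, engine=engine)  # log2fc = a over b
    different = (res["p"].to_numpy() <= thresholds.p_max) & (
        np.abs(res["log2fc"].to_numpy()) >= thresholds.fc_min
    )
    lfc = res["log2fc"].to_numpy()
    return np.where(~different, "=", np.where(lfc > 0, ">", "<"))


def pairwise_relations(
    f: np.ndarray, m: np.ndarray, h: np.ndarray,
    thresholds: DEThresholds = ELD_THRESHOLDS,
    engine: str = "student",
) -> pd.DataFrame:
    """Relations (F vs M, H vs F, H vs M) from normalized replicate matrices."""
    return pd.DataFrame({
        "rel_FM": _relation(f, m, thresholds, engine),
        "rel_HF": _relation(h, f, thresholds, engine),
        "rel_HM": _relation(h, m, thresholds, engine),
    })


def classify_eld(rel_fm: str, rel_hf: str, rel_hm: str) -> int:
    """Class id (1-12) for one relation triple; 0 for none/inconsistent."""
    return ELD_LOOKUP.get((rel_fm, rel_hf, rel_hm), 0)


def classify_eld_calls(relations: pd.DataFrame, gene_ids=None) -> pd.DataFrame:
    """Classify every relation triple; returns class id, category, parent level."""
    class_ids = [
        classify_eld(a, b, c)
        for a, b, c in zip(relations["rel_FM"], relations["rel_HF"], relations["rel_HM"])
    ]
    meta = [class_metadata(c) for c in class_ids]
    out = pd.DataFrame({
        "class_id": class_ids,
        "category": [m[0] for m in meta],
        "parent_level": [m[1] for m in meta],
    })
    if gene_ids is not None:
        out.index = pd.Index(gene_ids, name="gene")
    return out


def summarize_eld(calls: pd.DataFrame) -> dict:
    """Counts per class and category, plus the high-parent ELD fraction.

    The high-parent fraction is (#class3 + #class5) / (#classes 3-6); NaN when
    no ELD gene was called.
    """
    by_class = calls["class_id"].value_counts().to_dict()
    by_category = calls["category"].value_counts().to_dict()
    n_eld = sum(by_class.get(c, 0) for c in (3, 4, 5, 6))
    n_high = by_class.get(3, 0) + by_class.get(5, 0)
    frac = (n_high / n_eld) if n_eld else float("nan")
    return {
        "by_class": {c: by_class.get(c, 0) for c in range(13)},
        "by_category": by_category,
        "n_eld": n_eld,
        "high_parent_fraction": frac,
    }
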