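"""Synthetic multi-omics data with planted ground truth.

Every downstream stage of the pipeline gets an input generator here, built to
emulate the design of the real study: three biological replicates per
genotype (female parent F, male parent M, hybrid H), negative-binomial RNA
counts with planted additive / expression-level-dominance / transgressive
genes, binomial allele splits with planted cis ratios and trans shifts,
beta-binomial cytosine reports with context-specific baselines (CG > CHG >
CHH) and planted DMRs plus the eight parental (F, M, H) methylation states,
and clustered 24-nt siRNA read positions concentrated on TEs.

Determinism: all draws come from named substreams of a single seed, so adding
one simulator never perturbs another, and identical (seed, config) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, FEATURE_COLUMNS
from .methylome import pattern_id_from_states

__all__ = [
    "SimConfig", "simulate_annotation", "homoeolog_pairs", "simulate_counts",
    "eld_truth_assignment", "simulate_allele_counts", "simulate_methylome",
    "simulate_sirna_reads", "SAMPLES",
]

#: sample names: 3 replicates per genotype, replicate-major within genotype
SAMPLES = [f"{g}{i}" for g in ("F", "M", "H") for i in (1, 2, 3)]

_SUBSTREAMS = {"annotation": 1, "counts": 2, "allele": 3, "methylome": 4, "sirna": 5}

_EXPRESSION_CLASSES = (
    "additive", "ELD-F-high", "ELD-F-low", "ELD-M-high", "ELD-M-low",
    "transgressive-up", "transgressive-down", "null",
)

READ_LENGTH = 24


@dataclass
class SimConfig:
    """Study-condition parameters for all simulators (defaults = the design)."""

    # genome / annotation
    n_genes: int = 200              # total, split 1:1 over the An and Dn chromosome
    n_te: int = 240
    chrom_length: int = 1_000_000
    min_gene_length: int = 1_000
    max_gene_length: int = 3_000
    flank: int = 2_000

    # RNA counts
    replicates: int = 3
    nb_dispersion: float = 0.1
    mean_log_mu: float = 5.0        # lognormal (natural log) of the count-scale mean
    mean_log_sigma: float = 1.5
    class_proportions: dict = field(default_factory=lambda: {
        "additive": 0.05, "ELD-F-high": 0.10, "ELD-F-low": 0.05,
        "ELD-M-high": 0.10, "ELD-M-low": 0.05,
        "transgressive-up": 0.05, "transgressive-down": 0.05, "null": 0.55,
    })
    eld_k: float = 8.0              # high:low parent ratio for planted ELD (log2FC 3)
    transgressive_k: float = 8.0    # hybrid beyond the extreme parent (>= 4x)

    # allele-specific expression
    cis_trans_proportions: dict = field(default_factory=lambda: {
        "none": 0.70, "cis-only": 0.10, "trans-only": 0.10, "cis+trans": 0.10,
    })
    cis_ratio_range: tuple = (3.0, 5.0)
    trans_shift_range: tuple = (1.5, 2.5)   # log2 shift added on top of cis for cis+trans
    allele_depth: float = 1000.0
    ase_pass_fraction: float = 0.9          # fraction of genes passing the FPKM filter

    # methylome
    context_baselines: dict = field(default_factory=lambda: {
        "CG": 0.60, "CHG": 0.35, "CHH": 0.10,
    })
    cytosine_density: dict = field(default_factory=lambda: {
        "CG": 0.08, "CHG": 0.05, "CHH": 0.15,
    })
    dmr_delta: dict = field(default_factory=lambda: {
        "CG": 0.5, "CHG": 0.3, "CHH": 0.2,
    })
    n_dmrs_per_context: int = 40
    dmr_max_windows: int = 3                # planted span: 1..this many 100-bp windows
    n_pattern_loci: int = 25                # planted loci per (F,M,H) state
    beta_binomial_overdispersion: float = 0.02
    site_precision: float = 10.0            # between-site spread of propensities
    coverage_mean: float = 20.0
    te_meth_boost: float = 0.2
    error_rate: float = 0.006               # residual non-conversion level

    # 24-nt siRNA
    n_clusters: int = 120
    te_cluster_fraction: float = 0.75
    cluster_span_log_mean: float = 5.3      # exp(5.3) ~ 200 nt mode
    cluster_span_log_sigma: float = 0.45
    cluster_span_range: tuple = (100, 1000)
    cluster_read_density: float = 0.2       # reads / bp / sample
    sirna_nonadditive_fraction: float = 0.2
    sirna_up_fraction: float = 0.7          # of the non-additive clusters
    sirna_fc: float = 3.0                   # planted hybrid fold change vs MPV
    background_read_density: float = 2e-5

    seed: int = 0

    def __post_init__(self) -> None:
        for name, props in (("class_proportions", self.class_proportions),
                            ("cis_trans_proportions", self.cis_trans_proportions)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be non-negative")
        unknown = set(self.class_proportions) - set(_EXPRESSION_CLASSES)
        if unknown:
            raise ValueError(f"unknown expression classes: {sorted(unknown)}")
        for ctx, b in self.context_baselines.items():
            if not (0.0 < b < 1.0):
                raise ValueError(f"context baseline {ctx}={b} must lie in (0, 1)")
        if self.replicates < 2:
            raise ValueError("need replicates >= 2")
        if self.cis_ratio_range[0] <= 0:
            raise ValueError("cis ratios must be > 0")

    def rng(self, substream: str) -> np.random.Generator:
        """Named substream generator (stable across additions of simulators)."""
        key = _SUBSTREAMS[substream]
        return np.random.default_rng(np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(key,)))


# --------------------------------------------------------------------------
# annotation

def simulate_annotation(cfg: SimConfig) -> AnnotationSet:
    """Toy two-chromosome genome: chrA01 (An) and chrD01 (Dn), ~cfg.chrom_length
    each, with 1:1 homoeolog gene pairs, 3-exon gene models, and TEs of the
    five classes interleaved in intergenic space."""
    if cfg.n_genes % 2:
        raise ValueError("n_genes must be even (genes are paired across subgenomes)")
    rng = cfg.rng("annotation")
    n_per = cfg.n_genes // 2
    margin = 2 * cfg.flank + 500
    slot = cfg.chrom_length // max(n_per, 1)
    if n_per and slot < cfg.max_gene_length + margin:
        raise ValueError(
            f"{cfg.n_genes} genes do not fit in {cfg.chrom_length} bp chromosomes "
            "with the minimum spacing"
        )
    te_classes = ["DNA", "LTR-copia", "LTR-gypsy", "LINE", "SINE"]
    rows = []
    chroms = [("chrA01", "An", "A01"), ("chrD01", "Dn", "D01")]
    for chrom, subg, tag in chroms:
        gene_lens = rng.integers(cfg.min_gene_length, cfg.max_gene_length + 1, n_per)
        strands = rng.choice(["+", "-"], n_per)
        gene_iv = []
        for i in range(n_per):
            room = slot - gene_lens[i] - margin
            start = i * slot + cfg.flank + 250 + int(rng.integers(0, max(room, 1)))
            end = start + int(gene_lens[i])
            gid = f"Gh{tag}G{i + 1:04d}"
            rows.append((chrom, start, end, strands[i], "gene", subg, "none", gid, ""))
            gene_iv.append((start, end))
            # 3 exons / 2 introns at fixed relative cuts
            L = end - start
            cuts = [0, int(0.3 * L), int(0.4 * L), int(0.6 * L), int(0.7 * L), L]
            kinds = ["exon", "intron", "exon", "intron", "exon"]
            for j, kind in enumerate(kinds):
                s, e = start + cuts[j], start + cuts[j + 1]
                if e > s:
                    rows.append((chrom, s, e, strands[i], kind, subg, "none",
                                 f"{gid}.{kind}{j}", gid))
        # TEs in intergenic gaps, kept off gene bodies
        gaps = _complement(gene_iv, cfg.chrom_length, pad=100)
        placed: list[tuple[int, int]] = []
        n_te_chrom = cfg.n_te // 2
        gap_lens = np.array([e - s for s, e in gaps], dtype=float)
        for t in range(n_te_chrom):
            te_len = int(rng.integers(500, 3001))
            ok = False
            for _try in range(50):
                gi = int(rng.choice(len(gaps), p=gap_lens / gap_lens.sum()))
                gs, ge = gaps[gi]
                if ge - gs < te_len + 2:
                    continue
                s = int(rng.integers(gs, ge - te_len))
                e = s + te_len
                if any(s < pe and ps < e for ps, pe in placed):
                    continue
                ok = True
                break
            if not ok:
                raise ValueError("could not place requested TEs; reduce n_te")
            placed.append((s, e))
            rows.append((chrom, s, e, "+", "TE", subg, te_classes[t % 5],
                         f"TE_{tag}_{t + 1:04d}", ""))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return AnnotationSet(df, chrom_sizes={c: cfg.chrom_length for c, _, _ in chroms})


def _complement(intervals: list[tuple[int, int]], length: int, pad: int = 0
                ) -> list[tuple[int, int]]:
    """Gaps of [0, length) not covered by the (sorted, padded) intervals."""
    gaps = []
    cur = 0
    for s, e in sorted(intervals):
        s, e = max(0, s - pad), min(length, e + pad)
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        gaps.append((cur, length))
    return gaps


def homoeolog_pairs(annotation: AnnotationSet) -> pd.DataFrame:
    """1:1 homoeolog pair table (An gene i <-> Dn gene i, by ordinal)."""
    an = sorted(annotation.genes.loc[annotation.genes["subgenome"] == "An", "id"])
    dn = sorted(annotation.genes.loc[annotation.genes["subgenome"] == "Dn", "id"])
    n = min(len(an), len(dn))
    return pd.DataFrame({"an_gene": an[:n], "dn_gene": dn[:n]})


# --------------------------------------------------------------------------
# RNA counts

def _noiseless_relation(a: float, b: float, fc_min: float) -> str:
    lfc = np.log2((a + 1.0) / (b + 1.0))
    if abs(lfc) < fc_min:
        return "="
    return ">" if lfc > 0 else "<"


def _expected_eld_class(mu_f: float, mu_m: float, mu_h: float,
                        fc_min: float = 1.0) -> int:
    """Noise-free 12-class label of a planted mean triple under the fc gate."""
    from .eld import classify_eld
    return classify_eld(
        _noiseless_relation(mu_f, mu_m, fc_min),
        _noiseless_relation(mu_h, mu_f, fc_min),
        _noiseless_relation(mu_h, mu_m, fc_min),
    )


def _expected_additivity(mu_f: float, mu_m: float, mu_h: float,
                         fc_min: float = 2.0) -> str:
    mpv = (mu_f + mu_m) / 2.0
    rel = _noiseless_relation(mu_h, mpv, fc_min)
    return {"=": "additive", ">": "nonadditive-up", "<": "nonadditive-down"}[rel]


def _class_means(category: str, mu: float, cfg: SimConfig,
                 rng: np.random.Generator) -> tuple[float, float, float]:
    k, tk = cfg.eld_k, cfg.transgressive_k
    variant = int(rng.integers(0, 3))         # consumed for every class: keeps
    flip = bool(rng.integers(0, 2))           # the stream aligned across classes
    if category == "null":
        return mu, mu, mu
    if category == "additive":
        hi, lo = k * mu, mu
        f, m = (hi, lo) if flip else (lo, hi)
        return f, m, (f + m) / 2.0
    if category == "ELD-F-high":
        return k * mu, mu, k * mu
    if category == "ELD-F-low":
        return mu, k * mu, mu
    if category == "ELD-M-high":
        return mu, k * mu, k * mu
    if category == "ELD-M-low":
        return k * mu, mu, mu
    if category == "transgressive-up":
        f, m = [(mu, 2 * mu), (mu, mu), (2 * mu, mu)][variant]
        return f, m, tk * max(f, m)
    if category == "transgressive-down":
        f, m = [(mu, 2 * mu), (mu, mu), (2 * mu, mu)][variant]
        return f, m, min(f, m) / tk
    raise ValueError(f"unknown expression class {category!r}")


def simulate_counts(
    cfg: SimConfig,
    truth_assignment: pd.DataFrame | None = None,
    gene_ids=None,
    base_mean: float | None = None,
):
    """NB-distributed counts for F/M/H with planted expression classes.

    ``truth_assignment`` may fix the planted design: either a ``category``
    column (class names from ``class_proportions``) or explicit ``mu_F``,
    ``mu_M``, ``mu_H`` columns. Without it, classes are drawn from
    ``cfg.class_proportions`` and baseline means from the lognormal prior
    (``base_mean`` fixes the baseline instead, for recovery tests at depth).

    Returns ``(ExpressionMatrix, truth)`` where truth carries the planted
    category, the mean triple, and the noise-free expected labels
    (``eld_class`` under the |log2FC|>=1 equality gate, ``additivity`` under
    the |log2FC|>=2 MPV gate).
    """
    from .diffexpr import ExpressionMatrix
    rng = cfg.rng("counts")
    if truth_assignment is not None and {"mu_F", "mu_M", "mu_H"} <= set(truth_assignment.columns):
        truth = truth_assignment.copy().reset_index(drop=True)
        if "category" not in truth:
            truth["category"] = "explicit"
    else:
        if truth_assignment is not None:
            cats = list(truth_assignment["category"])
        else:
            n = cfg.n_genes if gene_ids is None else len(gene_ids)
            names = list(cfg.class_proportions)
            probs = np.array([cfg.class_proportions[c] for c in names])
            cats = list(rng.choice(names, size=n, p=probs))
        mus = (np.full(len(cats), base_mean) if base_mean is not None
               else rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, len(cats)))
        trip = [_class_means(c, float(m), cfg, rng) for c, m in zip(cats, mus)]
        truth = pd.DataFrame(trip, columns=["mu_F", "mu_M", "mu_H"])
        truth.insert(0, "category", cats)
    n = len(truth)
    if gene_ids is None:
        gene_ids = (list(truth_assignment["gene_id"])
                    if truth_assignment is not None and "gene_id" in truth_assignment
                    else [f"g{i + 1:05d}" for i in range(n)])
    if "gene_id" in truth.columns:
        truth = truth.drop(columns="gene_id")
    truth.insert(0, "gene_id", list(gene_ids))
    truth["eld_class"] = [
        _expected_eld_class(r.mu_F, r.mu_M, r.mu_H) for r in truth.itertuples()
    ]
    truth["additivity"] = [
        _expected_additivity(r.mu_F, r.mu_M, r.mu_H) for r in truth.itertuples()
    ]
    r_nb = 1.0 / cfg.nb_dispersion
    cols = {}
    for geno in ("F", "M", "H"):
        mu = truth[f"mu_{geno}"].to_numpy(dtype=float)
        p_nb = r_nb / (r_nb + np.maximum(mu, 1e-12))
        for rep in range(1, cfg.replicates + 1):
            cols[f"{geno}{rep}"] = rng.negative_binomial(r_nb, p_nb)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    meta = pd.DataFrame(
        {
            "genotype": [s[0] for s in counts.columns],
            "replicate": [int(s[1:]) for s in counts.columns],
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return ExpressionMatrix(counts=counts, sample_meta=meta), truth


#: mean triples (relative to a unit baseline) planting each of the 12 classes
#: with 8-fold margins on every "different" relation
_ELD_CLASS_TRIPLES = {
    1: (1, 8, 64), 2: (64, 8, 1),
    3: (8, 8, 1), 4: (1, 1, 8), 5: (1, 8, 8), 6: (8, 1, 1),
    7: (1, 64, 8), 8: (1, 8, 1), 9: (8, 64, 1),
    10: (8, 1, 64), 11: (8, 1, 8), 12: (64, 1, 8),
}


def eld_truth_assignment(n_per_class: int, base_mean: float = 500.0) -> pd.DataFrame:
    """Planted design covering all 12 expression classes with wide margins.

    Mean triples are (F, H, M) patterns with 8-fold separation on every
    unequal relation, scaled by ``base_mean``.
    """
    rows = []
    for cls, (f, h, m) in _ELD_CLASS_TRIPLES.items():
        for i in range(n_per_class):
            rows.append({
                "gene_id": f"cls{cls:02d}_{i + 1:03d}",
                "category": f"class-{cls}",
                "mu_F": f * base_mean, "mu_H": h * base_mean, "mu_M": m * base_mean,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# allele-specific expression

def simulate_allele_counts(cfg: SimConfig, n_genes: int | None = None):
    """Binomial allele splits with planted cis/trans architectures.

    Planted categories use the analysis vocabulary: ``none`` (both ratios 1),
    ``cis-only`` (parental ratio r preserved in the hybrid), ``trans-only``
    (parental ratio r, hybrid balanced), ``cis+trans`` (hybrid ratio shifted
    beyond r by 2**shift). Returns (records, truth).
    """
    rng = cfg.rng("allele")
    n = int(n_genes if n_genes is not None else cfg.n_genes)
    names = list(cfg.cis_trans_proportions)
    probs = np.array([cfg.cis_trans_proportions[c] for c in names])
    cats = rng.choice(names, size=n, p=probs)
    lo, hi = cfg.cis_ratio_range
    r = np.where(cats == "none", 1.0, rng.uniform(lo, hi, n))
    shift = rng.uniform(*cfg.trans_shift_range, n)
    r_h = np.select(
        [cats == "none", cats == "cis-only", cats == "trans-only"],
        [1.0, r, 1.0],
        default=r * np.power(2.0, shift),
    )
    p_par = r / (1.0 + r)
    p_hyb = r_h / (1.0 + r_h)
    n_par = rng.poisson(cfg.allele_depth, n)
    n_hyb = rng.poisson(cfg.allele_depth, n)
    f = rng.binomial(n_par, p_par)
    hf = rng.binomial(n_hyb, p_hyb)
    passes = rng.random(n) < cfg.ase_pass_fraction
    fpkm_min = np.where(passes, rng.uniform(2.0, 50.0, n), rng.uniform(0.1, 1.9, n))
    genes = [f"g{i + 1:05d}" for i in range(n)]
    records = pd.DataFrame({
        "gene": genes, "F": f, "M": n_par - f, "HF": hf, "HM": n_hyb - hf,
        "fpkm_min": fpkm_min,
    })
    truth = pd.DataFrame({
        "gene": genes, "category": cats, "r": r, "r_hybrid": r_h,
        "passes_filter": passes,
    })
    return records, truth


# --------------------------------------------------------------------------
# methylome

_TRI = {"CG": "CGG", "CHG": "CAG", "CHH": "CAT"}


def _beta_draw(rng, mean: np.ndarray, precision: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1.0 - 1e-4)
    return rng.beta(mean * precision, (1.0 - mean) * precision)


def simulate_methylome(cfg: SimConfig, annotation: AnnotationSet):
    """Beta-binomial CX reports for F/M/H with planted DMRs and 8 patterns.

    Per-site methylation propensities sit around the context baseline
    (elevated inside TE bodies), are shared across genotypes, and get a
    genotype-specific shift of ``dmr_delta`` inside planted DMR windows (shift
    direction is chosen with headroom so the planted |delta| survives the
    (0, 1) clamp). Planted pattern loci override the three genotype levels
    with each of the 2**3 methylated/unmethylated states. Coverage is
    Poisson(``coverage_mean``).

    Returns ``(records, truth)`` where records maps genotype -> CX DataFrame
    (0-based positions) and truth has ``dmrs`` and ``patterns`` tables.
    """
    rng = cfg.rng("methylome")
    genotypes = ("F", "M", "H")
    chroms = sorted(annotation.chrom_sizes) or sorted(set(annotation.features["chrom"]))
    sizes = annotation.chrom_sizes
    tes = annotation.tes
    win = 100

    # planted DMR windows per context, aligned to the 100-bp grid
    dmr_rows = []
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for ctx in ("CG", "CHG", "CHH"):
        delta = cfg.dmr_delta[ctx]
        base = cfg.context_baselines[ctx]
        for i in range(cfg.n_dmrs_per_context):
            for _try in range(100):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                size = sizes.get(chrom, 1_000_000)
                n_win = int(rng.integers(1, cfg.dmr_max_windows + 1))
                w0 = int(rng.integers(0, size // win - n_win))
                s, e = w0 * win, (w0 + n_win) * win
                if all(e + 400 <= us or ue + 400 <= s for us, ue in used[chrom]):
                    used[chrom].append((s, e))
                    break
            else:
                raise ValueError("could not place planted DMRs; genome too small")
            target = ("H", "H", "F", "M")[int(rng.integers(0, 4))]
            dirs = [d for d in (+1, -1)
                    if 0.02 <= base + d * delta <= 0.95]
            if not dirs:
                warnings.warn(f"dmr_delta for {ctx} clamped into (0,1)")
                dirs = [+1 if base < 0.5 else -1]
            direction = dirs[int(rng.integers(0, len(dirs)))]
            dmr_rows.append({
                "chrom": chrom, "start": s, "end": e, "context": ctx,
                "target": target,
                "direction": "hyper" if direction > 0 else "hypo",
                "delta": direction * delta,
            })
    dmr_truth = pd.DataFrame(dmr_rows)

    within_precision = (1.0 - cfg.beta_binomial_overdispersion) / cfg.beta_binomial_overdispersion

    records: dict[str, list[pd.DataFrame]] = {g: [] for g in genotypes}
    pattern_rows = []
    for chrom in chroms:
        size = sizes.get(chrom, 1_000_000)
        te_chrom = tes[tes["chrom"] == chrom]
        te_s = te_chrom["start"].to_numpy()
        te_e = te_chrom["end"].to_numpy()
        order_te = np.argsort(te_s)
        te_s, te_e = te_s[order_te], te_e[order_te]
        for ctx in ("CG", "CHG", "CHH"):
            n_sites = int(size * cfg.cytosine_density[ctx])
            pos = np.sort(rng.choice(size, size=n_sites, replace=False))
            strand = rng.choice(["+", "-"], n_sites)
            base = np.full(n_sites, cfg.context_baselines[ctx])
            if len(te_s):
                idx = np.searchsorted(te_s, pos, side="right") - 1
                in_te = (idx >= 0) & (pos < te_e[np.clip(idx, 0, None)])
                base[in_te] = np.clip(base[in_te] + cfg.te_meth_boost, None, 0.95)
            propensity = _beta_draw(rng, base, cfg.site_precision)
            # genotype-specific site means (shared propensity + planted shifts)
            means = {g: propensity.copy() for g in genotypes}
            truth_ctx = dmr_truth[(dmr_truth["chrom"] == chrom) & (dmr_truth["context"] == ctx)]
            for d in truth_ctx.itertuples():
                mask = (pos >= d.start) & (pos < d.end)
                shifted = means[d.target][mask] + d.delta
                clamped = np.clip(shifted, 0.005, 0.995)
                means[d.target][mask] = clamped
            # planted 8-pattern loci: CG sites on the first chromosome,
            # outside planted DMR windows
            if ctx == "CG" and chrom == chroms[0]:
                in_dmr = np.zeros(n_sites, dtype=bool)
                for us, ue in used[chrom]:
                    in_dmr |= (pos >= us - win) & (pos < ue + win)
                candidates = np.flatnonzero(~in_dmr)
                need = 8 * cfg.n_pattern_loci
                if len(candidates) < need:
                    raise ValueError("not enough CG sites for planted patterns")
                chosen = rng.choice(candidates, size=need, replace=False)
                states = [(f_, m_, h_) for f_ in (0, 1) for m_ in (0, 1) for h_ in (0, 1)]
                for k, site_idx in enumerate(chosen):
                    f_, m_, h_ = states[k % 8]
                    for g, st in zip(genotypes, (f_, m_, h_)):
                        means[g][site_idx] = 0.7 if st else cfg.error_rate
                    pattern_rows.append({
                        "chrom": chrom, "pos": int(pos[site_idx]), "context": ctx,
                        "state_F": f_, "state_M": m_, "state_H": h_,
                        "pattern_id": pattern_id_from_states(f_, m_, h_),
                    })
            for g in genotypes:
                level = _beta_draw(rng, means[g], within_precision)
                level = np.clip(level + cfg.error_rate * (1 - level), 0.0, 1.0)
                cov = rng.poisson(cfg.coverage_mean, n_sites)
                meth = rng.binomial(cov, level)
                records[g].append(pd.DataFrame({
                    "chrom": chrom, "pos": pos, "strand": strand,
                    "meth": meth, "unmeth": cov - meth,
                    "context": ctx, "tri": _TRI[ctx], "total": cov,
                }))
    out = {
        g: pd.concat(records[g], ignore_index=True)
            .sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        for g in genotypes
    }
    truth = {
        "dmrs": dmr_truth,
        "patterns": pd.DataFrame(pattern_rows),
    }
    return out, truth


# --------------------------------------------------------------------------
# 24-nt siRNA reads

def simulate_sirna_reads(cfg: SimConfig, annotation: AnnotationSet):
    """Clustered 24-nt read intervals per sample with planted cluster truth.

    Cluster spans are lognormal (mode ~150-250 nt) clipped to 100-1000 nt; a
    configurable fraction (default 0.75) is placed fully inside TEs, the rest
    in TE-free intergenic space. Per-sample read counts are Poisson with the
    planted F/M/H abundance ratios; background reads are sprinkled uniformly.

    Returns ``(reads, truth)`` with reads mapping sample name -> BED-like
    DataFrame of 24-nt intervals.
    """
    rng = cfg.rng("sirna")
    chroms = sorted(annotation.chrom_sizes)
    sizes = annotation.chrom_sizes
    tes = annotation.tes.reset_index(drop=True)
    genes = annotation.genes

    lo, hi = cfg.cluster_span_range
    spans = np.clip(
        np.round(rng.lognormal(cfg.cluster_span_log_mean, cfg.cluster_span_log_sigma,
                               cfg.n_clusters)).astype(int),
        lo, hi,
    )
    n_te_clusters = int(round(cfg.te_cluster_fraction * cfg.n_clusters))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _free(chrom: str, s: int, e: int, sep: int = 300) -> bool:
        return all(e + sep <= ps or pe + sep <= s for ps, pe in placed[chrom])

    clusters = []
    for ci in range(cfg.n_clusters):
        span = int(spans[ci])
        in_te = ci < n_te_clusters
        for _try in range(200):
            if in_te:
                ti = int(rng.integers(0, len(tes)))
                te = tes.iloc[ti]
                te_len = te["end"] - te["start"]
                use_span = min(span, int(te_len))
                s = int(rng.integers(te["start"], te["end"] - use_span + 1))
                chrom = te["chrom"]
                e = s + use_span
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                size = sizes[chrom]
                s = int(rng.integers(0, size - span))
                e = s + span
                blockers = pd.concat([
                    tes[tes["chrom"] == chrom][["start", "end"]],
                    genes[genes["chrom"] == chrom][["start", "end"]],
                ])
                if ((blockers["start"] < e + 50) & (s - 50 < blockers["end"])).any():
                    continue
            if _free(chrom, s, e):
                placed[chrom].append((s, e))
                clusters.append({"cluster_id": f"cl{ci + 1:04d}", "chrom": chrom,
                                 "start": s, "end": e, "in_te": in_te})
                break
        else:
            raise ValueError("could not place planted siRNA clusters; reduce n_clusters")
    truth = pd.DataFrame(clusters)

    nonadd = rng.random(cfg.n_clusters) < cfg.sirna_nonadditive_fraction
    up = rng.random(cfg.n_clusters) < cfg.sirna_up_fraction
    ratio_h = np.where(nonadd, np.where(up, cfg.sirna_fc, 1.0 / cfg.sirna_fc), 1.0)
    truth["ratio_F"] = 1.0
    truth["ratio_M"] = 1.0
    truth["ratio_H"] = ratio_h
    # per-million scaling only sees relative abundance, so the recoverable
    # truth is the composition-adjusted ratio: planted ratio divided by the
    # hybrid's total library-mass factor
    span_mass = (truth["end"] - truth["start"]).to_numpy(dtype=float)
    bg_mass = sum(sizes[c] for c in chroms) * cfg.background_read_density / cfg.cluster_read_density
    mass_h = ((span_mass * ratio_h).sum() + bg_mass) / (span_mass.sum() + bg_mass)
    truth["ratio_H_rpm"] = ratio_h / mass_h
    truth["label"] = np.where(
        truth["ratio_H_rpm"] >= 1.5, "up",
        np.where(truth["ratio_H_rpm"] <= 1 / 1.5, "down", "ns"))

    reads: dict[str, pd.DataFrame] = {}
    spans_arr = (truth["end"] - truth["start"]).to_numpy()
    for sample in SAMPLES:
        geno = sample[0]
        scale = truth[f"ratio_{geno}"].to_numpy()
        frames = []
        n_reads = rng.poisson(spans_arr * cfg.cluster_read_density * scale)
        for row, k in zip(truth.itertuples(), n_reads):
            if k == 0:
                continue
            max_start = max(row.end - READ_LENGTH, row.start + 1)
            starts = rng.integers(row.start, max_start, k)
            frames.append(pd.DataFrame({
                "chrom": row.chrom, "start": starts, "end": starts + READ_LENGTH,
            }))
        for chrom in chroms:
            size = sizes[chrom]
            n_bg = rng.poisson(size * cfg.background_read_density)
            starts = rng.integers(0, size - READ_LENGTH, n_bg)
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + READ_LENGTH,
            }))
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        df["name"] = [f"{sample}_r{i}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = "+"
        reads[sample] = df
    return reads, truth
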