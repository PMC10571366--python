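"""Context levels, site calling, metaplots, DMRs, patterns, DMGs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heteromics._stats import fisher_exact_two_sided
from heteromics.intervals import AnnotationSet, FEATURE_COLUMNS
from heteromics.methylome import (
    annotate_dmrs, call_dmrs, call_methylated_site, call_methylated_sites,
    classify_vs_mpv, context_levels, expression_quartile_methylation,
    identify_dmgs, metaplot, parental_pattern, pattern_id_from_states,
)


def _cx(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth",
                                       "unmeth", "context", "tri", "total"])


class TestContextLevels:
    def test_weighted_level(self):
        recs = _cx([("c", 1, "+", 5, 5, "CG", "CGG", 10),
                    ("c", 5, "+", 0, 10, "CG", "CGG", 10)])
        out = context_levels(recs).set_index("context")
        assert out.loc["CG", "level"] == pytest.approx(0.25)

    def test_all_unmethylated(self):
        recs = _cx([("c", 1, "+", 0, 10, "CHH", "CAT", 10)])
        out = context_levels(recs).set_index("context")
        assert out.loc["CHH", "level"] == 0.0
        assert out.loc["CHH", "mc_proportion"] == 0.0

    def test_simulated_cg_level_recovered(self, methylome_sim, cfg):
        records, _ = methylome_sim
        out = context_levels(records["M"]).set_index("context")
        # TE bodies are boosted, so the global level sits at or above baseline
        assert out.loc["CG", "level"] == pytest.approx(
            cfg.context_baselines["CG"], abs=0.05)
        # ordering CG > CHG > CHH is preserved
        assert out.loc["CG", "level"] > out.loc["CHG", "level"] > out.loc["CHH", "level"]


class TestSiteCaller:
    def test_zero_methylated_gives_p_one(self):
        assert call_methylated_site(0, 10) == pytest.approx(1.0)

    def test_exact_tail_matches_enumeration(self):
        # P(X >= 5 | n=10, err=0.006) by direct summation
        want = sum(math.comb(10, k) * 0.006 ** k * 0.994 ** (10 - k)
                   for k in range(5, 11))
        assert call_methylated_site(5, 10) == pytest.approx(want, rel=1e-9)
        assert want == pytest.approx(1.911e-9, rel=1e-3)

    def test_error_rate_half_boundary(self):
        assert call_methylated_site(5, 10, error_rate=0.5) > 0.5

    def test_caller_excludes_low_coverage(self):
        recs = _cx([("c", 1, "+", 3, 0, "CG", "CGG", 3),
                    ("c", 5, "+", 10, 0, "CG", "CGG", 10)])
        out = call_methylated_sites(recs, min_cov=4)
        assert len(out) == 1
        assert out.iloc[0]["methylated"]


class TestMetaplot:
    def _features(self, strand="+"):
        return pd.DataFrame({"chrom": ["c"], "start": [2000], "end": [3000],
                             "strand": [strand], "id": ["g1"]})

    def _uniform_records(self, level=0.5, step=10):
        pos = np.arange(0, 5000, step)
        meth = int(level * 10)
        return _cx([("c", p, "+", meth, 10 - meth, "CG", "CGG", 10) for p in pos])

    def test_uniform_methylation_flat_profile(self):
        profile, _ = metaplot(self._uniform_records(), self._features(),
                              flank=2000, body_bins=20, flank_bins=30)
        cg = profile[profile["context"] == "CG"]
        np.testing.assert_allclose(cg["level"].dropna(), 0.5)

    def test_coverage_weighted_mean_equals_global_level(self, methylome_sim, annotation):
        records, _ = methylome_sim
        genes = annotation.genes.head(10)
        profile, _ = metaplot(records["F"], genes, flank=500)
        for ctx in ("CG", "CHH"):
            sub = profile[profile["context"] == ctx]
            binned = sub["meth"].sum() / sub["total"].sum()
            # global level over exactly the binned region records
            lo = genes["start"].min()
            regional = []
            f = records["F"]
            for g in genes.itertuples():
                m = ((f["chrom"] == g.chrom) & (f["context"] == ctx)
                     & (f["pos"] >= g.start - 500) & (f["pos"] < g.end + 500))
                regional.append(f[m])
            reg = pd.concat(regional)
            assert binned == pytest.approx(reg["meth"].sum() / reg["total"].sum())

    def test_minus_strand_reverses_flanks(self):
        # methylation only upstream of the + coordinates: on a minus-strand
        # feature that flank appears on the downstream side of the profile
        recs = _cx([("c", p, "+", 8, 2, "CG", "CGG", 10) for p in range(0, 2000, 10)])
        plus, _ = metaplot(recs, self._features("+"), flank=2000,
                           body_bins=20, flank_bins=30)
        minus, _ = metaplot(recs, self._features("-"), flank=2000,
                            body_bins=20, flank_bins=30)
        p_cg = plus[plus["context"] == "CG"].set_index("bin")["total"]
        m_cg = minus[minus["context"] == "CG"].set_index("bin")["total"]
        assert p_cg.loc[range(0, 30)].sum() > 0
        assert p_cg.loc[range(30, 80)].sum() == 0
        assert m_cg.loc[range(50, 80)].sum() > 0
        assert m_cg.loc[range(0, 50)].sum() == 0

    def test_short_feature_skipped(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [110],
                              "strand": ["+"], "id": ["tiny"]})
        _, skipped = metaplot(self._uniform_records(), feats, body_bins=20)
        assert skipped == 1


def _window_frame(rows):
    cols = ["chrom", "start", "end", "context"]
    gcols = []
    for g in ("F", "M", "H"):
        gcols += [f"meth_{g}", f"total_{g}", f"n_{g}"]
    df = pd.DataFrame(rows, columns=cols + gcols)
    for g in ("F", "M", "H"):
        df[f"level_{g}"] = df[f"meth_{g}"] / df[f"total_{g}"]
    return df


class TestDMRs:
    def test_fisher_matches_scipy_on_random_tables(self, rng):
        draws = rng.integers(0, 200, size=(1000, 4))
        for a, b, c, d in draws:
            want = stats.fisher_exact([[a, b], [c, d]]).pvalue
            got = fisher_exact_two_sided(a, b, c, d)
            assert got == pytest.approx(want, abs=1e-9)

    def test_strong_difference_called(self):
        win = _window_frame([
            ("c", 0, 100, "CG", 80, 100, 5, 80, 100, 5, 20, 100, 5),
        ])
        dmrs = call_dmrs(win, ("F", "H"))
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["direction"] == "hypo"
        assert dmrs.iloc[0]["delta"] == pytest.approx(-0.6)

    def test_identical_counts_not_called(self):
        win = _window_frame([
            ("c", 0, 100, "CG", 50, 100, 5, 50, 100, 5, 50, 100, 5),
        ])
        assert len(call_dmrs(win, ("F", "H"))) == 0

    def test_small_delta_blocked_regardless_of_p(self):
        # CG needs |delta| >= 0.4: 0.15 at huge depth is significant but not a DMR
        win = _window_frame([
            ("c", 0, 100, "CG", 5000, 10000, 5, 5000, 10000, 5, 6500, 10000, 5),
        ])
        assert len(call_dmrs(win, ("F", "H"))) == 0

    def test_low_cytosine_window_untested(self):
        win = _window_frame([
            ("c", 0, 100, "CG", 80, 100, 2, 80, 100, 2, 20, 100, 2),
        ])
        assert len(call_dmrs(win, ("F", "H"))) == 0

    def test_adjacent_same_direction_windows_merged(self):
        rows = [("c", s, s + 100, "CG", 90, 100, 5, 90, 100, 5, 10, 100, 5)
                for s in (0, 200)]  # 100-bp gap <= 200 merge distance
        dmrs = call_dmrs(_window_frame(rows), ("F", "H"))
        assert len(dmrs) == 1
        assert (dmrs.iloc[0]["start"], dmrs.iloc[0]["end"]) == (0, 300)
        assert dmrs.iloc[0]["n_windows"] == 2

    def test_distant_windows_not_merged(self):
        rows = [("c", s, s + 100, "CG", 90, 100, 5, 90, 100, 5, 10, 100, 5)
                for s in (0, 400)]
        assert len(call_dmrs(_window_frame(rows), ("F", "H"))) == 2


class TestClassifyVsMPV:
    def test_tcm_when_hybrid_above_mpv(self):
        t = _window_frame([
            ("c", 0, 100, "CG", 80, 200, 5, 80, 200, 5, 160, 200, 5),
        ])
        out = classify_vs_mpv(t)
        assert out.iloc[0]["class"] == "interactive"
        assert out.iloc[0]["trans_class"] == "TCM"

    def test_tcdm_when_hybrid_below_mpv(self):
        t = _window_frame([
            ("c", 0, 100, "CG", 80, 200, 5, 80, 200, 5, 20, 200, 5),
        ])
        out = classify_vs_mpv(t)
        assert out.iloc[0]["trans_class"] == "TCdM"

    def test_matching_hybrid_noninteractive(self):
        t = _window_frame([
            ("c", 0, 100, "CG", 80, 200, 5, 80, 200, 5, 80, 200, 5),
        ])
        out = classify_vs_mpv(t)
        assert out.iloc[0]["class"] == "noninteractive"
        assert out.iloc[0]["trans_class"] == "n/a"


class TestPatterns:
    def test_all_eight_states_distinct(self):
        ids = {pattern_id_from_states(f, m, h)
               for f in (0, 1) for m in (0, 1) for h in (0, 1)}
        assert ids == set(range(1, 9))

    def test_denovo_and_conserved_names(self):
        from heteromics.methylome import PATTERN_NAMES
        assert PATTERN_NAMES[pattern_id_from_states(0, 0, 1)] == "de-novo"
        assert PATTERN_NAMES[pattern_id_from_states(1, 1, 1)] == "conserved"

    def test_planted_patterns_recovered(self, methylome_sim):
        records, truth = methylome_sim
        calls = parental_pattern(records)
        merged = truth["patterns"].merge(
            calls, on=["chrom", "pos", "context"], suffixes=("_true", ""))
        assert len(merged) / len(truth["patterns"]) > 0.95
        agree = (merged["pattern_id"] == merged["pattern_id_true"]).mean()
        assert agree >= 0.9
        # every planted state is recovered somewhere
        assert set(merged.loc[
            merged["pattern_id"] == merged["pattern_id_true"], "pattern_id"
        ]) == set(range(1, 9))


def _toy_annotation():
    rows = [
        ("c", 10_000, 13_000, "+", "gene", "An", "none", "g1", ""),
        ("c", 30_000, 32_000, "-", "gene", "An", "none", "g2", ""),
    ]
    return AnnotationSet(pd.DataFrame(rows, columns=FEATURE_COLUMNS),
                         chrom_sizes={"c": 50_000})


class TestDMRAnnotation:
    def _dmr(self, start, end):
        return pd.DataFrame({"chrom": ["c"], "start": [start], "end": [end]})

    def test_inside_gene_intragenic(self):
        assert annotate_dmrs(self._dmr(11_000, 11_200), _toy_annotation()).iloc[0] == "intragenic"

    def test_within_promoter(self):
        assert annotate_dmrs(self._dmr(8_500, 8_700), _toy_annotation()).iloc[0] == "promoter"

    def test_minus_strand_promoter_downstream_of_end(self):
        assert annotate_dmrs(self._dmr(32_500, 32_700), _toy_annotation()).iloc[0] == "promoter"

    def test_nowhere_intergenic(self):
        assert annotate_dmrs(self._dmr(45_000, 45_200), _toy_annotation()).iloc[0] == "intergenic"


class TestDMGs:
    def test_upstream_flag_within_1kb(self):
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [9_400], "end": [9_600]})
        out = identify_dmgs(["g1"], dmrs, _toy_annotation()).set_index("gene")
        assert out.loc["g1", "up1kb"]
        assert not out.loc["g1", "body"]

    def test_upstream_beyond_1kb_not_flagged(self):
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [8_400], "end": [8_600]})
        out = identify_dmgs(["g1"], dmrs, _toy_annotation()).set_index("gene")
        assert not out.loc["g1", "up1kb"]

    def test_all_three_regions_flagged(self):
        dmrs = pd.DataFrame({"chrom": ["c"] * 3,
                             "start": [9_500, 11_000, 13_200],
                             "end": [9_700, 11_200, 13_400]})
        out = identify_dmgs(["g1"], dmrs, _toy_annotation()).set_index("gene")
        assert out.loc["g1", ["up1kb", "body", "down1kb"]].all()


class TestQuartiles:
    def test_too_few_genes_rejected(self, methylome_sim, annotation, counts_sim):
        em, _ = counts_sim
        records, _ = methylome_sim
        tiny = AnnotationSet(annotation.genes.head(3), annotation.chrom_sizes)
        with pytest.raises(ValueError, match="quartiles"):
            expression_quartile_methylation(em, records["H"], tiny)

    def test_quartile_sizes_remainder_to_lower(self, methylome_sim, annotation, counts_sim):
        em, _ = counts_sim
        records, _ = methylome_sim
        out = expression_quartile_methylation(em, records["H"], annotation,
                                              flank=500)
        assert set(out) == {"low", "mid-low", "mid-high", "high"}
        for profile in out.values():
            assert {"context", "bin", "level"} <= set(profile.columns)
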