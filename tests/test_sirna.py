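"""Cluster sweep, quantification, MPV testing and genomic annotation."""

import numpy as np
import pandas as pd
import pytest

from heteromics.intervals import AnnotationSet, FEATURE_COLUMNS
from heteromics.sirna import (
    ClusterParams, annotate_clusters, call_clusters, de_clusters_vs_mpv,
    te_expression_change,
)


def _reads(starts, chrom="c", length=24):
    starts = np.asarray(starts)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + length})


class TestSweep:
    def test_groups_past_max_gap_split(self):
        reads = {"s": _reads(list(range(0, 240, 20)) + list(range(740, 980, 20)))}
        clusters, _ = call_clusters(reads, ClusterParams(max_gap=100, min_reads=5))
        assert len(clusters) == 2

    def test_tiled_reads_single_cluster_span(self):
        # 12 reads every 20 bp from 0: last start 220, cluster = [0, 244)
        reads = {"s": _reads(range(0, 240, 20))}
        clusters, _ = call_clusters(reads, ClusterParams(min_reads=10, min_span=50))
        assert len(clusters) == 1
        assert (clusters.iloc[0]["start"], clusters.iloc[0]["end"]) == (0, 244)

    def test_min_reads_filter(self):
        reads = {"s": _reads([0, 30, 60])}
        clusters, _ = call_clusters(reads, ClusterParams(min_reads=10))
        assert len(clusters) == 0

    def test_non_24nt_reads_skipped_and_counted(self):
        df = _reads(range(0, 400, 20))
        df.loc[3, "end"] = df.loc[3, "start"] + 21
        clusters, skipped = call_clusters({"s": df})
        assert skipped == 1

    def test_idempotence(self, sirna_sim):
        reads, _ = sirna_sim
        clusters, _ = call_clusters(reads)
        # re-cluster only the reads inside called clusters: identical intervals
        from heteromics.intervals import any_overlap
        member = {
            s: df[any_overlap(
                df.assign(end=df["start"] + 1)[["chrom", "start", "end"]],
                clusters[["chrom", "start", "end"]])]
            for s, df in reads.items()
        }
        again, _ = call_clusters(member)
        merged = again.merge(clusters, on=["chrom", "start", "end"], how="left")
        assert len(again) <= len(clusters)
        assert merged["span_y"].notna().all()

    def test_input_order_invariance(self, rng):
        starts = rng.integers(0, 50_000, 400)
        a = {"s": _reads(starts)}
        b = {"s": _reads(starts[::-1])}
        ca, _ = call_clusters(a)
        cb, _ = call_clusters(b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_maximality_no_two_clusters_within_max_gap(self, rng):
        starts = np.sort(rng.integers(0, 100_000, 2000))
        clusters, _ = call_clusters({"s": _reads(starts)},
                                    ClusterParams(min_reads=1, min_span=1))
        gaps = clusters["start"].to_numpy()[1:] - clusters["end"].to_numpy()[:-1]
        assert (gaps > 100).all()


def _toy_annotation():
    rows = [
        ("c", 10_000, 13_000, "+", "gene", "An", "none", "g1", ""),
        ("c", 20_000, 21_000, "+", "TE", "An", "LTR-copia", "t1", ""),
    ]
    return AnnotationSet(pd.DataFrame(rows, columns=FEATURE_COLUMNS),
                         chrom_sizes={"c": 50_000})


class TestAnnotate:
    def _clusters(self, start, end):
        return pd.DataFrame({"chrom": ["c"], "start": [start], "end": [end]})

    def test_inside_te(self):
        labels, _ = annotate_clusters(self._clusters(20_100, 20_400), _toy_annotation())
        assert labels.iloc[0] == "TE"

    def test_gene_body_beats_minor_te_overlap(self):
        # 70% in the gene, 30% in the TE: the TE overlap fails min_frac
        ann = AnnotationSet(pd.DataFrame([
            ("c", 10_000, 13_000, "+", "gene", "An", "none", "g1", ""),
            ("c", 13_000, 14_000, "+", "TE", "An", "DNA", "t1", ""),
        ], columns=FEATURE_COLUMNS), chrom_sizes={"c": 50_000})
        labels, _ = annotate_clusters(self._clusters(12_300, 13_300), ann)
        assert labels.iloc[0] == "gene-body"

    def test_upstream_flank(self):
        labels, _ = annotate_clusters(self._clusters(8_500, 9_000), _toy_annotation())
        assert labels.iloc[0] == "flank-up"

    def test_downstream_flank(self):
        labels, _ = annotate_clusters(self._clusters(13_500, 14_000), _toy_annotation())
        assert labels.iloc[0] == "flank-down"

    def test_intergenic(self):
        labels, summary = annotate_clusters(self._clusters(40_000, 40_500), _toy_annotation())
        assert labels.iloc[0] == "intergenic"
        assert summary["te_fraction"] == 0.0


class TestDEvsMPV:
    def _cluster_frame(self, rpm_f, rpm_m, rpm_h):
        n = len(rpm_f)
        out = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 1000,
                            "end": np.arange(n) * 1000 + 200})
        for i in range(3):
            out[f"rpm_F{i+1}"] = rpm_f[:, i]
            out[f"rpm_M{i+1}"] = rpm_m[:, i]
            out[f"rpm_H{i+1}"] = rpm_h[:, i]
        return out

    def _samples(self):
        return {g: [f"{g}{i}" for i in (1, 2, 3)] for g in "FMH"}

    def test_identical_rpm_all_ns(self):
        rpm = np.full((10, 3), 50.0)
        table, _ = de_clusters_vs_mpv(self._cluster_frame(rpm, rpm, rpm), self._samples())
        assert (table["de_status"] == "ns").all()

    def test_doubled_hybrid_called_up(self, rng):
        f = rng.normal(100, 1, (20, 3))
        m = rng.normal(100, 1, (20, 3))
        table, _ = de_clusters_vs_mpv(self._cluster_frame(f, m, 2 * (f + m) / 2),
                                      self._samples())
        assert (table["de_status"] == "up").all()

    def test_planted_mixture_recovered(self, rng):
        # 70:30 up:down mixture at depth >= 200 reads per cluster, equal
        # library mass: the recovered up fraction is within +-5%
        n = 1000
        up = rng.random(n) < 0.7
        lam = 300.0
        f = rng.poisson(lam, (n, 3)).astype(float)
        m = rng.poisson(lam, (n, 3)).astype(float)
        scale = np.where(up, 2.0, 0.5)
        h = rng.poisson(lam * scale[:, None], (n, 3)).astype(float)
        table, summary = de_clusters_vs_mpv(self._cluster_frame(f, m, h), self._samples())
        assert summary["fraction_above_mpv"] == pytest.approx(0.7, abs=0.05)


class TestTEExpression:
    def _means(self, f, m, h):
        return pd.DataFrame({"mean_F": [f], "mean_M": [m], "mean_H": [h]},
                            index=["te1"])

    def test_equal_is_ns(self):
        status, _ = te_expression_change(self._means(100, 100, 100))
        assert status.iloc[0] == "ns"

    def test_fold_above_threshold_is_up(self):
        status, _ = te_expression_change(self._means(100, 100, 160))
        assert status.iloc[0] == "up"

    def test_reciprocal_fold_is_down(self):
        status, _ = te_expression_change(self._means(100, 100, 50))
        assert status.iloc[0] == "down"

    def test_sirna_bearing_fraction(self):
        means = pd.DataFrame({
            "mean_F": [100, 100], "mean_M": [100, 100], "mean_H": [50, 160],
        }, index=["t1", "t2"])
        _, summary = te_expression_change(means, sirna_te_ids=["t1"])
        assert summary["sirna_te_down_fraction"] == 1.0


class TestPlantedRecovery:
    def test_planted_clusters_recovered_with_high_jaccard(self, sirna_sim):
        reads, truth = sirna_sim
        clusters, _ = call_clusters(reads)
        ok = 0
        for row in truth.itertuples():
            hit = clusters[(clusters["chrom"] == row.chrom)
                           & (clusters["start"] < row.end)
                           & (row.start < clusters["end"])]
            if len(hit) == 1:
                c = hit.iloc[0]
                inter = min(c["end"], row.end) - max(c["start"], row.start)
                union = max(c["end"], row.end) - min(c["start"], row.start)
                ok += inter / union >= 0.8
        assert ok / len(truth) >= 0.95

    def test_te_colocalization_recovered(self, sirna_sim, annotation, cfg):
        reads, _ = sirna_sim
        clusters, _ = call_clusters(reads)
        _, summary = annotate_clusters(clusters, annotation)
        assert summary["te_fraction"] == pytest.approx(cfg.te_cluster_fraction, abs=0.05)
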