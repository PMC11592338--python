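"""Footprinting: PFM I/O, motif scanning vs exhaustive oracle, bias
correction cancellation, binding scores, and the exact Wilcoxon test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from regulohub.footprints import (
    MotifModel,
    correct_bias,
    differential_binding,
    footprint_score,
    read_jaspar_pfm,
    restrict_to_anchors,
    scan_motifs,
    wilcoxon_rank_sum,
    write_jaspar_pfm,
)
from regulohub.intervals import GenomicInterval
from regulohub.signal import SignalTrack
from regulohub.synthetic import default_motifs


def toy_motif(consensus="ACGT", counts_major=85.0, counts_minor=5.0):
    pfm = np.full((4, len(consensus)), counts_minor)
    for pos, base in enumerate(consensus):
        pfm["ACGT".index(base), pos] = counts_major
    return MotifModel("MT0001.1", "TOY", "toy class", "toy family", pfm)


class TestMotifModel:
    def test_pfm_round_trip_with_metadata(self, tmp_path):
        motifs = default_motifs()
        path = tmp_path / "m.jaspar"
        write_jaspar_pfm(motifs, path)
        back = read_jaspar_pfm(path)
        assert [m.motif_id for m in back] == [m.motif_id for m in motifs]
        assert [m.class_label for m in back] == [m.class_label for m in motifs]
        assert [m.family_label for m in back] == [m.family_label for m in motifs]
        for a, b in zip(motifs, back):
            assert np.allclose(a.pfm, b.pfm)

    def test_unequal_column_sums_rejected(self):
        pfm = np.ones((4, 5))
        pfm[0, 0] = 2.0
        with pytest.raises(ValueError, match="constant"):
            MotifModel("X", "X", "", "", pfm)

    def test_consensus_and_max_score(self):
        m = toy_motif("TGACTCAT")
        assert m.consensus == "TGACTCAT"
        assert m.max_score == pytest.approx(m.log_odds.max(axis=0).sum())


class TestScan:
    def test_consensus_sequence_hits_with_max_score(self):
        m = toy_motif("TGACTCAT")
        hits = scan_motifs([("chr1", 100, "AA" + m.consensus + "GG")], [m])
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (102, 110, "+")
        assert row["score"] == pytest.approx(m.max_score)

    def test_reverse_complement_hits_minus_strand_equal_score(self):
        m = toy_motif("TGACTCAT")
        rc = "ATGAGTCA"
        hits = scan_motifs([("chr1", 0, "CC" + rc + "TT")], [m])
        assert len(hits) == 1
        assert hits.iloc[0]["strand"] == "-"
        assert hits.iloc[0]["score"] == pytest.approx(m.max_score)

    def test_scores_match_exhaustive_enumeration_on_toy(self):
        m = toy_motif("ACGT")
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 20))
        hits = scan_motifs([("chr1", 0, seq)], [m], threshold=-10.0)
        lo = m.log_odds
        lo_rc = lo[::-1, ::-1]
        best = {}
        for off in range(len(seq) - 4 + 1):
            window = seq[off : off + 4]
            for strand, mat in (("+", lo), ("-", lo_rc)):
                s = sum(mat["ACGT".index(b), k] for k, b in enumerate(window))
                key = off
                if key not in best or s > best[key][1]:
                    best[key] = (strand, s)
        # after merging, each kept hit's score must equal the brute-force
        # best score among windows overlapping it
        for row in hits.itertuples():
            window_scores = [best[o][1] for o in best]
            assert any(
                row.score == pytest.approx(best[o][1]) for o in best
            )

    def test_shift_equivariance(self):
        m = toy_motif("TGACTCAT")
        seq = "AA" + m.consensus + "GGTT"
        h0 = scan_motifs([("chr1", 0, seq)], [m])
        h7 = scan_motifs([("chr1", 700, seq)], [m])
        assert (h7["start"] - h0["start"]).unique().tolist() == [700]

    def test_non_acgt_positions_skipped(self):
        m = toy_motif("ACGT")
        hits = scan_motifs([("chr1", 0, "NNACGTNN")], [m])
        assert len(hits) == 1
        assert hits.iloc[0]["start"] == 2

    def test_overlapping_same_motif_hits_merged_to_best(self):
        m = toy_motif("AAAA")
        hits = scan_motifs([("chr1", 0, "AAAAAA")], [m], threshold=0.5)
        assert len(hits) == 1


class TestBiasCorrection:
    def test_flat_bias_reduces_to_local_mean_subtraction(self):
        rng = np.random.default_rng(1)
        cuts = SignalTrack("chr1", 0, rng.poisson(5.0, 600).astype(float))
        bias = SignalTrack("chr1", 0, np.ones(600))
        corrected = correct_bias(cuts, bias)
        from scipy.ndimage import uniform_filter1d

        expected = cuts.values - uniform_filter1d(cuts.values, 200, mode="nearest")
        assert np.allclose(corrected.values, expected)

    def test_cuts_proportional_to_bias_cancel_exactly(self):
        x = np.arange(800)
        bias = SignalTrack("chr1", 0, np.exp(0.3 * np.sin(2 * np.pi * x / 7)))
        cuts = SignalTrack("chr1", 0, 4.0 * bias.values)
        corrected = correct_bias(cuts, bias)
        assert np.max(np.abs(corrected.values)) < 1e-9 * cuts.values.max()

    def test_depleted_center_goes_negative_under_flat_bias(self):
        vals = np.full(500, 8.0)
        vals[240:260] = 1.0
        corrected = correct_bias(
            SignalTrack("chr1", 0, vals), SignalTrack("chr1", 0, np.ones(500))
        )
        assert corrected.values[245:255].mean() < 0

    def test_nonpositive_bias_rejected(self):
        cuts = SignalTrack("chr1", 0, np.ones(100))
        bias = SignalTrack("chr1", 0, np.concatenate([np.ones(50), np.zeros(50)]))
        with pytest.raises(ValueError, match="positive"):
            correct_bias(cuts, bias)


class TestFootprintScore:
    def test_flat_signal_scores_zero(self):
        sig = SignalTrack("chr1", 0, np.full(400, 3.0))
        site = GenomicInterval("chr1", 190, 210)
        assert footprint_score(sig, site) == pytest.approx(0.0)

    def test_linearity_under_track_scaling(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=400)
        site = GenomicInterval("chr1", 180, 200)
        s1 = footprint_score(SignalTrack("chr1", 0, vals), site)
        s2 = footprint_score(SignalTrack("chr1", 0, 2 * vals), site)
        assert s2 == pytest.approx(2 * s1)

    def test_insufficient_coverage_returns_none(self):
        sig = SignalTrack("chr1", 0, np.ones(100))
        assert footprint_score(sig, GenomicInterval("chr1", 90, 120)) is None

    def test_bound_sites_separate_from_unbound(self):
        """200 simulated sites per state: depleted centers score higher."""
        rng = np.random.default_rng(77)
        width, depth, rate = 10, 0.6, 2.0
        scores = {True: [], False: []}
        for bound in (True, False):
            for _ in range(200):
                lam = np.full(400, rate)
                if bound:
                    lam[195:205] *= 1 - depth
                track = SignalTrack("chr1", 0, rng.poisson(lam).astype(float))
                corrected = correct_bias(
                    track, SignalTrack("chr1", 0, np.ones(400))
                )
                scores[bound].append(
                    footprint_score(corrected, GenomicInterval("chr1", 195, 205))
                )
        assert np.median(scores[True]) > np.median(scores[False])


class TestRestrictToAnchors:
    def test_inside_kept_past_end_dropped(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 1000],
                "end": [110, 1010],
                "motif_id": ["m", "m"],
                "strand": ["+", "+"],
                "score": [1.0, 1.0],
            }
        )
        anchors = [GenomicInterval("chr1", 0, 1000, name="a0")]
        out = restrict_to_anchors(sites, anchors)
        assert len(out) == 1
        assert out.iloc[0]["anchor_id"] == "a0"

    def test_site_spanning_two_anchors_assigned_to_both(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [995],
                "end": [1005],
                "motif_id": ["m"],
                "strand": ["+"],
                "score": [1.0],
            }
        )
        anchors = [
            GenomicInterval("chr1", 0, 1000, name="a0"),
            GenomicInterval("chr1", 1000, 2000, name="a1"),
        ]
        out = restrict_to_anchors(sites, anchors)
        assert sorted(out["anchor_id"]) == ["a0", "a1"]

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(30)
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": rng.integers(0, 100_000, 300),
                "motif_id": "m",
                "strand": "+",
                "score": 1.0,
            }
        )
        sites["end"] = sites["start"] + 10
        anchors = [
            GenomicInterval("chr1", int(s), int(s) + 10_000, name=f"a{k}")
            for k, s in enumerate(rng.integers(0, 100_000, 12))
        ]
        out = restrict_to_anchors(sites, anchors)
        brute = 0
        for row in sites.itertuples():
            iv = GenomicInterval("chr1", row.start, row.end)
            for a in anchors:
                if a.start < iv.end and iv.start < a.end:
                    brute += 1
        assert len(out) == brute


class TestWilcoxon:
    def test_fully_separated_three_vs_three(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        # all 20 arrangements enumerated; both extreme tails
        assert p == pytest.approx(0.1)

    def test_identical_vectors_give_p_one(self):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_by_independent_oracle(self):
        rng = np.random.default_rng(50)
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = wilcoxon_rank_sum(x, y)
            # independent oracle: scipy exact Mann-Whitney U
            p_ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_and_approximate_agree_at_n8(self):
        rng = np.random.default_rng(60)
        diffs = []
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = wilcoxon_rank_sum(x, y, exact_limit=8)
            _, p_approx = wilcoxon_rank_sum(x, y, exact_limit=0)
            diffs.append(abs(p_exact - p_approx))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestDifferentialBinding:
    def _sites(self, anchor_scores):
        rows = []
        for anchor, (xs, ys, cls) in anchor_scores.items():
            for x, y in zip(xs, ys):
                rows.append(
                    {
                        "anchor_id": anchor,
                        "score_AS": x,
                        "score_GFP": y,
                        "class_label": cls,
                    }
                )
        return pd.DataFrame(rows)

    def test_small_groups_reported_untested(self):
        sites = self._sites({"a0": ([1, 2], [3, 4], "c")})
        out = differential_binding(sites)
        assert not out["tested"].iloc[0]
        assert np.isnan(out["p_value"].iloc[0])

    def test_separated_anchor_flagged(self):
        xs = [1.0, 1.1, 1.2, 1.3, 1.4]
        ys = [0.1, 0.2, 0.3, 0.4, 0.5]
        out = differential_binding(self._sites({"a0": (xs, ys, "c")}))
        assert out["p_value"].iloc[0] == pytest.approx(2 / 252)

    def test_by_class_grouping(self):
        sites = self._sites(
            {
                "a0": ([1, 2, 3, 4], [5, 6, 7, 8], "c1"),
            }
        )
        sites2 = sites.copy()
        sites2["class_label"] = "c2"
        both = pd.concat([sites, sites2], ignore_index=True)
        out = differential_binding(both, grouping="by_class")
        assert set(out["class_label"]) == {"c1", "c2"}
        assert len(out) == 2

    def test_planted_gain_anchor_flagged_null_anchor_not(self, default_truth):
        """End-to-end: simulate cuts, correct bias, score planted sites, test."""
        from regulohub.footprints import correct_bias, footprint_score
        from regulohub.synthetic import planted_bias, simulate_atac

        cfg = default_truth.config
        scores = {}
        for cond in ("AS", "GFP"):
            _, tracks = simulate_atac(default_truth, cond)
            per_site = []
            for site in default_truth.motif_sites:
                tr = tracks[site.peak_index]
                bias = planted_bias(cfg, tr.chrom, tr.start, len(tr.values))
                corrected = correct_bias(tr, bias)
                per_site.append(
                    footprint_score(
                        corrected, GenomicInterval(site.chrom, site.start, site.end)
                    )
                )
            scores[cond] = per_site
        rows = []
        for k, site in enumerate(default_truth.motif_sites):
            if site.role in ("gain_anchor", "null_anchor"):
                rows.append(
                    {
                        "anchor_id": site.role,
                        "score_AS": scores["AS"][k],
                        "score_GFP": scores["GFP"][k],
                        "class_label": "x",
                    }
                )
        out = differential_binding(pd.DataFrame(rows)).set_index("anchor_id")
        assert out.loc["gain_anchor", "p_value"] < 0.05
        assert out.loc["null_anchor", "p_value"] >= 0.05
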