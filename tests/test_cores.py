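"""CORE detection (chain clustering vs connected-components oracle) and
CORE-promoter loop annotation."""

import numpy as np
import pandas as pd
import pytest

from regulohub.cores import (
    CORE,
    annotate_core_promoter_loops,
    detect_cores,
    intersect_differential_loops_with_cores,
)
from regulohub.intervals import GenomicInterval, overlaps, promoter_from_tss


def random_peaks(rng, n=500, span=5_000_000):
    starts = np.sort(rng.integers(0, span, size=n))
    widths = rng.integers(100, 900, size=n)
    return [
        GenomicInterval("chr1", int(s), int(s + w), name=f"p{k}")
        for k, (s, w) in enumerate(zip(starts, widths))
    ]


def oracle_cores(peaks, max_gap=20_000, min_length=1_000, min_peaks=2):
    """Brute-force all-pairs gap-graph connected components (networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i, a in enumerate(peaks):
        for j, b in enumerate(peaks):
            if i >= j or a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap < max_gap:
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda k: peaks[k].start)
        start = min(peaks[k].start for k in members)
        end = max(peaks[k].end for k in members)
        if len(members) >= min_peaks and end - start >= min_length:
            out.append((start, end, frozenset(peaks[k].name for k in members)))
    return sorted(out)


class TestDetectCores:
    def test_two_close_peaks_form_one_core(self):
        peaks = [
            GenomicInterval("chr1", 0, 500, name="a"),
            GenomicInterval("chr1", 5_500, 6_000, name="b"),  # 5 Kb gap
        ]
        cores = detect_cores(peaks)
        assert len(cores) == 1
        assert cores[0].n_peaks == 2
        assert (cores[0].interval.start, cores[0].interval.end) == (0, 6_000)

    def test_single_isolated_peak_is_not_a_core(self):
        assert detect_cores([GenomicInterval("chr1", 0, 2000)]) == []

    def test_span_boundary_cases(self):
        # span 999 rejected, span 1000 accepted (>= 1 Kb rule)
        short = [
            GenomicInterval("chr1", 0, 400, name="a"),
            GenomicInterval("chr1", 600, 999, name="b"),
        ]
        exact = [
            GenomicInterval("chr1", 0, 400, name="a"),
            GenomicInterval("chr1", 600, 1000, name="b"),
        ]
        assert detect_cores(short) == []
        assert len(detect_cores(exact)) == 1

    def test_gap_boundary_cases(self):
        # gap of exactly 20 Kb breaks the chain (< rule, strict)
        at_limit = [
            GenomicInterval("chr1", 0, 1000, name="a"),
            GenomicInterval("chr1", 21_000, 22_000, name="b"),
        ]
        below = [
            GenomicInterval("chr1", 0, 1000, name="a"),
            GenomicInterval("chr1", 20_999, 22_000, name="b"),
        ]
        assert detect_cores(at_limit) == []
        assert len(detect_cores(below)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng)
        cores = detect_cores(peaks)
        got = sorted(
            (c.interval.start, c.interval.end, frozenset(c.member_peak_ids))
            for c in cores
        )
        assert got == oracle_cores(peaks)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        peaks = random_peaks(rng, n=200)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        a = [(c.interval.start, c.interval.end) for c in detect_cores(peaks)]
        b = [(c.interval.start, c.interval.end) for c in detect_cores(shuffled)]
        assert a == b

    def test_cores_are_disjoint(self):
        rng = np.random.default_rng(13)
        cores = detect_cores(random_peaks(rng))
        ordered = sorted(cores, key=lambda c: c.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start or not overlaps(
                a.interval, b.interval
            )

    def test_planted_cores_recovered_exactly(self, default_truth):
        from regulohub.synthetic import simulate_atac

        peaks_df, _ = simulate_atac(default_truth, "GFP")
        peaks = [
            GenomicInterval(r.chrom, r.start, r.end, name=r.name)
            for r in peaks_df.itertuples()
        ]
        detected = {frozenset(c.member_peak_ids) for c in detect_cores(peaks)}
        names = default_truth.peaks["name"].tolist()
        planted = [
            frozenset(names[i] for i in g) for g in default_truth.cores_truth
        ]
        assert all(g in detected for g in planted)


def simple_loops(pairs, categories=None):
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "bin_i": [p[0] for p in pairs],
            "bin_j": [p[1] for p in pairs],
        }
    )
    if categories is not None:
        df["category"] = categories
        df["significant"] = True
    return df


class TestCorePromoterLoops:
    BIN = 10_000

    def _core(self, start, end, name="core_000"):
        return CORE(GenomicInterval("chr1", start, end, name=name), 3, ["a", "b", "c"])

    def test_promoter_anchor_to_core_anchor_included_complete(self):
        # promoter wholly inside anchor bin 2; CORE overlapping anchor bin 30
        prom = promoter_from_tss("chr1", 25_000, "+", "loop_promoter", name="g1")
        core = self._core(295_000, 320_000)
        loops = simple_loops([(2, 30)])
        out = annotate_core_promoter_loops(loops, [core], [prom], self.BIN)
        assert len(out) == 1
        assert out[0].promoter_gene_ids == ["g1"]
        assert out[0].core_ids == ["core_000"]
        assert out[0].complete_overlap  # entire promoter inside the anchor

    def test_anchor_contained_in_wide_core_is_complete(self):
        prom = promoter_from_tss("chr1", 25_000, "+", "loop_promoter", name="g1")
        core = self._core(295_000, 320_000)  # 25 Kb-wide CORE containing anchor 30
        loops = simple_loops([(2, 30)])
        out = annotate_core_promoter_loops(loops, [core], [prom], self.BIN)
        assert out[0].complete_overlap

    def test_loop_without_core_excluded(self):
        prom = promoter_from_tss("chr1", 25_000, "+", "loop_promoter", name="g1")
        loops = simple_loops([(2, 30)])
        out = annotate_core_promoter_loops(loops, [], [prom], self.BIN)
        assert out == []

    def test_loop_without_promoter_excluded(self):
        core = self._core(295_000, 300_500)
        loops = simple_loops([(2, 30)])
        assert annotate_core_promoter_loops(loops, [core], [], self.BIN) == []

    def test_planted_core_promoter_loops_recovered(
        self, loop_table, default_truth
    ):
        from regulohub.synthetic import simulate_atac

        peaks_df, _ = simulate_atac(default_truth, "GFP")
        peaks = [
            GenomicInterval(r.chrom, r.start, r.end, name=r.name)
            for r in peaks_df.itertuples()
        ]
        cores = detect_cores(peaks)
        promoters = [
            promoter_from_tss(g.chrom, g.tss, g.strand, "loop_promoter", name=g.gene_id)
            for g in default_truth.genes
        ]
        out = annotate_core_promoter_loops(loop_table, cores, promoters, self.BIN)
        found = {(c.bin_i, c.bin_j) for c in out}
        planted_cp = {
            (lp.bin_i, lp.bin_j)
            for lp in default_truth.loops
            if lp.kind == "core_promoter"
        }
        # every planted CORE-promoter loop that was called significant is annotated
        sig = set(
            zip(
                loop_table.loc[loop_table["significant"], "bin_i"],
                loop_table.loc[loop_table["significant"], "bin_j"],
            )
        )
        recoverable = planted_cp & sig
        assert recoverable  # the default genome plants detectable CP loops
        assert recoverable <= found


class TestDifferentialCoreIntersection:
    BIN = 10_000

    def test_empty_without_cores(self):
        loops = simple_loops([(2, 30)], ["gained"])
        out = intersect_differential_loops_with_cores(loops, [], self.BIN)
        assert (out["n_loops_with_core"] == 0).all()

    def test_loop_with_both_anchors_in_same_core_counted_once(self):
        core = CORE(GenomicInterval("chr1", 15_000, 320_000, name="c0"), 5, [])
        loops = simple_loops([(2, 30)], ["gained"])
        out = intersect_differential_loops_with_cores(loops, [core], self.BIN)
        row = out.set_index("category").loc["gained"]
        assert row["n_loops_with_core"] == 1
        assert row["n_cores_involved"] == 1

    def test_agreement_with_brute_force(self):
        rng = np.random.default_rng(17)
        pairs = [(int(i), int(i + rng.integers(10, 100))) for i in rng.integers(0, 400, 40)]
        cats = rng.choice(["gained", "lost", "static"], size=40).tolist()
        loops = simple_loops(pairs, cats)
        cores = [
            CORE(
                GenomicInterval(
                    "chr1", int(s), int(s + rng.integers(2_000, 40_000)), name=f"c{k}"
                ),
                2,
                [],
            )
            for k, s in enumerate(rng.integers(0, 5_000_000, 15))
        ]
        out = intersect_differential_loops_with_cores(loops, cores, self.BIN)
        for cat in ("gained", "lost"):
            expected = set()
            for (i, j), c in zip(pairs, cats):
                if c != cat:
                    continue
                a1 = GenomicInterval("chr1", i * self.BIN, (i + 1) * self.BIN)
                a2 = GenomicInterval("chr1", j * self.BIN, (j + 1) * self.BIN)
                if any(
                    overlaps(a1, co.interval) or overlaps(a2, co.interval)
                    for co in cores
                ):
                    expected.add((i, j))
            got = out.set_index("category").loc[cat, "n_loops_with_core"]
            assert got == len(expected)
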