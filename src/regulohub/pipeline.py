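"""End-to-end orchestration: simulate -> matrices -> loops -> domains ->
compartments -> COREs -> footprints -> accessibility -> report.

The pipeline runs every stage on a synthetic genome with planted
architecture and writes plain-text intermediates plus a flat key=value
report, including recovery metrics against the planted truth. All default
thresholds are the printed conventions of the analysis this package
reproduces: loop significance q <= 0.05 within 50 Kb - 2 Mb, differential
loops at |log2FC| > 1 and p < 0.05, accessibility at |FC| > 1.5 and
p < 0.05, COREs at >= 2 peaks, >= 1 Kb span, < 20 Kb gaps, and resolutions
of 10 Kb (loops/TADs) and 100 Kb (compartments).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from regulohub import cores as cores_mod
from regulohub import domains, footprints, loops as loops_mod
from regulohub.accessibility import differential_accessibility, map_peaks_to_promoters
from regulohub.hic import coarsen, ice_normalize, merge_replicates, pearson_matrix, observed_expected
from regulohub.intervals import GenomicInterval, promoter_from_tss, write_bed
from regulohub.synthetic import (
    CONDITIONS,
    SimulationConfig,
    build_truth,
    default_motifs,
    simulate_atac,
    simulate_contacts,
    simulate_peak_counts,
)

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("regulohub")


@dataclass
class RunConfig:
    """Thresholds and simulation block for a full pipeline run."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    q_loop: float = 0.05
    log2fc_loop: float = 1.0
    p_loop: float = 0.05
    dmin_bp: int = 50_000
    dmax_bp: int = 2_000_000
    fc_acc: float = 1.5
    p_acc: float = 0.05
    core_max_gap_bp: int = 20_000
    core_min_length_bp: int = 1_000
    core_min_peaks: int = 2
    loop_resolution_bp: int = 10_000
    compartment_resolution_bp: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", {})
        sim = SimulationConfig(**sim_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=sim, **raw)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the report dict and writes files.

    Report keys cover per-condition loop counts, static/gained/lost counts,
    CORE counts, CORE-promoter loop counts, boundary-distance labels for
    the regulatory-hub anchors, the per-class Wilcoxon table, differential
    accessibility counts, and recovery metrics against the planted truth.
    Identical config and seed reproduce the report byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    sim = cfg.simulate
    report: dict[str, object] = {"seed": sim.seed}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate")
        truth = build_truth(sim)
        chrom = next(iter(sim.chrom_sizes))
        matrices = {
            (cond, rep): simulate_contacts(truth, cond, rep, chrom)
            for cond in CONDITIONS
            for rep in range(1, sim.n_replicates_per_condition + 1)
        }
        logger.info("simulated %d matrices on %s", len(matrices), chrom)

        stage("ice/merge")
        merged = {
            cond: merge_replicates(
                [m for (c, _), m in matrices.items() if c == cond]
            )
            for cond in CONDITIONS
        }
        iced = {cond: ice_normalize(m) for cond, m in merged.items()}
        factor = cfg.compartment_resolution_bp // sim.bin_size_bp
        iced_coarse = {
            cond: ice_normalize(coarsen(m, factor)) for cond, m in merged.items()
        }

        stage("loops")
        loop_table = loops_mod.call_loops(
            matrices,
            conditions=CONDITIONS,
            q_cut=cfg.q_loop,
            min_distance_bp=cfg.dmin_bp,
            max_distance_bp=cfg.dmax_bp,
        )
        loops_mod.write_bedpe(loop_table, outdir / "loops.bedpe", sim.bin_size_bp)
        sig = loop_table.loc[loop_table["significant"]]
        for cond in CONDITIONS:
            report[f"loops.significant.{cond}"] = int(
                (loop_table[f"q_{cond}"] <= cfg.q_loop).sum()
            )
        report["loops.significant.union"] = int(len(sig))
        for cat in ("static", "gained", "lost"):
            report[f"loops.{cat}"] = int((sig["category"] == cat).sum())
        logger.info("significant loops: %d", len(sig))

        stage("tads")
        tads = {cond: domains.call_tads(iced[cond]) for cond in CONDITIONS}
        for cond, tlist in tads.items():
            write_bed(
                [t.interval for t in tlist],
                outdir / f"tads_{cond}.bed",
                extra_columns=[(t.level, f"{t.confidence:.4f}") for t in tlist],
            )
            report[f"tads.retained.{cond}"] = len(tlist)
            report[f"tads.outermost.{cond}"] = sum(t.is_outermost for t in tlist)

        stage("compartments")
        atac = {cond: simulate_atac(truth, cond) for cond in CONDITIONS}
        comp_tracks = {}
        for cond in CONDITIONS:
            oe, _ = observed_expected(iced_coarse[cond])
            pear = pearson_matrix(oe)
            peak_ivs = [
                GenomicInterval(r.chrom, r.start, r.end, name=r.name)
                for r in atac[cond][0].itertuples()
            ]
            comp_tracks[cond] = domains.call_compartments(
                pear, peak_ivs, chrom, cfg.compartment_resolution_bp
            )
            comp_tracks[cond].to_frame().to_csv(
                outdir / f"compartments_{cond}.tsv", sep="\t", index=False
            )
            labels = comp_tracks[cond].labels
            report[f"compartments.A.{cond}"] = int((labels == "A").sum())
            report[f"compartments.B.{cond}"] = int((labels == "B").sum())

        stage("localize")
        loc = domains.localize_loops(sig, tads["GFP"], sim.bin_size_bp)
        for key in ("intra", "inter", "unassigned"):
            report[f"loops.localization.{key}"] = int(
                (loc["localization"] == key).sum()
            )
        report["loops.inter.non_adjacent"] = int(
            (loc["tad_adjacency"] == "non-adjacent").sum()
        )

        stage("cores")
        core_sets = {}
        for cond in CONDITIONS:
            peak_ivs = [
                GenomicInterval(r.chrom, r.start, r.end, name=r.name)
                for r in atac[cond][0].itertuples()
            ]
            core_sets[cond] = cores_mod.detect_cores(
                peak_ivs,
                max_gap_bp=cfg.core_max_gap_bp,
                min_length_bp=cfg.core_min_length_bp,
                min_peaks=cfg.core_min_peaks,
            )
            write_bed(
                [c.interval for c in core_sets[cond]],
                outdir / f"cores_{cond}.bed",
                extra_columns=[(c.n_peaks,) for c in core_sets[cond]],
            )
            report[f"cores.count.{cond}"] = len(core_sets[cond])

        stage("core_promoter_loops")
        promoters = [
            promoter_from_tss(g.chrom, g.tss, g.strand, "loop_promoter", name=g.gene_id)
            for g in truth.genes
        ]
        cp_loops = cores_mod.annotate_core_promoter_loops(
            sig, core_sets["GFP"], promoters, sim.bin_size_bp
        )
        report["core_promoter_loops.count"] = len(cp_loops)
        report["core_promoter_loops.complete_overlap"] = sum(
            c.complete_overlap for c in cp_loops
        )
        diff_core = cores_mod.intersect_differential_loops_with_cores(
            sig, core_sets["GFP"], sim.bin_size_bp
        )
        diff_core.to_csv(outdir / "differential_loops_cores.tsv", sep="\t", index=False)
        for row in diff_core.itertuples():
            report[f"cores.diff_loops.{row.category}"] = int(row.n_loops_with_core)

        stage("footprints")
        motifs = default_motifs()
        class_of = {m.motif_id: m.class_label for m in motifs}
        regions = [
            (chrom, w_start, seq)
            for _, (w_start, seq) in sorted(truth.peak_sequences.items())
        ]
        sites = footprints.scan_motifs(regions, motifs)
        anchor_bins = sorted(
            set(sig["bin_i"]).union(sig["bin_j"])
        )
        anchors = [
            GenomicInterval(
                chrom, b * sim.bin_size_bp, (b + 1) * sim.bin_size_bp, name=f"anchor_{b}"
            )
            for b in anchor_bins
        ]
        sites = footprints.restrict_to_anchors(sites, anchors)
        from regulohub.synthetic import planted_bias

        score_cols = {}
        for cond in CONDITIONS:
            tracks = atac[cond][1]
            corrected = {}
            for idx, tr in tracks.items():
                bias = planted_bias(sim, tr.chrom, tr.start, len(tr.values))
                corrected[idx] = footprints.correct_bias(tr, bias)
            scores = []
            for row in sites.itertuples():
                site_iv = GenomicInterval(row.chrom, row.start, row.end)
                val = None
                for tr in corrected.values():
                    val = footprints.footprint_score(tr, site_iv)
                    if val is not None:
                        break
                scores.append(np.nan if val is None else val)
            score_cols[f"score_{cond}"] = scores
        for col, vals in score_cols.items():
            sites[col] = vals
        sites["class_label"] = sites["motif_id"].map(class_of)
        sites.to_csv(outdir / "footprint_sites.tsv", sep="\t", index=False)
        report["footprints.sites_at_anchors"] = int(len(sites))

        stage("diffbind")
        db_all = footprints.differential_binding(sites, grouping="all")
        db_class = footprints.differential_binding(sites, grouping="by_class")
        db_all.to_csv(outdir / "diffbind_anchors.tsv", sep="\t", index=False)
        db_class.to_csv(outdir / "diffbind_classes.tsv", sep="\t", index=False)
        tested = db_all.loc[db_all["tested"]]
        report["diffbind.anchors_tested"] = int(len(tested))
        report["diffbind.anchors_p05"] = int((tested["p_value"] < 0.05).sum())

        stage("boundary_ranking")
        gfp_boundaries = domains.boundary_positions_bp(tads["GFP"], sim.bin_size_bp)
        hub_anchors = [
            GenomicInterval(
                chrom,
                lp.bin_j * sim.bin_size_bp,
                (lp.bin_j + 1) * sim.bin_size_bp,
                name=f"hub_anchor_{k}",
            )
            for k, lp in enumerate(
                [l for l in truth.loops if l.kind == "core_promoter"][:3]
            )
        ]
        if hub_anchors and len(gfp_boundaries):
            ranking = domains.rank_anchor_boundary_distance(hub_anchors, gfp_boundaries)
            ranking.to_csv(outdir / "hub_anchor_ranking.tsv", sep="\t", index=False)
            for row in ranking.itertuples():
                report[f"hub.{row.name}.rank"] = row.rank_label

        stage("diffacc")
        counts = simulate_peak_counts(truth)
        acc = differential_accessibility(
            counts, CONDITIONS, fc_cut=cfg.fc_acc, p_cut=cfg.p_acc
        )
        tss_ivs = [
            GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.gene_id)
            for g in truth.genes
        ]
        acc = map_peaks_to_promoters(acc, tss_ivs)
        acc.to_csv(outdir / "differential_accessibility.tsv", sep="\t", index=False)
        report["diffacc.significant"] = int(acc["significant"].sum())
        report["diffacc.more_accessible"] = int(
            (acc["significant"] & (acc["log2fc"] > 0)).sum()
        )
        report["diffacc.less_accessible"] = int(
            (acc["significant"] & (acc["log2fc"] < 0)).sum()
        )

        stage("recovery")
        report.update(_recovery_metrics(truth, loop_table, tads, comp_tracks, core_sets))
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    lines = [f"{k}={_fmt(v)}" for k, v in report.items()]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report


def _recovery_metrics(truth, loop_table, tads, comp_tracks, core_sets) -> dict:
    """Recovery of planted loops, boundaries, compartments, and COREs."""
    out: dict[str, object] = {}
    sig = loop_table.loc[loop_table["significant"]]
    called = set(zip(sig["bin_i"], sig["bin_j"]))
    planted = {(lp.bin_i, lp.bin_j): lp.category for lp in truth.loops}
    if planted:
        recall = sum(1 for p in planted if p in called) / len(planted)
        out["recovery.loop_recall"] = recall
    if len(called):
        false = sum(
            1
            for (i, j) in called
            if not any(abs(i - a) <= 1 and abs(j - b) <= 1 for a, b in planted)
        )
        out["recovery.loop_fdr"] = false / len(called)
    cat_called = dict(zip(zip(sig["bin_i"], sig["bin_j"]), sig["category"]))
    for want in ("gained", "lost"):
        keys = [k for k, c in planted.items() if c == want]
        if keys:
            hit = sum(1 for k in keys if cat_called.get(k) == want)
            out[f"recovery.{want}_recall"] = hit / len(keys)
    swaps = sum(
        1
        for k, c in planted.items()
        if c in ("gained", "lost")
        and cat_called.get(k) in ("gained", "lost")
        and cat_called.get(k) != c
    )
    out["recovery.category_swaps"] = swaps

    planted_bounds = sorted(
        {b for t in truth.tads for b in (t.start_bin, t.end_bin)}
    )
    for cond, tlist in tads.items():
        found = {b for t in tlist for b in (t.start_bin, t.end_bin)}
        if planted_bounds:
            hit = sum(
                1
                for b in planted_bounds
                if any(abs(b - f) <= 1 for f in found)
            )
            out[f"recovery.tad_boundary_recall.{cond}"] = hit / len(planted_bounds)

    chrom = next(iter(truth.config.chrom_sizes))
    planted_labels = truth.compartment_labels[chrom]
    for cond, track in comp_tracks.items():
        mask = track.labels != "masked"
        n = min(len(planted_labels), len(track.labels))
        agree = np.mean(
            planted_labels[:n][mask[:n]] == track.labels[:n][mask[:n]]
        )
        out[f"recovery.compartment_agreement.{cond}"] = float(agree)

    peak_names = truth.peaks["name"].tolist()
    planted_cores = [
        frozenset(peak_names[i] for i in group) for group in truth.cores_truth
    ]
    for cond, clist in core_sets.items():
        detected = {frozenset(c.member_peak_ids) for c in clist}
        if planted_cores:
            out[f"recovery.core_exact.{cond}"] = sum(
                1 for g in planted_cores if g in detected
            ) / len(planted_cores)
    return out
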