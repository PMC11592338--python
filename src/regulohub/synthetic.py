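"""Synthetic genome generator with planted regulatory architecture.

Builds a small genome carrying every feature the pipeline detects —
checkerboard A/B compartments (at 100 Kb granularity), nested TADs,
condition-specific chromatin loops, genes with promoters, ATAC peaks grouped
into clusters of cis-regulatory elements (COREs), and motif occurrences with
transcription-factor footprints — then simulates binned Hi-C contact counts
and per-base ATAC insertion tracks for two conditions ("AS": antisense
overexpression, "GFP": control) with replicates.

Contact model
-------------
For a bin pair (i, j) at distance d bins (d > 0) the expected count is

    mu_ij = depth_scale * d**(-alpha)
            * tad_boost**(number of planted TADs containing both bins)
            * compartment_factor**[same planted compartment]
            * loop_strength**[planted loop at (i, j), per condition]

with depth_scale set so the expected total over all bin pairs equals the
configured sequencing depth. The diagonal (d = 0) uses a separate high rate
and is never part of loop calling. Realized counts are negative-binomial
with mean mu and variance mu + mu^2 / nb_dispersion; replicates are
independent draws. Gained loops carry the loop multiplier in AS only, lost
loops in GFP only, static loops in both.

ATAC model
----------
Insertion counts are Poisson per base: a low background rate, an elevated
rate inside peaks, and at "bound" motif sites a central depletion of the
motif-width window by factor (1 - footprint depth). A known periodic
multiplicative Tn5-like bias is applied to every track so that bias
correction has an exact oracle. Sequence is generated for peak windows with
the motif consensus implanted at each planted site.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from regulohub.hic import SparseContactMatrix, write_triplet
from regulohub.intervals import GenomicInterval
from regulohub.signal import SignalTrack, write_bedgraph_tracks

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "PlantedArchitecture",
    "build_truth",
    "simulate_contacts",
    "expected_contacts",
    "simulate_atac",
    "simulate_peak_counts",
    "write_simulation",
]

CONDITIONS = ("AS", "GFP")

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: name, class, family, consensus for the planted motif repertoire
_DEFAULT_MOTIFS = [
    ("MS0001.1", "JUNX", "Basic leucine zipper factors (bZIP)", "Jun-related", "TGACTCAT"),
    ("MS0002.1", "KLFX", "C2H2 zinc finger factors", "Krueppel-related", "GGGGCGGGGC"),
    ("MS0003.1", "FOXX", "Fork head/winged helix factors", "FOX", "TGTTTACTTA"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted genome and of both simulators.

    Defaults describe the package's standard test genome: one 20 Mb
    chromosome binned at 10 Kb, two replicates per condition, 3e6 expected
    cis contacts per replicate (a realistic slice of a ~300 M read
    experiment), and 50 planted loops split 20 static / 10 gained / 20 lost.
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 20_000_000})
    bin_size_bp: int = 10_000
    compartment_bin_bp: int = 100_000
    seed: int = 1
    n_replicates_per_condition: int = 2
    decay_exponent: float = 1.0
    sequencing_depth: float = 5e6
    nb_dispersion: float = 10.0
    tad_boost: float = 1.35
    loop_strength: float = 10.0
    compartment_factor: float = 1.3
    footprint_depth: float = 0.6
    diagonal_factor: float = 2.0

    # architecture sizes
    n_tads: int = 20
    n_loops_static: int = 20
    n_loops_gained: int = 10
    n_loops_lost: int = 20
    n_genes: int = 60
    n_peaks: int = 120
    n_extra_cores: int = 3
    n_core_promoter_loops: int = 5

    # ATAC rates (per bp per sample)
    atac_background_rate: float = 0.05
    atac_peak_rate: float = 2.0
    bias_amplitude: float = 0.3
    bias_period_bp: int = 7
    peak_flank_bp: int = 200

    # accessibility counts
    peak_count_mean: float = 200.0
    accessibility_fold: float = 3.0
    n_peaks_more_accessible: int = 10
    n_peaks_less_accessible: int = 15

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        if self.bin_size_bp < 1000:
            raise ValueError("bin_size_bp must be >= 1000")
        for chrom, size in self.chrom_sizes.items():
            if size < 10 * self.bin_size_bp:
                raise ValueError(
                    f"chromosome {chrom} shorter than 10 bins; cannot host a TAD"
                )
        for name in ("tad_boost", "loop_strength", "compartment_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.footprint_depth < 1):
            raise ValueError("footprint_depth must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def n_loops(self) -> int:
        return self.n_loops_static + self.n_loops_gained + self.n_loops_lost

    def null(self) -> "SimulationConfig":
        """A loop-free, TAD-free, compartment-free copy (background only)."""
        return replace(
            self,
            n_tads=0,
            n_loops_static=0,
            n_loops_gained=0,
            n_loops_lost=0,
            n_core_promoter_loops=0,
            compartment_factor=1.0,
        )


@dataclass
class PlantedTad:
    chrom: str
    start_bin: int
    end_bin: int  # exclusive
    nested: bool  # True for inner (level-2) domains

    @property
    def boundaries(self) -> tuple[int, int]:
        return (self.start_bin, self.end_bin)


@dataclass
class PlantedLoop:
    chrom: str
    bin_i: int
    bin_j: int
    category: str  # static | gained | lost
    kind: str = "plain"  # plain | core_promoter

    def strength_in(self, condition: str, loop_strength: float) -> float:
        if self.category == "static":
            return loop_strength
        if self.category == "gained":
            return loop_strength if condition == "AS" else 1.0
        if self.category == "lost":
            return loop_strength if condition == "GFP" else 1.0
        raise ValueError(f"unknown category {self.category}")


@dataclass
class PlantedGene:
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass
class PlantedMotifSite:
    chrom: str
    start: int
    end: int
    motif_id: str
    strand: str
    peak_index: int
    bound: bool
    depth_as: float
    depth_gfp: float
    role: str  # gain_anchor | null_anchor | background


@dataclass
class PlantedArchitecture:
    """Ground truth for recovery tests and input to both simulators."""

    config: SimulationConfig
    compartment_labels: dict  # chrom -> array of 'A'/'B' per 100 Kb bin
    tads: list  # list[PlantedTad]
    loops: list  # list[PlantedLoop]
    genes: list  # list[PlantedGene]
    peaks: pd.DataFrame  # chrom, start, end, name
    cores_truth: list  # list of lists of peak indices
    motif_sites: list  # list[PlantedMotifSite]
    peak_effects: np.ndarray  # per-peak AS/GFP accessibility multiplier
    peak_sequences: dict  # peak index -> (window_start, sequence str)

    def n_bins(self, chrom: str) -> int:
        return -(-self.config.chrom_sizes[chrom] // self.config.bin_size_bp)

    def compartment_labels_fine(self, chrom: str) -> np.ndarray:
        """Per-(bin_size) labels expanded from the 100 Kb compartment grid."""
        reps = self.config.compartment_bin_bp // self.config.bin_size_bp
        fine = np.repeat(self.compartment_labels[chrom], reps)
        return fine[: self.n_bins(chrom)]

    def loop_bins(self, chrom: str) -> set:
        return {
            (lp.bin_i, lp.bin_j) for lp in self.loops if lp.chrom == chrom
        }


# ---------------------------------------------------------------------------
# truth construction


def _place_compartments(rng, n_cbins: int) -> np.ndarray:
    labels = []
    lab = "A" if rng.random() < 0.5 else "B"
    while len(labels) < n_cbins:
        block = int(rng.integers(3, 11))
        labels.extend([lab] * block)
        lab = "B" if lab == "A" else "A"
    return np.array(labels[:n_cbins])


def _place_tads(rng, chrom: str, n_bins: int, n_tads: int) -> list:
    """Plant a contiguous chain of outer TADs (domains tile real genomes
    nearly back-to-back, which is what makes insulation boundaries sharp);
    every other outer TAD nests one inner domain."""
    tads: list[PlantedTad] = []
    pos = 6  # clear of the chromosome edge so the smallest window scores it
    k = 0
    while k < n_tads and pos + 40 <= n_bins - 3:
        size = int(rng.integers(40, min(101, n_bins - 3 - pos + 1)))
        tads.append(PlantedTad(chrom, pos, pos + size, nested=False))
        if k % 2 == 0 and size >= 30:  # nest an inner domain in every other TAD
            inner_size = int(rng.integers(size // 3, size // 2))
            off = int(rng.integers(3, size - inner_size - 2))
            tads.append(
                PlantedTad(chrom, pos + off, pos + off + inner_size, nested=True)
            )
        pos += size
        k += 1
    return tads


def _place_loops(rng, chrom: str, n_bins: int, cfg: SimulationConfig) -> list:
    categories = (
        ["static"] * cfg.n_loops_static
        + ["gained"] * cfg.n_loops_gained
        + ["lost"] * cfg.n_loops_lost
    )
    loops: list[PlantedLoop] = []
    used: set = set()
    n_cp = min(cfg.n_core_promoter_loops, cfg.n_loops_static)
    for idx, cat in enumerate(categories):
        kind = "core_promoter" if cat == "static" and idx < n_cp else "plain"
        for _ in range(1000):
            lo = 30 if kind == "core_promoter" else 6
            d = int(rng.integers(lo, 151 if kind == "core_promoter" else 196))
            i = int(rng.integers(2, n_bins - d - 2))
            j = i + d
            if (i, j) in used or any(abs(i - a) + abs(j - b) < 3 for a, b in used):
                continue
            used.add((i, j))
            loops.append(PlantedLoop(chrom, i, j, cat, kind))
            break
        else:  # pragma: no cover - only on absurdly dense configs
            raise RuntimeError("could not place loop without collision")
    return loops


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_truth(config: SimulationConfig) -> PlantedArchitecture:
    """Plant the full architecture; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0xA11CE])

    chrom = next(iter(config.chrom_sizes))  # architecture lives on the first chrom
    length = config.chrom_sizes[chrom]
    n_bins = -(-length // config.bin_size_bp)
    n_cbins = -(-length // config.compartment_bin_bp)

    compartments = {c: _place_compartments(rng, -(-sz // config.compartment_bin_bp))
                    for c, sz in config.chrom_sizes.items()}
    if config.compartment_factor == 1.0:
        pass  # labels still planted; they simply have no contact effect
    tads = _place_tads(rng, chrom, n_bins, config.n_tads) if config.n_tads else []
    loops = _place_loops(rng, chrom, n_bins, config)

    bs = config.bin_size_bp
    cp_loops = [lp for lp in loops if lp.kind == "core_promoter"]

    def mostly_open(pos: int) -> bool:
        """Accessible features live mainly in the A compartment."""
        label = compartments[chrom][min(pos // config.compartment_bin_bp, n_cbins - 1)]
        return label == "A" or rng.random() < 0.1

    # genes: one TSS inside each core-promoter loop's first anchor, rest random
    genes: list[PlantedGene] = []
    for g, lp in enumerate(cp_loops):
        tss = lp.bin_i * bs + bs // 2
        genes.append(PlantedGene(f"gene_cp{g:03d}", chrom, tss, "+" if g % 2 == 0 else "-"))
    while len(genes) < config.n_genes:
        tss = int(rng.integers(10_000, length - 10_000))
        if not mostly_open(tss):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(PlantedGene(f"gene_{len(genes):04d}", chrom, tss, strand))

    # peaks: CORE chains inside core-promoter anchors, extra COREs, promoter
    # peaks, isolated peaks -- all pairwise >= 25 Kb apart across groups
    peak_rows: list[tuple[str, int, int]] = []
    core_groups: list[list[int]] = []

    def far_from_existing(s: int, e: int, min_gap: int = 25_000) -> bool:
        return all(
            not (s - min_gap < pe and ps < e + min_gap) for _, ps, pe in peak_rows
        )

    for lp in cp_loops:
        base = lp.bin_j * bs + 300
        group = []
        pos = base
        for _ in range(5):  # 5 peaks: an exact 5v5 rank-sum test can reach p<0.01
            w = int(rng.integers(380, 440))
            group.append(len(peak_rows))
            peak_rows.append((chrom, pos, pos + w))
            pos += w + int(rng.integers(1500, 1750))
        core_groups.append(group)

    for _ in range(config.n_extra_cores):
        for _ in range(1000):
            start = int(rng.integers(50_000, length - 120_000))
            if not mostly_open(start):
                continue
            n_members = int(rng.integers(3, 6))
            widths = rng.integers(300, 800, size=n_members)
            gaps = rng.integers(4_000, 16_000, size=n_members - 1)
            span = int(widths.sum() + gaps.sum())
            if far_from_existing(start, start + span):
                group = []
                pos = start
                for k in range(n_members):
                    group.append(len(peak_rows))
                    peak_rows.append((chrom, pos, pos + int(widths[k])))
                    pos += int(widths[k]) + (int(gaps[k]) if k < n_members - 1 else 0)
                core_groups.append(group)
                break

    for gene in genes[len(cp_loops) : len(cp_loops) + 25]:
        s, e = gene.tss - 300, gene.tss + 200
        if s > 0 and far_from_existing(s, e):
            peak_rows.append((chrom, s, e))

    while len(peak_rows) < config.n_peaks:
        s = int(rng.integers(30_000, length - 30_000))
        w = int(rng.integers(300, 800))
        if mostly_open(s) and far_from_existing(s, s + w):
            peak_rows.append((chrom, s, s + w))

    order = np.argsort([s for _, s, _ in peak_rows], kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    peak_rows = [peak_rows[i] for i in order]
    core_groups = [sorted(remap[i] for i in g) for g in core_groups]
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    peaks["name"] = [f"peak_{k:04d}" for k in range(len(peaks))]

    # motif sites: differential binding planted at the first CP anchor
    motif_sites: list[PlantedMotifSite] = []
    anchor_roles: dict[int, str] = {}
    if cp_loops:
        anchor_roles[cp_loops[0].bin_j] = "gain_anchor"
    if len(cp_loops) > 1:
        anchor_roles[cp_loops[1].bin_j] = "null_anchor"
    for idx, row in peaks.iterrows():
        anchor_bin = row["start"] // bs
        role = anchor_roles.get(anchor_bin, "background")
        want_site = role != "background" or rng.random() < 0.5
        if not want_site:
            continue
        motif_id, _, _, _, consensus = _DEFAULT_MOTIFS[idx % len(_DEFAULT_MOTIFS)]
        width = len(consensus)
        if row["end"] - row["start"] < width + 40:
            continue
        center = (row["start"] + row["end"]) // 2
        s = center - width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if role == "gain_anchor":  # bound after AS overexpression, unbound in control
            bound, d_as, d_gfp = True, config.footprint_depth, 0.0
        elif role == "null_anchor":
            bound, d_as, d_gfp = True, config.footprint_depth, config.footprint_depth
        else:
            bound = bool(rng.random() < 0.6)
            depth = config.footprint_depth if bound else 0.0
            d_as = d_gfp = depth
        motif_sites.append(
            PlantedMotifSite(
                chrom, s, s + width, motif_id, strand, int(idx), bound, d_as, d_gfp, role
            )
        )

    # accessibility effects (AS relative to GFP); CORE members stay constant so
    # accessibility changes never confound the footprint comparison
    effects = np.ones(len(peaks))
    core_members = {i for g in core_groups for i in g}
    candidates = np.array(
        [i for i in range(len(peaks)) if i not in core_members], dtype=int
    )
    n_diff = config.n_peaks_more_accessible + config.n_peaks_less_accessible
    if n_diff and len(candidates):
        chosen = rng.choice(candidates, size=min(n_diff, len(candidates)), replace=False)
        effects[chosen[: config.n_peaks_more_accessible]] = config.accessibility_fold
        effects[chosen[config.n_peaks_more_accessible :]] = 1 / config.accessibility_fold

    # sequence for each peak window with motif consensus implanted
    flank = config.peak_flank_bp
    sequences: dict[int, tuple[int, str]] = {}
    sites_by_peak: dict[int, list[PlantedMotifSite]] = {}
    for site in motif_sites:
        sites_by_peak.setdefault(site.peak_index, []).append(site)
    for idx, row in peaks.iterrows():
        w_start = max(0, row["start"] - flank)
        seq = list(_random_seq(rng, row["end"] + flank - w_start))
        for site in sites_by_peak.get(int(idx), []):
            consensus = next(m[4] for m in _DEFAULT_MOTIFS if m[0] == site.motif_id)
            planted = consensus if site.strand == "+" else _revcomp(consensus)
            off = site.start - w_start
            seq[off : off + len(planted)] = list(planted)
        sequences[int(idx)] = (int(w_start), "".join(seq))

    return PlantedArchitecture(
        config=config,
        compartment_labels=compartments,
        tads=tads,
        loops=loops,
        genes=genes,
        peaks=peaks,
        cores_truth=core_groups,
        motif_sites=motif_sites,
        peak_effects=effects,
        peak_sequences=sequences,
    )


# ---------------------------------------------------------------------------
# Hi-C simulation


def expected_contacts(
    truth: PlantedArchitecture, condition: str, chrom: str | None = None
) -> np.ndarray:
    """Dense matrix of expected counts mu_ij for one condition replicate."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    cfg = truth.config
    if chrom is None:
        chrom = next(iter(cfg.chrom_sizes))
    n = truth.n_bins(chrom)

    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        weight = np.where(d > 0, d ** (-cfg.decay_exponent), cfg.diagonal_factor)

    logm = np.zeros((n, n))
    for tad in truth.tads:
        if tad.chrom == chrom:
            s, e = tad.start_bin, tad.end_bin
            logm[s:e, s:e] += np.log(cfg.tad_boost)
    fine = truth.compartment_labels_fine(chrom)
    same_comp = fine[:, None] == fine[None, :]
    logm += np.where(same_comp, np.log(cfg.compartment_factor), 0.0)
    base = weight * np.exp(logm)

    # depth_scale is anchored to the control (GFP) condition's total weight
    # so condition-specific loop multipliers translate into exact expected
    # AS/GFP count ratios rather than being renormalized away
    delta = {c: 0.0 for c in CONDITIONS}
    for lp in truth.loops:
        if lp.chrom == chrom:
            for c in CONDITIONS:
                s = lp.strength_in(c, cfg.loop_strength)
                delta[c] += (s - 1.0) * base[lp.bin_i, lp.bin_j]
    total_ref = np.triu(base).sum() + delta["GFP"]

    out = base.copy()
    for lp in truth.loops:
        if lp.chrom == chrom:
            s = lp.strength_in(condition, cfg.loop_strength)
            out[lp.bin_i, lp.bin_j] *= s
            out[lp.bin_j, lp.bin_i] *= s
    return out * (cfg.sequencing_depth / total_ref)


def simulate_contacts(
    truth: PlantedArchitecture,
    condition: str,
    replicate: int,
    chrom: str | None = None,
) -> SparseContactMatrix:
    """Draw one replicate's negative-binomial contact matrix."""
    cfg = truth.config
    if chrom is None:
        chrom = next(iter(cfg.chrom_sizes))
    mu = expected_contacts(truth, condition, chrom)
    n = mu.shape[0]
    rng = np.random.default_rng(
        [cfg.seed, CONDITIONS.index(condition), replicate, 0xC0FFEE]
    )
    iu, ju = np.triu_indices(n)
    m = mu[iu, ju]
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + m))
    keep = counts > 0
    return SparseContactMatrix(
        chrom,
        cfg.bin_size_bp,
        n,
        iu[keep],
        ju[keep],
        counts[keep].astype(float),
        chrom_length=cfg.chrom_sizes[chrom],
    )


# ---------------------------------------------------------------------------
# ATAC simulation


def planted_bias(cfg: SimulationConfig, chrom: str, start: int, length: int) -> SignalTrack:
    """The known periodic multiplicative Tn5-like insertion bias."""
    x = np.arange(start, start + length)
    values = np.exp(cfg.bias_amplitude * np.sin(2 * np.pi * x / cfg.bias_period_bp))
    return SignalTrack(chrom, start, values, name="bias")


def simulate_atac(
    truth: PlantedArchitecture, condition: str
) -> tuple[pd.DataFrame, dict]:
    """Simulate narrowPeak records and per-base cut tracks for one condition.

    Returns (peaks, tracks): ``peaks`` is a narrowPeak DataFrame; ``tracks``
    maps peak index -> SignalTrack of Poisson insertion counts over the peak
    window (peak +/- flank), with planted footprint depletion and bias.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if len(truth.peaks) == 0:
        raise ValueError("truth contains no peaks")
    cfg = truth.config
    rng = np.random.default_rng(
        [cfg.seed, CONDITIONS.index(condition), 0xA7AC]
    )
    sites_by_peak: dict[int, list[PlantedMotifSite]] = {}
    for site in truth.motif_sites:
        sites_by_peak.setdefault(site.peak_index, []).append(site)

    tracks: dict[int, SignalTrack] = {}
    signal_values = []
    for idx, row in truth.peaks.iterrows():
        idx = int(idx)
        w_start = max(0, int(row["start"]) - cfg.peak_flank_bp)
        w_end = int(row["end"]) + cfg.peak_flank_bp
        x = np.arange(w_start, w_end)
        rate = np.full(len(x), cfg.atac_background_rate)
        in_peak = (x >= row["start"]) & (x < row["end"])
        peak_rate = cfg.atac_peak_rate
        if condition == "AS":
            peak_rate = peak_rate * truth.peak_effects[idx]
        rate[in_peak] = peak_rate
        for site in sites_by_peak.get(idx, []):
            depth = site.depth_as if condition == "AS" else site.depth_gfp
            if depth > 0:
                center = (x >= site.start) & (x < site.end)
                rate[center] *= 1.0 - depth
        bias = planted_bias(cfg, row["chrom"], w_start, len(x))
        counts = rng.poisson(rate * bias.values)
        tracks[idx] = SignalTrack(row["chrom"], w_start, counts.astype(float), row["name"])
        signal_values.append(counts[in_peak].mean())

    peaks = truth.peaks.copy()
    peaks["score"] = 0
    peaks["strand"] = "."
    peaks["signalValue"] = np.round(signal_values, 4)
    peaks["pValue"] = -1.0
    peaks["qValue"] = -1.0
    peaks["summit"] = ((peaks["end"] - peaks["start"]) // 2).astype(int)
    return peaks, tracks


def simulate_peak_counts(truth: PlantedArchitecture) -> pd.DataFrame:
    """NB read counts per peak per (condition, replicate) for accessibility.

    Columns ``<cond>_rep<k>``; AS means are the GFP means times the planted
    per-peak effect.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 0xACC])
    widths = (truth.peaks["end"] - truth.peaks["start"]).to_numpy()
    base_mu = cfg.peak_count_mean * widths / widths.mean()
    out = truth.peaks[["chrom", "start", "end", "name"]].copy()
    theta = cfg.nb_dispersion
    for cond in CONDITIONS:
        mu = base_mu * (truth.peak_effects if cond == "AS" else 1.0)
        for rep in range(1, cfg.n_replicates_per_condition + 1):
            out[f"{cond}_rep{rep}"] = rng.negative_binomial(
                theta, theta / (theta + mu)
            )
    return out


# ---------------------------------------------------------------------------
# fixture writing


def _motif_pfms(rng_seed: int = 0) -> list:
    """PFMs for the planted motifs: 85 counts to the consensus base, 5 each
    to the rest (columns sum to 100)."""
    from regulohub.footprints import MotifModel

    models = []
    for motif_id, name, cls, fam, consensus in _DEFAULT_MOTIFS:
        pfm = np.full((4, len(consensus)), 5.0)
        for pos, base in enumerate(consensus):
            pfm["ACGT".index(base), pos] = 85.0
        models.append(MotifModel(motif_id, name, cls, fam, pfm))
    return models


def default_motifs() -> list:
    """The planted motif models (JASPAR-style PFMs with class/family)."""
    return _motif_pfms()


def write_simulation(config: SimulationConfig, outdir: str | Path) -> PlantedArchitecture:
    """Generate truth + all per-condition fixtures as text files under outdir.

    Writes HiC-Pro triplet/bed matrices per condition x replicate, narrowPeak
    and cut/bias bedGraphs per condition, TSS BED, peak-count table, JASPAR
    PFMs, peak-window FASTA, and a flat key=value truth manifest.
    """
    from regulohub.footprints import write_jaspar_pfm

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    chrom = next(iter(config.chrom_sizes))

    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates_per_condition + 1):
            m = simulate_contacts(truth, cond, rep, chrom)
            write_triplet(
                m,
                outdir / f"hic_{cond}_rep{rep}.matrix",
                outdir / f"hic_{cond}_rep{rep}_abs.bed",
            )
        peaks, tracks = simulate_atac(truth, cond)
        from regulohub.intervals import write_narrowpeak

        write_narrowpeak(peaks, outdir / f"atac_{cond}_peaks.narrowPeak")
        write_bedgraph_tracks(
            [tracks[k] for k in sorted(tracks)], outdir / f"atac_{cond}_cuts.bedGraph"
        )

    bias_tracks = [
        planted_bias(config, chrom, max(0, int(r["start"]) - config.peak_flank_bp),
                     int(r["end"]) + config.peak_flank_bp
                     - max(0, int(r["start"]) - config.peak_flank_bp))
        for _, r in truth.peaks.iterrows()
    ]
    write_bedgraph_tracks(bias_tracks, outdir / "tn5_bias.bedGraph")

    with open(outdir / "tss.bed", "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")

    simulate_peak_counts(truth).to_csv(outdir / "peak_counts.tsv", sep="\t", index=False)
    write_jaspar_pfm(default_motifs(), outdir / "motifs.jaspar")

    with open(outdir / "peak_windows.fa", "w") as fh:
        for idx in sorted(truth.peak_sequences):
            w_start, seq = truth.peak_sequences[idx]
            name = truth.peaks.iloc[idx]["name"]
            fh.write(f">{name} {chrom}:{w_start}-{w_start + len(seq)}\n{seq}\n")

    write_truth_manifest(truth, outdir / "truth.txt")
    return truth


def write_truth_manifest(truth: PlantedArchitecture, path: str | Path) -> None:
    """Flat key=value manifest of every planted object."""
    cfg = truth.config
    buf = io.StringIO()
    buf.write(f"seed={cfg.seed}\nbin_size_bp={cfg.bin_size_bp}\n")
    for chrom, labels in truth.compartment_labels.items():
        buf.write(f"compartments.{chrom}={''.join(labels)}\n")
    for k, t in enumerate(truth.tads):
        buf.write(
            f"tad.{k:03d}={t.chrom}:{t.start_bin}:{t.end_bin}:"
            f"{'inner' if t.nested else 'outer'}\n"
        )
    for k, lp in enumerate(truth.loops):
        buf.write(f"loop.{k:03d}={lp.chrom}:{lp.bin_i}:{lp.bin_j}:{lp.category}:{lp.kind}\n")
    for k, g in enumerate(truth.cores_truth):
        buf.write(f"core.{k:03d}={','.join(str(i) for i in g)}\n")
    for k, s in enumerate(truth.motif_sites):
        buf.write(
            f"motif_site.{k:04d}={s.chrom}:{s.start}:{s.end}:{s.motif_id}:"
            f"{'bound' if s.bound else 'unbound'}:{s.role}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
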