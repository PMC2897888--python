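"""Synthetic ChIP-seq data with planted ground truth.

Generates, from one seed, a random genome carrying planted motif
instances — isolated sites, near-identical "repeat" copies each holding a
tandem site pair at a fixed 21 bp center-to-center spacing (emulating an
LTR-family consensus), and non-repeat tandems with spacing drawn from
18-22 bp — plus repeat/TSS annotations, a per-base conservation track
elevated at the planted sites, and stranded 5'-end tag sets for a
stimulated and an unstimulated condition.

The two conditions differ only in how site occupancy depends on motif
score: stimulated occupancy follows a logistic curve in the integer PWM
score of the planted instance, unstimulated occupancy is a small
score-independent constant.  Each occupied fragment of length L' ~
round(Normal(fragment_length, jitter)) centered near the site emits a +
strand tag at ``center - floor(L'/2)`` and a - strand tag at
``center + ceil(L'/2)``, so the +/- displacement histogram of the output
peaks at the fragment length, and centering by half of it stacks both
tags onto the site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from chipgas.sga import GenomicInterval, TagRecord, sort_key, write_sga
from chipgas.motif import (
    BASES,
    IntegerPwm,
    ProbabilityMatrix,
    probability_to_weight,
)

__all__ = [
    "DEFAULT_MOTIF",
    "SimulationConfig",
    "PlantedSite",
    "SyntheticTruth",
    "generate_truth",
    "generate_training_windows",
    "simulate_tags",
    "write_truth",
    "write_wiggle",
]

# GAS-like generator motif (11 positions, ACGT columns): strong TTC...GAA
# half-sites, a C/G-biased 3-bp spacer (core consensus TTCCCGGAA) and
# weakly biased single-base flanks, mirroring refined STAT1 site models
DEFAULT_MOTIF = ProbabilityMatrix(np.array([
    [0.20, 0.20, 0.20, 0.40],
    [0.05, 0.05, 0.05, 0.85],
    [0.05, 0.05, 0.05, 0.85],
    [0.05, 0.85, 0.05, 0.05],
    [0.10, 0.60, 0.20, 0.10],
    [0.15, 0.35, 0.35, 0.15],
    [0.10, 0.20, 0.60, 0.10],
    [0.05, 0.05, 0.85, 0.05],
    [0.85, 0.05, 0.05, 0.05],
    [0.85, 0.05, 0.05, 0.05],
    [0.40, 0.20, 0.20, 0.20],
]))

_CONDITION_STREAM = {"stimulated": 1, "unstimulated": 2}


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed fixes every draw."""

    seed: int = 0
    chrom: str = "chrS"
    genome_length: int = 400_000
    gc: float = 0.41
    motif: ProbabilityMatrix = field(default_factory=lambda: DEFAULT_MOTIF)

    n_isolated_sites: int = 150
    n_repeat_copies: int = 25          # induced family, tandem inside each copy
    repeat_length: int = 330
    repeat_spacing: int = 21           # tandem center-to-center, family consensus
    repeat_mutation_rate: float = 0.02
    n_control_repeat_copies: int = 25  # uninduced family, no sites
    control_repeat_length: int = 300
    n_nonrepeat_tandems: int = 20
    nonrepeat_spacing_range: tuple[int, int] = (18, 22)
    tandem_site_min_score: int = 32    # sampled tandem halves rejected below this
    n_tss: int = 20
    min_element_gap: int = 800         # between planted element footprints

    fragment_length: int = 140
    fragment_jitter_sd: float = 10.0
    positional_noise_sd: float = 20.0
    depth: int = 100                   # fragment draws per site per condition
    # stimulated occupancy: logistic in PWM score, centered at the score
    # where occupation separates from background in the real data
    stim_occupancy_max: float = 0.9
    stim_occupancy_midpoint: float = 30.0
    stim_occupancy_scale: float = 2.0
    unstim_occupancy: float = 0.005    # flat, near-background
    background_rate: float = 0.0005    # tags per bp per condition
    # The simulated region stands in for a small slice of a genome-scale
    # experiment; induction normalization uses the experiment-scale library
    # totals (nearly equal between conditions, as real background-dominated
    # ChIP-seq libraries are), not the slice sums.
    stim_library_total: int = 15_250_744
    unstim_library_total: int = 13_019_977

    conservation_background: float = 0.07
    conservation_site_level: float = 0.7
    conservation_halfwidth: int = 10

    def stim_rate(self, score: float) -> float:
        z = (score - self.stim_occupancy_midpoint) / self.stim_occupancy_scale
        return self.stim_occupancy_max / (1.0 + math.exp(-z))


@dataclass(frozen=True, slots=True)
class PlantedSite:
    chrom: str
    pos: int          # 1-based center (6th base of the 11-mer)
    strand: str
    score: int        # forward PWM score of the planted instance
    kind: str         # isolated | repeat_tandem | nonrepeat_tandem


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    genome: str
    sites: list[PlantedSite]
    repeat_intervals: list[GenomicInterval]
    tss_positions: list[tuple[str, int]]
    conservation: np.ndarray  # per-base, index 0 = position 1
    pwm: IntegerPwm

    def conservation_track(self, stride: int = 1) -> list[tuple[str, int, float]]:
        """The track as (chrom, pos, value) triples, optionally strided."""
        chrom = self.config.chrom
        return [(chrom, i + 1, float(self.conservation[i]))
                for i in range(0, len(self.conservation), stride)]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=probs).astype(np.int8)


def _score_forward(pwm: IntegerPwm, kmer: np.ndarray) -> int:
    return int(pwm.weights[np.arange(len(kmer)), kmer].sum())


def _sample_kmer(rng: np.random.Generator, matrix: ProbabilityMatrix) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in matrix.probs], dtype=np.int8)


def _revcomp(kmer: np.ndarray) -> np.ndarray:
    return (3 - kmer)[::-1].astype(np.int8)


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Build the genome, planted sites, annotations and conservation track.

    Planted elements are rejection-sampled to non-overlapping positions
    separated by at least ``min_element_gap``; an infeasible density raises
    after bounded retries.  Repeat copies derive from one consensus block
    (max-score tandem at the family spacing) by independent per-base
    mutation, so copies are pairwise nearly identical; site scores are
    recomputed per copy after mutation.
    """
    rng = np.random.default_rng([config.seed, 0])
    G = config.genome_length
    genome = _random_bases(rng, G, config.gc)
    pwm = probability_to_weight(config.motif)
    width = config.motif.width
    center_off = width // 2  # 0-based offset of the center base

    occupied: list[tuple[int, int]] = []  # 0-based [start, end) footprints

    def place(footprint: int) -> int:
        """Return a free 0-based start for a footprint, or raise."""
        for _ in range(20_000):
            start = int(rng.integers(0, G - footprint))
            lo = start - config.min_element_gap
            hi = start + footprint + config.min_element_gap
            if all(e <= lo or s >= hi for s, e in occupied):
                occupied.append((start, start + footprint))
                return start
        raise RuntimeError(
            "could not place all planted elements; genome too small for "
            "the configured element counts and minimum gap"
        )

    sites: list[PlantedSite] = []
    repeat_intervals: list[GenomicInterval] = []

    def plant_kmer(start0: int, kmer: np.ndarray, strand: str) -> int:
        inserted = kmer if strand == "+" else _revcomp(kmer)
        genome[start0:start0 + width] = inserted
        return start0 + center_off + 1  # 1-based center

    # --- induced repeat family: near-identical copies with a tandem inside
    if config.n_repeat_copies > 0:
        consensus = _random_bases(rng, config.repeat_length, config.gc)
        best = np.argmax(config.motif.probs, axis=1).astype(np.int8)
        off1 = config.repeat_length // 2 - config.repeat_spacing  # room for both
        off2 = off1 + config.repeat_spacing
        consensus[off1:off1 + width] = best
        consensus[off2:off2 + width] = best
        for _ in range(config.n_repeat_copies):
            start = place(config.repeat_length)
            copy = consensus.copy()
            mut = rng.random(config.repeat_length) < config.repeat_mutation_rate
            shifts = rng.integers(1, 4, size=int(mut.sum())).astype(np.int8)
            copy[mut] = (copy[mut] + shifts) % 4
            genome[start:start + config.repeat_length] = copy
            repeat_intervals.append(GenomicInterval(
                config.chrom, start + 1, start + config.repeat_length,
                "SynMER41", "LTR"))
            for off in (off1, off2):
                kmer = copy[off:off + width]
                sites.append(PlantedSite(
                    config.chrom, start + off + center_off + 1, "+",
                    _score_forward(pwm, kmer), "repeat_tandem"))

    # --- uninduced control repeat family: sequence blocks without sites
    for _ in range(config.n_control_repeat_copies):
        start = place(config.control_repeat_length)
        repeat_intervals.append(GenomicInterval(
            config.chrom, start + 1, start + config.control_repeat_length,
            "SynAlu", "SINE"))

    # --- non-repeat tandems: high-scoring pairs, spacing drawn from a range
    lo_sp, hi_sp = config.nonrepeat_spacing_range
    for _ in range(config.n_nonrepeat_tandems):
        spacing = int(rng.integers(lo_sp, hi_sp + 1))
        start = place(width + spacing)
        for off in (0, spacing):
            kmer = _sample_kmer(rng, config.motif)
            while _score_forward(pwm, kmer) < config.tandem_site_min_score:
                kmer = _sample_kmer(rng, config.motif)
            pos = plant_kmer(start + off, kmer, "+")
            sites.append(PlantedSite(config.chrom, pos,
                                     "+", _score_forward(pwm, kmer),
                                     "nonrepeat_tandem"))

    # --- isolated sites: unconstrained samples, so scores span the range
    for _ in range(config.n_isolated_sites):
        start = place(width)
        kmer = _sample_kmer(rng, config.motif)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = plant_kmer(start, kmer, strand)
        sites.append(PlantedSite(config.chrom, pos, strand,
                                 _score_forward(pwm, kmer), "isolated"))

    tss = sorted(int(p) for p in rng.integers(1, G + 1, size=config.n_tss))
    tss_positions = [(config.chrom, p) for p in tss]

    conservation = np.full(G, config.conservation_background)
    hw = config.conservation_halfwidth
    for s in sites:
        lo = max(s.pos - 1 - hw, 0)
        hi = min(s.pos + hw, G)
        conservation[lo:hi] = config.conservation_site_level

    genome_str = "".join(BASES[b] for b in genome)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return SyntheticTruth(config, genome_str, sites, repeat_intervals,
                          tss_positions, conservation, pwm)


def generate_training_windows(n: int, width: int = 200, seed: int = 0,
                              matrix: ProbabilityMatrix = DEFAULT_MOTIF,
                              gc: float = 0.5,
                              repeat_fraction: float = 0.0,
                              n_repeat_families: int = 16,
                              repeat_site_min_score: int | None = None,
                              ) -> list[str]:
    """Peak-window-like training sequences with one planted motif each.

    Each window is random background with a single motif instance sampled
    from ``matrix`` at a uniformly random placement — the structure the
    motif trainer's one-occurrence window model assumes.  With
    ``repeat_fraction > 0``, that share of windows are near-identical
    copies (2% per-base mutations) of fixed prototype windows spread over
    ``n_repeat_families`` distinct families, emulating the repeat
    redundancy of an unfiltered peak set (real repeat content spans many
    unrelated families, the largest a few percent of the set).  Prototype
    motif instances are drawn like every other window's, or conditioned on
    a minimum PWM score via ``repeat_site_min_score`` to emulate
    consensus-strength sites.
    """
    rng = np.random.default_rng([seed, 3])
    width_m = matrix.width
    pwm = probability_to_weight(matrix)

    def one_window(kmer: np.ndarray | None = None) -> np.ndarray:
        seq = _random_bases(rng, width, gc)
        if kmer is None:
            kmer = _sample_kmer(rng, matrix)
        s = int(rng.integers(0, width - width_m + 1))
        seq[s:s + width_m] = kmer
        return seq

    n_repeat = int(round(n * repeat_fraction))
    windows = [one_window() for _ in range(n - n_repeat)]
    if n_repeat:
        protos = []
        for _ in range(max(n_repeat_families, 1)):
            kmer = _sample_kmer(rng, matrix)
            if repeat_site_min_score is not None:
                while _score_forward(pwm, kmer) < repeat_site_min_score:
                    kmer = _sample_kmer(rng, matrix)
            protos.append(one_window(kmer))
        for i in range(n_repeat):
            copy = protos[i % len(protos)].copy()
            mut = rng.random(width) < 0.02
            shifts = rng.integers(1, 4, size=int(mut.sum())).astype(np.int8)
            copy[mut] = (copy[mut] + shifts) % 4
            windows.append(copy)
    return ["".join(BASES[b] for b in w) for w in windows]


def simulate_tags(truth: SyntheticTruth, condition: str) -> list[TagRecord]:
    """Draw stranded, uncentered 5'-end tags for one condition.

    Per planted site, ``depth`` fragment draws each succeed with the
    condition's occupancy rate for that site's score; each fragment emits
    one + and one - tag a fragment length apart, straddling the site.
    Background tags are uniform over position and strand.  The output is a
    sorted SGA record set; identical truth and condition give identical
    records.
    """
    if condition not in _CONDITION_STREAM:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_STREAM)}")
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, _CONDITION_STREAM[condition]])
    G = cfg.genome_length
    counts: dict[tuple[int, str], int] = {}

    def add(pos: int, strand: str) -> None:
        pos = min(max(pos, 1), G)
        key = (pos, strand)
        counts[key] = counts.get(key, 0) + 1

    for site in truth.sites:
        rate = (cfg.stim_rate(site.score) if condition == "stimulated"
                else cfg.unstim_occupancy)
        n_frag = int(np.sum(rng.random(cfg.depth) < rate))
        if n_frag == 0:
            continue
        centers = site.pos + np.rint(
            rng.normal(0.0, cfg.positional_noise_sd, size=n_frag)).astype(int)
        lengths = np.rint(
            rng.normal(cfg.fragment_length, cfg.fragment_jitter_sd,
                       size=n_frag)).astype(int)
        lengths = np.clip(lengths, 20, 4 * cfg.fragment_length)
        for c, L in zip(centers, lengths):
            add(int(c) - L // 2, "+")
            add(int(c) + (L + 1) // 2, "-")

    n_bg = int(rng.poisson(cfg.background_rate * G))
    bg_pos = rng.integers(1, G + 1, size=n_bg)
    bg_strand = rng.integers(0, 2, size=n_bg)
    for p, s in zip(bg_pos, bg_strand):
        add(int(p), "+" if s == 0 else "-")

    records = [TagRecord(cfg.chrom, condition, pos, strand, count)
               for (pos, strand), count in counts.items()]
    records.sort(key=sort_key)
    return records


def write_wiggle(track: np.ndarray, chrom: str, path) -> None:
    """Write a per-base track as fixed-step wiggle (start=1, step=1)."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
        for v in track:
            fh.write(f"{v:.4f}\n")


def write_truth(truth: SyntheticTruth, outdir) -> dict[str, Path]:
    """Write genome FASTA, site/annotation tables, conservation and tags.

    Emits ``genome.fa``, ``sites.tsv``, ``repeats.tsv`` (1-based TSV with
    name and class), ``tss.tsv``, ``conservation.wig`` and per-condition
    SGA tag files; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{truth.config.chrom}\n")
        for i in range(0, len(truth.genome), 60):
            fh.write(truth.genome[i:i + 60] + "\n")
    paths["genome"] = fasta

    sites = outdir / "sites.tsv"
    with open(sites, "w") as fh:
        fh.write("chrom\tpos\tstrand\tscore\tkind\n")
        for s in truth.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.score}\t{s.kind}\n")
    paths["sites"] = sites

    repeats = outdir / "repeats.tsv"
    with open(repeats, "w") as fh:
        for iv in truth.repeat_intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{iv.class_label}\n")
    paths["repeats"] = repeats

    tss = outdir / "tss.tsv"
    with open(tss, "w") as fh:
        for chrom, pos in truth.tss_positions:
            fh.write(f"{chrom}\t{pos}\n")
    paths["tss"] = tss

    wig = outdir / "conservation.wig"
    write_wiggle(truth.conservation, truth.config.chrom, wig)
    paths["conservation"] = wig

    totals = outdir / "library_totals.tsv"
    with open(totals, "w") as fh:
        fh.write(f"stimulated\t{truth.config.stim_library_total}\n")
        fh.write(f"unstimulated\t{truth.config.unstim_library_total}\n")
    paths["library_totals"] = totals

    for condition in ("stimulated", "unstimulated"):
        sga = outdir / f"tags_{condition}.sga"
        write_sga(simulate_tags(truth, condition), sga)
        paths[condition] = sga
    return paths
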