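"""Interval-based analyses: repeat-family induction, tandem sites,
compartment enrichment, occupancy classes and conservation profiles.

These operations relate ChIP-seq tag counts and predicted PWM sites to
genome annotations: how strongly binding is induced within each repeat
family between two conditions, whether tandem site pairs at particular
center-to-center spacings carry the induced signal (inside repeats the
planted spacing of the family consensus dominates), whether an element is
over- or under-represented in a genomic compartment relative to its random
expectation, and how a per-base conservation track averages around sites
grouped by their tag occupancy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from chipgas.sga import GenomicInterval, TagRecord
from chipgas.motif import PredictedSite
from chipgas.occupancy import TagIndex, induction_log_ratio, round_half_away
from chipgas.tagproc import feature_correlation

__all__ = [
    "TandemPair",
    "merge_intervals",
    "tags_in_annotations",
    "repeat_induction_table",
    "find_tandem_sites",
    "spacing_induction_histogram",
    "compartment_enrichment",
    "classify_sites",
    "average_profile",
]

logger = logging.getLogger(__name__)

OCCUPATION_CLASS_EDGES = (0, 5, 14)  # class 1: 0, class 2: 1-5, 3: 6-14, 4: >14


@dataclass(frozen=True, slots=True)
class TandemPair:
    """Two predicted sites on one chromosome within tandem distance."""

    chrom: str
    pos1: int
    pos2: int
    mean_score: float
    in_repeat: bool

    @property
    def spacing(self) -> int:
        return self.pos2 - self.pos1

    @property
    def midpoint(self) -> int:
        return (self.pos1 + self.pos2) // 2


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals per chromosome.

    Name and class label of the first interval of each merged run are kept.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    merged_any = False
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur = ivs[0]
        for iv in ivs[1:]:
            if iv.start <= cur.end + 1:
                merged_any = True
                if iv.end > cur.end:
                    cur = GenomicInterval(chrom, cur.start, iv.end,
                                          cur.name, cur.class_label)
            else:
                out.append(cur)
                cur = iv
        out.append(cur)
    if merged_any:
        logger.info("merge_intervals: merged overlapping intervals")
    return out


def tags_in_annotations(
    records: Sequence[TagRecord] | TagIndex,
    intervals: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Per-annotation-name tag totals and genomic coverage.

    A tag at position p belongs to an interval when ``start <= p <= end``.
    Overlapping intervals sharing a name are merged first, so nested
    annotation fragments are not double counted within a name; a tag inside
    two differently named annotations counts once in each.

    Returns a DataFrame indexed by name with columns ``class_label``,
    ``tags`` and ``coverage_bp``.
    """
    index = records if isinstance(records, TagIndex) else TagIndex(records)
    by_name: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_name.setdefault(iv.name, []).append(iv)
    rows = []
    for name in sorted(by_name):
        merged = merge_intervals(by_name[name])
        total = sum(index.count(iv.chrom, iv.start, iv.end) for iv in merged)
        coverage = sum(iv.length for iv in merged)
        class_label = by_name[name][0].class_label
        rows.append((name, class_label, total, coverage))
    return pd.DataFrame(rows, columns=["name", "class_label", "tags",
                                       "coverage_bp"]).set_index("name")


def repeat_induction_table(
    stim_records: Sequence[TagRecord] | TagIndex,
    unstim_records: Sequence[TagRecord] | TagIndex,
    annotations: Sequence[GenomicInterval],
    n_stim: int,
    n_unstim: int,
    min_coverage_kb: float = 100.0,
    tandem_spacing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-family induction of tag counts within repeat annotations.

    One row per family covering more than ``min_coverage_kb`` of sequence,
    ordered by descending induction log-ratio, followed by pooled rows per
    repeat class (named ``Class``) over all members of the class.  The
    ``ln_ratio`` column is the pseudocounted, library-normalized natural
    log ratio rounded to two decimals (the underlying exact value is in
    ``ln_ratio_exact``).  ``tandem_spacing`` optionally annotates each
    family's consensus tandem spacing for display ('21', '+', 'na').
    """
    stim = tags_in_annotations(stim_records, annotations)
    unstim = tags_in_annotations(unstim_records, annotations)

    def make_row(class_label, name, c_stim, c_unstim, coverage_bp):
        lr = induction_log_ratio(int(c_stim), int(c_unstim), n_stim, n_unstim)
        spacing = (tandem_spacing or {}).get(name, "na")
        return {
            "class_label": class_label, "name": name,
            "ln_ratio": round_half_away(lr, 2), "ln_ratio_exact": lr,
            "tags_stim": int(c_stim), "tags_unstim": int(c_unstim),
            "coverage_kb": coverage_bp / 1000.0, "tandem_spacing": spacing,
        }

    family_rows = []
    for name, row in stim.iterrows():
        coverage = row["coverage_bp"]
        if coverage / 1000.0 <= min_coverage_kb:
            continue
        c_un = int(unstim.loc[name, "tags"]) if name in unstim.index else 0
        family_rows.append(make_row(row["class_label"], name, row["tags"],
                                    c_un, coverage))

    class_rows = []
    by_class: dict[str, list[str]] = {}
    for name, row in stim.iterrows():
        if row["class_label"]:
            by_class.setdefault(row["class_label"], []).append(name)
    for class_label in sorted(by_class):
        names = by_class[class_label]
        c_s = int(stim.loc[names, "tags"].sum())
        c_u = int(unstim.loc[[n for n in names if n in unstim.index],
                             "tags"].sum()) if len(unstim) else 0
        cov = int(stim.loc[names, "coverage_bp"].sum())
        class_rows.append(make_row(class_label, "Class", c_s, c_u, cov))

    family_rows.sort(key=lambda r: -r["ln_ratio_exact"])
    class_rows.sort(key=lambda r: -r["ln_ratio_exact"])
    return pd.DataFrame(family_rows + class_rows)


def find_tandem_sites(
    sites: Sequence[PredictedSite],
    min_mean_score: float = 30.0,
    max_spacing: int = 100,
    repeat_intervals: Sequence[GenomicInterval] | None = None,
) -> list[TandemPair]:
    """High-affinity tandem site pairs within ``max_spacing`` bp.

    Every ordered same-chromosome pair with center-to-center spacing in
    (0, max_spacing] and mean PWM score strictly above ``min_mean_score``
    is reported once.  ``in_repeat`` marks pairs whose midpoint lies inside
    any repeat interval.
    """
    repeat_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if repeat_intervals:
        merged = merge_intervals(list(repeat_intervals))
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            repeat_index[chrom] = (
                np.asarray([iv.start for iv in ivs], dtype=np.int64),
                np.asarray([iv.end for iv in ivs], dtype=np.int64),
            )

    def in_repeat(chrom: str, pos: int) -> bool:
        if chrom not in repeat_index:
            return False
        starts, ends = repeat_index[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= ends[i]

    by_chrom_sites: dict[str, list[PredictedSite]] = {}
    for s in sites:
        by_chrom_sites.setdefault(s.chrom, []).append(s)
    pairs: list[TandemPair] = []
    for chrom in sorted(by_chrom_sites):
        ss = sorted(by_chrom_sites[chrom], key=lambda s: s.pos)
        for i, a in enumerate(ss):
            for b in ss[i + 1:]:
                spacing = b.pos - a.pos
                if spacing > max_spacing:
                    break
                if spacing <= 0:
                    continue
                mean_score = (a.score + b.score) / 2.0
                if mean_score <= min_mean_score:
                    continue
                mid = (a.pos + b.pos) // 2
                pairs.append(TandemPair(chrom, a.pos, b.pos, mean_score,
                                        in_repeat(chrom, mid)))
    return pairs


def spacing_induction_histogram(
    pairs: Sequence[TandemPair],
    stim_records: Sequence[TagRecord] | TagIndex,
    unstim_records: Sequence[TagRecord] | TagIndex,
    n_stim: int,
    n_unstim: int,
    induced_cutoff: float = 2.0,
    halfwidth: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair induction log-ratios by spacing, with an induced summary.

    Tags are counted within +/- ``halfwidth`` of each pair midpoint (400 bp
    around the center by default).  The first returned table has one row
    per pair (spacing, in_repeat, counts, ln_ratio); the second counts, for
    pairs with ln_ratio above ``induced_cutoff``, how many induced pairs
    fall at each spacing, split by repeat membership.
    """
    stim = stim_records if isinstance(stim_records, TagIndex) else TagIndex(stim_records)
    unstim = (unstim_records if isinstance(unstim_records, TagIndex)
              else TagIndex(unstim_records))
    rows = []
    for p in pairs:
        c_s = stim.count(p.chrom, p.midpoint - halfwidth, p.midpoint + halfwidth)
        c_u = unstim.count(p.chrom, p.midpoint - halfwidth, p.midpoint + halfwidth)
        rows.append({
            "chrom": p.chrom, "spacing": p.spacing, "in_repeat": p.in_repeat,
            "mean_score": p.mean_score, "tags_stim": c_s, "tags_unstim": c_u,
            "ln_ratio": induction_log_ratio(c_s, c_u, n_stim, n_unstim),
        })
    pair_table = pd.DataFrame(
        rows, columns=["chrom", "spacing", "in_repeat", "mean_score",
                       "tags_stim", "tags_unstim", "ln_ratio"])
    if pair_table.empty:
        summary = pd.DataFrame(columns=["spacing", "in_repeat", "n_induced"])
        return pair_table, summary
    induced = pair_table[pair_table["ln_ratio"] > induced_cutoff]
    summary = (induced.groupby(["spacing", "in_repeat"], as_index=False)
               .size().rename(columns={"size": "n_induced"}))
    return pair_table, summary


def _overlap_length(iv: GenomicInterval,
                    starts: np.ndarray, ends: np.ndarray) -> int:
    lo = int(np.searchsorted(ends, iv.start, side="left"))
    hi = int(np.searchsorted(starts, iv.end, side="right"))
    if lo >= hi:
        return 0
    s = np.maximum(starts[lo:hi], iv.start)
    e = np.minimum(ends[lo:hi], iv.end)
    return int(np.maximum(e - s + 1, 0).sum())


def compartment_enrichment(
    instances: Sequence[GenomicInterval],
    compartment: Sequence[GenomicInterval],
    compartment_len_mb: float,
    genome_len_mb: float,
    min_overlap: int = 10,
) -> float:
    """Density of element instances in a compartment relative to the genome.

    An instance is "in" the compartment when it overlaps it by at least
    ``min_overlap`` bp (after merging the compartment intervals).  The
    ratio ``(n_in / compartment_len) / (n_total / genome_len)`` is 1 under
    random placement, > 1 for over-representation.
    """
    if compartment_len_mb <= 0 or genome_len_mb <= 0:
        raise ValueError("compartment and genome lengths must be positive")
    if not instances:
        raise ValueError("no element instances supplied")
    merged = merge_intervals(list(compartment))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = sorted((iv for iv in merged if iv.chrom == chrom),
                     key=lambda iv: iv.start)
        by_chrom[chrom] = (
            np.asarray([iv.start for iv in ivs], dtype=np.int64),
            np.asarray([iv.end for iv in ivs], dtype=np.int64),
        )
    n_in = 0
    for iv in instances:
        if iv.chrom not in by_chrom:
            continue
        if _overlap_length(iv, *by_chrom[iv.chrom]) >= min_overlap:
            n_in += 1
    return (n_in / compartment_len_mb) / (len(instances) / genome_len_mb)


def classify_sites(
    sites: Sequence[PredictedSite],
    records: Sequence[TagRecord] | TagIndex,
    tss_positions: Sequence[tuple[str, int]],
    tss_radius: int = 1000,
    halfwidth: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify sites by tag occupation and TSS proximity.

    Occupation classes from the +/-100 bp centered tag count: class 1 has
    0 tags, class 2 has 1-5, class 3 has 6-14, class 4 more than 14.  A
    site is ``at_tss`` when an annotated TSS lies within ``tss_radius`` bp.
    Returns the per-site table and a per-(class, at_tss) summary with site
    counts and mean +/- sd of PWM scores.
    """
    index = records if isinstance(records, TagIndex) else TagIndex(records)
    tss_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for chrom, pos in tss_positions:
        tmp.setdefault(chrom, []).append(pos)
    for chrom, positions in tmp.items():
        tss_by_chrom[chrom] = np.sort(np.asarray(positions, dtype=np.int64))

    e0, e1, e2 = OCCUPATION_CLASS_EDGES
    rows = []
    for s in sites:
        n = index.count(s.chrom, s.pos - halfwidth, s.pos + halfwidth)
        if n <= e0:
            cls = 1
        elif n <= e1:
            cls = 2
        elif n <= e2:
            cls = 3
        else:
            cls = 4
        at_tss = False
        if s.chrom in tss_by_chrom:
            t = tss_by_chrom[s.chrom]
            i = int(np.searchsorted(t, s.pos))
            for j in (i - 1, i):
                if 0 <= j < len(t) and abs(int(t[j]) - s.pos) <= tss_radius:
                    at_tss = True
                    break
        rows.append({"chrom": s.chrom, "pos": s.pos, "score": s.score,
                     "tags": n, "occupation_class": cls, "at_tss": at_tss})
    per_site = pd.DataFrame(
        rows, columns=["chrom", "pos", "score", "tags",
                       "occupation_class", "at_tss"])
    if per_site.empty:
        summary = pd.DataFrame(columns=["occupation_class", "at_tss",
                                        "n_sites", "score_mean", "score_sd"])
        return per_site, summary
    summary = (per_site.groupby(["occupation_class", "at_tss"], as_index=False)
               .agg(n_sites=("score", "size"), score_mean=("score", "mean"),
                    score_sd=("score", "std")))
    return per_site, summary


def average_profile(
    site_classes: Mapping[object, Sequence[tuple[str, int]]],
    track: Sequence[tuple[str, int, float]],
    dmin: int = -1000,
    dmax: int = 1000,
) -> dict[object, tuple[np.ndarray, np.ndarray]]:
    """Mean track value vs. offset from site center, per site class.

    Wraps the count-density-normalized feature correlation: for each class
    the profile at offset d is the mean over sites of the track value at
    ``site.pos + d`` (bases missing from the track contribute zero).
    Classes with no sites are skipped with a notice.
    """
    out: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    for label, positions in site_classes.items():
        if not positions:
            logger.info("average_profile: class %r has no sites; skipped", label)
            continue
        reference = [TagRecord(chrom, str(label), pos, "0", 1)
                     for chrom, pos in positions]
        out[label] = feature_correlation(reference, track, dmin, dmax,
                                         normalization="density")
    return out
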