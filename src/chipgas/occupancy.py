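"""Occupancy and induction statistics around predicted binding sites.

A predicted site counts as occupied when more than a threshold number of
centered ChIP fragments (default 5) fall within +/-100 bp of its center.
Grouping the site catalog by integer PWM score and plotting the occupied
fraction per score class shows, for stimulated cells, how in vivo occupancy
rises with predicted affinity, and stays flat for unstimulated background.

Induction of binding between two conditions is measured as

    ln( ((c_stim + 1) / N_stim) / ((c_unstim + 1) / N_unstim) )

one pseudocount per condition, counts normalized by the library totals.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chipgas.sga import TagRecord
from chipgas.motif import PredictedSite

__all__ = [
    "TagIndex",
    "count_tags_in_window",
    "occupancy_by_score_class",
    "induction_log_ratio",
    "consensus_frequency_profile",
    "round_half_away",
]

OCCUPANCY_THRESHOLD = 5
OCCUPANCY_HALFWIDTH = 100


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (table display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class TagIndex:
    """Per-chromosome sorted position/cumulative-count index over tags."""

    def __init__(self, records: Sequence[TagRecord]):
        pos: dict[str, list[int]] = {}
        cnt: dict[str, list[int]] = {}
        for r in records:
            pos.setdefault(r.chrom, []).append(r.pos)
            cnt.setdefault(r.chrom, []).append(r.count)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pos:
            p = np.asarray(pos[chrom], dtype=np.int64)
            c = np.asarray(cnt[chrom], dtype=np.int64)
            order = np.argsort(p, kind="stable")
            self._index[chrom] = (
                p[order],
                np.concatenate([[0], np.cumsum(c[order])]),
            )

    def count(self, chrom: str, lo: int, hi: int) -> int:
        """Total tag count at positions in [lo, hi], inclusive."""
        if chrom not in self._index:
            return 0
        p, csum = self._index[chrom]
        return int(csum[np.searchsorted(p, hi, side="right")]
                   - csum[np.searchsorted(p, lo, side="left")])

    def total(self) -> int:
        return int(sum(csum[-1] for _, csum in self._index.values()))


def count_tags_in_window(records: Sequence[TagRecord] | TagIndex, chrom: str,
                         pos: int, halfwidth: int = OCCUPANCY_HALFWIDTH) -> int:
    """Total centered-tag count within |q - pos| <= halfwidth, bounds inclusive."""
    index = records if isinstance(records, TagIndex) else TagIndex(records)
    return index.count(chrom, pos - halfwidth, pos + halfwidth)


def occupancy_by_score_class(
    sites: Sequence[PredictedSite],
    records: Sequence[TagRecord] | TagIndex,
    threshold: int = OCCUPANCY_THRESHOLD,
    halfwidth: int = OCCUPANCY_HALFWIDTH,
    control_positions: Sequence[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Fraction of sites occupied (> threshold tags), per integer PWM score.

    Returns a DataFrame indexed by score with columns ``n_sites``,
    ``n_occupied`` and ``fraction`` (score classes with no sites are simply
    absent), plus the pooled occupied fraction of an optional control
    position set (None when no control is given).
    """
    index = records if isinstance(records, TagIndex) else TagIndex(records)
    per_score: dict[int, list[int]] = {}
    for s in sites:
        n = index.count(s.chrom, s.pos - halfwidth, s.pos + halfwidth)
        per_score.setdefault(int(s.score), []).append(n)
    rows = []
    for score in sorted(per_score):
        counts = per_score[score]
        n_occ = sum(1 for c in counts if c > threshold)
        rows.append((score, len(counts), n_occ, n_occ / len(counts)))
    table = pd.DataFrame(rows, columns=["score", "n_sites", "n_occupied",
                                        "fraction"]).set_index("score")
    control_fraction = None
    if control_positions is not None and len(control_positions) > 0:
        occ = sum(
            1 for chrom, pos in control_positions
            if index.count(chrom, pos - halfwidth, pos + halfwidth) > threshold
        )
        control_fraction = occ / len(control_positions)
    return table, control_fraction


def induction_log_ratio(c_stim: int, c_unstim: int,
                        n_stim: int, n_unstim: int) -> float:
    """Natural-log induction ratio, pseudocounted and library-normalized.

    ``ln(((c_stim + 1) / n_stim) / ((c_unstim + 1) / n_unstim))``; positive
    values mean more (normalized) signal in the stimulated condition.
    Antisymmetric under swapping the two conditions.
    """
    if n_stim <= 0 or n_unstim <= 0:
        raise ValueError("library totals must be positive")
    if c_stim < 0 or c_unstim < 0:
        raise ValueError("tag counts must be non-negative")
    return math.log(((c_stim + 1) / n_stim) / ((c_unstim + 1) / n_unstim))


def consensus_frequency_profile(
    site_positions: Sequence[tuple[str, int]],
    match_positions: Sequence[tuple[str, int]],
    window: int = 100,
    offsets: tuple[int, int] = (-1000, 1000),
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of sites with >= 1 consensus match, per window offset.

    ``profile[d]`` is the fraction of sites s for which at least one match
    m satisfies ``|m.pos - (s.pos + d)| <= window / 2`` — i.e. the
    occurrence frequency of the consensus in a sliding window whose center
    is displaced by d from the site.  Peaks at d = 0 when matches co-locate
    with sites; the tail level reflects the background match density.
    """
    if not site_positions:
        raise ValueError("empty site list")
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even width")
    dmin, dmax = offsets
    if dmin > dmax:
        raise ValueError("invalid offset range")
    half = window // 2
    n_off = dmax - dmin + 1

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in match_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    sorted_matches = {c: np.sort(np.asarray(p, dtype=np.int64))
                      for c, p in by_chrom.items()}

    covered = np.zeros(n_off, dtype=np.int64)
    for chrom, spos in site_positions:
        if chrom not in sorted_matches:
            continue
        m = sorted_matches[chrom]
        lo = np.searchsorted(m, spos + dmin - half, side="left")
        hi = np.searchsorted(m, spos + dmax + half, side="right")
        if lo == hi:
            continue
        # each match m covers offsets d in [m - spos - half, m - spos + half]
        d_lo = np.clip(m[lo:hi] - spos - half, dmin, dmax + 1) - dmin
        d_hi = np.clip(m[lo:hi] - spos + half, dmin - 1, dmax) - dmin + 1
        site_cov = np.zeros(n_off + 1, dtype=np.int64)
        np.add.at(site_cov, d_lo, 1)
        np.add.at(site_cov, d_hi, -1)
        covered += np.cumsum(site_cov)[:n_off] > 0  # site covers d at least once

    # covered now holds, per offset, the number of sites with >= 1 match
    profile = covered.astype(np.float64) / len(site_positions)
    return np.arange(dmin, dmax + 1, dtype=np.int64), profile
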