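"""Fixed-threshold peak calling on centered ChIP-seq tags.

Every line of a centered, sorted SGA record set is a candidate peak.  The
candidate's score is the total (optionally capped) tag count in a window
centered on its position; a candidate is reported when the score reaches a
fixed threshold and strictly dominates the window sum of every other record
position within a wider vicinity range, ties going to the leftmost position.
The canonical defaults are a 200 bp window, 400 bp vicinity, a threshold
of 50 tags, and a permissive count cut-off of 999999, with a posteriori
center-of-gravity refinement available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from chipgas.sga import TagRecord

__all__ = ["Peak", "PeakMatchResult", "call_peaks", "match_peak_sets"]


@dataclass(frozen=True, slots=True)
class Peak:
    chrom: str
    pos: int
    window_sum: int
    refined: bool = False


class PeakMatchResult(NamedTuple):
    pairs: list[tuple[Peak, Peak]]  # (a, nearest matching b)
    n_matched: int
    fraction: float  # matched / |A|; NaN when A is empty


def call_peaks(records: Sequence[TagRecord], *, window: int = 200,
               vicinity: int = 400, threshold: int = 50,
               count_cutoff: int = 999999,
               refine: bool = False) -> list[Peak]:
    """Call peaks from centered tags by window sum + vicinity dominance.

    For each record position p the window sum ``s(p)`` adds
    ``min(count, count_cutoff)`` over all record positions within
    ``window/2`` of p on the same chromosome (inclusive bounds).  p is
    reported iff ``s(p) >= threshold`` and ``s(p)`` strictly exceeds the
    window sum of every other record position within ``vicinity/2``; on a
    tie the leftmost of the tied positions wins.  With ``refine``, the
    reported position is the count-weighted mean position inside the
    window, rounded to the nearest bp.

    Input must be centered (all strands ``0``) and sorted.
    """
    if window <= 0 or vicinity <= 0:
        raise ValueError("window and vicinity must be positive")
    if threshold < 0 or count_cutoff < 1:
        raise ValueError("threshold must be >= 0 and count_cutoff >= 1")
    for r in records:
        if r.strand != "0":
            raise ValueError(
                "call_peaks requires centered input (strand 0); "
                f"found strand {r.strand!r}"
            )

    half_w = window / 2
    half_v = vicinity / 2
    peaks: list[Peak] = []

    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for r in records:
        p, c = by_chrom.setdefault(r.chrom, ([], []))
        p.append(r.pos)
        c.append(min(r.count, count_cutoff))

    for chrom in sorted(by_chrom):
        pos = np.asarray(by_chrom[chrom][0], dtype=np.int64)
        cnt = np.asarray(by_chrom[chrom][1], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos, cnt = pos[order], cnt[order]
        # duplicate (chrom,pos) can arise from capping independent records;
        # each is its own candidate, matching the line-per-candidate contract
        csum = np.concatenate([[0], np.cumsum(cnt)])
        wlo = np.searchsorted(pos, pos - half_w, side="left")
        whi = np.searchsorted(pos, pos + half_w, side="right")
        s = csum[whi] - csum[wlo]

        vlo = np.searchsorted(pos, pos - half_v, side="left")
        vhi = np.searchsorted(pos, pos + half_v, side="right")
        for i in range(len(pos)):
            si = s[i]
            if si < threshold:
                continue
            neigh = s[vlo[i]:vhi[i]]
            # strict dominance over every other candidate in the vicinity;
            # a tie survives only for the leftmost tied position
            if (neigh > si).any():
                continue
            ties = np.flatnonzero(neigh == si) + vlo[i]
            if ties[0] != i:
                continue
            if refine:
                w = cnt[wlo[i]:whi[i]].astype(np.float64)
                cog = float(np.sum(w * pos[wlo[i]:whi[i]]) / np.sum(w))
                rpos = int(math.floor(cog + 0.5))
            else:
                rpos = int(pos[i])
            peaks.append(Peak(chrom, rpos, int(si), refined=refine))
    peaks.sort(key=lambda p: (p.chrom, p.pos))
    return peaks


def match_peak_sets(set_a: Sequence[Peak], set_b: Sequence[Peak],
                    tol: int = 100) -> PeakMatchResult:
    """Match each peak in A to its nearest same-chromosome peak in B.

    A peak a is matched iff some b on the same chromosome satisfies
    ``|a.pos - b.pos| <= tol`` (inclusive).  Returns the (a, nearest-b)
    pairs and the matched fraction of A (NaN for empty A).
    """
    b_by_chrom: dict[str, list[Peak]] = {}
    for b in set_b:
        b_by_chrom.setdefault(b.chrom, []).append(b)
    b_pos = {
        chrom: (np.asarray([p.pos for p in plist], dtype=np.int64), plist)
        for chrom, plist in (
            (c, sorted(pl, key=lambda p: p.pos)) for c, pl in b_by_chrom.items()
        )
    }
    pairs: list[tuple[Peak, Peak]] = []
    for a in set_a:
        if a.chrom not in b_pos:
            continue
        positions, plist = b_pos[a.chrom]
        i = int(np.searchsorted(positions, a.pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(int(positions[j]) - a.pos)
                if d <= tol and (best is None or d < best[0]):
                    best = (d, plist[j])
        if best is not None:
            pairs.append((a, best[1]))
    n = len(set_a)
    fraction = float("nan") if n == 0 else len(pairs) / n
    return PeakMatchResult(pairs, len(pairs), fraction)
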