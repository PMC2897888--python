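"""Tag centering and positional correlation of genomic feature lists.

ChIP-seq tags map the 5' ends of immunoprecipitated fragments, so + and -
strand tags cluster on opposite sides of a protein binding site, displaced
by roughly one fragment length.  The displacement histogram (how often a
``-`` tag sits at a given signed distance downstream of a ``+`` tag) makes
that fragment length measurable as the histogram mode; shifting each strand
by half of it ("centering") moves every tag to its fragment midpoint, which
is what the peak caller consumes.

The same sweep generalises to correlating any two positional feature lists,
e.g. averaging a per-base conservation track around predicted sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from chipgas.sga import TagRecord, sort_key

__all__ = [
    "DisplacementHistogram",
    "FragmentLengthEstimate",
    "center_tags",
    "displacement_histogram",
    "estimate_fragment_length",
    "feature_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisplacementHistogram:
    """Count-weighted (+,-) tag pair counts per signed distance.

    ``weight[i]`` is the number of same-chromosome tag pairs (p on +, q on -)
    with ``q.pos - p.pos == offsets[i]``, weighting each pair by the product
    of the two tag counts.  ``n_ref`` is the total + strand tag count.
    """

    offsets: np.ndarray
    weights: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.weights):
            raise ValueError("offsets and weights must have equal length")


class FragmentLengthEstimate(NamedTuple):
    length: int
    centering: int  # round(length / 2): the shift to use for centering


def _group_by_chrom(records: Sequence[TagRecord], strand: str | None = None):
    """chrom -> (positions, counts) as sorted int64 arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pos: dict[str, list[int]] = {}
    cnt: dict[str, list[int]] = {}
    for r in records:
        if strand is not None and r.strand != strand:
            continue
        pos.setdefault(r.chrom, []).append(r.pos)
        cnt.setdefault(r.chrom, []).append(r.count)
    for chrom in pos:
        p = np.asarray(pos[chrom], dtype=np.int64)
        c = np.asarray(cnt[chrom], dtype=np.int64)
        order = np.argsort(p, kind="stable")
        out[chrom] = (p[order], c[order])
    return out


def center_tags(records: Sequence[TagRecord], shift: int) -> list[TagRecord]:
    """Shift + tags downstream and - tags upstream by ``shift`` bp.

    Produces centered records with strand ``0``; counts landing on the same
    (chrom, pos) are merged by summation so the output is again a valid SGA
    record set.  Positions shifted below 1 are clamped to 1.  Total tag
    count is conserved.

    Raises
    ------
    ValueError
        If the input contains strand-0 records (already centered) or
        ``shift`` is negative.
    """
    if shift < 0:
        raise ValueError(f"shift must be >= 0, got {shift}")
    merged: dict[tuple[str, int], int] = {}
    features: dict[tuple[str, int], str] = {}
    n_clamped = 0
    for r in records:
        if r.strand == "0":
            raise ValueError("input already centered (strand 0 record found)")
        pos = r.pos + shift if r.strand == "+" else r.pos - shift
        if pos < 1:
            pos = 1
            n_clamped += 1
        key = (r.chrom, pos)
        merged[key] = merged.get(key, 0) + r.count
        features.setdefault(key, r.feature)
    if n_clamped:
        logger.warning("center_tags: clamped %d shifted positions to 1", n_clamped)
    out = [
        TagRecord(chrom, features[(chrom, pos)], pos, "0", count)
        for (chrom, pos), count in merged.items()
    ]
    out.sort(key=sort_key)
    return out


def displacement_histogram(records: Sequence[TagRecord], dmin: int,
                           dmax: int) -> DisplacementHistogram:
    """Histogram of signed (+ to -) tag distances, count-weighted.

    For every same-chromosome pair of a + record p and a - record q with
    ``dmin <= q.pos - p.pos <= dmax``, the pair contributes
    ``p.count * q.count`` to the bin at that distance.  Computed with a
    sorted sweep; equal to the all-pairs double loop.
    """
    if dmin > dmax:
        raise ValueError(f"dmin ({dmin}) must be <= dmax ({dmax})")
    offsets = np.arange(dmin, dmax + 1, dtype=np.int64)
    weights = np.zeros(len(offsets), dtype=np.float64)
    plus = _group_by_chrom(records, "+")
    minus = _group_by_chrom(records, "-")
    n_ref = int(sum(c.sum() for _, c in plus.values()))
    if not plus or not minus:
        logger.warning("displacement_histogram: no stranded tag pairs in input")
        return DisplacementHistogram(offsets, weights, n_ref)
    for chrom, (ppos, pcnt) in plus.items():
        if chrom not in minus:
            continue
        mpos, mcnt = minus[chrom]
        lo = np.searchsorted(mpos, ppos + dmin, side="left")
        hi = np.searchsorted(mpos, ppos + dmax, side="right")
        for i in range(len(ppos)):
            sl = slice(lo[i], hi[i])
            if sl.start == sl.stop:
                continue
            np.add.at(weights, mpos[sl] - ppos[i] - dmin,
                      pcnt[i] * mcnt[sl].astype(np.float64))
    return DisplacementHistogram(offsets, weights, n_ref)


def estimate_fragment_length(hist: DisplacementHistogram,
                             smooth_window: int = 5,
                             search_range: tuple[int, int] = (50, 500),
                             ) -> FragmentLengthEstimate:
    """Fragment length = mode of the smoothed + / - displacement histogram.

    The histogram is smoothed with a centered moving average of
    ``smooth_window`` bins and restricted to ``search_range`` (positive
    offsets).  Among offsets tied for the smoothed maximum (smoothing
    turns an isolated spike into a plateau) the one with the largest raw
    weight wins, remaining ties going to the smallest offset.  The
    companion centering distance is the nearest integer to half the
    length (140 bp fragments -> shift 70).
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    lo, hi = search_range
    mask = (hist.offsets >= lo) & (hist.offsets <= hi)
    if not mask.any():
        raise ValueError("search range does not intersect histogram offsets")
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist.weights, kernel, mode="same")
    sm = smoothed[mask]
    if not sm.any():
        raise ValueError("histogram is all-zero over the search range")
    offs = hist.offsets[mask]
    raw = hist.weights[mask]
    ties = np.flatnonzero(np.isclose(sm, sm.max()))
    best = ties[int(np.argmax(raw[ties]))]  # argmax: first max = smallest offset
    length = int(offs[best])
    return FragmentLengthEstimate(length, round(length / 2))


def feature_correlation(reference: Sequence[TagRecord],
                        target: Sequence[tuple[str, int, float]] | Sequence[TagRecord],
                        dmin: int, dmax: int,
                        normalization: str = "density",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Positional cross-correlation of a reference tag list with a target.

    ``profile[d] = sum over pairs (r, t) with t.pos - r.pos == d of
    r.count * t.value``; under count-density normalization (default) the sum
    is divided by the total reference count, so a constant target track of
    value c yields a flat profile at c.  ``normalization='raw'`` returns the
    raw weighted sums.

    ``target`` items are either TagRecords (value = count) or
    (chrom, pos, value) triples, e.g. a per-base conservation track.

    Returns (offsets, profile).
    """
    if normalization not in ("density", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if dmin > dmax:
        raise ValueError("dmin must be <= dmax")
    if not reference:
        raise ValueError("reference feature list is empty")
    offsets = np.arange(dmin, dmax + 1, dtype=np.int64)
    profile = np.zeros(len(offsets), dtype=np.float64)

    tgt: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tpos: dict[str, list[int]] = {}
    tval: dict[str, list[float]] = {}
    for t in target:
        if isinstance(t, TagRecord):
            chrom, pos, val = t.chrom, t.pos, float(t.count)
        else:
            chrom, pos, val = t[0], int(t[1]), float(t[2])
        tpos.setdefault(chrom, []).append(pos)
        tval.setdefault(chrom, []).append(val)
    for chrom in tpos:
        p = np.asarray(tpos[chrom], dtype=np.int64)
        v = np.asarray(tval[chrom], dtype=np.float64)
        order = np.argsort(p, kind="stable")
        tgt[chrom] = (p[order], v[order])

    total_ref = 0
    for r in reference:
        total_ref += r.count
        if r.chrom not in tgt:
            continue
        p, v = tgt[r.chrom]
        lo = np.searchsorted(p, r.pos + dmin, side="left")
        hi = np.searchsorted(p, r.pos + dmax, side="right")
        if lo == hi:
            continue
        np.add.at(profile, p[lo:hi] - r.pos - dmin, r.count * v[lo:hi])
    if normalization == "density":
        profile /= total_ref
    return offsets, profile
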