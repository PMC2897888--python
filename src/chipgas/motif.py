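"""GAS motif refinement and integer-PWM scanning.

The gamma-interferon activated site (GAS) bound by STAT1 dimers is a
palindromic element of two 3-bp half-sites, TTC...GAA, separated by a
short spacer whose length varies between 2 and 4 bp.  The motif model here
is a two-half-site hidden Markov model with three parallel spacer branches
(lengths 2, 3 and 4) plus one flanking position on each side, trained on
peak-centered sequence windows by Baum-Welch EM under a ZOOPS occurrence
model (zero or one motif per window, uniform background).  When training
concentrates essentially all branch probability on the spacer-3 branch, the
model collapses to an 11-position probability matrix, which is converted to
an additive integer position weight matrix via

    w[i][b] = int( (3 / ln 2) * ln( p[i][b] / q_b ) )

with uniform background q_b = 0.25, so +3 score units correspond to a
doubling of a base frequency over background.  Scanning, above-cutoff
k-mer enumeration and IUPAC consensus matching operate on that PWM.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "BASES",
    "GasHmm",
    "ProbabilityMatrix",
    "IntegerPwm",
    "PredictedSite",
    "build_initial_hmm",
    "train_hmm",
    "collapse_to_matrix",
    "probability_to_weight",
    "score_window",
    "scan_sequence",
    "enumerate_matching_kmers",
    "match_consensus",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SPACER_LENGTHS = (2, 3, 4)
HALF = 4  # left/right block length: one flank + three consensus positions


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to int8 indices (A=0 C=1 G=2 T=3, anything else 4)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _check_rows(p: np.ndarray, what: str) -> None:
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{what}: probabilities outside [0, 1]")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError(f"{what}: emission rows must sum to 1")


@dataclass
class GasHmm:
    """Two-half-site motif HMM with parallel spacer branches of length 2/3/4.

    ``left`` and ``right`` are 4x4 emission blocks (rows = positions
    L1..L4 / R1..R4, columns = A C G T); ``spacers[k]`` is the k x 4
    emission block of the length-k spacer branch, entered with prior
    ``branch_priors[k - 2]``.  ``occurrence_prior`` is the ZOOPS
    probability that a training window contains one motif instance;
    background emissions are uniform.
    """

    left: np.ndarray
    right: np.ndarray
    spacers: dict[int, np.ndarray]
    branch_priors: np.ndarray
    occurrence_prior: float = 0.5

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=np.float64)
        self.right = np.asarray(self.right, dtype=np.float64)
        self.branch_priors = np.asarray(self.branch_priors, dtype=np.float64)
        if self.left.shape != (HALF, 4) or self.right.shape != (HALF, 4):
            raise ValueError("left/right emission blocks must be 4x4")
        if tuple(sorted(self.spacers)) != SPACER_LENGTHS:
            raise ValueError(f"spacer branches must have lengths {SPACER_LENGTHS}")
        for k in SPACER_LENGTHS:
            self.spacers[k] = np.asarray(self.spacers[k], dtype=np.float64)
            if self.spacers[k].shape != (k, 4):
                raise ValueError(f"spacer-{k} emission block must be {k}x4")
            _check_rows(self.spacers[k], f"spacer-{k}")
        _check_rows(self.left, "left half-site")
        _check_rows(self.right, "right half-site")
        if self.branch_priors.shape != (3,) or not math.isclose(
            float(self.branch_priors.sum()), 1.0, abs_tol=1e-8
        ):
            raise ValueError("branch priors must be 3 values summing to 1")
        if not 0.0 < self.occurrence_prior <= 1.0:
            raise ValueError("occurrence_prior must be in (0, 1]")

    def branch_emissions(self, k: int) -> np.ndarray:
        """Stacked (8 + k) x 4 emission matrix of the spacer-k branch."""
        return np.vstack([self.left, self.spacers[k], self.right])

    def motif_length(self, k: int) -> int:
        return 2 * HALF + k


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-position base probabilities of the collapsed spacer-3 motif."""

    probs: np.ndarray  # shape (11, 4), rows sum to 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=np.float64))
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probability matrix must be L x 4")
        _check_rows(self.probs, "probability matrix")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class IntegerPwm:
    """Additive integer position weight matrix (rows = positions, cols ACGT)."""

    weights: np.ndarray
    background: float = 0.25

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("weight matrix must be L x 4")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> int:
        return int(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> int:
        return int(self.weights.min(axis=1).sum())

    def reverse_complement(self) -> "IntegerPwm":
        return IntegerPwm(self.weights[::-1, ::-1].copy(), self.background)

    def to_tsv(self) -> str:
        """Rows = positions, columns = A C G T."""
        lines = ["\t".join(BASES)]
        for row in self.weights:
            lines.append("\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "IntegerPwm":
        rows = []
        for line in text.strip().splitlines():
            fields = line.split("\t")
            if fields[0].upper() == "A" and len(fields) == 4:
                continue  # header
            rows.append([int(v) for v in fields])
        return cls(np.asarray(rows, dtype=np.int64))


@dataclass(frozen=True, slots=True)
class PredictedSite:
    """A PWM match; ``pos`` is the 1-based coordinate of the center base."""

    chrom: str
    pos: int
    strand: str
    score: int


def build_initial_hmm(consensus_left: str = "TTC", consensus_right: str = "GAA",
                      consensus_weight: float = 0.7,
                      occurrence_prior: float = 0.5) -> GasHmm:
    """Consensus-biased starting model for Baum-Welch refinement.

    The three consensus positions of each half-site get probability
    ``consensus_weight`` on the consensus base and (1 - w)/3 elsewhere;
    the outer flank positions (L1, R4) and all spacer positions start
    uniform, and the three spacer branches start equiprobable.
    """
    if not 0.25 < consensus_weight < 1.0:
        raise ValueError(
            "consensus_weight must be in (0.25, 1): below 0.25 the "
            "initialization carries no consensus information"
        )
    if len(consensus_left) != 3 or len(consensus_right) != 3:
        raise ValueError("half-site consensus strings must have length 3")
    for b in consensus_left + consensus_right:
        if b not in _BASE_INDEX:
            raise ValueError(f"consensus base {b!r} not in ACGT")

    def biased(base: str) -> np.ndarray:
        row = np.full(4, (1.0 - consensus_weight) / 3.0)
        row[_BASE_INDEX[base]] = consensus_weight
        return row

    uniform = np.full(4, 0.25)
    left = np.vstack([uniform] + [biased(b) for b in consensus_left])
    right = np.vstack([biased(b) for b in consensus_right] + [uniform])
    spacers = {k: np.tile(uniform, (k, 1)) for k in SPACER_LENGTHS}
    return GasHmm(left, right, spacers, np.full(3, 1.0 / 3.0),
                  occurrence_prior=occurrence_prior)


def _window_log_odds(X: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """Log odds (vs uniform background) of the motif at every placement.

    X is an (n_seq, T) int8 matrix; returns (n_seq, T - m + 1).
    N (index 4) contributes log-odds 0 at any position.
    """
    m = emissions.shape[0]
    n, T = X.shape
    V = T - m + 1
    if V <= 0:
        return np.zeros((n, 0))
    acc = np.zeros((n, V), dtype=np.float64)
    for i in range(m):
        table = np.zeros(5)
        table[:4] = np.log(emissions[i]) - math.log(0.25)
        acc += table[X[:, i:i + V]]
    return acc


def _sequence_log_background(X: np.ndarray) -> np.ndarray:
    """Per-sequence log probability under the uniform background model."""
    return (X != 4).sum(axis=1) * math.log(0.25)


def train_hmm(model: GasHmm, sequences: Sequence[str], max_iter: int = 200,
              tol: float = 1e-4,
              adapt_spacers: tuple[int, ...] = (3,)) -> tuple[GasHmm, list[float]]:
    """Baum-Welch (EM) refinement of the spacer-branch motif model.

    Each window is explained as background with one optional motif pass
    (ZOOPS): placement start and spacer branch are latent, placements are
    uniform a priori within a window, and the forward sum over placements
    and branches gives the exact window likelihood.  Emission rows, branch
    priors and the occurrence prior are re-estimated from the posterior
    placement weights each iteration; the log-likelihood is non-decreasing.

    Spacer emission rows are re-estimated only for the branch lengths in
    ``adapt_spacers``; the others stay at their initial (background)
    distributions, a parameter tying that keeps the alternative-length
    branches pure spacer-length detectors.  With all spacer emissions
    free, a minority branch can instead absorb a shifted parse of the
    dominant motif — the GAS core is self-similar enough (the C/G-rich
    spacer resembles the half-site boundaries) that a freely adapting
    length-2 branch retains a few percent posterior mass that does not
    reflect genuine spacer-length variation.  Pass ``adapt_spacers=(2, 3,
    4)`` for fully free emission training.

    N bases emit with probability 1 from every state and contribute
    nothing to the emission counts.

    Stops when the log-likelihood gain drops below ``tol`` or after
    ``max_iter`` iterations.  An infinite ``tol`` means "converged from
    the start": the initial model is returned untouched with an empty
    trace.

    Returns the trained model and the per-iteration log-likelihood trace
    (element 0 is the initial model's log-likelihood).
    """
    if not sequences:
        raise ValueError("empty training set")
    if not math.isfinite(tol):
        return model, []

    min_len = min(len(s) for s in sequences)
    if min_len < 2 * HALF + max(SPACER_LENGTHS):
        raise ValueError("training windows shorter than the longest motif form")

    # group equal-length windows so the E-step vectorizes across sequences
    groups: dict[int, np.ndarray] = {}
    for s in sequences:
        groups.setdefault(len(s), []).append(encode(s))  # type: ignore[arg-type]
    groups = {T: np.vstack(rows) for T, rows in groups.items()}

    left = model.left.copy()
    right = model.right.copy()
    spacers = {k: v.copy() for k, v in model.spacers.items()}
    priors = model.branch_priors.copy()
    gamma = model.occurrence_prior
    n_total = len(sequences)

    def log_likelihood() -> float:
        ll = 0.0
        for T, X in groups.items():
            log_bg = _sequence_log_background(X)
            mix = np.full(X.shape[0], 1.0 - gamma)
            for ki, k in enumerate(SPACER_LENGTHS):
                lo = _window_log_odds(X, np.vstack([left, spacers[k], right]))
                if lo.shape[1] == 0:
                    continue
                mix += gamma * priors[ki] * np.exp(lo).mean(axis=1)
            ll += float(np.sum(log_bg + np.log(mix)))
        return ll

    trace = [log_likelihood()]
    for _ in range(max_iter):
        # E-step: posterior over (branch, placement) per window
        new_left = np.zeros_like(left)
        new_right = np.zeros_like(right)
        new_spacers = {k: np.zeros_like(v) for k, v in spacers.items()}
        branch_mass = np.zeros(3)
        occ_mass = 0.0
        for T, X in groups.items():
            odds = {}
            denom = np.full(X.shape[0], 1.0 - gamma)
            for ki, k in enumerate(SPACER_LENGTHS):
                lo = _window_log_odds(X, np.vstack([left, spacers[k], right]))
                V = lo.shape[1]
                r = gamma * priors[ki] / max(V, 1) * np.exp(lo)
                odds[k] = r
                denom += r.sum(axis=1)
            for ki, k in enumerate(SPACER_LENGTHS):
                z = odds[k] / denom[:, None]  # (n, V) posterior placement weights
                branch_mass[ki] += float(z.sum())
                m = 2 * HALF + k
                V = z.shape[1]
                zf = z.ravel()
                for i in range(m):
                    col = X[:, i:i + V].ravel()
                    w = np.bincount(col, weights=zf, minlength=5)[:4]
                    if i < HALF:
                        new_left[i] += w
                    elif i < HALF + k:
                        new_spacers[k][i - HALF] += w
                    else:
                        new_right[i - HALF - k] += w
            # occurrence mass per sequence: 1 - P(no motif | x)
            occ_mass += float(((denom - (1.0 - gamma)) / denom).sum())

        # M-step with a tiny floor so emission rows stay valid distributions
        def normalize(counts: np.ndarray) -> np.ndarray:
            c = counts + 1e-9
            return c / c.sum(axis=1, keepdims=True)

        left = normalize(new_left)
        right = normalize(new_right)
        spacers = {k: (normalize(new_spacers[k]) if k in adapt_spacers
                       else spacers[k])
                   for k in spacers}
        priors = (branch_mass + 1e-12) / (branch_mass.sum() + 3e-12)
        gamma = min(max(occ_mass / n_total, 1e-6), 1.0 - 1e-6)

        trace.append(log_likelihood())
        if abs(trace[-1] - trace[-2]) < tol:
            break

    trained = GasHmm(left, right, spacers, priors, occurrence_prior=gamma)
    return trained, trace


def collapse_to_matrix(model: GasHmm, branch_floor: float = 0.01) -> ProbabilityMatrix:
    """Collapse a trained model dominated by spacer 3 to an 11-row matrix.

    Valid only when the alternative spacer branches (2 and 4) have
    posterior priors at or below ``branch_floor``, i.e. the trained model
    effectively describes a fixed-length 11-bp motif.
    """
    pi2, pi3, pi4 = (float(v) for v in model.branch_priors)
    if pi2 > branch_floor or pi4 > branch_floor:
        raise ValueError(
            f"spacer branches 2/4 carry probability {pi2:.3f}/{pi4:.3f} "
            f"(> {branch_floor}); the model is not a fixed-spacer motif and "
            "should not be collapsed to a single matrix"
        )
    return ProbabilityMatrix(np.vstack([model.left, model.spacers[3], model.right]))


def _int_nearest(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def probability_to_weight(matrix: ProbabilityMatrix, background: float = 0.25,
                          floor: float = 1e-3) -> IntegerPwm:
    """Convert base probabilities to integer weights.

    ``w[i][b] = int((3 / ln 2) * ln(max(p[i][b], floor) / q))`` with
    rounding to the nearest integer.  The scale makes +3 score units equal
    one doubling of a base frequency relative to background; probabilities
    are floored before the logarithm so the weights stay finite.
    """
    if not 0.0 < background < 1.0:
        raise ValueError("background must be in (0, 1)")
    p = np.maximum(matrix.probs, floor)
    w = _int_nearest((3.0 / math.log(2.0)) * np.log(p / background))
    return IntegerPwm(w.astype(np.int64), background)


def score_window(pwm: IntegerPwm, window: str,
                 both_strands: bool = True) -> tuple[float, str]:
    """Score one window against the PWM; returns (score, strand).

    The reverse-complement orientation is scored as well when
    ``both_strands``; the better of the two is returned, ties going to the
    forward strand.  Windows containing non-ACGT characters score -inf.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    x = encode(window)
    if (x == 4).any():
        return (float("-inf"), "+")
    idx = np.arange(pwm.width)
    fwd = float(pwm.weights[idx, x].sum())
    if not both_strands:
        return (fwd, "+")
    rc = pwm.reverse_complement()
    rev = float(rc.weights[idx, x].sum())
    return (fwd, "+") if fwd >= rev else (rev, "-")


def scan_sequence(pwm: IntegerPwm, sequence: str, cutoff: int,
                  chrom: str = "seq", both_strands: bool = True,
                  offset: int = 0) -> list[PredictedSite]:
    """Report every position whose best-strand window score >= cutoff.

    Site coordinates are 1-based positions of the window's center base
    (the 6th of 11), shifted by ``offset`` (useful when scanning a
    sub-sequence of a chromosome).  Windows overlapping non-ACGT bases are
    skipped.
    """
    L = pwm.width
    if len(sequence) < L:
        return []
    x = encode(sequence)
    V = len(x) - L + 1
    fwd = np.zeros(V, dtype=np.float64)
    valid = np.ones(V, dtype=bool)
    for i in range(L):
        col = x[i:i + V]
        valid &= col != 4
        fwd += np.where(col == 4, 0, pwm.weights[i][np.minimum(col, 3)])
    scores = fwd
    strands = np.full(V, "+", dtype="U1")
    if both_strands:
        rcw = pwm.reverse_complement().weights
        rev = np.zeros(V, dtype=np.float64)
        for i in range(L):
            col = x[i:i + V]
            rev += np.where(col == 4, 0, rcw[i][np.minimum(col, 3)])
        better = rev > fwd  # tie -> forward
        scores = np.where(better, rev, fwd)
        strands = np.where(better, "-", "+")
    hits = np.flatnonzero(valid & (scores >= cutoff))
    center = L // 2  # 11-mer: index 5, the 6th base
    return [
        PredictedSite(chrom, offset + int(s) + center + 1, str(strands[s]),
                      int(scores[s]))
        for s in hits
    ]


def enumerate_matching_kmers(pwm: IntegerPwm, cutoff: int,
                             max_results: int = 4 ** 11) -> set[str]:
    """All k-mers with forward PWM score >= cutoff, by branch and bound.

    A prefix is abandoned as soon as its score plus the best achievable
    suffix score falls below the cutoff.  Scanning a sequence for exact
    matches of this set (and of its reverse complements) is equivalent to
    a direct PWM scan at the same cutoff.

    Raises if more than ``max_results`` k-mers qualify.
    """
    L = pwm.width
    suffix_max = np.zeros(L + 1, dtype=np.int64)
    for i in range(L - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + pwm.weights[i].max()
    out: set[str] = set()

    stack: list[tuple[int, int, str]] = [(0, 0, "")]
    while stack:
        i, score, prefix = stack.pop()
        if i == L:
            out.add(prefix)
            if len(out) > max_results:
                raise ValueError(
                    f"more than {max_results} k-mers match at cutoff {cutoff}"
                )
            continue
        for b in range(4):
            s = score + int(pwm.weights[i, b])
            if s + suffix_max[i + 1] >= cutoff:
                stack.append((i + 1, s, prefix + BASES[b]))
    return out


def _iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        values = ambiguous_dna_values.get(ch)
        if values is None:
            raise ValueError(f"invalid IUPAC symbol {ch!r}")
        parts.append(values if len(values) == 1 else f"[{values}]")
    return "".join(parts)


def match_consensus(sequence: str, pattern: str = "TCCNNNGAA",
                    both_strands: bool = True) -> list[tuple[int, str]]:
    """Find IUPAC consensus matches; returns (center position, strand).

    Positions are 1-based centers of the match span.  Matches of the
    reverse-complemented pattern on the forward sequence are reported with
    strand '-'.  Overlapping matches are all reported.
    """
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    patterns = [(pattern, "+")]
    if both_strands:
        rc = str(Seq(pattern.upper()).reverse_complement())
        if rc != pattern.upper():
            patterns.append((rc, "-"))
    half = len(pattern) // 2
    for pat, strand in patterns:
        rx = re.compile(f"(?=({_iupac_regex(pat)}))")
        for m in rx.finditer(seq):
            hits.append((m.start() + half + 1, strand))
    hits.sort()
    return hits
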