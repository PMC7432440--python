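"""Repeat and transfer-fragment detection on mitochondrial genomes.

Three detectors cover the repeat landscape of an AT-rich circular genome:

* :func:`find_exact_repeats` -- maximal exact repeat pairs in the four
  orientation classes used by REPuter-style analyses: forward (direct),
  reverse, complemented, and palindromic (reverse-complemented).
* :func:`find_interspersed_repeats` -- BLASTN-like self-comparison: word
  seeding, ungapped X-drop extension, and Karlin-Altschul E-values, keeping
  hits below a significance threshold (default 1e-10).
* :func:`find_tandem_repeats` -- arrays of two or more adjacent copies of a
  short motif (period up to ``max_period``), reported when the array is
  longer than 10 bp.

:func:`find_transfer_fragments` applies the same local-alignment engine
across genomes to locate mitochondrial segments present (possibly diverged)
in a nuclear assembly -- NUMT-like transfer evidence.

Scoring scheme: match +1, mismatch -2 (gap open 5 / extend 2 are declared
for completeness; extension is ungapped). lambda is solved from the
Karlin-Altschul identity for a uniform background; K is the standard value
for this scheme.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .mito_io import (
    GenomeSequence,
    Interval,
    MitogenomeAnnotation,
    complement,
    reverse_complement,
)

__all__ = [
    "ScoringScheme",
    "RepeatHit",
    "TandemRepeat",
    "TransferFragment",
    "find_exact_repeats",
    "find_interspersed_repeats",
    "find_tandem_repeats",
    "find_transfer_fragments",
    "repeat_coverage",
    "seed_entropy",
]

ORIENTATIONS = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class ScoringScheme:
    """Ungapped scoring with Karlin-Altschul statistics.

    K for the +1/-2 ungapped scheme on a uniform background is 0.621
    (the standard tabulated value); lambda is solved numerically from
    sum_ij p_i p_j exp(lambda * s_ij) = 1.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.621

    @property
    def lam(self) -> float:
        return _lambda_for(self.match, self.mismatch)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


_LAMBDA_CACHE: dict[tuple[int, int], float] = {}


def _lambda_for(match: int, mismatch: int) -> float:
    key = (match, mismatch)
    if key not in _LAMBDA_CACHE:
        f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(
            lam * mismatch
        ) - 1.0
        _LAMBDA_CACHE[key] = float(brentq(f, 1e-6, 10.0))
    return _LAMBDA_CACHE[key]


@dataclass(frozen=True)
class RepeatHit:
    interval_a: Interval
    interval_b: Interval
    orientation: str
    length: int
    identity: float  # percent
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class TandemRepeat:
    interval: Interval
    period: int
    copies: float
    consensus: str
    total_length: int
    identity: float = 100.0


@dataclass(frozen=True)
class TransferFragment:
    mito_interval: Interval
    nuclear_interval: Interval
    identity: float
    length: int
    score: float
    evalue: float
    overlapped_mito_features: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# low-complexity (dust-like) seed filter


def seed_entropy(word: str) -> float:
    """Shannon entropy (bits) of the base composition of a seed word."""
    counts = np.array([word.count(b) for b in "ACGT"], dtype=float)
    p = counts[counts > 0] / len(word)
    return float(-(p * np.log2(p)).sum())


def _low_complexity(word: str, threshold: float = 1.0) -> bool:
    return seed_entropy(word) < threshold


# ---------------------------------------------------------------------------
# maximal exact repeats


def _transform(seq: str, orientation: str) -> str:
    if orientation == "forward":
        return seq
    if orientation == "reverse":
        return seq[::-1]
    if orientation == "complement":
        return complement(seq)
    if orientation == "palindromic":
        return reverse_complement(seq)
    raise ValueError(orientation)


def _map_back(j0: int, length: int, L: int, orientation: str) -> tuple[int, int]:
    """Map a match start in the transformed sequence back to 0-based
    (start, end-exclusive) coordinates on the original strand."""
    if orientation in ("forward", "complement"):
        return j0, j0 + length
    # reversed coordinate frames
    return L - j0 - length, L - j0


def _canonical_pair(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[tuple[int, int], tuple[int, int]]:
    return (a, b) if a <= b else (b, a)


def find_exact_repeats(
    genome: GenomeSequence | str,
    min_len: int = 8,
    kinds: tuple[str, ...] = ORIENTATIONS,
    low_complexity_filter: bool = False,
    entropy_threshold: float = 1.0,
) -> list[RepeatHit]:
    """Maximal exact repeat pairs of the requested orientation classes.

    A pair is maximal when it cannot be extended by one position on either
    side in the (sequence, transformed-sequence) comparison. Each unordered
    pair of distinct intervals is reported once; the trivial forward
    self-match is excluded. With ``low_complexity_filter`` seeds whose base
    entropy falls below ``entropy_threshold`` bits are ignored, which
    suppresses homopolymer-driven hits.
    """
    s = genome.residues if isinstance(genome, GenomeSequence) else genome.upper()
    L = len(s)
    if L < min_len:
        return []
    hits: list[RepeatHit] = []
    for orientation in kinds:
        t = _transform(s, orientation)
        index: dict[str, list[int]] = defaultdict(list)
        for j in range(L - min_len + 1):
            index[t[j : j + min_len]].append(j)
        seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
        for i in range(L - min_len + 1):
            word = s[i : i + min_len]
            if low_complexity_filter and _low_complexity(word, entropy_threshold):
                continue
            for j in index.get(word, ()):
                # left-maximality: skip seeds interior to a longer match
                if i > 0 and j > 0 and s[i - 1] == t[j - 1]:
                    continue
                # extend right
                k = min_len
                while i + k < L and j + k < L and s[i + k] == t[j + k]:
                    k += 1
                a = (i, i + k)
                b = _map_back(j, k, L, orientation)
                if orientation == "forward" and a == b:
                    continue  # trivial self-match on the main diagonal
                if a == b:
                    continue  # degenerate self-pair in any orientation
                pair = _canonical_pair(a, b)
                if pair in seen:
                    continue
                seen.add(pair)
                (a0, a1), (b0, b1) = pair
                hits.append(
                    RepeatHit(
                        interval_a=Interval(a0 + 1, a1),
                        interval_b=Interval(b0 + 1, b1),
                        orientation=orientation,
                        length=k,
                        identity=100.0,
                        score=float(k),
                        evalue=ScoringScheme().evalue(k, L, L),
                    )
                )
    hits.sort(key=lambda h: (-h.length, h.interval_a.start, h.interval_b.start,
                             h.orientation))
    return hits


# ---------------------------------------------------------------------------
# seeded ungapped local alignment (shared engine)


@dataclass(frozen=True)
class _Hsp:
    q_start: int  # 0-based inclusive, query frame
    s_start: int  # 0-based inclusive, subject frame (transformed)
    length: int
    score: float
    matches: int


def _extend_one_way(
    q: str, s: str, qi: int, si: int, step: int,
    scheme: ScoringScheme, xdrop: float,
) -> tuple[int, int, float]:
    """X-drop extension from (qi, si) exclusive, in direction ``step``.

    Returns (extension length, matches within it, score gained).
    """
    best, best_ext, best_m = 0.0, 0, 0
    cur, cur_m, k = 0.0, 0, 0
    while 0 <= qi + step * (k + 1) < len(q) and 0 <= si + step * (k + 1) < len(s):
        k += 1
        hit = q[qi + step * k] == s[si + step * k]
        cur += scheme.match if hit else scheme.mismatch
        cur_m += 1 if hit else 0
        if cur > best:
            best, best_ext, best_m = cur, k, cur_m
        if cur < best - xdrop:
            break
    return best_ext, best_m, best


def _xdrop_extend(
    q: str, s: str, qi: int, si: int, word: int,
    scheme: ScoringScheme, xdrop: float,
) -> _Hsp:
    """Ungapped extension of an exact word seed in both directions."""
    right, right_m, right_gain = _extend_one_way(
        q, s, qi + word - 1, si + word - 1, +1, scheme, xdrop
    )
    left, left_m, left_gain = _extend_one_way(q, s, qi, si, -1, scheme, xdrop)
    return _Hsp(
        q_start=qi - left,
        s_start=si - left,
        length=word + left + right,
        score=float(word * scheme.match + left_gain + right_gain),
        matches=word + left_m + right_m,
    )


def _seeded_hsps(
    query: str, subject: str, word: int, scheme: ScoringScheme,
    xdrop: float, skip_diagonal: bool, dust: bool,
    entropy_threshold: float = 1.0,
    circular_wrap: int = 0,
) -> list[_Hsp]:
    """All distinct ungapped HSPs from exact word seeds.

    ``circular_wrap`` extends both sequences by that many wrap-around
    characters for seeding; reported coordinates are reduced modulo the
    original length downstream.
    """
    qL, sL = len(query), len(subject)
    q = query + query[: circular_wrap]
    s = subject + subject[: circular_wrap]
    # seeds stay within the original coordinate range; extension may run
    # into the wrapped copy so origin-spanning HSPs come out full length
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(min(len(s) - word + 1, sL)):
        w = s[j : j + word]
        if dust and _low_complexity(w, entropy_threshold):
            continue
        index[w].append(j)
    done_diags: dict[int, int] = {}  # diagonal -> rightmost q covered
    out: dict[tuple[int, int], _Hsp] = {}
    for i in range(min(len(q) - word + 1, qL)):
        w = q[i : i + word]
        if dust and _low_complexity(w, entropy_threshold):
            continue
        for j in index.get(w, ()):
            if skip_diagonal and (i % qL) == (j % sL):
                continue
            diag = i - j
            if done_diags.get(diag, -1) >= i:
                continue  # seed inside an HSP already extended on this diagonal
            hsp = _xdrop_extend(q, s, i, j, word, scheme, xdrop)
            done_diags[diag] = hsp.q_start + hsp.length - 1
            out[(hsp.q_start, hsp.s_start)] = hsp
    return list(out.values())


def find_interspersed_repeats(
    genome: GenomeSequence | str,
    word: int = 11,
    evalue_max: float = 1e-10,
    scheme: ScoringScheme = ScoringScheme(),
    xdrop: float = 20.0,
    dust: bool = True,
) -> list[RepeatHit]:
    """Self-comparison of the genome (both strands) for interspersed repeats.

    The genome is compared against itself (forward hits) and against its
    reverse complement (palindromic hits), the trivial main diagonal is
    masked, mirror duplicates (a,b)/(b,a) are collapsed, and hits are kept
    when their Karlin-Altschul E-value is below ``evalue_max``. Results are
    sorted by score, best first.
    """
    if word < 8:
        raise ValueError("word size must be >= 8")
    if isinstance(genome, GenomeSequence):
        s = genome.residues
        circular = genome.circular
    else:
        s, circular = genome.upper(), False
    L = len(s)
    if L < word:
        return []
    wrap = L if circular else 0  # full doubling finds origin spanners once
    hits: list[RepeatHit] = []
    seen: set[tuple[tuple[int, int], tuple[int, int], str]] = set()
    for orientation, subject in (("forward", s), ("palindromic",
                                                  reverse_complement(s))):
        hsps = _seeded_hsps(
            s, subject, word, scheme, xdrop,
            skip_diagonal=(orientation == "forward"),
            dust=dust, circular_wrap=wrap,
        )
        for h in hsps:
            ev = scheme.evalue(h.score, L, L)
            if ev >= evalue_max:
                continue
            qa = (h.q_start % L, h.q_start % L + h.length)
            sb0 = h.s_start % L
            b0, _ = _map_back(sb0, h.length, L, orientation)
            b0 %= L
            b = (b0, b0 + h.length)
            if qa == b:
                continue
            pair = _canonical_pair(qa, b)
            key = (pair[0], pair[1], orientation)
            if key in seen:
                continue
            seen.add(key)
            (a0, a1), (b0, b1) = pair
            hits.append(
                RepeatHit(
                    interval_a=Interval(a0 + 1, min(a1, L) if a1 <= L else a1 - L),
                    interval_b=Interval(b0 + 1, min(b1, L) if b1 <= L else b1 - L),
                    orientation=orientation,
                    length=h.length,
                    identity=100.0 * h.matches / h.length,
                    score=h.score,
                    evalue=ev,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.interval_a.start, h.interval_b.start))
    return hits


# ---------------------------------------------------------------------------
# tandem repeats


def _consensus(copies: list[str]) -> str:
    period = len(copies[0])
    cols = []
    for k in range(period):
        col = [c[k] for c in copies if k < len(c)]
        cols.append(max(sorted(set(col)), key=col.count))
    return "".join(cols)


def find_tandem_repeats(
    genome: GenomeSequence | str,
    min_total: int = 11,
    max_period: int = 500,
    min_identity: float = 80.0,
) -> list[TandemRepeat]:
    """Arrays of >=2 adjacent copies of a period-p motif, total length > 10 bp.

    Detection scans each candidate period p for runs of positions where
    ``s[i] == s[i+p]`` (allowing mismatches down to ``min_identity`` percent
    within a run), which flags arrays with internal period-p structure.
    Overlapping calls with different periods are reduced to the
    highest-scoring (then smallest-period) call; copy number is reported to
    0.1 resolution.
    """
    s = genome.residues if isinstance(genome, GenomeSequence) else genome.upper()
    L = len(s)
    candidates: list[TandemRepeat] = []
    max_p = min(max_period, L // 2)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for p in range(1, max_p + 1):
        eq = arr[:-p] == arr[p:]
        # maximal exact runs of lag-p agreement, vectorized
        padded = np.concatenate([[False], eq, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]  # half-open runs of True
        lengths = ends - starts
        # a run of length r spans an array of r + p positions (>= 2 copies
        # needs r >= p); merge neighbouring substantial runs across few
        # mismatches when identity stays high, which picks up degenerate
        # copies without letting chance matches smear array boundaries
        core = np.flatnonzero(lengths >= p)
        used = np.zeros(len(starts), dtype=bool)
        for idx in core:
            if used[idx]:
                continue
            a, b = int(starts[idx]), int(ends[idx])
            matches, mism = int(lengths[idx]), 0
            j = idx
            while j + 1 < len(starts):
                gap = int(starts[j + 1]) - int(ends[j])
                nxt = int(lengths[j + 1])
                # merge only when both sides carry >= 2 full copies of
                # structure, so chance background matches cannot smear a
                # planted boundary
                if (
                    min(nxt, matches) >= 2 * p
                    and gap <= 2
                    and 100.0 * (matches + nxt)
                    / (matches + nxt + mism + gap) >= min_identity
                ):
                    b = int(ends[j + 1])
                    matches += nxt
                    mism += gap
                    used[j + 1] = True
                    j += 1
                else:
                    break
            run = b - a
            total = run + p
            if total >= min_total and run >= p:
                seg = s[a : a + total]
                full = [seg[k : k + p] for k in range(0, total - p + 1, p)]
                candidates.append(
                    TandemRepeat(
                        interval=Interval(a + 1, a + total),
                        period=p,
                        copies=round(total / p, 1),
                        consensus=_consensus(full),
                        total_length=total,
                        identity=round(100.0 * matches / (matches + mism), 2),
                    )
                )
    # reduce overlapping calls: best score first (longer exact-matched span,
    # then smaller period); a candidate is dropped when it shares at least
    # half of the shorter span with a kept call, which removes harmonic
    # duplicates (period 2p over a period-p array) but keeps neighbours
    candidates.sort(
        key=lambda t: (-(t.total_length * t.identity), t.period, t.interval.start)
    )
    kept: list[TandemRepeat] = []
    occupied = np.zeros(L, dtype=np.int8)
    for cand in candidates:
        a, b = cand.interval.start - 1, cand.interval.end
        if int(occupied[a:b].sum()) >= 0.5 * (b - a):
            continue
        occupied[a:b] = 1
        kept.append(cand)
    kept.sort(key=lambda t: t.interval.start)
    return kept


# ---------------------------------------------------------------------------
# mito <-> nuclear transfer fragments


def find_transfer_fragments(
    mito: GenomeSequence | str,
    nuclear: GenomeSequence | str,
    evalue_max: float = 1e-10,
    word: int = 11,
    scheme: ScoringScheme = ScoringScheme(),
    xdrop: float = 20.0,
    annotation: MitogenomeAnnotation | None = None,
    min_length: int = 0,
) -> list[TransferFragment]:
    """Local alignments of the mitogenome against a nuclear sequence.

    Both nuclear strands are searched. When ``annotation`` is supplied each
    fragment lists the mitochondrial genes (exons or introns) it overlaps.
    """
    m = mito.residues if isinstance(mito, GenomeSequence) else mito.upper()
    n = nuclear.residues if isinstance(nuclear, GenomeSequence) else nuclear.upper()
    if not m or not n:
        raise ValueError("both sequences must be non-empty")
    mL, nL = len(m), len(n)
    out: list[TransferFragment] = []
    seen: set[tuple[int, int, int]] = set()
    for strand, subject in (("+", n), ("-", reverse_complement(n))):
        hsps = _seeded_hsps(m, subject, word, scheme, xdrop,
                            skip_diagonal=False, dust=True)
        for h in hsps:
            ev = scheme.evalue(h.score, mL, nL)
            if ev >= evalue_max or h.length < min_length:
                continue
            if strand == "+":
                ns, ne = h.s_start, h.s_start + h.length
            else:
                ns, ne = nL - (h.s_start + h.length), nL - h.s_start
            key = (h.q_start, ns, h.length)
            if key in seen:
                continue
            seen.add(key)
            mito_iv = Interval(h.q_start + 1, h.q_start + h.length)
            feats: tuple[str, ...] = ()
            if annotation is not None:
                feats = _overlapped_features(annotation, mito_iv)
            out.append(
                TransferFragment(
                    mito_interval=mito_iv,
                    nuclear_interval=Interval(ns + 1, ne,
                                              "+" if strand == "+" else "-"),
                    identity=100.0 * h.matches / h.length,
                    length=h.length,
                    score=h.score,
                    evalue=ev,
                    overlapped_mito_features=feats,
                )
            )
    out.sort(key=lambda f: (-f.score, f.mito_interval.start))
    return out


def _overlapped_features(
    annotation: MitogenomeAnnotation, iv: Interval
) -> tuple[str, ...]:
    L = annotation.genome.length
    pos = set(iv.positions(L))
    names: list[str] = []
    for g in annotation.genes:
        if any(p in pos for e in g.exons for p in e.positions(L)):
            names.append(g.name)
    for i in annotation.introns:
        if any(p in pos for p in i.location.positions(L)):
            names.append(f"{i.host_gene}_intron{i.ordinal}")
    return tuple(dict.fromkeys(names))


# ---------------------------------------------------------------------------
# coverage


def repeat_coverage(
    hits: list[RepeatHit], genome_length: int
) -> tuple[int, float]:
    """Union of all hit intervals (both members), as bp and percent of genome.

    Positions covered by several hits count once.
    """
    covered = np.zeros(genome_length, dtype=bool)
    for h in hits:
        for iv in (h.interval_a, h.interval_b):
            for a, b in iv.slices(genome_length):
                covered[a:b] = True
    bp = int(covered.sum())
    return bp, 100.0 * bp / genome_length
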