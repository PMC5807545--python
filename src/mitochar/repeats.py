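"""Tandem repeats, palindromes / inverted repeats, and motif occurrence.

Tandem repeats are found by a shift-match scan: position i is part of a
period-p array when sequence[i] == sequence[i+p]; maximal runs of such
matches of length L define an array spanning L + p bases, i.e. (L + p)/p
copies.  A bounded fraction of isolated mismatches inside the run is
tolerated.  This exact-core scan deterministically recovers planted repeats
with zero mismatches and reports a consensus (column majority over complete
copies).

Palindromes follow the EMBOSS convention: an inverted repeat is a span whose
two arms are reverse complements around a center (an optional unpaired loop
of up to ``max_loop`` bases); a mirror repeat reads the same forwards and
backwards literally.  Hits are center-maximal: the arms cannot be extended
symmetrically by one more base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._codes import revcomp

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class RepeatHit:
    start: int      # 1-based
    period: int
    copies: float
    consensus: str
    mismatches: int

    @property
    def span(self) -> int:
        return int(round(self.period * self.copies))


@dataclass(frozen=True)
class PalindromeHit:
    start: int  # 1-based
    end: int    # inclusive
    length: int
    mode: str   # inverted | mirror
    sequence: str


def _runs_with_mismatch(match: list[bool], max_mismatch_frac: float):
    """Maximal segments of `match` that begin and end on a match and carry at
    most floor(frac * (segment + period)) mismatches; greedy left-to-right."""
    n = len(match)
    segs = []
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        j = i
        mism = 0
        best_j = i
        while j < n:
            if match[j]:
                best_j = j
            else:
                mism += 1
                if mism > max_mismatch_frac * (j - i + 1):
                    break
            j += 1
        segs.append((i, best_j))
        i = best_j + 1
    return segs


def find_tandem_repeats(
    sequence: str,
    min_period: int = 10,
    max_period: int = 200,
    min_copies: float = 2.0,
    max_mismatch_frac: float = 0.2,
) -> list[RepeatHit]:
    """All maximal, non-redundant tandem arrays with period in range.

    A hit whose span is covered by another hit of a smaller period that
    divides its period (the same array re-detected at a multiple of its true
    period) is suppressed.  Output is sorted by start, then period.
    """
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    hits: list[RepeatHit] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        match = [seq[i] == seq[i + p] for i in range(n - p)]
        for i, j in _runs_with_mismatch(match, max_mismatch_frac):
            run_len = j - i + 1
            copies = (run_len + p) / p
            if copies + 1e-9 < min_copies:
                continue
            span = run_len + p
            full = span // p
            cols = [
                Counter(seq[i + c * p + k] for c in range(full)) for k in range(p)
            ]
            consensus = "".join(max(sorted(c), key=c.get) for c in cols)
            mism = sum(
                seq[i + c * p + k] != consensus[k]
                for k in range(p)
                for c in range(full)
            )
            hits.append(RepeatHit(i + 1, p, round(copies, 3), consensus, mism))

    hits.sort(key=lambda h: (h.start, h.period))
    kept: list[RepeatHit] = []
    for h in hits:
        redundant = any(
            k.period < h.period
            and h.period % k.period == 0
            and k.start <= h.start
            and k.start + k.span >= h.start + h.span
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def _arm_len(seq: str, left: int, right: int, mode: str) -> int:
    """Longest arm pairing seq[left-k] with seq[right+k] under the mode."""
    n = len(seq)
    k = 0
    while left - k >= 0 and right + k < n:
        a, b = seq[left - k], seq[right + k]
        ok = (_COMP.get(a) == b) if mode == "inverted" else (a == b)
        if not ok:
            break
        k += 1
    return k


def find_palindromes(
    sequence: str, min_len: int = 6, mode: str = "inverted", max_loop: int = 0
) -> list[PalindromeHit]:
    """All center-maximal palindromic spans of total length >= min_len.

    For inverted mode a center loop of up to ``max_loop`` unpaired bases is
    allowed; mirror mode additionally has odd-length hits with a single
    center base.  Duplicate spans arising from different loop sizes are
    reported once (smallest loop wins).
    """
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    if mode not in ("inverted", "mirror"):
        raise ValueError("mode must be 'inverted' or 'mirror'")
    seq = sequence.upper()
    n = len(seq)
    seen: set[tuple[int, int]] = set()
    hits: list[PalindromeHit] = []
    loops = range(0, max_loop + 1) if mode == "inverted" else (0, 1)
    for gap in loops:
        for c in range(n - gap + 1):
            left, right = c - 1, c + gap
            k = _arm_len(seq, left, right, mode)
            total = 2 * k + gap
            if k >= 1 and total >= min_len:
                s, e = left - k + 1, right + k - 1
                if (s, e) not in seen:
                    seen.add((s, e))
                    hits.append(
                        PalindromeHit(s + 1, e + 1, total, mode, seq[s : e + 1])
                    )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def count_motif(sequence: str, motif: str, max_mismatch: int = 0) -> list[int]:
    """1-based start positions of all (possibly overlapping) motif matches."""
    seq, motif = sequence.upper(), motif.upper()
    m = len(motif)
    if m > len(seq):
        raise ValueError("motif longer than sequence")
    out = []
    for i in range(len(seq) - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], motif):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            out.append(i + 1)
    return out


__all__ = [
    "RepeatHit",
    "PalindromeHit",
    "find_tandem_repeats",
    "find_palindromes",
    "count_motif",
]
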