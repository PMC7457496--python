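"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seeded/indexed code paths: repeats are
found by scanning every diagonal in full, SSRs by unit-level enumeration, and
read alignment by a plain dynamic-programming matrix.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _transform(g: str, kind: str) -> str:
    if kind == "forward":
        return g
    if kind == "reverse":
        return g[::-1]
    if kind == "complement":
        return "".join(_COMP[c] for c in g)
    if kind == "palindromic":
        return "".join(_COMP[c] for c in reversed(g))
    raise ValueError(kind)


def brute_force_repeats(g: str, kinds, min_length: int, max_hamming: int):
    """All maximal repeat pairs, via full scans of every diagonal."""
    n = len(g)
    found = {}
    for kind in kinds:
        t = _transform(g, kind)
        for d in range(-(n - 1), n):
            lo, hi = max(0, -d), min(n, n - d)
            if hi - lo < min_length:
                continue
            mism = [i for i in range(lo, hi) if g[i] != t[i + d]]
            m = len(mism)
            candidates = set()
            for a in range(-1, m):
                b = min(a + max_hamming + 1, m)
                start = lo if a == -1 else mism[a] + 1
                end = hi if b == m else mism[b]
                candidates.add((start, end))
            for start, end in candidates:
                if end - start < min_length:
                    continue
                ham = sum(1 for p in mism if start <= p < end)
                grow_left = start > lo and ham < max_hamming
                grow_right = end < hi and ham < max_hamming
                if grow_left or grow_right:
                    continue
                length = end - start
                if kind in ("forward", "complement"):
                    j = start + d
                else:
                    j = n - (start + d) - length
                if kind == "forward" and start == j:
                    continue
                a1, a2 = min(start, j), max(start, j)
                found[(kind, a1, a2, length)] = ham
    return found


def brute_force_ssrs(g: str, min_repeats=(10, 6, 5, 3, 3, 3)):
    """Simple (non-compound) SSR hits as (start, end, motif, repeats)."""

    def minimal(motif: str) -> bool:
        for p in range(1, len(motif)):
            if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
                return False
        return True

    n = len(g)
    hits = []
    spans = []  # base-level run spans of already-reported smaller periods
    for m in range(1, 7):
        for start in range(n - m):
            if start > 0 and g[start - 1] == g[start - 1 + m]:
                continue  # same run starts earlier
            end = start + m
            while end < n and g[end] == g[end - m]:
                end += 1
            reps = (end - start) // m
            if reps < min_repeats[m - 1]:
                continue
            motif = g[start : start + m]
            if not minimal(motif):
                continue
            if any(s <= start and start + reps * m <= e for s, e in spans):
                continue
            hits.append((start, start + reps * m, motif, reps))
            spans.append((start, end))
    hits.sort()
    return hits


def local_alignment_best_score(
    ref: str, read: str, mismatch: int = 2, insertion: int = 3, deletion: int = 3
) -> float:
    """Smith-Waterman best score with match +1 and the given penalties,
    considering both read strands."""
    best = 0
    for query in (read, _revcomp(read)):
        rows = len(query) + 1
        cols = len(ref) + 1
        prev = [0] * cols
        for i in range(1, rows):
            cur = [0] * cols
            qc = query[i - 1]
            for j in range(1, cols):
                diag = prev[j - 1] + (1 if qc == ref[j - 1] else -mismatch)
                up = prev[j] - insertion  # consume read base, gap in reference
                left = cur[j - 1] - deletion  # consume reference base
                cur[j] = max(0, diag, up, left)
                if cur[j] > best:
                    best = cur[j]
            prev = cur
    return float(best)


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))
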