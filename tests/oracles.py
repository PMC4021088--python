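"""Independent exhaustive oracles for the scanners.

Each function recomputes a finder's result by full-scan mechanics (position
loops and per-offset/anti-diagonal equality arrays) with no shared code
with the implementation, which uses regex lookahead and k-mer
seed-and-extend.  Results are returned as plain tuples for set comparison.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_motif_hits(seq: str, pattern: str) -> set[tuple[int, int]]:
    """All (overlapping) occurrences of an IUPAC pattern, by position loop."""
    m = len(pattern)
    hits = set()
    for i in range(len(seq) - m + 1):
        if all(seq[i + t] in IUPAC[pattern[t]] for t in range(m)):
            hits.add((i, i + m))
    return hits


def brute_at_runs(seq: str, min_run: int) -> set[tuple[int, int]]:
    hits = set()
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in "AT":
            j = i
            while j < n and seq[j] in "AT":
                j += 1
            if j - i >= min_run:
                hits.add((i, j))
            i = j
        else:
            i += 1
    return hits


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop) of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def brute_direct_repeats(
    seq: str, min_len: int
) -> set[tuple[int, int, int, int]]:
    """Maximal identical non-overlapping pairs via per-offset diagonal scan.

    For each spacing d >= min_len, positionwise equality seq[x] == seq[x+d]
    is scanned for maximal runs of length R >= min_len; each run yields one
    pair with arm length min(R, d) anchored at the run start.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    out = set()
    for d in range(min_len, n):
        eq = arr[: n - d] == arr[d:]
        for s, stop in _runs_of_true(eq):
            run_len = stop - s
            if run_len >= min_len:
                arm = min(run_len, d)
                out.add((s, s + arm, s + d, s + d + arm))
    return out


def brute_inverted_repeats(
    seq: str, min_stem: int
) -> set[tuple[int, int, int, int]]:
    """Maximal stems via full anti-diagonal complementarity scans.

    On anti-diagonal u + v = C, positions u (arm2) pair with v = C - u
    (arm1).  Non-overlap confines u to u > C/2; each maximal run of
    complementarity of length >= min_stem yields one stem.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_arr = np.frombuffer(
        "".join(COMP[b] for b in seq).encode(), dtype=np.uint8
    )
    out = set()
    for C in range(2 * n - 1):
        u_min = max(C // 2 + 1, C - n + 1)
        u_max = min(n - 1, C)
        if u_max - u_min + 1 < min_stem:
            continue
        u = np.arange(u_min, u_max + 1)
        mask = arr[u] == comp_arr[C - u]
        for s, stop in _runs_of_true(mask):
            L = stop - s
            if L >= min_stem:
                j = u_min + s  # arm2 start
                b = u_min + stop - 1  # last arm2 position
                i = C - b  # arm1 start
                out.add((i, i + L, j, j + L))
    return out


def brute_palindromes(seq: str, min_len: int) -> set[tuple[int, int]]:
    """Maximal even self-reverse-complement substrings by enumeration."""
    n = len(seq)
    out = set()
    for i in range(n):
        for L in range(min_len, n - i + 1, 2):
            sub = seq[i : i + L]
            if sub != revcomp(sub):
                continue
            extendable = (
                i > 0 and i + L < n and seq[i - 1] == COMP[seq[i + L]]
            )
            if not extendable:
                out.add((i, i + L))
    return out
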