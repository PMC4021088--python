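"""Excluded-feature screening for candidate coding sequences.

Transgenes transcribed in a heterologous host can be silenced or truncated
by unintended sequence features: cryptic polyadenylation signals, AU-rich
instability elements, cryptic splice signals, AT-rich runs, direct repeats,
and self-complementary regions whose transcripts fold into double-stranded
stems (silencing triggers).  This module locates every such feature in a
candidate so the optimizer can resample the offending codons.

All finders return :class:`Violation` records with 0-based half-open
coordinates on the forward strand, sorted deterministically.

Definitions used by the pair finders (direct and inverted repeats) need a
precise notion of "maximal, reported once":

* direct repeat — for every spacing ``d`` between two occurrences, each
  maximal run of position-wise equality ``seq[i] == seq[i+d]`` of length
  ``R >= min_len`` yields exactly one violation whose arm length is
  ``min(R, d)`` (an arm longer than ``d`` would overlap its partner),
  anchored at the run start;
* inverted repeat — on every anti-diagonal ``i + j = const``, each maximal
  run of complementarity ``seq[j] == complement(seq[i])`` on the
  non-overlapping half yields exactly one stem, whose arms meet at the
  center when the loop closes to zero.

These rules make every reported feature non-extendable in any direction and
give an unambiguous target for exhaustive cross-checking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidParameterError, PatternError
from .genetics import (
    IUPAC_CODES,
    check_dna,
    complement_base,
    gc_fraction,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Domain types

MOTIF_CATEGORIES = (
    "polyadenylation",
    "splice_signal",
    "rna_instability",
    "restriction_site",
    "user",
)

VIOLATION_KINDS = (
    "motif",
    "at_run",
    "direct_repeat",
    "palindrome",
    "inverted_repeat",
    "restriction_site",
    "gc_window",
)


@dataclass(frozen=True)
class MotifPattern:
    """An excluded sequence element as an IUPAC degenerate DNA pattern."""

    pattern: str
    label: str
    category: str = "user"

    def __post_init__(self) -> None:
        if self.category not in MOTIF_CATEGORIES:
            raise PatternError(
                f"unknown motif category {self.category!r} for {self.label!r}"
            )
        if len(self.pattern) < 4:
            raise PatternError(
                f"pattern {self.label!r} is shorter than 4 bases: {self.pattern!r}"
            )
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise PatternError(
                f"pattern {self.label!r} has non-IUPAC character(s): "
                f"{', '.join(sorted(bad))}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def to_regex(self) -> re.Pattern[str]:
        """Compile to a lookahead regex yielding overlapping matches."""
        body = "".join(
            b if len(IUPAC_CODES[b]) == 1 else "[" + "".join(sorted(IUPAC_CODES[b])) + "]"
            for b in self.pattern
        )
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True, order=True)
class Violation:
    """A located breach of one design rule.

    ``start``/``end`` delimit the offending subsequence on the forward
    strand; for paired features (direct and inverted repeats) they delimit
    the first arm and ``mate`` delimits the second.  ``matched`` always
    equals the sequence slice ``[start, end)``.
    """

    start: int
    end: int
    kind: str
    label: str
    matched: str = field(compare=False)
    mate: tuple[int, int] | None = field(default=None, compare=False)
    strand: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in VIOLATION_KINDS:
            raise InvalidParameterError(f"unknown violation kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise InvalidParameterError(
                f"bad violation interval [{self.start}, {self.end})"
            )


#: Default excluded-motif set: canonical plant polyadenylation signals,
#: the AU-rich RNA instability element, and splice donor/acceptor
#: consensus patterns.  Fully user-replaceable; see `io.read_motif_table`.
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("AATAAA", "polyA_AATAAA", "polyadenylation"),
    MotifPattern("AATAAT", "polyA_AATAAT", "polyadenylation"),
    MotifPattern("ATTTA", "ARE_ATTTA", "rna_instability"),
    MotifPattern("GTAAGT", "splice_donor", "splice_signal"),
    MotifPattern("TTNCAG", "splice_acceptor", "splice_signal"),
)

NOTI_SITE = "GCGGCCGC"
PACI_SITE = "TTAATTAA"

DEFAULT_FORBIDDEN_SITES: tuple[MotifPattern, ...] = (
    MotifPattern(NOTI_SITE, "NotI", "restriction_site"),
    MotifPattern(PACI_SITE, "PacI", "restriction_site"),
)


@dataclass(frozen=True)
class DesignConstraints:
    """The full exclusion rule set applied by :func:`screen`.

    Parameters
    ----------
    motifs:
        IUPAC patterns to exclude (polyadenylation signals, instability
        elements, splice signals...).
    min_at_run:
        Minimum length of a pure A/T run (mixed allowed) to flag.
    min_direct_repeat:
        Minimum arm length of a flagged direct repeat.
    min_palindrome:
        Minimum (even) length of a flagged self-reverse-complement
        substring.
    min_stem:
        Minimum arm length of a flagged inverted repeat — the transcript
        would fold into a double-stranded stem of this many base pairs.
    forbidden_sites:
        Restriction sites that must stay absent from the ORF body so the
        flanking cloning sites remain unique.
    gc_target, gc_window:
        Acceptable global G+C percent is ``gc_target ± gc_window``.
    scan_both_strands:
        Scan motifs on the reverse strand too (restriction-site patterns
        are scanned as given; the NotI/PacI defaults are their own reverse
        complements, so strand is moot for them).
    """

    motifs: tuple[MotifPattern, ...] = DEFAULT_MOTIFS
    min_at_run: int = 6
    min_direct_repeat: int = 10
    min_palindrome: int = 8
    min_stem: int = 12
    forbidden_sites: tuple[MotifPattern, ...] = DEFAULT_FORBIDDEN_SITES
    gc_target: float = 55.0
    gc_window: float = 3.0
    scan_both_strands: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        object.__setattr__(self, "forbidden_sites", tuple(self.forbidden_sites))
        if self.min_stem < 2:
            raise InvalidParameterError("min_stem must be >= 2")
        if self.min_palindrome % 2 != 0 or self.min_palindrome < 4:
            raise InvalidParameterError("min_palindrome must be even and >= 4")
        if self.min_at_run < 2:
            raise InvalidParameterError("min_at_run must be >= 2")
        if self.min_direct_repeat < 4:
            raise InvalidParameterError("min_direct_repeat must be >= 4")
        if not 0.0 < self.gc_target < 100.0:
            raise InvalidParameterError("gc_target must be in (0, 100)")
        if self.gc_window <= 0:
            raise InvalidParameterError("gc_window must be positive")


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a full screen: all violations plus summary counts."""

    violations: tuple[Violation, ...]
    counts: dict[str, int]
    gc_percent: float
    gc_ok: bool

    @property
    def clean(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Finders


def scan_motifs(
    seq: str,
    patterns: list[MotifPattern] | tuple[MotifPattern, ...],
    *,
    kind: str = "motif",
    both_strands: bool = False,
) -> list[Violation]:
    """Every (overlapping) occurrence of each pattern, sorted by start.

    With ``both_strands`` the reverse strand is scanned too and minus-strand
    hits are reported in forward coordinates with ``strand='-'``; ``matched``
    is then the forward-strand slice under the hit.
    """
    check_dna(seq)
    hits: list[Violation] = []
    n = len(seq)
    for pat in patterns:
        rx = pat.to_regex()
        m = len(pat.pattern)
        for match in rx.finditer(seq):
            s = match.start()
            hits.append(
                Violation(s, s + m, kind, pat.label, seq[s : s + m])
            )
        if both_strands:
            rc = reverse_complement(seq)
            for match in rx.finditer(rc):
                s_rc = match.start()
                s, e = n - (s_rc + m), n - s_rc
                hits.append(
                    Violation(s, e, kind, pat.label, seq[s:e], strand="-")
                )
    return sorted(hits)


_AT_RUN_RE = re.compile(r"[AT]+")


def find_at_runs(seq: str, min_run: int = 6) -> list[Violation]:
    """Maximal runs consisting only of A/T (mixed) of length >= min_run."""
    check_dna(seq)
    if min_run < 2:
        raise InvalidParameterError("min_run must be >= 2")
    out = []
    for m in _AT_RUN_RE.finditer(seq):
        if m.end() - m.start() >= min_run:
            out.append(
                Violation(m.start(), m.end(), "at_run", "at_run", m.group())
            )
    return out


def find_direct_repeats(seq: str, min_len: int = 10) -> list[Violation]:
    """Maximal pairs of identical non-overlapping substrings, arm >= min_len.

    Seed-and-extend: every exact ``min_len``-mer match at spacing
    ``d >= min_len`` seeds an equality run that is extended maximally; the
    reported arm is capped at ``d`` so the two copies never overlap.
    """
    check_dna(seq)
    if min_len < 4:
        raise InvalidParameterError("min_len must be >= 4")
    n = len(seq)
    k = min_len
    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    # seeds grouped by spacing d; consecutive seed positions merge into runs
    by_offset: dict[int, list[int]] = {}
    for pos_list in positions.values():
        if len(pos_list) < 2:
            continue
        for a in range(len(pos_list)):
            for b in range(a + 1, len(pos_list)):
                d = pos_list[b] - pos_list[a]
                if d >= k:
                    by_offset.setdefault(d, []).append(pos_list[a])

    out: list[Violation] = []
    for d, starts in by_offset.items():
        starts = sorted(set(starts))
        run_start = prev = starts[0]
        runs: list[tuple[int, int]] = []
        for s in starts[1:]:
            if s == prev + 1:
                prev = s
            else:
                runs.append((run_start, prev))
                run_start = prev = s
        runs.append((run_start, prev))
        for s, e in runs:
            run_len = e - s + k  # equality run seq[s:s+run_len] == shifted
            arm = min(run_len, d)
            out.append(
                Violation(
                    s,
                    s + arm,
                    "direct_repeat",
                    "direct_repeat",
                    seq[s : s + arm],
                    mate=(s + d, s + d + arm),
                )
            )
    return sorted(out, key=lambda v: (v.start, v.end, v.mate))


def find_inverted_repeats(seq: str, min_stem: int = 12) -> list[Violation]:
    """Maximal stems: arm2 (later) equals the reverse complement of arm1.

    Loop length is unconstrained (zero loop = a palindrome).  Seeds are
    exact reverse-complement ``min_stem``-mer matches, extended outward and
    inward until a mismatch or until the arms would overlap.
    """
    check_dna(seq)
    if min_stem < 2:
        raise InvalidParameterError("min_stem must be >= 2")
    n = len(seq)
    k = min_stem
    if n < 2 * k:
        return []
    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    found: set[tuple[int, int, int]] = set()  # (arm1_start, arm2_start, L)
    for j in range(n - k + 1):
        rc = reverse_complement(seq[j : j + k])
        for i in positions.get(rc, ()):
            if i + k > j:
                continue  # arms overlap or wrong order
            # extend outward: arm1 grows left, arm2 grows right
            L, ii, jj = k, i, j
            while ii > 0 and jj + L < n and seq[ii - 1] == complement_base(seq[jj + L]):
                ii -= 1
                L += 1
            # extend inward: arm1 grows right, arm2 grows left
            while jj - 1 >= ii + L + 1 and seq[ii + L] == complement_base(seq[jj - 1]):
                jj -= 1
                L += 1
            found.add((ii, jj, L))

    out = [
        Violation(
            i,
            i + L,
            "inverted_repeat",
            "inverted_repeat",
            seq[i : i + L],
            mate=(j, j + L),
        )
        for i, j, L in found
    ]
    return sorted(out, key=lambda v: (v.start, v.end, v.mate))


def find_palindromes(seq: str, min_len: int = 8) -> list[Violation]:
    """Maximal even-length substrings equal to their own reverse complement.

    Center expansion: for every inter-base center the complementarity radius
    is grown until a mismatch; one maximal hit per center with length
    >= min_len.
    """
    check_dna(seq)
    if min_len % 2 != 0 or min_len < 4:
        raise InvalidParameterError("min_len must be even and >= 4")
    n = len(seq)
    out = []
    for c in range(1, n):
        r = 0
        while c - r - 1 >= 0 and c + r < n and seq[c - r - 1] == complement_base(seq[c + r]):
            r += 1
        if 2 * r >= min_len:
            out.append(
                Violation(
                    c - r, c + r, "palindrome", "palindrome", seq[c - r : c + r]
                )
            )
    return out


_KIND_ORDER = {kind: i for i, kind in enumerate(VIOLATION_KINDS)}


def screen(seq: str, constraints: DesignConstraints | None = None) -> ScreenReport:
    """Run every finder plus the global GC check; deterministic ordering."""
    if constraints is None:
        constraints = DesignConstraints()
    check_dna(seq)
    c = constraints
    violations: list[Violation] = []
    violations += scan_motifs(
        seq, c.motifs, kind="motif", both_strands=c.scan_both_strands
    )
    violations += scan_motifs(
        seq, c.forbidden_sites, kind="restriction_site",
        both_strands=c.scan_both_strands,
    )
    violations += find_at_runs(seq, c.min_at_run)
    violations += find_direct_repeats(seq, c.min_direct_repeat)
    violations += find_palindromes(seq, c.min_palindrome)
    violations += find_inverted_repeats(seq, c.min_stem)

    gc = 100.0 * gc_fraction(seq)
    gc_ok = abs(gc - c.gc_target) <= c.gc_window
    if not gc_ok:
        violations.append(
            Violation(0, len(seq), "gc_window", "gc_window", seq)
        )

    violations.sort(key=lambda v: (v.start, _KIND_ORDER[v.kind], v.end, v.label))
    counts: dict[str, int] = {k: 0 for k in VIOLATION_KINDS}
    for v in violations:
        counts[v.kind] += 1
    return ScreenReport(
        violations=tuple(violations), counts=counts, gc_percent=gc, gc_ok=gc_ok
    )
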