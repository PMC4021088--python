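"""Codon-usage tables and rare-codon filtering.

A :class:`CodonUsageTable` tallies codon counts over a training set of host
coding sequences (or a pre-built Kazusa-style export) and derives, for each
amino acid, the *relative synonymous frequency* of every codon — its share
within the family of codons encoding that amino acid.  Host-biased reverse
translation then samples from an :class:`AllowedCodonSet`, the per-family
distribution left after codons whose relative frequency falls below a
threshold (20% by default) are discarded and the survivors renormalized.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import (
    EmptyInputError,
    IncompleteTableError,
    InvalidThresholdError,
    KazusaParseError,
    RecodonError,
)
from .genetics import STANDARD_CODE, GeneticCode, codons_of

logger = logging.getLogger(__name__)

DEFAULT_RARE_THRESHOLD = 0.20


def _relative_frequencies(
    counts: dict[str, int], code: GeneticCode
) -> dict[str, float]:
    """Per-family relative synonymous frequencies; uniform for empty families."""
    rel: dict[str, float] = {}
    for _aa, family in code.families().items():
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                rel[c] = 1.0 / len(family)
        else:
            for c in family:
                rel[c] = counts.get(c, 0) / total
    return rel


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts and per-family relative synonymous frequencies.

    Attributes
    ----------
    counts:
        Raw codon tallies over the training CDS set (all 64 codons present,
        zeros allowed).
    rel_freq:
        Relative synonymous frequency of each codon, normalized within its
        amino-acid family; families with zero total count get uniform
        frequencies.
    n_cds:
        Number of coding sequences tallied (0 for parsed tables where the
        training-set size is unknown).
    source_label:
        Free-text provenance.
    """

    counts: dict[str, int]
    rel_freq: dict[str, float]
    n_cds: int = 0
    source_label: str = ""
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        *,
        n_cds: int = 0,
        source_label: str = "",
        code: GeneticCode = STANDARD_CODE,
    ) -> "CodonUsageTable":
        missing = set(code.table) - set(counts)
        full = {c: int(counts.get(c, 0)) for c in code.table}
        if any(v < 0 for v in full.values()):
            raise RecodonError("codon counts must be non-negative")
        del missing  # absent codons are zero-filled, not an error here
        return cls(
            counts=full,
            rel_freq=_relative_frequencies(full, code),
            n_cds=n_cds,
            source_label=source_label,
            code=code,
        )

    def family_frequencies(self, amino_acid: str) -> dict[str, float]:
        return {c: self.rel_freq[c] for c in self.code.synonymous_codons(amino_acid)}

    def gc_percent_of_counts(self) -> float:
        """GC percent of the tallied codon population (training-set GC)."""
        total = bases = 0
        for codon, n in self.counts.items():
            total += 3 * n
            bases += n * (codon.count("G") + codon.count("C"))
        if total == 0:
            raise EmptyInputError("usage table has zero total counts")
        return 100.0 * bases / total


def build_usage_table(
    cds_records: list[str],
    *,
    source_label: str = "",
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodonUsageTable, int]:
    """Tally a codon-usage table from coding sequences.

    Records that fail translation preconditions (bad alphabet, broken frame,
    internal stop) are skipped with a logged warning.  Returns the table and
    the number of skipped records.
    """
    if not cds_records:
        raise EmptyInputError("cannot build a usage table from zero sequences")
    counts: dict[str, int] = {c: 0 for c in code.table}
    skipped = 0
    used = 0
    for i, rec in enumerate(cds_records):
        try:
            codon_list = codons_of(rec)
        except RecodonError as exc:
            logger.warning("skipping CDS record %d: %s", i, exc)
            skipped += 1
            continue
        for codon in codon_list:
            counts[codon] += 1
        used += 1
    if used == 0:
        raise EmptyInputError("no translatable CDS records in input")
    table = CodonUsageTable.from_counts(
        counts, n_cds=used, source_label=source_label, code=code
    )
    return table, skipped


_CODON_RE = re.compile(r"^[ACGTU]{3}$")
_NUMBER_RE = re.compile(r"^\(?(\d+(?:\.\d+)?)\)?$")


def parse_kazusa_table(
    text: str, *, source_label: str = "kazusa", code: GeneticCode = STANDARD_CODE
) -> CodonUsageTable:
    """Parse a Kazusa-style codon-usage export into a table.

    The dialect is whitespace-separated entries of the form
    ``codon [amino-acid] [fraction] frequency-per-thousand (count)``; RNA
    codons (U) are accepted and converted to DNA.  Only the trailing count
    of each entry is trusted — relative frequencies are recomputed from the
    counts, never read from the file.
    """
    counts: dict[str, int] = {}
    current: str | None = None
    numbers: list[str] = []

    def _commit(lineno: int) -> None:
        nonlocal current, numbers
        if current is None:
            return
        if not numbers:
            raise KazusaParseError(
                f"line {lineno}: codon {current} has no count field"
            )
        raw = numbers[-1]
        m = _NUMBER_RE.match(raw)
        if m is None:
            raise KazusaParseError(
                f"line {lineno}: unparseable count {raw!r} for codon {current}"
            )
        if current in counts:
            raise KazusaParseError(f"line {lineno}: duplicate codon {current}")
        counts[current] = int(round(float(m.group(1))))
        current, numbers = None, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0]
        for token in line.replace(",", " ").split():
            if _CODON_RE.match(token.upper()):
                _commit(lineno)
                current = token.upper().replace("U", "T")
            elif _NUMBER_RE.match(token):
                numbers.append(token)
            elif current is not None and len(token) == 1:
                pass  # one-letter amino-acid column; ignored
            elif current is None:
                raise KazusaParseError(
                    f"line {lineno}: unexpected token {token!r} before any codon"
                )
            else:
                raise KazusaParseError(
                    f"line {lineno}: unexpected token {token!r} in entry for {current}"
                )
        _commit(lineno)

    missing = set(code.table) - set(counts)
    if missing:
        raise IncompleteTableError(missing)
    return CodonUsageTable.from_counts(counts, source_label=source_label, code=code)


@dataclass(frozen=True)
class AllowedCodonSet:
    """Threshold-filtered, renormalized per-amino-acid sampling distributions.

    ``allowed`` maps each amino acid (and ``*`` for stops) to a non-empty
    list of ``(codon, probability)`` pairs summing to 1.
    """

    allowed: dict[str, tuple[tuple[str, float], ...]]
    threshold_used: float

    def codons(self, amino_acid: str) -> tuple[str, ...]:
        return tuple(c for c, _p in self.allowed[amino_acid])

    def probabilities(self, amino_acid: str) -> tuple[float, ...]:
        return tuple(p for _c, p in self.allowed[amino_acid])


def filter_rare_codons(
    table: CodonUsageTable, threshold: float = DEFAULT_RARE_THRESHOLD
) -> AllowedCodonSet:
    """Drop codons whose relative synonymous frequency is below ``threshold``.

    A codon survives iff its per-family relative frequency is >= threshold;
    survivors are renormalized to sum to 1 within each family.  Single-codon
    amino acids (Met, Trp) always survive.  If an entire family would fall
    below threshold (possible only for families of 6 at thresholds > 1/6),
    the maximum-frequency codon is retained, ties broken by lexicographic
    codon order, so every protein remains encodable.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidThresholdError(
            f"threshold must be in [0, 1), got {threshold!r}"
        )
    allowed: dict[str, tuple[tuple[str, float], ...]] = {}
    for aa, family in table.code.families().items():
        freqs = {c: table.rel_freq[c] for c in family}
        if len(family) == 1:
            allowed[aa] = ((family[0], 1.0),)
            continue
        keep = {c: f for c, f in freqs.items() if f >= threshold}
        if not keep:
            best = max(sorted(freqs), key=lambda c: freqs[c])
            keep = {best: freqs[best]}
        total = sum(keep.values())
        allowed[aa] = tuple(
            (c, keep[c] / total) for c in sorted(keep)
        )
    # the stop "family" (*) is kept alongside the 20 amino acids
    return AllowedCodonSet(allowed=allowed, threshold_used=threshold)
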