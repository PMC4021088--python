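"""Genetic code, translation, and nucleotide alphabet utilities.

All sequences are uppercase DNA (``ACGT``); codons are DNA trinucleotides.
Coordinates throughout the package are 0-based, half-open, on the forward
strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import FrameError, InternalStopError, InvalidAlphabetError

DNA_ALPHABET = frozenset("ACGT")
STOP = "*"

#: IUPAC degenerate nucleotide codes mapped to the bases they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

def _build_standard_table() -> dict[str, str]:
    # NCBI translation table 1, taken from Biopython to guard against typos.
    from Bio.Data import CodonTable

    bio = CodonTable.unambiguous_dna_by_id[1]
    table = {c: aa for c, aa in bio.forward_table.items()}
    for c in bio.stop_codons:
        table[c] = STOP
    # Biopython omits nothing else: 61 sense + 3 stop = 64.
    assert len(table) == 64
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map.

    Parameters
    ----------
    table:
        Mapping from each of the 64 uppercase DNA codons to a one-letter
        amino acid, with ``*`` marking stops.
    id:
        Translation-table identifier (1 = the standard code).
    """

    table: dict[str, str] = field(default_factory=_build_standard_table)
    id: int = 1

    def __post_init__(self) -> None:
        codons = {a + b + c for a, b, c in itertools.product("ACGT", repeat=3)}
        if set(self.table) != codons:
            raise ValueError("genetic code must define exactly the 64 DNA codons")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == STOP))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({aa for aa in self.table.values() if aa != STOP}))

    def synonymous_codons(self, amino_acid: str) -> tuple[str, ...]:
        """Codons encoding ``amino_acid`` (or the stops, for ``'*'``)."""
        return tuple(sorted(c for c, aa in self.table.items() if aa == amino_acid))

    def families(self) -> dict[str, tuple[str, ...]]:
        """All synonymous-codon families, keyed by amino acid (incl. ``*``)."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.table):
            fams.setdefault(self.table[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}


STANDARD_CODE = GeneticCode()

AMINO_ACIDS = STANDARD_CODE.amino_acids  # the canonical 20, sorted


def check_dna(seq: str, *, what: str = "sequence") -> str:
    """Validate that ``seq`` is non-degenerate uppercase DNA and return it."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"{what} contains non-ACGT character(s): {', '.join(sorted(bad))}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def codons_of(cds: str) -> list[str]:
    """Split a CDS into its codons; raises on bad alphabet or frame."""
    check_dna(cds, what="CDS")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def split_orf(cds: str, code: GeneticCode = STANDARD_CODE) -> tuple[str, list[str]]:
    """Translate a CDS into (protein body, trailing stop codons).

    Trailing stop codons (one or more, at the very end) are stripped from
    the protein and returned separately.  A stop codon anywhere before the
    trailing block is an error: synonymous recoding must never interrupt
    the reading frame.
    """
    codon_list = codons_of(cds)
    aas = [code.table[c] for c in codon_list]
    n_stops = 0
    while aas and aas[-1] == STOP:
        aas.pop()
        n_stops += 1
    if STOP in aas:
        pos = aas.index(STOP)
        raise InternalStopError(
            f"internal stop codon {codon_list[pos]} at codon {pos}"
        )
    stops = codon_list[len(codon_list) - n_stops :] if n_stops else []
    return "".join(aas), stops


def translate(cds: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a CDS to its protein body (trailing stops excluded)."""
    protein, _ = split_orf(cds, code)
    return protein


def gc_fraction(seq: str) -> float:
    """G+C fraction in [0, 1]; callers wanting percent use metrics.gc_content."""
    if not seq:
        raise InvalidAlphabetError("cannot compute GC of an empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)
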