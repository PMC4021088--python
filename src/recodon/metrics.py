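"""Verification metrics for designed sequences.

GC content, nucleotide identity (positional for equal-length synonymous
recodings, global alignment as the general-case fallback), and a summary of
which codon positions the recoding touched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    EmptyInputError,
    LengthMismatchError,
    ProteinMismatchError,
)
from .genetics import check_dna, codons_of, translate


@dataclass(frozen=True)
class IdentityReport:
    """Nucleotide identity between two sequences.

    ``percent_identity`` is ``100 * matches / aligned_length``;
    ``aligned_length`` is the sequence length for positional mode and the
    number of alignment columns for global-alignment mode.
    """

    percent_identity: float
    aligned_length: int
    matches: int
    mode: str  # "positional" | "global_alignment"


def gc_content(seq: str) -> float:
    """G+C percent of a sequence, to one decimal."""
    if not seq:
        raise EmptyInputError("cannot compute GC content of an empty sequence")
    check_dna(seq)
    return round(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


def positional_identity(a: str, b: str) -> IdentityReport:
    """Position-wise identity of two equal-length sequences (case-insensitive).

    Synonymous recodings preserve length, so this is the natural metric for
    native-vs-synthetic comparisons; unequal lengths raise and direct the
    caller to :func:`global_identity`.
    """
    if len(a) != len(b):
        raise LengthMismatchError(
            f"sequence lengths differ ({len(a)} vs {len(b)}); "
            "use global_identity for unequal lengths"
        )
    if not a:
        raise EmptyInputError("cannot compare empty sequences")
    au, bu = a.upper(), b.upper()
    matches = sum(x == y for x, y in zip(au, bu))
    return IdentityReport(
        percent_identity=100.0 * matches / len(a),
        aligned_length=len(a),
        matches=matches,
        mode="positional",
    )


def global_identity(
    a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> IdentityReport:
    """Identity from a global (Needleman–Wunsch) alignment.

    Identity is matches over alignment columns (gap columns included in the
    denominator).  Linear gap penalty; scores configurable.
    """
    if not a or not b:
        raise EmptyInputError("cannot align empty sequences")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a.upper(), b.upper())[0]
    cols = 0
    matches = 0
    for x, y in zip(aln[0], aln[1]):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return IdentityReport(
        percent_identity=100.0 * matches / cols,
        aligned_length=cols,
        matches=matches,
        mode="global_alignment",
    )


def codon_change_summary(native_cds: str, synthetic_cds: str) -> dict:
    """How a synonymous recoding differs from its native CDS.

    Returns codon totals, the number of codons altered, and base changes
    broken down by codon position (1/2/3).  The two sequences must be
    equal-length and encode the same protein.
    """
    if len(native_cds) != len(synthetic_cds):
        raise LengthMismatchError(
            f"CDS lengths differ ({len(native_cds)} vs {len(synthetic_cds)})"
        )
    nat = native_cds.upper()
    syn = synthetic_cds.upper()
    if translate(nat) != translate(syn):
        raise ProteinMismatchError(
            "sequences are not synonymous: encoded proteins differ"
        )
    nat_codons = codons_of(nat)
    syn_codons = codons_of(syn)
    changed = 0
    per_pos = [0, 0, 0]
    for cn, cs in zip(nat_codons, syn_codons):
        if cn != cs:
            changed += 1
            for p in range(3):
                if cn[p] != cs[p]:
                    per_pos[p] += 1
    return {
        "codons_total": len(nat_codons),
        "codons_changed": changed,
        "per_position_base_changes": tuple(per_pos),
    }
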