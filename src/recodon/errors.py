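"""Exception hierarchy.

Every user-facing failure raises a :class:`RecodonError` subclass so the CLI
can distinguish data errors (exit 1) from usage errors (exit 2) without ever
showing a raw traceback.
"""


class RecodonError(Exception):
    """Base class for all toolkit errors."""


class InvalidAlphabetError(RecodonError):
    """Sequence contains characters outside the expected alphabet."""


class FrameError(RecodonError):
    """CDS length is not divisible by 3."""


class InternalStopError(RecodonError):
    """A stop codon occurs before the final codon of a CDS."""


class EmptyInputError(RecodonError):
    """An operation received an empty collection or sequence."""


class KazusaParseError(RecodonError):
    """A codon-usage table file could not be parsed."""


class IncompleteTableError(KazusaParseError):
    """A codon-usage table is missing codons."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"codon usage table is missing {len(self.missing)} codon(s): "
            + ", ".join(self.missing)
        )


class InvalidThresholdError(RecodonError):
    """Rare-codon threshold outside [0, 1)."""


class PatternError(RecodonError):
    """A motif pattern contains a non-IUPAC character or is too short."""


class InvalidParameterError(RecodonError):
    """A numeric parameter violates its documented constraint."""


class UnencodableError(RecodonError):
    """A residue has no allowed codon in the sampling distribution."""


class FinalizeError(RecodonError):
    """Construct assembly failed (internal flank site, bad stop list...)."""


class LengthMismatchError(RecodonError):
    """Positional comparison of unequal-length sequences."""


class ProteinMismatchError(RecodonError):
    """Two CDSs expected to be synonymous encode different proteins."""


class NoDiscriminatingSiteError(RecodonError):
    """No transgene-specific polymorphism available for primer anchoring."""


class PrimerDesignError(RecodonError):
    """No primer geometry satisfies the amplicon/Tm constraints."""


class InsufficientPointsError(RecodonError):
    """A dilution series has too few points or too narrow a range."""


class DegenerateSeriesError(RecodonError):
    """A dilution series has zero variance in the input amounts."""


class ConfigError(RecodonError):
    """A run-configuration file is malformed or has unknown keys."""


class FixtureError(RecodonError):
    """Synthetic-fixture construction failed (overlap, context clash...)."""
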