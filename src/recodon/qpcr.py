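"""Transgene-discriminating qPCR: primer design and comparative-CT math.

A native transgene and its synonymous recoding are ~75% identical at the
nucleotide level, so allele-specific primer pairs can quantify the two
transcripts separately in the same cDNA pool.  The designer anchors each
primer's 3' end on a transgene-specific polymorphism (a 3'-terminal
mismatch against the wrong template blocks extension) and forces both pairs
to amplify identical amplicon lengths from the 3' region of the CDS, so the
two reactions run at matched efficiency.

Quantification follows the comparative-CT method: with amplification
efficiency ``E`` (1.0 = perfect doubling), a cycle-threshold difference
``ΔCt`` corresponds to a ``(1+E)**ΔCt`` abundance ratio.  Efficiency itself
is estimated from the slope of a Ct vs log10(input) dilution series:
``E = 10**(-1/slope) - 1`` (slope −3.3219 ⇔ 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeriesError,
    InsufficientPointsError,
    InvalidParameterError,
    LengthMismatchError,
    NoDiscriminatingSiteError,
    PrimerDesignError,
)
from .genetics import check_dna, reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on one template.

    ``discriminating_positions`` maps ``"forward"``/``"reverse"`` to
    3'-anchored offsets (0 = the 3'-terminal base) at which the primer
    differs from the other transgene.
    """

    forward: str
    reverse: str
    amplicon_start: int
    amplicon_end: int
    discriminating_positions: dict[str, tuple[int, ...]]
    tm_forward: float
    tm_reverse: float

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass(frozen=True)
class CtExperiment:
    """Replicate Ct measurements, optionally with a dilution series.

    ``replicates`` holds ``(condition label, Ct)`` pairs;
    ``dilution_series`` holds ``(log10 relative input, Ct)`` pairs.
    """

    replicates: tuple[tuple[str, float], ...] = ()
    dilution_series: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for _label, ct in self.replicates:
            if ct <= 0:
                raise InvalidParameterError("Ct values must be positive")
        if self.dilution_series is not None and len(self.dilution_series) < 2:
            raise InsufficientPointsError(
                "a dilution series needs at least 2 points"
            )

    def condition_cts(self, label: str) -> list[float]:
        return [ct for lab, ct in self.replicates if lab == label]


@dataclass(frozen=True)
class PrimerParams:
    """Geometry and Tm constraints for the discriminating-primer search."""

    primer_len_min: int = 18
    primer_len_max: int = 25
    amplicon_min: int = 70
    amplicon_max: int = 180
    tm_window: float = 6.0
    three_prime_region_fraction: float = 0.33

    def __post_init__(self) -> None:
        if not 0 < self.three_prime_region_fraction <= 1.0:
            raise InvalidParameterError(
                "three_prime_region_fraction must be in (0, 1]"
            )
        if self.primer_len_min < 10 or self.primer_len_max < self.primer_len_min:
            raise InvalidParameterError("bad primer length window")
        if self.amplicon_min > self.amplicon_max:
            raise InvalidParameterError("bad amplicon length window")


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), in °C.

    A deliberately simple, dependency-free rule; adequate for balancing a
    primer pair, not for absolute Tm prediction.
    """
    check_dna(primer)
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def _diff_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def design_discriminating_primers(
    native: str,
    synthetic: str,
    params: PrimerParams | None = None,
) -> tuple[PrimerPair, PrimerPair]:
    """Design gene-specific pairs for a native/synthetic transgene pair.

    Both pairs use the same template coordinates, so they amplify equal
    amplicon lengths; each primer's 3'-terminal base sits on a polymorphic
    position, so it mismatches the other transgene at its 3' end.  The
    search scans the 3' region of the CDS (the fraction set by
    ``three_prime_region_fraction``) and returns the first geometry, in
    deterministic left-to-right order, whose four primers fall within the
    amplicon-length window and whose Tm spread is at most ``tm_window``.
    """
    if params is None:
        params = PrimerParams()
    check_dna(native, what="native CDS")
    check_dna(synthetic, what="synthetic CDS")
    if len(native) != len(synthetic):
        raise LengthMismatchError(
            "native and synthetic sequences must be equal length"
        )
    n = len(native)
    diffs = _diff_positions(native, synthetic)
    if not diffs:
        raise NoDiscriminatingSiteError(
            "sequences are identical: no transgene-specific polymorphism"
        )
    region_start = int(math.floor(n * (1.0 - params.three_prime_region_fraction)))
    region_diffs = [p for p in diffs if p >= region_start]
    if not region_diffs:
        raise NoDiscriminatingSiteError(
            f"no polymorphism in the 3' region (from {region_start}); "
            "raise three_prime_region_fraction"
        )

    for p_f in region_diffs:  # forward primer 3'-terminal base
        for q_r in region_diffs:  # template base under the reverse 3' terminus
            if q_r <= p_f:
                continue
            for len_f in range(params.primer_len_min, params.primer_len_max + 1):
                f_start = p_f - len_f + 1
                if f_start < 0:
                    continue
                for len_r in range(params.primer_len_min, params.primer_len_max + 1):
                    r_end = q_r + len_r
                    if r_end > n:
                        continue
                    amp_len = r_end - f_start
                    if not params.amplicon_min <= amp_len <= params.amplicon_max:
                        continue
                    pair = _build_pairs(
                        native, synthetic, f_start, p_f, q_r, r_end, params
                    )
                    if pair is not None:
                        return pair
    raise PrimerDesignError(
        "no primer geometry satisfies the amplicon/Tm constraints; "
        "widen the amplicon window or tm_window"
    )


def _build_pairs(
    native: str,
    synthetic: str,
    f_start: int,
    p_f: int,
    q_r: int,
    r_end: int,
    params: PrimerParams,
) -> tuple[PrimerPair, PrimerPair] | None:
    primers = {}
    tms = []
    for name, template in (("native", native), ("synthetic", synthetic)):
        fwd = template[f_start : p_f + 1]
        rev = reverse_complement(template[q_r:r_end])
        tm_f, tm_r = wallace_tm(fwd), wallace_tm(rev)
        primers[name] = (fwd, rev, tm_f, tm_r)
        tms += [tm_f, tm_r]
    if max(tms) - min(tms) > params.tm_window:
        return None

    def _disc(template: str, other: str) -> dict[str, tuple[int, ...]]:
        # offsets are 3'-anchored: 0 = the primer's 3'-terminal base
        fwd_diffs = tuple(
            p_f - i for i in range(f_start, p_f + 1) if template[i] != other[i]
        )
        # the reverse primer's 3' terminus sits on template base q_r
        rev_diffs = tuple(
            i - q_r for i in range(q_r, r_end) if template[i] != other[i]
        )
        return {
            "forward": tuple(sorted(fwd_diffs)),
            "reverse": tuple(sorted(rev_diffs)),
        }

    out = []
    for name, template, other in (
        ("native", native, synthetic),
        ("synthetic", synthetic, native),
    ):
        fwd, rev, tm_f, tm_r = primers[name]
        out.append(
            PrimerPair(
                forward=fwd,
                reverse=rev,
                amplicon_start=f_start,
                amplicon_end=r_end,
                discriminating_positions=_disc(template, other),
                tm_forward=tm_f,
                tm_reverse=tm_r,
            )
        )
    return out[0], out[1]


def amplification_efficiency(
    dilution_series: list[tuple[float, float]] | tuple[tuple[float, float], ...],
) -> dict[str, float]:
    """Efficiency from a Ct vs log10(input) standard curve.

    Least-squares slope; ``efficiency_percent = (10**(-1/slope) - 1) * 100``.
    A perfect doubling assay has slope −3.3219 and efficiency 100%.
    Requires at least 3 points spanning at least 2 log10 units.
    """
    pts = list(dilution_series)
    if len(pts) < 3:
        raise InsufficientPointsError(
            f"need >= 3 dilution points, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("dilution inputs have zero variance")
    if np.ptp(x) < 2.0:
        raise InsufficientPointsError(
            f"dilution series spans only {np.ptp(x):.2f} log10 units (< 2)"
        )
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope == 0:
        raise DegenerateSeriesError("flat standard curve: slope is zero")
    efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return {
        "slope": slope,
        "efficiency_percent": efficiency,
        "r_squared": float(fit.rvalue) ** 2,
    }


def comparative_ct_fold(
    ct_a: float,
    ct_b: float,
    efficiency: float = 1.0,
    *,
    ct_a_reference: float | None = None,
    ct_b_reference: float | None = None,
) -> float:
    """Abundance of transcript B relative to A by the comparative-CT method.

    Direct form (default): ``fold = (1+E)**(ct_a - ct_b)`` — appropriate
    when the two templates were delivered in equimolar amounts, as in a
    co-bombardment, so no reference gene is needed.  Supplying both
    reference Cts switches to the ΔΔCt form
    ``fold = (1+E)**(-ΔΔCt)`` with
    ``ΔΔCt = (ct_b - ct_b_reference) - (ct_a - ct_a_reference)``.
    ``efficiency`` is a fraction (1.0 = 100%).
    """
    if ct_a <= 0 or ct_b <= 0:
        raise InvalidParameterError("Ct values must be positive")
    if not 0 < efficiency <= 1.2:
        raise InvalidParameterError("efficiency must be in (0, 1.2]")
    if (ct_a_reference is None) != (ct_b_reference is None):
        raise InvalidParameterError(
            "supply both reference Cts or neither"
        )
    base = 1.0 + efficiency
    if ct_a_reference is None:
        return base ** (ct_a - ct_b)
    ddct = (ct_b - ct_b_reference) - (ct_a - ct_a_reference)
    return base ** (-ddct)


def fold_from_replicates(
    experiment: CtExperiment,
    condition_a: str,
    condition_b: str,
    efficiency: float = 1.0,
) -> float:
    """Mean-Ct comparative fold of condition B relative to condition A."""
    cts_a = experiment.condition_cts(condition_a)
    cts_b = experiment.condition_cts(condition_b)
    if not cts_a or not cts_b:
        raise InvalidParameterError(
            f"missing replicates for {condition_a!r} or {condition_b!r}"
        )
    return comparative_ct_fold(
        float(np.mean(cts_a)), float(np.mean(cts_b)), efficiency
    )


def relative_copy_number(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """ΔΔCt relative copy number against a single-copy calibrator line.

    ``2**(-ΔΔCt)`` with
    ``ΔΔCt = (ct_target - ct_reference) - (ct_target_calibrator -
    ct_reference_calibrator)``; the reference is a genomic housekeeping
    amplicon (e.g. GAPDH) and assumed 100% efficient.
    """
    for ct in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if ct <= 0:
            raise InvalidParameterError("Ct values must be positive")
    ddct = (ct_target - ct_reference) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return 2.0 ** (-ddct)
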