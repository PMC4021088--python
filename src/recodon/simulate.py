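"""Synthetic data generators.

Everything the test-bench needs is generated here with seeded RNGs:
random proteins, host-like CDS training sets with a controllable
third-position G/C bias, clean DNA backbones with planted ground-truth
features (the screening oracle's counterpart), and Ct datasets with known
fold change and noise.

The CDS generator emulates a GC-rich monocot host: real sugarcane coding
sequences average ~55.7% G+C, driven largely by strong G/C preference at
synonymous third positions.  ``DEFAULT_GC3_BIAS`` is calibrated so a
generated training set reproduces that bulk G+C level; lowering the bias
produces AT-rich "native-like" genes resembling the insect and cnidarian
luciferase CDSs (45% and 36.5% G+C) that motivated recoding.  What the
generator does *not* emulate: real codon-pair effects, gene-length and GC
heterogeneity between genes, and any biological ordering of amino acids —
tests passing on these fixtures show the machinery is correct, not that any
particular real genome was reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FixtureError, InvalidParameterError
from .genetics import AMINO_ACIDS, STANDARD_CODE, STOP, reverse_complement
from .qpcr import CtExperiment
from .screen import DesignConstraints, Violation, screen

#: Mean third-position G/C preference giving a ~55.7% G+C training set
#: under the host-like amino-acid composition below (the GC-rich host
#: condition).
DEFAULT_GC3_BIAS = 0.53

#: Spread of per-family GC3 preferences around the mean: each synonymous
#: family's preference is drawn once per gene set from a Beta distribution
#: with this concentration, emulating the family-to-family variation real
#: codon-usage tables show (no real table sits at one uniform GC3 level).
GC3_BETA_CONCENTRATION = 8.0

#: Amino-acid weights for generated host coding sequences.  GC-rich
#: genomes are enriched for amino acids with G/C-rich codons (Ala, Gly,
#: Pro, Arg) at the expense of Phe/Lys/Asn/Ile-class residues; these
#: weights give the first+second codon positions a realistically elevated
#: G+C so the third-position bias needed for a 55.7% bulk G+C stays
#: moderate, as in real grass tables.
HOST_AA_WEIGHTS: dict[str, float] = {
    "A": 0.13, "G": 0.09, "P": 0.06, "R": 0.07, "V": 0.07, "L": 0.09,
    "S": 0.07, "T": 0.05, "E": 0.06, "D": 0.05, "K": 0.04, "I": 0.04,
    "F": 0.03, "N": 0.03, "Q": 0.04, "Y": 0.02, "H": 0.02, "M": 0.02,
    "C": 0.01, "W": 0.01,
}


def random_protein(n_residues: int, seed: int = 0) -> str:
    """A uniform random protein over the 20 amino acids."""
    if n_residues < 1:
        raise InvalidParameterError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(aas, size=n_residues))


def _within_subset_weights(codons: list[str]) -> np.ndarray:
    """Skewed within-subset codon weights.

    Mirrors two regularities of real usage tables: among G/C-ending
    synonyms C-ending codons are favored (0.6 vs 0.4), and among A/T-ending
    synonyms A-ending codons are the rarest (0.3 vs 0.7 for T-ending).
    """
    third = [c[2] for c in codons]
    major = {"C": 0.6, "G": 0.4, "T": 0.7, "A": 0.3}
    w = np.array([major[t] for t in third], dtype=float)
    # split the per-ending mass evenly when several codons share an ending
    for t in set(third):
        idx = [i for i, x in enumerate(third) if x == t]
        w[idx] = w[idx] / len(idx)
    return w / w.sum()


def synthetic_cds_set(
    n_genes: int,
    mean_len_codons: int = 300,
    gc3_bias: float = DEFAULT_GC3_BIAS,
    seed: int = 0,
) -> list[str]:
    """Host-like coding sequences with tunable third-position G/C bias.

    Each CDS starts with ATG and has a stop-free body.  Amino acids are
    drawn from :data:`HOST_AA_WEIGHTS`; at every degenerate position the
    codon's third base is G/C with a per-family probability drawn around
    ``gc3_bias`` (Beta-distributed across families, fixed within one gene
    set), and codons within the chosen G/C or A/T subset follow the skewed
    weights of :func:`_within_subset_weights`.  Gene lengths are Poisson
    around ``mean_len_codons`` (minimum 30 codons).
    """
    if not 0.0 <= gc3_bias <= 1.0:
        raise InvalidParameterError("gc3_bias must be in [0, 1]")
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    families = {
        aa: fam for aa, fam in STANDARD_CODE.families().items() if aa != STOP
    }
    aa_list = sorted(families)
    aa_weights = np.array([HOST_AA_WEIGHTS[a] for a in aa_list])
    aa_weights = aa_weights / aa_weights.sum()

    # one GC3 preference per family per gene set
    c = GC3_BETA_CONCENTRATION
    family_gc3: dict[str, float] = {}
    for aa in aa_list:
        if gc3_bias in (0.0, 1.0):
            family_gc3[aa] = gc3_bias
        else:
            family_gc3[aa] = float(
                rng.beta(gc3_bias * c, (1.0 - gc3_bias) * c)
            )

    pools: dict[str, tuple[list[str], np.ndarray, list[str], np.ndarray]] = {}
    for aa, fam in families.items():
        gc_end = [cdn for cdn in fam if cdn[2] in "GC"]
        at_end = [cdn for cdn in fam if cdn[2] in "AT"]
        pools[aa] = (
            gc_end,
            _within_subset_weights(gc_end) if gc_end else np.array([]),
            at_end,
            _within_subset_weights(at_end) if at_end else np.array([]),
        )

    out = []
    for _ in range(n_genes):
        n_codons = max(30, int(rng.poisson(mean_len_codons)))
        codons = ["ATG"]
        aas = rng.choice(aa_list, size=n_codons - 1, p=aa_weights)
        for aa in aas:
            gc_end, gc_w, at_end, at_w = pools[aa]
            if gc_end and at_end:
                if rng.random() < family_gc3[aa]:
                    pool, w = gc_end, gc_w
                else:
                    pool, w = at_end, at_w
            elif gc_end:
                pool, w = gc_end, gc_w
            else:
                pool, w = at_end, at_w
            codons.append(pool[rng.choice(len(pool), p=w)])
        out.append("".join(codons))
    return out


def clean_backbone(
    length: int,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> str:
    """A random DNA sequence with zero violations under ``constraints``.

    Rejection sampling: candidates are drawn with per-base G/C probability
    matched to the constraint's GC target until one screens clean; errors
    after ``max_tries`` rejections.
    """
    if constraints is None:
        constraints = DesignConstraints()
    rng = np.random.default_rng(seed)
    g = constraints.gc_target / 200.0  # per-base probability of G (and of C)
    p = np.array([0.5 - g, g, g, 0.5 - g])  # A, C, G, T
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        seq = "".join(rng.choice(bases, size=length, p=p))
        if screen(seq, constraints).clean:
            return seq
    raise FixtureError(
        f"no clean backbone of length {length} found in {max_tries} tries"
    )


@dataclass(frozen=True)
class PlantedFeature:
    """One feature to embed: kind, payload, and forward-strand position."""

    kind: str  # motif | at_run | direct_repeat | inverted_repeat | palindrome
    payload: object
    position: int


def _render_feature(f: PlantedFeature) -> tuple[str, list[tuple[str, int, int, tuple | None]]]:
    """Expand a feature into its DNA insert and ground-truth intervals."""
    if f.kind == "motif":
        insert = str(f.payload).upper()
        return insert, [("motif", 0, len(insert), None)]
    if f.kind == "at_run":
        insert = str(f.payload).upper()
        if set(insert) - set("AT"):
            raise FixtureError("at_run payload must be A/T only")
        return insert, [("at_run", 0, len(insert), None)]
    if f.kind == "direct_repeat":
        unit, gap_seq = f.payload  # type: ignore[misc]
        insert = unit + gap_seq + unit
        L = len(unit)
        second = L + len(gap_seq)
        return insert, [("direct_repeat", 0, L, (second, second + L))]
    if f.kind == "inverted_repeat":
        stem, loop = f.payload  # type: ignore[misc]
        insert = stem + loop + reverse_complement(stem)
        L = len(stem)
        j = L + len(loop)
        return insert, [("inverted_repeat", 0, L, (j, j + L))]
    if f.kind == "palindrome":
        half = str(f.payload).upper()
        insert = half + reverse_complement(half)
        return insert, [("palindrome", 0, len(insert), None)]
    raise FixtureError(f"unknown feature kind {f.kind!r}")


def plant_features(
    base_seq: str, features: list[PlantedFeature]
) -> tuple[str, list[Violation]]:
    """Overwrite ``base_seq`` with features and return the ground truth.

    Returns the mutated sequence and a manifest of the violations the
    planted features should produce (kind, interval, matched text, mate).
    Features must not overlap each other; a planted feature whose flanking
    context would extend it (e.g. an A/T base adjacent to a planted A/T
    run, which would shift the maximal run's boundaries) raises, keeping
    the manifest an exact ground truth rather than a hopeful one.
    """
    seq = list(base_seq)
    occupied: list[tuple[int, int]] = []
    manifest: list[Violation] = []
    for f in features:
        insert, truths = _render_feature(f)
        start, end = f.position, f.position + len(insert)
        if start < 0 or end > len(seq):
            raise FixtureError(
                f"feature {f.kind} at {f.position} exceeds sequence bounds"
            )
        for s, e in occupied:
            if start < e and s < end:
                raise FixtureError(
                    f"feature {f.kind} at {f.position} overlaps a prior feature"
                )
        occupied.append((start, end))
        seq[start:end] = insert
        for kind, s, e, mate in truths:
            mate_abs = (mate[0] + start, mate[1] + start) if mate else None
            manifest.append(
                Violation(
                    s + start,
                    e + start,
                    kind,
                    kind,
                    insert[s:e],
                    mate=mate_abs,
                )
            )
    planted = "".join(seq)
    _check_context(planted, manifest)
    return planted, sorted(manifest)


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}[b]


def _check_context(seq: str, manifest: list[Violation]) -> None:
    """Reject plantings whose flanking context extends the feature.

    The manifest records *maximal* coordinates; a junction base that
    happens to continue an A/T run, a repeat arm, a stem or a palindrome
    would shift the maximal hit and silently invalidate the ground truth,
    so such contexts raise instead.
    """
    n = len(seq)
    for v in manifest:
        s, e = v.start, v.end
        if v.kind == "at_run":
            if (s > 0 and seq[s - 1] in "AT") or (e < n and seq[e] in "AT"):
                raise FixtureError(
                    f"planted A/T run at {s} is extended by its context"
                )
        elif v.kind == "direct_repeat":
            ms, me = v.mate
            if (s > 0 and seq[s - 1] == seq[ms - 1]) or (
                me < n and seq[e] == seq[me]
            ):
                raise FixtureError(
                    f"planted direct repeat at {s} is extended by its context"
                )
        elif v.kind == "inverted_repeat":
            ms, me = v.mate
            if s > 0 and me < n and seq[s - 1] == _comp(seq[me]):
                raise FixtureError(
                    f"planted stem at {s} is extended outward by its context"
                )
            if e < ms and seq[e] == _comp(seq[ms - 1]):
                raise FixtureError(
                    f"planted stem at {s} is extended inward by its loop ends"
                )
        elif v.kind == "palindrome":
            if s > 0 and e < n and seq[s - 1] == _comp(seq[e]):
                raise FixtureError(
                    f"planted palindrome at {s} is extended by its context"
                )


def simulate_ct_data(
    true_fold: float,
    efficiency: float = 1.0,
    sigma: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct: float = 20.0,
    dilution_decades: int = 4,
) -> CtExperiment:
    """Ct data for a two-condition comparison with known ground truth.

    Condition ``"A"`` is the calibrator; condition ``"B"`` is
    ``true_fold``-times more abundant, so its mean Ct is lower by
    ``log(true_fold) / log(1+E)`` cycles.  Gaussian noise ``sigma`` is
    added per replicate.  A dilution series with the theoretically correct
    slope ``-1 / log10(1+E)`` (same noise) is attached for
    efficiency-estimation tests.
    """
    if true_fold <= 0:
        raise InvalidParameterError("true_fold must be positive")
    if not 0 < efficiency <= 1.2:
        raise InvalidParameterError("efficiency must be in (0, 1.2]")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base = 1.0 + efficiency
    delta_ct = np.log(true_fold) / np.log(base)
    reps: list[tuple[str, float]] = []
    for _ in range(n_replicates):
        reps.append(("A", float(base_ct + sigma * rng.standard_normal())))
        reps.append(
            ("B", float(base_ct - delta_ct + sigma * rng.standard_normal()))
        )
    # Ct rises as input falls: Ct = base_ct + slope * log10(input), slope < 0.
    slope = -1.0 / np.log10(base)
    series = tuple(
        (
            float(-d),
            float(base_ct + slope * (-d) + sigma * rng.standard_normal()),
        )
        for d in range(dilution_decades + 1)
    )
    return CtExperiment(replicates=tuple(reps), dilution_series=series)
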