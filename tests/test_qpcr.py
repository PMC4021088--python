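import math

import numpy as np
import pytest

from recodon.errors import (
    DegenerateSeriesError,
    InsufficientPointsError,
    NoDiscriminatingSiteError,
)
from recodon.genetics import reverse_complement
from recodon.qpcr import (
    PrimerParams,
    amplification_efficiency,
    comparative_ct_fold,
    design_discriminating_primers,
    fold_from_replicates,
    relative_copy_number,
)
from recodon.simulate import simulate_ct_data


def _synonymous_pair(rng, n_codons=120, every=4):
    """An equal-length pair differing at third positions of every k-th codon.

    Uses 4-fold degenerate families only, so the pair is synonymous with
    polymorphisms spread along the whole length.
    """
    fourfold = ["GC", "GT", "CC", "CT", "CG", "AC", "GG", "TC"]
    native = []
    synth = []
    for i in range(n_codons):
        stem = fourfold[int(rng.integers(len(fourfold)))]
        third = "ACGT"[int(rng.integers(4))]
        native.append(stem + third)
        if i % every == 0:
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[third]
            synth.append(stem + alt)
        else:
            synth.append(stem + third)
    return "".join(native), "".join(synth)


class TestPrimerDesign:
    def test_constructed_pair_geometry(self, rng):
        native, synth = _synonymous_pair(rng)
        nat, syn = design_discriminating_primers(native, synth)
        assert nat.amplicon_length == syn.amplicon_length
        assert (nat.amplicon_start, nat.amplicon_end) == (
            syn.amplicon_start,
            syn.amplicon_end,
        )
        # each primer discriminates at its 3' terminus
        for pair in (nat, syn):
            assert 0 in pair.discriminating_positions["forward"]
            assert 0 in pair.discriminating_positions["reverse"]
        # primers really come from their template's 3' region
        assert native[
            nat.amplicon_start : nat.amplicon_start + len(nat.forward)
        ] == nat.forward
        assert (
            reverse_complement(
                native[nat.amplicon_end - len(nat.reverse) : nat.amplicon_end]
            )
            == nat.reverse
        )

    def test_wrong_template_has_three_prime_mismatch(self, rng):
        for trial in range(10):
            native, synth = _synonymous_pair(rng, every=3 + trial % 4)
            nat, syn = design_discriminating_primers(native, synth)
            # the native forward primer's last base mismatches the
            # synthetic template at the same coordinate, and vice versa
            end = nat.amplicon_start + len(nat.forward) - 1
            assert nat.forward[-1] != synth[end]
            end_s = syn.amplicon_start + len(syn.forward) - 1
            assert syn.forward[-1] != native[end_s]

    def test_identical_sequences_rejected(self):
        seq = "ACGT" * 50
        with pytest.raises(NoDiscriminatingSiteError):
            design_discriminating_primers(seq, seq)

    def test_five_prime_only_polymorphisms_need_wider_region(self, rng):
        native, synth = _synonymous_pair(rng, n_codons=120, every=4)
        # confine polymorphisms to the first third
        cut = 120  # nt; first 40 codons
        native2 = native
        synth2 = synth[:cut] + native[cut:]
        with pytest.raises(NoDiscriminatingSiteError):
            design_discriminating_primers(native2, synth2)
        params = PrimerParams(three_prime_region_fraction=1.0)
        nat, syn = design_discriminating_primers(native2, synth2, params)
        assert nat.amplicon_length == syn.amplicon_length


class TestEfficiency:
    def test_perfect_doubling_series(self):
        series = [(-d, 20.0 + 3.3219 * d) for d in range(5)]
        out = amplification_efficiency(series)
        assert out["efficiency_percent"] == pytest.approx(100.0, abs=0.01)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_slower_assay_closed_form(self):
        series = [(-d, 20.0 + 3.6 * d) for d in range(4)]
        out = amplification_efficiency(series)
        expected = (10 ** (1 / 3.6) - 1) * 100
        assert out["efficiency_percent"] == pytest.approx(expected, abs=0.01)
        assert out["efficiency_percent"] == pytest.approx(89.6, abs=0.05)

    def test_exact_k_fold_per_step_series(self):
        # Ct falling by 1 per 10-fold step means (1+E) = 10; by 1 per
        # 2-fold step means (1+E) = 2
        for k, expected in ((2, 100.0), (10, 900.0)):
            series = [
                (d * math.log10(k), 20.0 - d) for d in range(-7, 1)
            ]
            out = amplification_efficiency(series)
            assert out["efficiency_percent"] == pytest.approx(expected, rel=1e-6)

    def test_two_points_rejected(self):
        with pytest.raises(InsufficientPointsError):
            amplification_efficiency([(0, 20.0), (-1, 23.3)])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            amplification_efficiency([(0, 20.0), (0, 21.0), (0, 22.0)])


class TestComparativeCt:
    def test_trivial_folds(self):
        assert comparative_ct_fold(20.0, 20.0) == 1.0
        assert comparative_ct_fold(21.0, 20.0) == 2.0

    def test_transcript_scale_fold(self):
        assert comparative_ct_fold(23.154, 20.0) == pytest.approx(8.9, abs=0.01)

    def test_reciprocity(self):
        for e in (1.0, 0.9, 0.85):
            assert comparative_ct_fold(24.1, 21.7, e) * comparative_ct_fold(
                21.7, 24.1, e
            ) == pytest.approx(1.0)

    def test_ddct_form_consistent_with_direct(self):
        direct = comparative_ct_fold(22.0, 20.0)
        normalized = comparative_ct_fold(
            22.0, 20.0, ct_a_reference=15.0, ct_b_reference=15.0
        )
        assert direct == pytest.approx(normalized)


class TestRelativeCopyNumber:
    def test_all_equal_is_one(self):
        assert relative_copy_number(20, 20, 20, 20) == 1.0

    def test_one_cycle_earlier_doubles(self):
        assert relative_copy_number(19, 20, 20, 20) == 2.0

    def test_two_copy_line_recovered_under_noise(self):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(1000):
            noise = rng.normal(0, 0.2, size=4)
            est = relative_copy_number(
                19.0 + noise[0], 20.0 + noise[1], 20.0 + noise[2], 20.0 + noise[3]
            )
            estimates.append(est)
        assert 1.7 <= float(np.mean(estimates)) <= 2.3


class TestFoldRecovery:
    @pytest.mark.parametrize("true_fold", [1.0, 2.0, 6.5, 8.9])
    def test_unbiased_recovery_from_simulated_ct(self, true_fold):
        estimates = []
        for rep in range(300):
            exp = simulate_ct_data(
                true_fold, efficiency=1.0, sigma=0.2, n_replicates=3,
                seed=1000 + rep,
            )
            estimates.append(fold_from_replicates(exp, "A", "B"))
        mean = float(np.mean(estimates))
        # sigma 0.2 over 3+3 replicates: Monte Carlo error well under 5%
        assert mean == pytest.approx(true_fold, rel=0.05)

    def test_noise_free_delta_ct_exact(self):
        exp = simulate_ct_data(2.0, efficiency=1.0, sigma=0.0, n_replicates=3)
        cts = dict(
            A=np.mean(exp.condition_cts("A")), B=np.mean(exp.condition_cts("B"))
        )
        assert cts["A"] - cts["B"] == pytest.approx(1.0)
        assert fold_from_replicates(exp, "A", "B") == pytest.approx(2.0)
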