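"""Shared fixture-construction helpers for the tests."""

from recodon.screen import DesignConstraints

#: Wide-GC constraints for planted-feature fixtures.  min_at_run is raised
#: to 8 so a planted 6-base polyadenylation signal (all A/T) is not itself
#: an A/T-run violation.
FIXTURE_CONSTRAINTS = DesignConstraints(
    gc_target=50.0, gc_window=45.0, min_at_run=8
)


def gc_flanked_position(
    backbone: str, insert_len: int, start: int = 1, same_letter: bool = False
) -> int:
    """First position >= start whose insert would be flanked by G/C bases.

    G/C flanks cannot extend a planted A/T run or repeat arm.  For
    palindromes and stems the two flanks must additionally be
    non-complementary (``same_letter=True``: both G or both C), or the
    planted feature's maximal extent would grow outward.
    """
    for i in range(max(1, start), len(backbone) - insert_len - 1):
        left, right = backbone[i - 1], backbone[i + insert_len]
        if left in "GC" and right in "GC":
            if not same_letter or left == right:
                return i
    raise AssertionError("no suitably flanked position available in backbone")
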