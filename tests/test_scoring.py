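import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cas9scan import (
    BINDING_WEIGHTS,
    CLEAVAGE_WEIGHTS,
    Mode,
    SegmentScheme,
    WeightSet,
    base_score,
    classify_mismatches,
    default_weights,
    score_candidates,
)
from cas9scan.genome_search import CandidateSite, PamClass
from oracles import naive_score


def mask_at(positions):
    return tuple(p in set(positions) for p in range(20))


def test_default_weight_sets():
    assert (BINDING_WEIGHTS.s1, BINDING_WEIGHTS.s2, BINDING_WEIGHTS.s3) == (5, 70, 50)
    assert BINDING_WEIGHTS.d == 20 and BINDING_WEIGHTS.mismatch_limit == 9
    assert (CLEAVAGE_WEIGHTS.s1, CLEAVAGE_WEIGHTS.s2, CLEAVAGE_WEIGHTS.s3) == (20, 60, 50)
    assert CLEAVAGE_WEIGHTS.d == 10 and CLEAVAGE_WEIGHTS.mismatch_limit == 6
    assert default_weights(Mode.BINDING) is BINDING_WEIGHTS
    assert default_weights("cleavage") is CLEAVAGE_WEIGHTS


def test_weightset_rejects_negative():
    with pytest.raises(ValueError):
        WeightSet(-1, 5, 5)


@pytest.mark.parametrize(
    "lengths",
    [(5, 5, 5), (0, 10, 10), (10, 10, 5)],
)
def test_segment_scheme_validation(lengths):
    with pytest.raises(ValueError):
        SegmentScheme(lengths=lengths)


def test_segment_assignment_orientation():
    distal = SegmentScheme().segment_of()
    assert distal == (0,) * 5 + (1,) * 5 + (2,) * 10
    proximal = SegmentScheme(orientation="pam_proximal_first").segment_of()
    assert proximal == distal[::-1]


@pytest.mark.parametrize(
    "positions,n,m,k,runs",
    [
        ((2,), 19, 0, 1, ()),  # isolated mismatch
        ((2, 3, 4), 17, 3, 0, ((2, 5),)),  # one run of three
        ((0, 2, 4), 17, 0, 3, ()),  # no adjacency
        ((), 20, 0, 0, ()),
        (tuple(range(20)), 0, 20, 0, ((0, 20),)),
        ((0, 1, 5, 10, 11, 12, 19), 13, 5, 2, ((0, 2), (10, 13))),
    ],
)
def test_classify_mismatches(positions, n, m, k, runs):
    cls = classify_mismatches(mask_at(positions))
    assert (cls.n, cls.m, cls.k) == (n, m, k)
    assert cls.runs == runs
    assert cls.n + cls.m + cls.k == 20


def test_classify_mismatches_rejects_wrong_length():
    with pytest.raises(ValueError):
        classify_mismatches([False] * 19)


def test_all_match_score():
    """Perfect match under binding weights: 5*5 + 5*70 + 10*50 = 875."""
    assert base_score(mask_at(()), BINDING_WEIGHTS) == 875


def test_single_mismatch_pam_proximal():
    """One isolated mismatch in the PAM-proximal segment (s=50) loses the
    match reward plus half the penalty: 875 - 50 - 25 = 800."""
    assert base_score(mask_at((19,)), BINDING_WEIGHTS) == 800


def test_consecutive_pair_within_segment():
    """Adjacent mismatches inside the 10-nt segment each take the full
    -50: 875 - 2*50 - 2*50 = 675."""
    assert base_score(mask_at((12, 13)), BINDING_WEIGHTS) == 675


def test_consecutive_pair_across_boundary():
    """A run straddling the s2/s3 boundary is charged the mean penalty
    (70+50)/2 at both positions: 875 - 70 - 50 - 120 = 635."""
    assert base_score(mask_at((9, 10)), BINDING_WEIGHTS) == 635


def test_run_spanning_all_three_segments():
    mask = mask_at(range(3, 13))  # run across segments 1, 2 and 3
    expected = naive_score(mask, (5, 70, 50))
    assert base_score(mask, BINDING_WEIGHTS) == pytest.approx(expected)
    # hand total: matches at 0-2 (s1) and 13-19 (s3); the 10-position run
    # spanning all three segments takes the mean of all three penalties
    hand = 3 * 5 + 7 * 50 - 10 * (5 + 70 + 50) / 3
    assert base_score(mask, BINDING_WEIGHTS) == pytest.approx(hand)


@pytest.mark.parametrize("weights", [BINDING_WEIGHTS, CLEAVAGE_WEIGHTS, WeightSet(3, 11, 7)])
def test_random_mask_oracle(weights, rng):
    """Implementation equals the naive per-position evaluator on random
    masks plus the two extremes."""
    masks = [tuple(bool(b) for b in rng.integers(0, 2, size=20)) for _ in range(2000)]
    masks += [mask_at(()), mask_at(range(20))]
    for mask in masks:
        assert base_score(mask, weights) == pytest.approx(
            naive_score(mask, weights.segment_scores)
        )


def test_maximum_at_all_match(rng):
    best = base_score(mask_at(()), BINDING_WEIGHTS)
    for _ in range(200):
        mask = tuple(bool(b) for b in rng.integers(0, 2, size=20))
        if any(mask):
            assert base_score(mask, BINDING_WEIGHTS) < best


def test_single_flip_strictly_decreases(rng):
    """Turning any match into a mismatch strictly lowers S when all
    weights are positive."""
    for _ in range(100):
        mask = [bool(b) for b in rng.integers(0, 5, size=20) == 0]
        before = base_score(mask, BINDING_WEIGHTS)
        matches = [i for i in range(20) if not mask[i]]
        if not matches:
            continue
        flip = matches[int(rng.integers(0, len(matches)))]
        mask[flip] = True
        assert base_score(mask, BINDING_WEIGHTS) < before


def test_equal_weights_depend_only_on_counts(rng):
    """With s1 = s2 = s3 = s the score collapses to (n - m - k/2) * s
    regardless of where the mismatches sit."""
    w = WeightSet(10, 10, 10)
    for _ in range(200):
        mask = tuple(bool(b) for b in rng.integers(0, 2, size=20))
        cls = classify_mismatches(mask)
        assert base_score(mask, w) == pytest.approx(
            (cls.n - cls.m - cls.k / 2) * 10
        )


def test_orientation_mirror(rng):
    """Scoring under pam_proximal_first equals scoring the reversed mask
    under pam_distal_first."""
    proximal = SegmentScheme(orientation="pam_proximal_first")
    for _ in range(100):
        mask = tuple(bool(b) for b in rng.integers(0, 2, size=20))
        assert base_score(mask, BINDING_WEIGHTS, proximal) == pytest.approx(
            base_score(mask[::-1], BINDING_WEIGHTS)
        )


def _make_site(start, mask):
    guide = "A" * 20
    seq = "".join("C" if m else "A" for m in mask)
    return CandidateSite(
        chrom="chr1",
        start=start,
        end=start + 20,
        strand="+",
        site_seq=seq,
        pam="AGG",
        pam_class=PamClass.NGG,
        mismatch_mask=tuple(mask),
        n_mismatches=sum(mask),
    )


def test_score_candidates_composition(rng):
    assert score_candidates([], BINDING_WEIGHTS) == []
    masks = [mask_at((1,)), mask_at((5, 6)), mask_at(())]
    sites = [_make_site(100 * i, m) for i, m in enumerate(masks)]
    scored = score_candidates(sites, BINDING_WEIGHTS)
    assert [s.S for s in scored] == [base_score(m, BINDING_WEIGHTS) for m in masks]
    assert all(s.S_d == 0 and s.S_f == s.S for s in scored)
    # order-preserving and permutation-consistent up to pairing
    perm = [2, 0, 1]
    scored_p = score_candidates([sites[i] for i in perm], BINDING_WEIGHTS)
    assert [s.S for s in scored_p] == [scored[i].S for i in perm]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=20, max_size=20))
def test_property_score_matches_oracle(mask):
    mask = tuple(mask)
    assert base_score(mask, CLEAVAGE_WEIGHTS) == pytest.approx(
        naive_score(mask, CLEAVAGE_WEIGHTS.segment_scores)
    )
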