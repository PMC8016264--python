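import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorec.events import (
    CO,
    CO_GC,
    NCO_GC,
    ClassificationError,
    call_events,
    chisq_proportion_test,
    classify,
    segment,
    summarize,
)
from mitorec.genotypes import H, MISSING, N, P, GenotypeVector

from conftest import gv, make_map
from oracle_classifier import oracle_classes


class TestSegment:
    def test_blocks_are_maximal_runs(self):
        blocks = segment(gv([H, H, N, N, H]))
        assert [(b.state, b.first_marker, b.last_marker) for b in blocks] == [
            (H, 0, 1), (N, 2, 3), (H, 4, 4)
        ]

    def test_uniform_vector_is_single_block(self):
        (b,) = segment(gv([H] * 8))
        assert (b.state, b.first_marker, b.last_marker) == (H, 0, 7)

    def test_missing_markers_are_skipped_and_bridged(self):
        blocks = segment(gv([H, MISSING, H, N, MISSING, N, H]))
        assert [(b.state, b.first_marker, b.last_marker) for b in blocks] == [
            (H, 0, 2), (N, 3, 5), (H, 6, 6)
        ]

    def test_all_missing_rejected(self):
        with pytest.raises(ClassificationError, match="missing"):
            segment(gv([MISSING, MISSING]))

    def test_reexpansion_reproduces_input(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            states = rng.choice([N, P, H, MISSING], size=rng.integers(1, 12))
            if all(s == MISSING for s in states):
                continue
            blocks = segment(gv(states))
            rebuilt = [None] * len(states)
            for b in blocks:
                for i in range(b.first_marker, b.last_marker + 1):
                    if states[i] != MISSING:
                        rebuilt[i] = b.state
            for s, r in zip(states, rebuilt):
                if s != MISSING:
                    assert r == s


_state_vectors = st.lists(
    st.sampled_from([N, P, H, MISSING]), min_size=1, max_size=12
).filter(lambda s: any(x != MISSING for x in s))


@settings(max_examples=300, derandomize=True, deadline=None)
@given(_state_vectors)
def test_segment_blocks_tile_and_are_maximal(states):
    blocks = segment(gv(states))
    # blocks cover the non-missing markers in order and neighbours differ
    covered = []
    for prev, b in zip([None] + blocks[:-1], blocks):
        if prev is not None:
            assert prev.last_marker < b.first_marker
            assert prev.state != b.state
        covered.extend(range(b.first_marker, b.last_marker + 1))
        for i in range(b.first_marker, b.last_marker + 1):
            if states[i] != MISSING:
                assert states[i] == b.state
    non_missing = [i for i, s in enumerate(states) if s != MISSING]
    assert set(non_missing) <= set(covered)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(_state_vectors)
def test_classified_conversion_events_always_carry_valid_tracts(states):
    mmap = make_map([10_000 * (i + 1) for i in range(12)])
    sub = make_map(mmap.position[: len(states)]) if len(states) > 1 else None
    if sub is None:
        return
    for e in call_events(gv(states), sub):
        if e.event_class == CO:
            assert e.tract is None
        else:
            assert e.tract is not None and e.tract.length > 0
        for left, right in e.breakpoints:
            assert 0 <= left < right <= len(states) - 1


class TestClassifyCanonical:
    def test_internal_tract_is_ncogc(self, dense_map6):
        (e,) = call_events(gv([H, H, N, N, H, H]), dense_map6)
        assert e.event_class == NCO_GC
        assert e.pattern_type == "Type1"
        assert e.donor == "to_N"
        assert e.tract.n_markers_converted == 2

    def test_terminal_run_is_co(self, dense_map6):
        (e,) = call_events(gv([H, H, H, P, P, P]), dense_map6)
        assert e.event_class == CO
        assert e.pattern_type == "Type5"
        assert e.donor == "to_P"
        assert e.tract is None

    def test_two_terminal_runs_are_type6(self, dense_map6):
        events = call_events(gv([N, H, H, H, P, P]), dense_map6)
        assert [e.event_class for e in events] == [CO, CO]
        assert all(e.pattern_type == "Type6" for e in events)

    def test_two_disjoint_tracts_are_type3(self, dense_map6):
        events = call_events(gv([H, N, H, H, P, H]), dense_map6)
        assert [e.event_class for e in events] == [NCO_GC, NCO_GC]
        assert all(e.pattern_type == "Type3" for e in events)

    def test_embedded_short_tract_is_cogc_type7(self, dense_map6):
        (e,) = call_events(gv([H, H, N, P, N, N]), dense_map6)
        assert e.event_class == CO_GC
        assert e.pattern_type == "Type7"
        assert e.donor == "to_P"
        assert e.tract.n_markers_converted == 1

    def test_abutting_short_tract_is_cogc_type8(self, dense_map6):
        (e,) = call_events(gv([H, H, H, P, N, N]), dense_map6)
        assert e.event_class == CO_GC
        assert e.pattern_type == "Type8"
        assert e.donor == "to_P"

    def test_long_embedded_block_reads_as_adjacent_cos(self, sparse_map6):
        events = call_events(gv([H, H, N, P, N, N]), sparse_map6)
        assert sorted(e.event_class for e in events) == [CO, CO, CO]

    def test_single_block_vector_has_no_events(self, dense_map6):
        assert call_events(gv([H] * 6), dense_map6) == []
        assert call_events(gv([N] * 6), dense_map6) == []

    def test_missing_inside_tract_flags_low_confidence(self, dense_map6):
        (e,) = call_events(gv([H, H, N, MISSING, N, H]), dense_map6)
        assert e.event_class == NCO_GC
        assert "low_confidence" in e.flags

    def test_deterministic(self, dense_map6):
        a = call_events(gv([H, N, P, H, N, N]), dense_map6)
        b = call_events(gv([H, N, P, H, N, N]), dense_map6)
        assert [(e.event_class, e.pattern_type) for e in a] == [
            (e.event_class, e.pattern_type) for e in b
        ]


class TestOracleEquivalence:
    @pytest.mark.parametrize("map_name", ["dense_map6", "sparse_map6"])
    def test_all_length6_vectors_match_oracle(self, map_name, request):
        """Exhaustive check of the decision procedure against an
        independent naive rule implementation on all 3^6 vectors."""
        mmap = request.getfixturevalue(map_name)
        for states in itertools.product((N, P, H), repeat=6):
            got = sorted(
                e.event_class for e in call_events(gv(states), mmap)
            )
            want = oracle_classes(states, mmap.position)
            assert got == want, states

    def test_shorter_vectors_match_oracle(self, request):
        for length in (2, 3, 4, 5):
            mmap_d = make_map([1000 * (i + 1) for i in range(length)])
            mmap_s = make_map([150_000 * (i + 1) for i in range(length)])
            for mmap in (mmap_d, mmap_s):
                for states in itertools.product((N, P, H), repeat=length):
                    got = sorted(e.event_class for e in call_events(gv(states), mmap))
                    assert got == oracle_classes(states, mmap.position), states


class TestSummary:
    def test_screen_totals(self):
        events = (
            [_fake(CO)] * 29 + [_fake(NCO_GC)] * 17 + [_fake(CO_GC)] * 7
        )
        s = summarize(events)
        assert s.co_to_ncogc_ratio == pytest.approx(36 / 17)
        assert round(s.co_to_ncogc_ratio, 2) == 2.12  # 36/17 = 2.1176...
        assert s.co_associated_fraction == pytest.approx(7 / 24)
        assert round(100 * s.co_associated_fraction, 1) == 29.2

    def test_zero_denominators_flagged_undefined(self):
        s = summarize([_fake(CO)] * 3)
        assert s.co_to_ncogc_ratio is None
        assert s.co_associated_fraction is None
        s = summarize([_fake(NCO_GC)] * 5)
        assert s.co_to_ncogc_ratio == 0
        assert s.co_associated_fraction == 0


class TestChisqProportion:
    def test_equal_proportions_give_zero(self):
        stat, p = chisq_proportion_test(50, 100, 50, 100)
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        from scipy.stats import chi2_contingency

        k1, n1, k2, n2 = 7, 24, 16, 59
        stat, p = chisq_proportion_test(k1, n1, k2, n2)
        ref = chi2_contingency(
            [[k1, n1 - k1], [k2, n2 - k2]], correction=False
        )
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_proportion_test(0, 10, 0, 10)


def _fake(event_class):
    from mitorec.events import RecombinationEvent
    from mitorec.tracts import ConversionTract

    tract = None
    if event_class in (NCO_GC, CO_GC):
        tract = ConversionTract(
            first_converted=1, last_converted=1, left_bound=0.0,
            right_bound=1.0, length=1.0, n_markers_converted=1,
            single_marker=True,
        )
    return RecombinationEvent(event_class, "Type1", "to_N", ((0, 1),), tract=tract)
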