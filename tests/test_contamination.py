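import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wordingsim.contamination import (
    ContaminationSpec,
    InfeasibleContaminationError,
    apply_acquiescence,
    apply_carelessness,
    apply_ivd,
    contaminate,
    reverse_categories,
)
from wordingsim.datagen import make_rng

from conftest import PATTERNS, make_sample, reverse_coded_sum


class TestReverseCategories:
    def test_worked_example_pattern(self):
        # low-trait NW block reversed: 3 3 4 4 4 -> 2 2 1 1 1
        out = reverse_categories(np.array([3, 3, 4, 4, 4]), np.arange(5))
        assert out.tolist() == [2, 2, 1, 1, 1]

    def test_empty_positions_identity(self):
        x = np.array([1, 2, 3, 4])
        assert reverse_categories(x, np.array([], dtype=int)).tolist() == x.tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reverse_categories(np.array([0, 2]), np.array([0]))

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_involution(self, values):
        x = np.array(values)
        pos = np.arange(x.size)
        assert np.array_equal(reverse_categories(reverse_categories(x, pos), pos), x)


class TestTargetItemCount:
    @pytest.mark.parametrize(
        "perc,k,expected",
        [(50, 10, 5), (10, 12, 1), (30, 12, 4), (10, 24, 2), (50, 60, 30), (0, 12, 0), (1, 60, 1)],
    )
    def test_round_half_up_with_minimum(self, perc, k, expected):
        spec = ContaminationSpec("carelessness", perc, k)
        assert spec.target_item_count == expected


class TestCarelessness:
    def test_careless_low_and_high_trait_patterns(self):
        data = make_sample([PATTERNS["low_none"], PATTERNS["high_none"]], flags=[True, True])
        spec = ContaminationSpec("carelessness", 50, 10)
        out, log = apply_carelessness(data, spec, make_rng(0))
        assert out.responses[0].tolist() == PATTERNS["low_careless"]
        assert out.responses[1].tolist() == PATTERNS["high_careless"]
        assert len(log.respondent) == 10

    def test_reverse_coded_sums_move_toward_midpoint(self):
        data = make_sample([PATTERNS["low_none"], PATTERNS["high_none"]], flags=[True, True])
        out, _ = apply_carelessness(data, ContaminationSpec("carelessness", 50, 10), make_rng(0))
        assert reverse_coded_sum(data.responses[0]) == 14
        assert reverse_coded_sum(out.responses[0]) == 25  # low-trait sum increases
        assert reverse_coded_sum(data.responses[1]) == 36
        assert reverse_coded_sum(out.responses[1]) == 25  # high-trait sum decreases

    def test_consistent_respondents_untouched_and_change_counts(self, rng):
        resp = rng.integers(1, 5, size=(40, 12))
        flags = np.zeros(40, dtype=bool)
        flags[:16] = True
        data = make_sample(resp, flags=flags)
        out, _ = apply_carelessness(data, ContaminationSpec("carelessness", 30, 12), make_rng(1))
        diff = out.responses != data.responses
        assert not diff[~flags].any()
        assert np.all(diff[flags].sum(axis=1) == 4)  # round(0.3*12)
        # reversal distances are 1 or 3 on changed cells, NW columns only
        assert set(np.abs(out.responses - data.responses)[diff]) <= {1, 3}
        assert not diff[:, :6].any()

    def test_perc_zero_identity(self, rng):
        resp = rng.integers(1, 5, size=(10, 12))
        data = make_sample(resp, flags=np.ones(10, dtype=bool))
        out, log = apply_carelessness(data, ContaminationSpec("carelessness", 0, 12), make_rng(2))
        assert np.array_equal(out.responses, data.responses)
        assert len(log.respondent) == 0

    def test_infeasible_target_rejected(self, rng):
        resp = rng.integers(1, 5, size=(4, 10))
        data = make_sample(resp, flags=np.ones(4, dtype=bool))
        with pytest.raises(InfeasibleContaminationError):
            # 8 of 10 items requested but only 5 NW items exist
            apply_carelessness(data, ContaminationSpec("carelessness", 80, 10), make_rng(3))


class TestIvd:
    def test_trait_conditional_reversal_patterns(self):
        data = make_sample([PATTERNS["low_none"], PATTERNS["high_none"]], flags=[True, True])
        spec = ContaminationSpec("ivd", 50, 10)
        out, _ = apply_ivd(data, spec, np.array([-1.2, 1.3]), make_rng(0))
        assert out.responses[0].tolist() == PATTERNS["low_ivd"]  # PW reversed
        assert out.responses[1].tolist() == PATTERNS["high_ivd"]  # NW reversed

    def test_zero_score_takes_high_trait_branch(self):
        data = make_sample([PATTERNS["low_none"]], flags=[True])
        out, _ = apply_ivd(data, ContaminationSpec("ivd", 50, 10), np.array([0.0]), make_rng(0))
        assert out.responses[0, :5].tolist() == PATTERNS["low_none"][:5]  # PW untouched
        assert out.responses[0, 5:].tolist() == [2, 2, 1, 1, 1]  # NW reversed

    def test_partial_reversal_counts(self, rng):
        resp = rng.integers(1, 5, size=(30, 24))
        flags = np.ones(30, dtype=bool)
        data = make_sample(resp, flags=flags)
        scores = rng.standard_normal(30)
        out, _ = apply_ivd(data, ContaminationSpec("ivd", 20, 24), scores, make_rng(4))
        diff = out.responses != data.responses
        assert np.all(diff.sum(axis=1) == 5)  # round(0.2*24) = 4.8 -> 5
        pw_changed = diff[:, :12].any(axis=1)
        assert np.array_equal(pw_changed, scores < 0)  # branch keyed on trait sign


class TestAcquiescence:
    def test_all_agree_respondent_unchanged_with_exhaustion(self):
        data = make_sample([[4] * 10], flags=[True])
        out, log = apply_acquiescence(data, ContaminationSpec("acquiescence", 50, 10), make_rng(0))
        assert np.array_equal(out.responses, data.responses)
        assert log.exhausted == [0]

    def test_category_mapping_is_upward(self, rng):
        resp = rng.integers(1, 5, size=(50, 12))
        data = make_sample(resp, flags=np.ones(50, dtype=bool))
        out, log = apply_acquiescence(data, ContaminationSpec("acquiescence", 50, 12), make_rng(5))
        old = np.array(log.old)
        new = np.array(log.new)
        assert np.all(new > old)  # strictly increasing
        assert np.all(new[old == 1] == 3)
        assert np.all(np.isin(new[old == 2], [3, 4]))
        assert np.all(new[old == 3] == 4)
        assert 4 not in old  # agree category never selected
        # mean response strictly increases for any respondent with a change
        changed = np.unique(log.respondent)
        assert np.all(
            out.responses[changed].mean(axis=1) > data.responses[changed].mean(axis=1)
        )

    def test_change_count_hits_target_unless_exhausted(self, rng):
        resp = rng.integers(1, 5, size=(60, 12))
        data = make_sample(resp, flags=np.ones(60, dtype=bool))
        spec = ContaminationSpec("acquiescence", 30, 12)
        out, log = apply_acquiescence(data, spec, make_rng(6))
        diff = (out.responses != data.responses).sum(axis=1)
        eligible = (resp < 4).sum(axis=1)
        expected = np.minimum(spec.target_item_count, eligible)
        assert np.array_equal(diff, expected)

    def test_switch_probs_default(self):
        spec = ContaminationSpec("acquiescence", 20, 12)
        assert spec.switch_probs == {1: 0.50, 2: 0.33, 3: 0.17}
        with pytest.raises(ValueError):
            ContaminationSpec("carelessness", 20, 12, switch_probs={1: 0.5})


@pytest.mark.parametrize("effect", ["carelessness", "ivd", "acquiescence"])
def test_dispatch_matches_direct_application(effect, rng):
    resp = rng.integers(1, 5, size=(20, 12))
    flags = np.zeros(20, dtype=bool)
    flags[::2] = True
    data = make_sample(resp, flags=flags)
    traits = rng.standard_normal(20)
    out, _ = contaminate(
        data, effect, 30, make_rng(9), trait_scores=traits if effect == "ivd" else None
    )
    diff = out.responses != data.responses
    assert not diff[~flags].any()
    assert diff[flags].any()
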