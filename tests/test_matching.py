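"""Field similarities, weights, aggregation and classification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pprlink.encoding import BitVector, ConfigError, EncodingConfig, encode_record
from pprlink.matching import (
    MATCH,
    NON_MATCH,
    POSSIBLE,
    aggregate_similarity,
    best_match,
    classify,
    compound_similarity,
    default_bloom_fields,
    default_plain_fields,
    dice_bits,
    dice_string,
    field_weight,
    numeric_equality,
)
from pprlink.preprocessing import normalize_record
from pprlink.synthetic import DatasetSpec, generate_dataset


class TestDiceString:
    def test_sara_sarah(self):
        # gram sets {SA,AR,RA} vs {SA,AR,RA,AH}: 2*3/(3+4)
        assert dice_string("SARA", "SARAH", 2) == pytest.approx(6 / 7)

    def test_identity(self):
        assert dice_string("MEYER", "MEYER", 2) == 1.0

    def test_disjoint(self):
        assert dice_string("AB", "CD", 2) == 0.0

    def test_empty_side(self):
        assert dice_string("", "ANNA", 2) == 0.0
        assert dice_string("A", "ANNA", 2) == 0.0  # too short for a bigram

    def test_multiset_counting(self):
        # "AAA" has grams {AA, AA}; "AA" has {AA}: intersection min-count = 1
        assert dice_string("AAA", "AA", 2) == pytest.approx(2 * 1 / (2 + 1))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.text(alphabet="ABCDE", min_size=2, max_size=12),
        st.text(alphabet="ABCDE", min_size=2, max_size=12),
    )
    def test_bounds_and_symmetry(self, a, b):
        d = dice_string(a, b, 2)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(dice_string(b, a, 2))


class TestDiceBits:
    def test_hand_counted(self):
        assert dice_bits(BitVector.from01("1100"), BitVector.from01("1010")) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        v = BitVector.from01("1011")
        assert dice_bits(v, v) == 1.0
        assert dice_bits(BitVector.from01("1100"), BitVector.from01("0011")) == 0.0

    def test_both_empty_is_zero(self):
        assert dice_bits(BitVector.zeros(16), BitVector.zeros(16)) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_bits(BitVector.zeros(16), BitVector.zeros(24))


def test_numeric_equality():
    assert numeric_equality(1990, 1990) == 1.0
    assert numeric_equality(1990, 1991) == 0.0
    assert numeric_equality(3, "3") == 1.0
    assert numeric_equality(None, 3) == 0.0


class TestFieldWeight:
    def test_trivial_value(self):
        assert field_weight(0.5, 0.0) == pytest.approx(1.0)

    def test_out_of_range(self):
        with pytest.raises(ConfigError):
            field_weight(0.0, 0.1)
        with pytest.raises(ConfigError):
            field_weight(0.1, 1.0)

    def test_matches_log_formula(self):
        assert field_weight(0.000235, 0.01) == pytest.approx(math.log2(0.99 / 0.000235))


class TestCompoundSimilarity:
    def test_pinkett_smith_vs_pinkett(self):
        sim = compound_similarity(["PINKETT", "SMITH"], ["PINKETT"], lambda a, b: dice_string(a, b, 2))
        assert sim == 1.0

    def test_identity_and_disjoint(self):
        f = lambda a, b: dice_string(a, b, 2)
        assert compound_similarity(["ANNA"], ["ANNA"], f) == 1.0
        assert compound_similarity(["ABCD"], ["XYZW"], f) == 0.0

    def test_greedy_one_to_one_use(self):
        # both query components prefer the same target, but it may be used once
        f = lambda a, b: dice_string(a, b, 2)
        sim = compound_similarity(["MEYER", "MEYER"], ["MEYER", "XYZW"], f)
        assert sim == pytest.approx(0.5)

    def test_order_invariance_of_sides(self):
        f = lambda a, b: dice_string(a, b, 2)
        a, b = ["PINKETT", "SMITH"], ["PINKETT"]
        assert compound_similarity(a, b, f) == compound_similarity(b, a, f)


class TestAggregate:
    def test_all_ones(self):
        assert aggregate_similarity({"a": 1, "b": 1}, {"a": 2.0, "b": 5.0}) == 1.0

    def test_two_fields(self):
        assert aggregate_similarity({"a": 1, "b": 0}, {"a": 1.0, "b": 3.0}) == pytest.approx(0.25)

    def test_table_weights_example(self):
        # hand evaluation with the registry weights, year disagrees:
        # (12.0406+15.1598+4.9011+3.5827)/40.8061 = 0.874478
        weights = {fc.field_id: fc.w for fc in default_plain_fields()}
        sims = {"first_name": 1, "last_name": 1, "birth_day": 1, "birth_month": 1, "birth_year": 0}
        assert aggregate_similarity(sims, weights) == pytest.approx(0.87448, abs=1e-4)

    def test_zero_weights_error(self):
        with pytest.raises(ConfigError):
            aggregate_similarity({"a": 1}, {})

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0.1, 20)), min_size=1, max_size=6))
    def test_bounded_by_field_extremes(self, pairs):
        sims = {f"f{i}": s for i, (s, _) in enumerate(pairs)}
        weights = {f"f{i}": w for i, (_, w) in enumerate(pairs)}
        agg = aggregate_similarity(sims, weights)
        assert min(sims.values()) - 1e-12 <= agg <= max(sims.values()) + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "sim,t1,t2,expected",
        [
            (0.95, 0.9, 0.8, MATCH),
            (0.9, 0.9, 0.8, MATCH),  # boundary: sim == t1
            (0.85, 0.9, 0.8, POSSIBLE),
            (0.8, 0.9, 0.8, POSSIBLE),  # boundary: sim == t2
            (0.5, 0.9, 0.8, NON_MATCH),
        ],
    )
    def test_three_way_rule(self, sim, t1, t2, expected):
        assert classify(sim, t1, t2) == expected

    def test_bad_thresholds(self):
        with pytest.raises(ConfigError):
            classify(0.5, 0.7, 0.9)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_similarity(self, s1, s2, t1, t2):
        """Raising the similarity never demotes the class."""
        if t1 < t2:
            t1, t2 = t2, t1
        lo, hi = min(s1, s2), max(s1, s2)
        rank = {NON_MATCH: 0, POSSIBLE: 1, MATCH: 2}
        assert rank[classify(hi, t1, t2)] >= rank[classify(lo, t1, t2)]


class TestBestMatch:
    def test_highest_candidate_wins(self):
        d = best_match([("y1", 0.9), ("y2", 0.95)], 0.8, 0.8)
        assert d.candidate_id == "y2" and d.decision == MATCH
        assert d.similarity == pytest.approx(0.95)

    def test_empty_candidates(self):
        d = best_match([], 0.8, 0.8)
        assert d.candidate_id is None and d.decision == NON_MATCH

    def test_tie_goes_to_earliest(self):
        d = best_match([("first", 0.9), ("second", 0.9)], 0.8, 0.8)
        assert d.candidate_id == "first"


def test_bloom_dice_tracks_string_dice():
    """Bit-vector Dice approximates q-gram Dice for random name pairs
    (statistical: the Bloom noise floor sits near the fill rate, so the
    bound holds on average, not per pair)."""
    ds = generate_dataset(DatasetSpec(total=200, seed=13))
    cfg = EncodingConfig()
    recs = [normalize_record(r) for r in ds.raw_records_a()[:120]]
    diffs = []
    for a, b in zip(recs[::2], recs[1::2]):
        if not (a.last_components and b.last_components):
            continue
        s_plain = dice_string(a.last_components[0], b.last_components[0], 2)
        ea, eb = encode_record(a, cfg), encode_record(b, cfg)
        s_bits = dice_bits(ea.components("last_name")[0], eb.components("last_name")[0])
        diffs.append(abs(s_plain - s_bits))
    assert len(diffs) >= 40
    assert sum(diffs) / len(diffs) <= 0.15
    assert max(diffs) <= 0.35
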