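import math

import edlib
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from seqchains import (
    SequenceSet,
    UnitInventory,
    coherence,
    levenshtein,
    loglog_r2,
    normalized_entropy,
    normalized_levenshtein,
    rank_table,
    segment_set,
    shannon_entropy,
    transmission_error,
    transmission_success,
    unit_inventory,
)

strings = st.text(alphabet="RYGB", min_size=1, max_size=14)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("RGBY", "RGBY", 0.0),
            ("RRRR", "GGGG", 1.0),
            ("RGB", "RG", 1 / 3),
        ],
    )
    def test_normalized_examples(self, a, b, expected):
        assert normalized_levenshtein(a, b) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalized_levenshtein("", "RG")

    @given(strings, strings)
    def test_matches_edlib_oracle(self, a, b):
        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]

    @given(strings, strings, strings)
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    def test_error_and_success(self):
        assert transmission_error("RGBY", "RGBY") == 0.0
        assert transmission_success("RGBY", "RGBY") == 1
        assert transmission_error("RRRR", "GGGG") == 1.0
        assert transmission_success("RRRR", "GGGG") == 0
        # accuracy display convention: (1 - error) * 100
        assert (1 - transmission_error("RGB", "RG")) * 100 == pytest.approx(100 * 2 / 3)


class TestInventory:
    def test_counts_and_sizes(self):
        inv = UnitInventory.from_units([["RGB", "YRG"], ["RGB"]])
        assert inv.freq == {"RGB": 2, "YRG": 1}
        assert inv.n_types == 2
        assert inv.n_tokens == 3

    def test_single_repeated_unit(self):
        inv = UnitInventory.from_units([["RG"] * 5])
        assert inv.n_types == 1
        assert inv.n_tokens == 5

    @given(st.integers(0, 300))
    def test_token_conservation_vs_segmentation(self, seed):
        from seqchains import random_set

        sset = random_set(n_seq=6, seq_len=10, seed=seed)
        seg = segment_set(sset, threshold=0.41)
        inv = unit_inventory(seg)
        assert sum(len(u) * f for u, f in inv.freq.items()) == sset.total_tokens


class TestEntropy:
    def test_uniform_four_types(self):
        inv = UnitInventory({"a": 1, "b": 1, "c": 1, "d": 1})
        assert shannon_entropy(inv) == pytest.approx(2.0)
        assert normalized_entropy(inv) == pytest.approx(1.0)

    def test_single_type_is_zero(self):
        inv = UnitInventory({"a": 5})
        assert shannon_entropy(inv) == 0.0
        assert normalized_entropy(inv) == 0.0

    def test_closed_form_three_to_one(self):
        inv = UnitInventory({"a": 3, "b": 1})
        expected = -0.75 * math.log2(0.75) - 0.25 * math.log2(0.25)
        assert shannon_entropy(inv) == pytest.approx(expected)

    @given(st.dictionaries(strings, st.integers(1, 30), min_size=1, max_size=20))
    def test_entropy_bounds(self, freq):
        inv = UnitInventory(freq)
        h = shannon_entropy(inv)
        assert -1e-12 <= h <= math.log2(inv.n_types) + 1e-12
        assert 0.0 <= normalized_entropy(inv) <= 1.0 + 1e-12


class TestRankTable:
    def test_descending_with_lexicographic_ties(self):
        inv = UnitInventory({"b": 2, "a": 2, "c": 3})
        table = rank_table(inv)
        assert list(table["unit"]) == ["c", "a", "b"]
        assert list(table["rank"]) == [1, 2, 3]
        assert list(table["frequency"]) == [3, 2, 2]

    @given(st.dictionaries(strings, st.integers(1, 50), min_size=1, max_size=25))
    def test_ranks_are_permutation_and_sorted(self, freq):
        table = rank_table(UnitInventory(freq))
        assert sorted(table["rank"]) == list(range(1, len(freq) + 1))
        assert list(table["frequency"]) == sorted(table["frequency"], reverse=True)


class TestLogLogR2:
    def test_exact_power_law_fits_perfectly(self):
        inv = UnitInventory({"a": 12, "b": 6, "c": 4, "d": 3})  # 12 / rank
        assert loglog_r2(rank_table(inv)) == pytest.approx(1.0)

    def test_equal_frequencies_return_zero(self):
        inv = UnitInventory({"a": 2, "b": 2, "c": 2})
        assert loglog_r2(rank_table(inv)) == 0.0

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            loglog_r2(rank_table(UnitInventory({"a": 3})))

    @given(st.dictionaries(strings, st.integers(1, 60), min_size=2, max_size=30))
    def test_matches_linregress_oracle(self, freq):
        table = rank_table(UnitInventory(freq))
        y = np.log(table["frequency"].to_numpy(dtype=float))
        if np.allclose(y.var(), 0):
            assert loglog_r2(table) == 0.0
            return
        fit = stats.linregress(np.log(table["rank"].to_numpy(dtype=float)), y)
        assert loglog_r2(table) == pytest.approx(fit.rvalue**2, abs=1e-10)

    def test_invariant_under_frequency_scaling(self):
        inv = UnitInventory({"a": 9, "b": 5, "c": 5, "d": 1})
        scaled = UnitInventory({k: 7 * v for k, v in inv.freq.items()})
        assert loglog_r2(rank_table(inv)) == pytest.approx(
            loglog_r2(rank_table(scaled))
        )


class TestCoherence:
    def test_no_boundaries_between_is_missing(self):
        sset = SequenceSet(["RRRR", "RRRR"])
        seg = segment_set(sset, threshold=0.41)
        coh = coherence(seg)
        assert coh.n_between == 0
        assert math.isnan(coh.between_tp)
        all_tps = [tp for tps in seg.tps for tp in tps]
        assert coh.within_tp == pytest.approx(np.mean(all_tps))

    def test_deterministic_repeats_have_unit_tps(self):
        sset = SequenceSet(["RGBRGBRGBRGB"] * 4)
        seg = segment_set(sset, threshold=0.41)
        coh = coherence(seg)
        assert coh.within_tp == pytest.approx(1.0)

    def test_hand_pooled_two_sequence_set(self, two_seq_set):
        seg = segment_set(two_seq_set, threshold=0.41)
        # force a known boundary layout: cut "RGB" nowhere, "RGY" nowhere,
        # then place one boundary manually and pool by hand
        manual = seg.replace_boundaries([(), ()])
        coh = coherence(manual)
        pooled = [tp for tps in seg.tps for tp in tps]
        assert coh.n_between == 0
        assert coh.within_tp == pytest.approx(np.mean(pooled))

    def test_classification_splits_positions(self):
        sset = SequenceSet(["RGBRGBRGBRGB"] * 3 + ["RGBYYYRGBYYY"])
        seg = segment_set(sset, threshold=0.41)
        coh = coherence(seg)
        total = sum(len(tps) for tps in seg.tps)
        assert coh.n_within + coh.n_between == total
        # between-unit positions are exactly those following a boundary
        n_bound = sum(len(b) for b in seg.boundaries)
        assert coh.n_between == n_bound
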