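"""Composition-preserving shuffles and empirical nulls."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cisconserve import (
    NullDistribution,
    ShuffleConfig,
    empirical_p,
    empirical_similarity_null,
    shuffle_preserving_klets,
)

dna = st.text(alphabet="ACGT", min_size=10, max_size=120)


def klet_counts(s: str, k: int) -> Counter:
    return Counter(s[i : i + k] for i in range(len(s) - k + 1))


class TestExactKletShuffle:
    def test_single_letter_alphabet_is_fixed_point(self, rng):
        assert shuffle_preserving_klets("AAAA", 1, rng) == "AAAA"

    def test_dinucleotide_counts_preserved(self, rng):
        s = "ACGTACGT"
        out = shuffle_preserving_klets(s, 2, rng)
        assert klet_counts(out, 2) == klet_counts(s, 2)

    def test_output_within_enumerated_doublet_preserving_set(self, rng):
        s = "ACACGT"
        target = klet_counts(s, 2)
        valid = {
            "".join(p)
            for p in itertools.permutations(s)
            if klet_counts("".join(p), 2) == target
        }
        for _ in range(20):
            assert shuffle_preserving_klets(s, 2, rng) in valid

    @given(dna, st.sampled_from([1, 2, 3]))
    def test_all_klet_tables_up_to_order_preserved(self, s, order):
        if len(s) <= order:
            return
        out = shuffle_preserving_klets(s, order, np.random.default_rng(0))
        assert len(out) == len(s)
        for k in range(1, order + 1):
            assert klet_counts(out, k) == klet_counts(s, k)

    def test_terminal_context_preserved_for_higher_orders(self, random_dna_factory):
        s = random_dna_factory(200)
        for order in (2, 3):
            out = shuffle_preserving_klets(s, order, np.random.default_rng(5))
            assert out[: order - 1] == s[: order - 1]
            assert out[-(order - 1) :] == s[-(order - 1) :]

    def test_same_seed_gives_identical_output(self, random_dna_factory):
        s = random_dna_factory(300)
        a = shuffle_preserving_klets(s, 3, np.random.default_rng(11))
        b = shuffle_preserving_klets(s, 3, np.random.default_rng(11))
        assert a == b

    def test_shuffle_actually_moves_things(self, random_dna_factory):
        s = random_dna_factory(300)
        outs = {shuffle_preserving_klets(s, 2, np.random.default_rng(i)) for i in range(5)}
        assert len(outs) > 1

    def test_degenerate_graph_warns_and_returns_input(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert shuffle_preserving_klets("ACGTT", 2, np.random.default_rng(0)) == "ACGTT"

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            shuffle_preserving_klets("AC", 3, np.random.default_rng(0))

    def test_n_positions_fixed_and_segments_preserved(self, rng):
        s = "ACGTACGTAC" + "N" + "TTGACCAGTT" + "NN" + "GT"
        out = shuffle_preserving_klets(s, 2, rng)
        assert len(out) == len(s)
        assert [i for i, c in enumerate(out) if c == "N"] == [10, 21, 22]
        # each N-free segment keeps its own dinucleotide table
        assert klet_counts(out[:10], 2) == klet_counts(s[:10], 2)
        assert klet_counts(out[11:21], 2) == klet_counts(s[11:21], 2)
        assert out[23:] == s[23:]


class TestMarkovShuffle:
    def test_counts_preserved_in_expectation_but_not_exactly(self, random_dna_factory):
        s = random_dna_factory(300)
        target = klet_counts(s, 2)
        exact_ok = all(
            klet_counts(shuffle_preserving_klets(s, 2, np.random.default_rng(i)), 2) == target
            for i in range(30)
        )
        markov_tables = [
            klet_counts(
                shuffle_preserving_klets(s, 2, np.random.default_rng(i), method="markov"), 2
            )
            for i in range(30)
        ]
        assert exact_ok
        assert any(t != target for t in markov_tables)
        # in expectation the per-dinucleotide mean count is close to the target
        mean_aa = np.mean([t["AA"] for t in markov_tables])
        assert abs(mean_aa - target["AA"]) < 5 * np.sqrt(max(target["AA"], 1))


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "counts,observed,expected",
        [([1, 2, 3, 4], 2, 0.5), ([1, 2, 3], 5, 0.0), ([4, 5, 6], 1, 1.0)],
    )
    def test_strict_greater_formula(self, counts, observed, expected):
        assert empirical_p(counts, observed) == expected

    def test_add_one_estimator_never_zero(self):
        assert empirical_p([1, 2, 3], 5, estimator="add_one") == pytest.approx(0.25)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            empirical_p([], 1)


class TestEmpiricalSimilarityNull:
    def test_self_comparison_is_never_exceeded(self, random_dna_factory):
        s = random_dna_factory(400)
        null = empirical_similarity_null(
            s, s, 10, config=ShuffleConfig(order=2, n_replicates=200, seed=9)
        )
        assert null.empirical_p == 0.0
        assert null.annotation == "< 0.005"

    def test_reproducible_from_config_seed(self, random_dna_factory):
        ref, qry = random_dna_factory(300), random_dna_factory(300)
        cfg = ShuffleConfig(order=2, n_replicates=50, seed=4)
        a = empirical_similarity_null(ref, qry, 8, config=cfg)
        b = empirical_similarity_null(ref, qry, 8, config=cfg)
        assert a.replicate_counts == b.replicate_counts
        assert a.observed == b.observed

    def test_null_location_scales_with_query_length(self, random_dna_factory):
        # a twice-as-long ortholog shifts the whole replicate distribution right
        ref = random_dna_factory(600, p=(0.32, 0.18, 0.18, 0.32))
        q1 = random_dna_factory(600, p=(0.32, 0.18, 0.18, 0.32))
        q2 = random_dna_factory(1200, p=(0.32, 0.18, 0.18, 0.32))
        cfg = ShuffleConfig(order=1, n_replicates=150, seed=2)
        short = empirical_similarity_null(ref, q1, 8, config=cfg)
        long = empirical_similarity_null(ref, q2, 8, config=cfg)
        assert np.mean(long.replicate_counts) > np.mean(short.replicate_counts)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ShuffleConfig(order=4)
        with pytest.raises(ValueError):
            ShuffleConfig(n_replicates=0)
        with pytest.raises(ValueError):
            ShuffleConfig(method="bogus")

    def test_null_distribution_json_summary(self, random_dna_factory):
        s = random_dna_factory(200)
        null = empirical_similarity_null(
            s, s, 8, config=ShuffleConfig(order=1, n_replicates=20, seed=1)
        )
        assert isinstance(null, NullDistribution)
        import json

        payload = json.loads(null.to_json())
        assert payload["observed"] == null.observed
        assert payload["n_replicates"] == 20
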