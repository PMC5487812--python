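"""Tests for starting-rating initialization from prior dominance history."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eloseq import (
    PriorSpec,
    categorical_to_ordinal,
    derive_starting_ratings,
    load_prior_config,
)


def brute_starting_ratings(ranks, s_e=1000.0, k=200.0, i_r=0.0):
    """Independent plain-loop evaluation of E_i = S_e + (x_r - S_ri) K S_ri^-I_r
    followed by mean-centering on S_e."""
    vals = sorted(ranks.values())
    m = len(vals)
    x_r = (vals[m // 2] if m % 2 else (vals[m // 2 - 1] + vals[m // 2]) / 2.0)
    raw = {i: s_e + (x_r - r) * k * r ** (-i_r) for i, r in ranks.items()}
    shift = s_e - sum(raw.values()) / m
    return {i: v + shift for i, v in raw.items()}


class TestCategoricalToOrdinal:
    def test_four_categories_at_n14(self):
        got = categorical_to_ordinal(
            {"a": "alpha", "b": "high", "c": "medium", "d": "low"}, 14
        )
        assert got == {"a": 1.0, "b": 3.5, "c": 7.0, "d": 10.5}

    def test_alpha_is_always_rank_one(self):
        assert categorical_to_ordinal({"a": "alpha"}, 4) == {"a": 1.0}

    def test_low_is_three_quarters_down(self):
        assert categorical_to_ordinal({"a": "low"}, 8) == {"a": 6.0}

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="boss"):
            categorical_to_ordinal({"a": "boss"}, 5)

    def test_shared_category_means_shared_rank(self):
        got = categorical_to_ordinal({"a": "high", "b": "high"}, 12)
        assert got["a"] == got["b"] == 3.0


class TestDeriveStartingRatings:
    def test_linear_spacing_at_zero_index(self):
        spec = PriorSpec(prior_ranks={"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        got = derive_starting_ratings(spec, {"a", "b", "c", "d", "e"})
        assert got == {"a": 1400.0, "b": 1200.0, "c": 1000.0, "d": 800.0, "e": 600.0}

    def test_single_ranked_id_sits_at_baseline(self):
        spec = PriorSpec(prior_ranks={"a": 1}, starting_value=1234.0, rank_index=0.7)
        assert derive_starting_ratings(spec, {"a"}) == {"a": 1234.0}

    def test_spreading_index_stretches_top_and_compresses_bottom(self):
        roster = {f"i{r}" for r in range(1, 11)}
        ranks = {f"i{r}": r for r in range(1, 11)}
        def gaps(i_r):
            spec = PriorSpec(prior_ranks=ranks, rank_index=i_r)
            got = derive_starting_ratings(spec, roster)
            top = got["i1"] - got["i2"]
            bottom = got["i9"] - got["i10"]
            return top / bottom
        assert gaps(0.3) > gaps(0.0)

    def test_matches_independent_formula_evaluation(self):
        ranks = {"a": 1, "b": 2.5, "c": 2.5, "d": 6, "e": 9}
        for i_r in (0.0, 0.3, 0.9):
            spec = PriorSpec(prior_ranks=ranks, rank_index=i_r, starting_value=900.0, k=150.0)
            got = derive_starting_ratings(spec, set(ranks) | {"z"})
            want = brute_starting_ratings(ranks, s_e=900.0, k=150.0, i_r=i_r)
            for sid in ranks:
                assert got[sid] == pytest.approx(want[sid], abs=1e-9)
            assert got["z"] == 900.0  # unranked id gets the baseline exactly

    def test_explicit_elo_wins_over_ranks(self):
        spec = PriorSpec(prior_elo={"a": 1500.0}, prior_ranks={"a": 1, "b": 2})
        got = derive_starting_ratings(spec, {"a", "b"})
        assert got == {"a": 1500.0, "b": 1000.0}

    def test_ranks_win_over_categories(self):
        spec = PriorSpec(
            prior_ranks={"a": 1, "b": 2, "c": 3},
            prior_categories={"a": "low", "b": "low", "c": "low"},
        )
        got = derive_starting_ratings(spec, {"a", "b", "c"})
        assert got["a"] > got["b"] > got["c"]

    def test_no_priors_means_common_start(self):
        got = derive_starting_ratings(PriorSpec(), {"a", "b"})
        assert got == {"a": 1000.0, "b": 1000.0}

    def test_categorical_priors_flow_through_formula(self):
        spec = PriorSpec(prior_categories={"a": "alpha", "b": "medium", "c": "low"})
        got = derive_starting_ratings(spec, {"a", "b", "c", "d"})
        # ordinal ranks 1, 2, 3 for N=4; centering keeps the mean at 1000
        assert got["a"] > got["b"] > got["c"]
        assert got["d"] == 1000.0
        assert np.mean([got["a"], got["b"], got["c"]]) == pytest.approx(1000.0, abs=1e-9)

    def test_prior_id_outside_roster_rejected(self):
        spec = PriorSpec(prior_ranks={"a": 1, "x": 2})
        with pytest.raises(ValueError, match="x"):
            derive_starting_ratings(spec, {"a", "b"})

    def test_negative_spreading_index_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(rank_index=-0.1)

    @given(
        st.lists(st.floats(1, 30), min_size=2, max_size=12),
        st.sampled_from([0.0, 0.3, 0.9]),
    )
    def test_order_preserved_and_centered(self, rank_values, i_r):
        ranks = {f"id{n}": r for n, r in enumerate(rank_values)}
        spec = PriorSpec(prior_ranks=ranks, rank_index=i_r)
        got = derive_starting_ratings(spec, set(ranks))
        # more dominant (smaller rank) never rated lower
        for a in ranks:
            for b in ranks:
                if ranks[a] < ranks[b]:
                    assert got[a] >= got[b]
                elif ranks[a] == ranks[b]:
                    assert got[a] == got[b]
        assert np.mean(list(got.values())) == pytest.approx(1000.0, abs=1e-9)

    @given(st.integers(2, 15))
    def test_complete_ranks_space_exactly_k_at_zero_index(self, n):
        ranks = {f"id{r}": r for r in range(1, n + 1)}
        got = derive_starting_ratings(PriorSpec(prior_ranks=ranks), set(ranks))
        for r in range(1, n):
            assert got[f"id{r}"] - got[f"id{r + 1}"] == pytest.approx(200.0, abs=1e-9)

    def test_top_to_bottom_gap_ratio_nondecreasing_in_index(self):
        ranks = {f"i{r}": r for r in range(1, 11)}
        ratios = []
        for i_r in (0.0, 0.1, 0.3, 0.6, 0.9):
            got = derive_starting_ratings(
                PriorSpec(prior_ranks=ranks, rank_index=i_r), set(ranks)
            )
            ratios.append((got["i1"] - got["i2"]) / (got["i9"] - got["i10"]))
        assert all(a <= b + 1e-12 for a, b in zip(ratios, ratios[1:]))


class TestLoadPriorConfig:
    def test_empty_file_gives_defaults(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("")
        spec = load_prior_config(p)
        assert spec.starting_value == 1000.0
        assert spec.k == 200.0
        assert spec.rank_index == 0.0
        assert not spec.has_priors

    def test_r_style_keys_accepted(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("priorRankIndex: 0.3\npriorRanks:\n  DN: 1\n  ZF: 2\n")
        spec = load_prior_config(p)
        assert spec.rank_index == 0.3
        assert spec.prior_ranks == {"DN": 1.0, "ZF": 2.0}
        assert spec.starting_value == 1000.0

    def test_both_elo_and_ranks_retained(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("prior_elo:\n  a: 1500\nprior_ranks:\n  a: 1\n  b: 2\n")
        spec = load_prior_config(p)
        assert spec.prior_elo and spec.prior_ranks  # precedence applied downstream

    def test_unknown_key_named_in_error(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("starting_valeu: 900\n")
        with pytest.raises(ValueError, match="starting_valeu"):
            load_prior_config(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("prior_ranks:\n  a: 1\n  a: 2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_prior_config(p)

    def test_non_numeric_rank_rejected(self, tmp_path):
        p = tmp_path / "priors.yaml"
        p.write_text("prior_ranks:\n  a: first\n")
        with pytest.raises(ValueError, match="prior_ranks"):
            load_prior_config(p)
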