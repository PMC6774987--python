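"""Song-type classification, eligibility, percent-matched and consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from levensong.assignment import (
    AssignmentConfig,
    assign_by_percent,
    build_assignment_table,
    classify_song_type,
    consensus,
    filter_eligible,
    percent_matched,
)
from levensong.corpus import SongCorpus

from conftest import make_corpus, make_singer


class TestClassifySongType:
    def test_full_type_sequences(self):
        assert classify_song_type([1, 2, 3, 4, 5, 6]).types == ("2",)
        assert classify_song_type([7, 9, 11, 12, 13, 14]).types == ("1b",)
        assert classify_song_type([15, 16, 17]).types == ("3",)

    def test_shared_themes_resolved_by_discriminating_theme(self):
        assert classify_song_type([7, 8, 9]).types == ("1a",)
        assert classify_song_type([7, 9, 12]).types == ("1b",)

    def test_only_shared_themes_flagged_ambiguous(self):
        call = classify_song_type([7, 9, 11])
        assert call.kind == "single" and call.ambiguous

    def test_hybrid_two_types(self):
        call = classify_song_type([1, 2, 3, 8])
        assert call.kind == "hybrid"
        assert call.types == ("2", "1a")

    def test_unclassified_three_types(self):
        assert classify_song_type([1, 8, 15]).kind == "unclassified"

    def test_unknown_theme_rejected(self):
        with pytest.raises(ValueError, match="unknown theme"):
            classify_song_type([1, 2, 99])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_song_type([])


class TestPercentMatched:
    def test_paper_worked_example(self):
        """Five phrase types, four shared -> 80%; five shared -> 100%."""
        singer = {"1A", "2A", "3A", "4A", "5A"}
        assert percent_matched(singer, {"1A", "2A", "3A", "4A"}) == 80.0
        assert percent_matched(singer, singer | {"6A"}) == 100.0

    def test_identical_and_disjoint(self):
        assert percent_matched({"1A"}, {"1A"}) == 100.0
        assert percent_matched({"1A"}, {"2A"}) == 0.0

    def test_empty_singer_rejected(self):
        with pytest.raises(ValueError):
            percent_matched(set(), {"1A"})

    def test_scale_free_in_ground_sampling(self):
        """Pooled inventories make the statistic independent of how many
        singers sampled a ground: duplicating singers changes nothing."""
        from levensong.corpus import phrase_inventory

        base = make_corpus(
            make_singer("NC01S1", [("1A", "a"), ("2A", "b")]),
            make_singer("NC02S1", [("3A", "c")]),
        )
        doubled = make_corpus(
            make_singer("NC01S1", [("1A", "a"), ("2A", "b")]),
            make_singer("NC02S1", [("3A", "c")]),
            make_singer("NC03S1", [("1A", "a"), ("2A", "b")]),
            make_singer("NC04S1", [("3A", "c")]),
        )
        singer = {"1A", "3A", "9B"}
        assert percent_matched(singer, phrase_inventory(base, "NC")) == (
            percent_matched(singer, phrase_inventory(doubled, "NC"))
        )


class TestAssignByPercent:
    def test_tie_is_unassigned(self):
        assert assign_by_percent({"NC": 100, "TO": 100, "NI": 100, "CI": 80}) is None

    def test_strict_argmax(self):
        assert assign_by_percent({"NC": 100, "TO": 80, "NI": 80, "CI": 60}) == "NC"

    def test_all_equal_unassigned(self):
        assert assign_by_percent({"NC": 50, "TO": 50}) is None

    @given(
        st.dictionaries(
            st.sampled_from(["NC", "TO", "NI", "CI"]),
            st.integers(0, 10).map(lambda v: 10.0 * v),
            min_size=1,
        )
    )
    def test_never_returns_non_unique_max(self, pct):
        call = assign_by_percent(pct)
        if call is not None:
            top = max(pct.values())
            assert pct[call] == top
            assert sum(v == top for v in pct.values()) == 1


def _grounds():
    return make_corpus(
        make_singer("NC01S1", [("1A", "a"), ("2A", "b"), ("3B", "q")]),
        make_singer("TO01S1", [("1A", "a"), ("2A", "b"), ("4A", "d")]),
    )


class TestFilterEligible:
    def test_single_phrase_type_excluded(self):
        stop = make_corpus(make_singer("KI01S1", [("1A", "a"), ("1A", "a b")]))
        eligible, excluded = filter_eligible(stop, _grounds())
        assert eligible == []
        assert excluded[0].flag == "single_phrase_type"

    def test_exclusive_phrase_conflict_excluded(self):
        # 3B exists only at NC; 4A is absent from NC
        stop = make_corpus(make_singer("KI02S1", [("3B", "q"), ("4A", "d")]))
        eligible, excluded = filter_eligible(stop, _grounds())
        assert eligible == []
        assert excluded[0].flag == "exclusive_phrase_conflict"

    def test_broadly_shared_singer_retained(self):
        stop = make_corpus(make_singer("KI03S1", [("1A", "a"), ("2A", "b")]))
        eligible, excluded = filter_eligible(stop, _grounds())
        assert eligible == ["KI03S1"] and excluded == []

    def test_exclusive_phrase_alone_is_fine(self):
        # singing NC-exclusive 3B plus phrases NC also has: consistent evidence
        stop = make_corpus(make_singer("KI04S1", [("3B", "q"), ("1A", "a")]))
        eligible, excluded = filter_eligible(stop, _grounds())
        assert eligible == ["KI04S1"]


class TestConsensus:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (("NC", "NC", "NC"), "NC"),
            (("CI", "CI", "CI"), "CI"),
            (("NC", "TO", None), None),
            (("NC", "NC", None), None),  # strict needs all three
            ((None, None, None), None),
        ],
    )
    def test_strict(self, calls, expected):
        assert consensus(*calls, mode="strict") == expected

    @pytest.mark.parametrize(
        "calls, expected",
        [
            (("NC", "NC", None), "NC"),
            (("NC", None, None), None),
            (("NC", "NC", "TO"), None),
        ],
    )
    def test_lenient(self, calls, expected):
        assert consensus(*calls, mode="lenient") == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            consensus("NC", "NC", "NC", mode="majority")


def test_empty_stopover_gives_empty_table(small_costs):
    table, excluded = build_assignment_table(
        _grounds(), SongCorpus(), small_costs,
        AssignmentConfig(B=100, seed=0),
    )
    assert len(table) == 0 and excluded == []
    assert "consensus" in table.columns


def test_consensus_implies_all_methods_agree(small_costs):
    """Whenever the strict consensus is defined, the three per-method origin
    columns name the same ground."""
    from levensong.synthetic import SyntheticConfig, generate_corpus, generate_unit_inventory
    from levensong.units import substitution_costs
    import warnings

    cfg = SyntheticConfig(
        seed=13, n_unit_types=16,
        song_type_assignments={"PA": "2", "PB": "2", "PC": "1a"},
        singers_per_population=4, n_stopover_singers=10,
    )
    grounds, stopover, _ = generate_corpus(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        costs = substitution_costs(generate_unit_inventory(cfg))
    table, _ = build_assignment_table(
        grounds, stopover, costs, AssignmentConfig(B=100, seed=1)
    )
    for row in table.itertuples():
        if row.consensus is not None:
            assert (
                row.origin_pct == row.origin_fine_lsi
                == row.origin_broad_lsi == row.consensus
            )


def test_single_population_stopover_never_assigned_elsewhere():
    """Stopover corpus drawn from one population: every call either names
    that population or abstains."""
    from levensong.synthetic import SyntheticConfig, generate_corpus, generate_unit_inventory
    from levensong.units import substitution_costs
    import warnings

    cfg = SyntheticConfig(
        seed=29, n_unit_types=16,
        song_type_assignments={"PA": "2", "PB": "2", "PC": "1a"},
        singers_per_population=4, n_stopover_singers=8,
        stopover_mixture={"PA": 1.0, "PB": 0.0, "PC": 0.0},
    )
    grounds, stopover, truth = generate_corpus(cfg)
    assert {truth[sid].population for sid in stopover.singers} == {"PA"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        costs = substitution_costs(generate_unit_inventory(cfg))
    table, _ = build_assignment_table(
        grounds, stopover, costs, AssignmentConfig(B=100, seed=2)
    )
    for col in ("origin_pct", "consensus"):
        vals = {v for v in table[col] if v is not None}
        assert vals <= {"PA"}
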