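"""Competitive partitioning: growth responses, expectations, components, BPM."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

import comppart as cp
from conftest import community_strategy


class TestMaxGrowthResponse:
    def test_dominant_release_from_half_density(self):
        ref = cp.SpeciesReference("Dactylis", 9.8, 6.0)
        mg = cp.max_growth_response(ref, 11.5, 3.0, is_more_competitive=True)
        assert mg == pytest.approx((11.5 / 3) / (9.8 / 6) - 1, rel=1e-12)
        assert mg == pytest.approx(1.3469, abs=1e-4)

    def test_subordinate_is_excluded(self):
        ref = cp.SpeciesReference("x", 5.0, 6.0)
        assert cp.max_growth_response(ref, None, 3.0, is_more_competitive=False) == -1.0

    def test_no_density_response_gives_zero(self):
        ref = cp.SpeciesReference("x", 6.0, 6.0)  # w_if = 1
        assert cp.max_growth_response(ref, 3.0, 3.0, True) == pytest.approx(0.0)

    def test_missing_partial_monoculture_raises(self):
        ref = cp.SpeciesReference("x", 6.0, 6.0)
        with pytest.raises(cp.ComppartError, match="MG override"):
            cp.max_growth_response(ref, None, 3.0, True)

    def test_dominant_shrinking_at_low_density_warns(self):
        ref = cp.SpeciesReference("x", 6.0, 6.0)
        with pytest.warns(cp.ComppartWarning, match="smaller at partial density"):
            mg = cp.max_growth_response(ref, 2.0, 3.0, True)
        assert mg < 0


class TestRelativeCompetitiveAbility:
    def test_two_species(self):
        rc = cp.relative_competitive_ability({"a": 5.5, "b": 9.8})
        assert rc["a"] == rc["b"] == pytest.approx(4.3 / 9.8)

    def test_equal_abilities_give_zero(self):
        rc = cp.relative_competitive_ability({"a": 3.0, "b": 3.0, "c": 3.0})
        assert all(v == 0.0 for v in rc.values())

    def test_zero_opponent_gives_unity(self):
        rc = cp.relative_competitive_ability({"a": 7.0, "b": 0.0})
        assert rc == pytest.approx({"a": 1.0, "b": 1.0})

    def test_all_zero_rejected(self):
        with pytest.raises(cp.ComppartError):
            cp.relative_competitive_ability({"a": 0.0, "b": 0.0})

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=6).filter(
            lambda h: max(h) > 0
        )
    )
    def test_bounded_in_unit_interval(self, h_values):
        rc = cp.relative_competitive_ability(
            {f"s{i}": h for i, h in enumerate(h_values)}
        )
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in rc.values())


class TestCompetitiveExpectation:
    def test_grassland_pair(self, bromus_dactylis):
        responses = cp.competitive_responses(bromus_dactylis)
        y_ce = cp.competitive_expectation(bromus_dactylis, responses)
        rc = 4.3 / 9.8
        assert y_ce["Dactylis"] == pytest.approx(4.9 * (1 + ((11.5 / 3) / (9.8 / 6) - 1) * rc))
        assert y_ce["Dactylis"] == pytest.approx(7.80, abs=0.01)
        assert y_ce["Bromus"] == pytest.approx(2.75 * (1 - rc))
        assert y_ce["Bromus"] == pytest.approx(1.543, abs=0.001)

    def test_equal_abilities_reduce_to_null_expectation(self):
        com = cp.make_two_species_community(
            "m", (8.0, 4.0), (5.0, 3.0), m_partial=(8.0, 4.0), abilities=(2.0, 2.0)
        )
        responses = cp.competitive_responses(com)
        y_ce = cp.competitive_expectation(com, responses)
        assert y_ce == pytest.approx(cp.null_expectation(com))
        part = cp.partition_community(com)
        assert part.competitive_effect == pytest.approx(0.0, abs=1e-12)
        assert part.positive_effect + part.negative_effect == pytest.approx(part.net)


class TestPartitionCommunity:
    @pytest.mark.parametrize(
        "mixture, positive, competitive, negative",
        [
            ("Bromus:Dactylis", 1.86, 1.69, 0.0),
            ("Dactylis:Sanguisorba", 0.0, 2.43, -1.63),
            ("Lotus:Sanguisorba", 0.0, None, None),
        ],
    )
    def test_grassland_rows(self, grassland, mixture, positive, competitive, negative):
        com = next(c for c in grassland if c.mixture_id == mixture)
        part = cp.partition_community(com)
        assert part.positive_effect == pytest.approx(positive, abs=0.01)
        if competitive is not None:
            assert part.competitive_effect == pytest.approx(competitive, abs=0.01)
            assert part.negative_effect == pytest.approx(negative, abs=0.01)

    def test_lotus_sanguisorba_combined_column(self, grassland):
        com = next(c for c in grassland if c.mixture_id == "Lotus:Sanguisorba")
        part = cp.partition_community(com)
        assert part.combined_comp_neg == pytest.approx(-0.9, abs=0.2)

    @given(community_strategy())
    def test_components_sum_to_net(self, com):
        part = cp.partition_community(com)
        total = part.positive_effect + part.negative_effect + part.competitive_effect
        assert total == pytest.approx(part.net, rel=1e-9, abs=1e-9)

    @given(community_strategy())
    def test_sign_separation(self, com):
        part = cp.partition_community(com)
        assert part.positive_effect >= 0.0
        assert part.negative_effect <= 0.0
        assert part.positive_effect * part.negative_effect == 0.0

    @given(community_strategy(min_species=2, max_species=2))
    def test_two_species_competitive_effect_equals_rc_times_bpm(self, com):
        """Closed form: with d_total = d_f the dominant's Y_NE*MG telescopes to
        M_ip - Y_NE, so competitive effect = RC * BPM."""
        abilities = {
            s: com.reference(s).mono_full_yield for s in com.species_ids
        }
        if len(set(abilities.values())) < 2:
            return  # tie: BPM ambiguous, competitive effect 0
        part = cp.partition_community(com)
        rc = cp.relative_competitive_ability(abilities)
        rc_value = next(iter(rc.values()))
        assert part.competitive_effect == pytest.approx(
            rc_value * part.bpm, rel=1e-9, abs=1e-9
        )

    def test_competitive_exclusion_limit(self):
        """RC = 1 with observed yields (M_ip, 0): the whole net effect is
        competitive and equals BPM."""
        com = cp.make_two_species_community(
            "m",
            (10.0, 6.0),
            (9.0, 0.0),
            m_partial=(9.0, 3.0),
            abilities=(10.0, 0.0),
        )
        part = cp.partition_community(com)
        assert part.positive_effect == pytest.approx(0.0, abs=1e-12)
        assert part.negative_effect == pytest.approx(0.0, abs=1e-12)
        assert part.competitive_effect == pytest.approx(part.net)
        assert part.competitive_effect == pytest.approx(part.bpm)

    @given(st.floats(5.0, 20.0), st.floats(0.0, 5.0))
    def test_competitive_effect_nondecreasing_in_dominant_partial_yield(
        self, m_ip, bump
    ):
        def comp(mp):
            com = cp.make_two_species_community(
                "m", (10.0, 4.0), (6.0, 2.0), m_partial=(mp, 2.0)
            )
            return cp.partition_community(com).competitive_effect

        assert comp(m_ip + bump) >= comp(m_ip) - 1e-12

    @given(community_strategy(), st.floats(0.01, 50.0))
    def test_scale_invariance(self, com, c):
        part = cp.partition_community(com)
        scaled = dataclasses.replace(
            com,
            observations=tuple(
                dataclasses.replace(
                    o,
                    yield_observed=o.yield_observed * c,
                    mono_partial_yield=None
                    if o.mono_partial_yield is None
                    else o.mono_partial_yield * c,
                )
                for o in com.observations
            ),
            references={
                k: dataclasses.replace(r, mono_full_yield=r.mono_full_yield * c)
                for k, r in com.references.items()
            },
        )
        scaled_part = cp.partition_community(scaled)
        for attr in ("net", "positive_effect", "competitive_effect", "negative_effect", "bpm"):
            assert getattr(scaled_part, attr) == pytest.approx(
                c * getattr(part, attr), rel=1e-9, abs=1e-9
            )

    def test_tied_abilities_are_inert(self):
        com = cp.make_two_species_community(
            "m", (8.0, 8.0), (5.0, 3.0), m_partial=(7.0, 7.0)
        )
        part = cp.partition_community(com)
        assert part.competitive_effect == pytest.approx(0.0, abs=1e-12)
        for sp in part.species:
            assert sp.mg == 0.0
            assert sp.rc == 0.0

    def test_error_carries_mixture_id(self):
        com = cp.make_two_species_community(
            "broken-mix", (8.0, 4.0), (5.0, 3.0)  # dominant lacks M_ip
        )
        with pytest.raises(cp.ComppartError, match="broken-mix"):
            cp.partition_community(com)

    def test_mg_override_replaces_partial_density_estimate(self):
        com = cp.make_two_species_community("m", (8.0, 4.0), (5.0, 3.0))
        config = cp.RunConfig(mg_overrides={("m", "sp1"): 0.5})
        part = cp.partition_community(com, config)
        sp1 = next(s for s in part.species if s.species_id == "sp1")
        assert sp1.mg == 0.5


class TestBpm:
    @pytest.mark.parametrize(
        "fixture_name, mixture, expected",
        [
            ("grassland", "Bromus:Dactylis", 3.85),
            ("trees", "Populus:Picea_40y_50:50", 28.2),
            ("trees", "Populus:Picea_80y_10:90", -28.31),
        ],
    )
    def test_fixture_values(self, request, fixture_name, mixture, expected):
        dataset = request.getfixturevalue(fixture_name)
        com = next(c for c in dataset if c.mixture_id == mixture)
        assert cp.bpm_statistic(com) == pytest.approx(expected, abs=0.01)

    def test_positive_in_32_of_35_mixtures(self, grassland, trees):
        values = [
            cp.bpm_statistic(c) for c in list(trees) + list(grassland)
        ]
        assert sum(v > 0 for v in values) == 32

    def test_tie_reports_maximum(self):
        com = cp.make_two_species_community(
            "m", (8.0, 8.0), (5.0, 3.0), m_partial=(7.0, 6.0)
        )
        assert cp.bpm_statistic(com) == pytest.approx(7.0 - 8.0)

    def test_missing_dominant_partial_yield_raises(self):
        com = cp.make_two_species_community(
            "m", (8.0, 4.0), (5.0, 3.0), m_partial=(None, 2.0)
        )
        with pytest.raises(cp.ComppartError, match="BPM undefined"):
            cp.bpm_statistic(com)


class TestClassification:
    def test_spruce_facilitation_in_mature_nearly_pure_stand(self, trees):
        com = next(c for c in trees if c.mixture_id == "Populus:Picea_80y_10:90")
        part = cp.partition_community(com)
        classes = {s.species_id: s.interaction_class for s in part.species}
        assert classes["Picea"] == "facilitative"

    def test_exact_competitive_expectation_is_neutral(self):
        com = cp.make_two_species_community(
            "m", (8.0, 4.0), (5.0, 3.0), m_partial=(7.0, 2.0)
        )
        part = cp.partition_community(com)
        sp1 = next(s for s in part.species if s.species_id == "sp1")
        obs = dataclasses.replace(
            com.observation("sp1"), yield_observed=sp1.y_ce
        )
        assert cp.classify_species(obs, sp1.y_ne, sp1.y_ce) == "neutral"

    def test_young_aspen_suppressed_below_competitive_expectation(self, trees):
        com = next(c for c in trees if c.mixture_id == "Populus:Picea_20y_50:50")
        part = cp.partition_community(com)
        populus = next(s for s in part.species if s.species_id == "Populus")
        assert populus.y_ce == pytest.approx(21.0, abs=0.2)
        assert populus.interaction_class == "negative"

    def test_missing_partial_yield_warns_and_falls_back_to_sign(self):
        obs = cp.MixtureObservation("x", 0.5, 9.0)
        with pytest.warns(cp.ComppartWarning, match="facilitation test skipped"):
            assert cp.classify_species(obs, 4.0, 5.0) == "positive"

    @pytest.mark.parametrize(
        "classes, label",
        [
            (("positive", "positive"), "mutualism (+/+)"),
            (("facilitative", "neutral"), "commensalism (+/0)"),
            (("positive", "negative"), "parasitism (+/-)"),
            (("neutral", "negative"), None),
        ],
    )
    def test_pair_labels(self, classes, label):
        assert cp.pair_interaction_label(classes) == label


class TestMultispeciesAdjustment:
    def test_top_ranked_species_unchanged(self):
        assert cp.multispecies_mg_adjustment(2.0, 0.3, []) == 2.0

    def test_mid_ranked_scaling(self):
        # stronger competitors hold 0.5; available gain shrinks to 1/3 of full
        assert cp.multispecies_mg_adjustment(3.0, 0.25, [0.5]) == pytest.approx(1.0)

    def test_everyone_else_stronger_zeroes_the_response(self):
        assert cp.multispecies_mg_adjustment(3.0, 0.25, [0.5, 0.25]) == pytest.approx(0.0)

    def test_full_share_rejected(self):
        with pytest.raises(cp.ComppartError):
            cp.multispecies_mg_adjustment(1.0, 1.0, [0.5])

    def test_three_species_pipeline_with_adjustment(self):
        com = cp.make_two_species_community(
            "m",
            (12.0, 9.0, 4.0),
            (5.0, 3.0, 1.0),
            m_partial=(10.0, 6.0, 2.0),
            ry=(0.25, 0.25, 0.5),
            species_ids=("a", "b", "c"),
        )
        plain = cp.partition_community(com)
        adjusted = cp.partition_community(
            com, cp.RunConfig(multispecies_adjustment=True)
        )
        mg = {s.species_id: s.mg for s in adjusted.species}
        mg0 = {s.species_id: s.mg for s in plain.species}
        assert mg["a"] == mg0["a"]  # top-ranked unchanged
        assert mg["c"] == mg0["c"] == -1.0  # weakest still excluded
        assert abs(mg["b"]) <= abs(mg0["b"])  # mid-ranked shrunk
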