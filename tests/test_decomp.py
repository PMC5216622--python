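"""Community means, the intra/inter partition and change conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleosize import synth
from paleosize.decomp import (
    community_mean_inter,
    community_mean_intra_inter,
    decompose,
    decompose_from_means,
    linear_change_percent,
    observation_weights,
    species_pooled_mean,
    species_weights,
    volume_change_percent,
)
from paleosize.errors import DegenerateWeightsError, InsufficientDataError
from paleosize.io_model import AssemblageCount, DiameterObservation


def obs(species, period, diameter):
    return DiameterObservation(species, period, diameter)


def zero_sd_config(mean_by_cell, weight_by_cell, n_by_cell, totals):
    """SynthConfig with sd=0 so every observation equals its cell mean."""
    specs = [
        synth.SpeciesPeriodSpec(s, p, mean=mean_by_cell[(s, p)], sd=0.0,
                                n_measured=n_by_cell[(s, p)],
                                assemblage_fraction=weight_by_cell[(s, p)])
        for (s, p) in mean_by_cell
    ]
    return synth.SynthConfig(specs, totals, seed=0)


class TestSpeciesWeights:
    @pytest.mark.parametrize(
        "counts, expected",
        [((50, 50), (0.5, 0.5)), ((30, 70), (0.3, 0.7))],
    )
    def test_weights_are_count_fractions(self, counts, expected):
        assemblage = [
            AssemblageCount("A", "warm", counts[0]),
            AssemblageCount("B", "warm", counts[1]),
        ]
        w = species_weights(assemblage, "warm")
        assert (w["A"], w["B"]) == pytest.approx(expected)

    def test_single_species_gets_weight_one(self):
        w = species_weights([AssemblageCount("A", "cold", 7)], "cold")
        assert w["A"] == 1.0

    def test_zero_total_count_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            species_weights([AssemblageCount("A", "warm", 0)], "warm")

    def test_missing_included_species_raises(self):
        with pytest.raises(KeyError, match="B"):
            species_weights([AssemblageCount("A", "warm", 5)], "warm", {"A", "B"})


class TestObservationWeights:
    def test_single_species_splits_weight_equally(self):
        observations = [obs("A", "warm", d) for d in (10, 11, 12, 13)]
        w_spe = species_weights([AssemblageCount("A", "warm", 99)], "warm")
        assert observation_weights(observations, w_spe) == pytest.approx([0.25] * 4)

    def test_two_species_example(self):
        observations = [obs("A", "warm", 1), obs("A", "warm", 2), obs("B", "warm", 3)]
        w_spe = species_weights(
            [AssemblageCount("A", "warm", 30), AssemblageCount("B", "warm", 70)], "warm"
        )
        assert observation_weights(observations, w_spe) == pytest.approx(
            [0.15, 0.15, 0.7]
        )

    def test_weights_sum_to_one_on_default_fixture(self, fixture_tables):
        observations, assemblage = fixture_tables
        for period in ("warm", "cold"):
            period_obs = [o for o in observations if o.period == period]
            w_spe = species_weights(
                assemblage, period, {o.species for o in period_obs}
            )
            w_obs = observation_weights(period_obs, w_spe)
            assert sum(w_obs) == pytest.approx(1.0, abs=1e-12)

    def test_weighted_species_without_observations_warns(self, caplog):
        observations = [obs("A", "warm", 1), obs("A", "warm", 2)]
        w_spe = species_weights(
            [AssemblageCount("A", "warm", 50), AssemblageCount("B", "warm", 50)], "warm"
        )
        with caplog.at_level("WARNING"):
            observation_weights(observations, w_spe)
        assert "B" in caplog.text

    def test_observation_without_weight_is_an_error(self):
        observations = [obs("A", "warm", 1), obs("C", "warm", 2)]
        w_spe = species_weights([AssemblageCount("A", "warm", 50)], "warm")
        with pytest.raises(KeyError, match="C"):
            observation_weights(observations, w_spe)


class TestCommunityMeans:
    def test_zero_sd_reduces_to_weighted_species_means(self):
        cfg = zero_sd_config(
            mean_by_cell={("A", "warm"): 10.0, ("B", "warm"): 20.0},
            weight_by_cell={("A", "warm"): 0.3, ("B", "warm"): 0.7},
            n_by_cell={("A", "warm"): 4, ("B", "warm"): 6},
            totals={"warm": 100},
        )
        observations = synth.generate_observations(cfg)
        assemblage = synth.generate_assemblage(cfg)
        cm = community_mean_intra_inter(observations, assemblage, "warm")
        assert cm.mean == pytest.approx(0.3 * 10 + 0.7 * 20)
        assert cm.level == "intra+inter"
        assert cm.n_obs == 10

    def test_equal_weights_equal_m_give_grand_mean(self):
        observations = [
            obs("A", "warm", 10), obs("A", "warm", 14),
            obs("B", "warm", 20), obs("B", "warm", 24),
        ]
        assemblage = [
            AssemblageCount("A", "warm", 40), AssemblageCount("B", "warm", 40),
        ]
        cm = community_mean_intra_inter(observations, assemblage, "warm")
        assert cm.mean == pytest.approx(np.mean([10, 14, 20, 24]))

    def test_monte_carlo_mean_matches_weighted_truth(self, default_config):
        """Over 200 seeds the Monte-Carlo average of the warm community mean
        sits within 2 SE of the fixture's weighted true means."""
        truth = sum(
            s.assemblage_fraction * s.mean
            for s in default_config.specs
            if s.period == "warm"
        )
        means = []
        for seed in range(200):
            cfg = default_config.with_seed(seed)
            observations = synth.generate_observations(cfg)
            assemblage = synth.generate_assemblage(cfg)
            means.append(
                community_mean_intra_inter(observations, assemblage, "warm").mean
            )
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - truth) <= 2 * se + 0.05

    def test_inter_mean_is_weighted_average_of_species_means(self):
        w = species_weights(
            [AssemblageCount("A", "warm", 25), AssemblageCount("B", "warm", 75)], "warm"
        )
        cm = community_mean_inter({"A": 10.0, "B": 20.0}, w)
        assert cm.mean == pytest.approx(17.5)
        assert cm.n_obs == 2
        assert cm.level == "inter"

    def test_inter_mean_missing_species_raises(self):
        w = species_weights(
            [AssemblageCount("A", "warm", 1), AssemblageCount("B", "warm", 1)], "warm"
        )
        with pytest.raises(KeyError):
            community_mean_inter({"A": 10.0}, w)


class TestSpeciesPooledMean:
    def test_pooled_mean_is_n_weighted(self):
        observations = (
            [obs("I. minutum", "warm", 34.08)] * 52
            + [obs("I. minutum", "cold", 37.96)] * 51
        )
        expected = (52 * 34.08 + 51 * 37.96) / 103
        assert species_pooled_mean(observations, "I. minutum") == pytest.approx(expected)
        assert species_pooled_mean(observations, "I. minutum") == pytest.approx(36.0, abs=0.01)

    def test_period_mean_mode_averages_period_means(self):
        observations = (
            [obs("X", "warm", 10.0)] * 3 + [obs("X", "cold", 20.0)] * 1
        )
        assert species_pooled_mean(observations, "X", pooling="period_mean") == 15.0
        assert species_pooled_mean(observations, "X", pooling="pooled") == 12.5

    def test_single_observation_and_missing_species(self):
        observations = [obs("X", "warm", 31.0)]
        assert species_pooled_mean(observations, "X") == 31.0
        with pytest.raises(InsufficientDataError):
            species_pooled_mean(observations, "Y")


class TestDecompose:
    def two_period_assemblage(self, warm_counts, cold_counts):
        return [
            AssemblageCount("A", "warm", warm_counts[0]),
            AssemblageCount("B", "warm", warm_counts[1]),
            AssemblageCount("A", "cold", cold_counts[0]),
            AssemblageCount("B", "cold", cold_counts[1]),
        ]

    def test_pure_composition_shift(self):
        """Species means fixed; only weights change: all change is inter."""
        observations = (
            [obs("A", "warm", 10), obs("A", "cold", 10)] * 2
            + [obs("B", "warm", 20), obs("B", "cold", 20)] * 2
        )
        assemblage = self.two_period_assemblage((50, 50), (25, 75))
        res = decompose(observations, assemblage, "warm", "cold")
        assert res.delta_total == pytest.approx(2.5)
        assert res.delta_inter == pytest.approx(2.5)
        assert res.delta_intra == pytest.approx(0.0, abs=1e-12)

    def test_pure_intraspecific_shift(self):
        """Weights fixed; species means move 10→12 and 20→22 with equal n:
        all change is intra."""
        observations = (
            [obs("A", "warm", 10)] * 2 + [obs("A", "cold", 12)] * 2
            + [obs("B", "warm", 20)] * 2 + [obs("B", "cold", 22)] * 2
        )
        assemblage = self.two_period_assemblage((50, 50), (50, 50))
        res = decompose(observations, assemblage, "warm", "cold")
        assert res.delta_total == pytest.approx(2.0)
        assert res.delta_inter == pytest.approx(0.0, abs=1e-12)
        assert res.delta_intra == pytest.approx(2.0)

    def test_published_community_rows_partition(self):
        """Partition evaluated at the published community means."""
        res = decompose_from_means(31.80, 36.24, 33.30, 34.53)
        assert res.delta_total == pytest.approx(4.44)
        assert res.delta_inter == pytest.approx(1.23)
        assert res.delta_intra == pytest.approx(4.44 - 1.23)
        assert res.fraction_intra > 0.70

    @given(
        total_ref=st.floats(10, 60), total_cmp=st.floats(10, 60),
        inter_ref=st.floats(10, 60), inter_cmp=st.floats(10, 60),
    )
    @settings(max_examples=100, derandomize=True)
    def test_conservation_identity_on_all_inputs(
        self, total_ref, total_cmp, inter_ref, inter_cmp
    ):
        res = decompose_from_means(total_ref, total_cmp, inter_ref, inter_cmp)
        # exact in the defining direction; the re-summed form only to rounding
        assert res.delta_intra == res.delta_total - res.delta_inter
        assert res.delta_intra + res.delta_inter == pytest.approx(
            res.delta_total, abs=1e-9
        )
        if res.delta_total != 0:
            assert res.fraction_intra + res.fraction_inter == pytest.approx(1.0)

    def test_zero_total_change_leaves_fractions_undefined(self):
        res = decompose_from_means(30.0, 30.0, 28.0, 29.0)
        assert res.fraction_intra is None and res.fraction_inter is None

    def test_equal_period_weights_give_zero_inter_delta(self, default_config):
        """Δinter is exactly zero when both periods share the same weights,
        whatever the observations do."""
        observations = synth.generate_observations(default_config)
        counts = {s.species: 100 for s in default_config.specs}
        assemblage = [
            AssemblageCount(sp, p, c)
            for sp, c in counts.items()
            for p in ("warm", "cold")
        ]
        res = decompose(observations, assemblage, "warm", "cold")
        assert res.delta_inter == pytest.approx(0.0, abs=1e-12)

    def test_intra_delta_vanishes_with_sd_when_means_static(self):
        cfg = zero_sd_config(
            mean_by_cell={("A", "warm"): 10.0, ("A", "cold"): 10.0,
                          ("B", "warm"): 20.0, ("B", "cold"): 20.0},
            weight_by_cell={("A", "warm"): 0.5, ("A", "cold"): 0.3,
                            ("B", "warm"): 0.5, ("B", "cold"): 0.7},
            n_by_cell={("A", "warm"): 4, ("A", "cold"): 4,
                       ("B", "warm"): 4, ("B", "cold"): 4},
            totals={"warm": 100, "cold": 100},
        )
        observations = synth.generate_observations(cfg)
        assemblage = synth.generate_assemblage(cfg)
        res = decompose(observations, assemblage, "warm", "cold")
        assert res.delta_intra == pytest.approx(0.0, abs=1e-12)


class TestChangeConversions:
    @pytest.mark.parametrize(
        "ref, cmp_, expected, digits",
        [
            (34.08, 37.96, 11.4, 1),   # linear
            (34.08, 34.08, 0.0, 6),
            (1.0, 2.0, 100.0, 6),
        ],
    )
    def test_linear_change(self, ref, cmp_, expected, digits):
        assert round(linear_change_percent(ref, cmp_), digits) == expected

    @pytest.mark.parametrize(
        "ref, cmp_, expected",
        [
            (34.08, 37.96, 38),  # I. minutum
            (47.75, 51.68, 27),  # B. simplex
            (24.55, 26.89, 31),  # I.? cezare
            (25.85, 27.31, 18),  # P. dalei
            (1.0, 2.0, 700),
        ],
    )
    def test_volume_change_rounds_to_published_percent(self, ref, cmp_, expected):
        assert round(volume_change_percent(ref, cmp_)) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            linear_change_percent(0.0, 10.0)
        with pytest.raises(ValueError):
            volume_change_percent(-1.0, 10.0)
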