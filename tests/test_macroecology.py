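import math

import numpy as np
import pandas as pd
import pytest

from evofoodweb.biomass_equilibrium import LocalWeb
from evofoodweb.evolution_engine import Snapshot
from evofoodweb.spatial_lattice import Lattice
from evofoodweb.trophic_network import Resource, SpeciesTraits
from evofoodweb import macroecology as mac


def assemble(traits, ids=None):
    ids = ids or list(range(1, len(traits) + 1))
    return LocalWeb.assemble(ids, traits, Resource(), 0.25)


BASAL = SpeciesTraits(2.0, 0.0, 0.75)
HERB = SpeciesTraits(4.0, 2.0, 0.75)


class TestTrophicLevels:
    def test_resource_feeder_is_level_one(self):
        assert mac.trophic_levels(assemble([BASAL])) == pytest.approx([1.0])

    def test_consumer_of_basal_is_level_two(self):
        assert mac.trophic_levels(assemble([BASAL, HERB])) == pytest.approx(
            [1.0, 2.0]
        )

    def test_mixed_diet_averages_prey_levels(self):
        omn = SpeciesTraits(5.0, 3.0, 1.0)  # eats basal (m=2) and herb (m=4)
        assert mac.trophic_levels(assemble([BASAL, HERB, omn])) == pytest.approx(
            [1.0, 2.0, 2.5]
        )

    def test_preyless_species_rejected(self):
        lonely = SpeciesTraits(9.0, 7.0, 0.5)
        with pytest.raises(ValueError):
            mac.trophic_levels(assemble([BASAL, lonely]))


class TestRankAbundance:
    def test_descending_biomass_order(self):
        web = assemble([BASAL, BASAL, BASAL])
        web.biomasses = np.array([3.0, 5.0, 1.0])
        assert mac.rank_abundance(web) == {2: 1, 1: 2, 3: 3}

    def test_ties_broken_by_smaller_id(self):
        web = assemble([BASAL, BASAL], ids=[9, 4])
        web.biomasses = np.array([2.0, 2.0])
        assert mac.rank_abundance(web) == {4: 1, 9: 2}

    def test_average_rank_over_occupied_habitats(self):
        # species 1 ranks 1st on habitat 0 and 3rd on habitat 1 -> mean 2.0
        ids = np.array([1, 2, 3])
        biomass = np.array([[5.0, 3.0, 1.0], [1.0, 3.0, 5.0]])
        snap = Snapshot(0.0, ids, biomass, np.ones_like(biomass))
        avg = mac.average_ranks(snap)
        assert avg.loc[1] == pytest.approx(2.0)
        assert avg.loc[2] == pytest.approx(2.0)
        assert avg.loc[3] == pytest.approx(2.0)


def _species_frame(lifetimes, avg_range=None, max_range=None, tl=1.0):
    n = len(lifetimes)
    lifetimes = np.asarray(lifetimes, dtype=float)
    return pd.DataFrame(
        {
            "species_id": np.arange(2, n + 2),
            "t_orig": np.zeros(n),
            "t_ext": lifetimes,
            "established": np.ones(n, bool),
            "origin_tl": np.full(n, tl),
            "lifetime": lifetimes,
            "avg_range": np.ones(n) if avg_range is None else np.asarray(avg_range),
            "max_range": np.ones(n) if max_range is None else np.asarray(max_range),
        }
    )


class TestLifetimeDistribution:
    def test_recovers_known_power_law(self, rng):
        # inverse-CDF sampling from density ~ x^-2.4 on [1, 100]
        alpha = -2.4
        u = rng.uniform(size=40_000)
        a, b = 1.0, 100.0
        x = (u * (b ** (alpha + 1) - a ** (alpha + 1)) + a ** (alpha + 1)) ** (
            1 / (alpha + 1)
        )
        fit = mac.lifetime_distribution(_species_frame(x), fit_window=(1, 100))
        assert fit.exponent == pytest.approx(-2.4, abs=0.15)

    def test_degenerate_support_omits_fit(self):
        fit = mac.lifetime_distribution(_species_frame(np.full(100, 7.0)))
        assert fit.exponent is None

    def test_alive_species_excluded(self):
        df = _species_frame(np.linspace(1, 50, 60))
        df.loc[5:, "t_ext"] = math.nan  # most species still alive
        fit = mac.lifetime_distribution(df)
        assert fit.exponent is None  # too few extinct lifetimes to fit


def _occupancy_snapshot(lattice, presence, tl=None):
    H, S = presence.shape
    ids = np.arange(1, S + 1)
    biomass = presence.astype(float) * 2.0
    tl_mat = np.ones_like(biomass) if tl is None else tl
    return Snapshot(0.0, ids, biomass, tl_mat * presence)


class TestSpeciesAreaRelation:
    def test_matches_exhaustive_enumeration_on_toy_grid(self, rng):
        lat = Lattice(5, 5)
        presence = rng.random((25, 12)) < 0.3
        snap = _occupancy_snapshot(lat, presence)
        df, _ = mac.species_area_relation(
            [snap], lat, starts=list(range(25))
        )
        # brute force: for every start and radius count species in the shell
        for k in range(lat.max_distance() + 1):
            counts = []
            for start in range(25):
                shell = sorted(lat.nested_shells(start, k)[k])
                counts.append(presence[shell].any(axis=0).sum())
            assert df.species.iloc[k] == pytest.approx(np.mean(counts))

    def test_full_area_counts_all_alive(self, rng):
        lat = Lattice(4, 4)
        presence = rng.random((16, 9)) < 0.4
        presence[0, :] = True  # make sure every species is alive somewhere
        snap = _occupancy_snapshot(lat, presence)
        df, _ = mac.species_area_relation([snap], lat, n_starts=3)
        assert df.species.iloc[-1] == presence.any(axis=0).sum()

    def test_ubiquitous_species_give_flat_curve(self):
        lat = Lattice(5, 5)
        presence = np.ones((25, 7), bool)
        df, slope = mac.species_area_relation(
            [_occupancy_snapshot(lat, presence)], lat, area_window=(1, 25)
        )
        assert df.species.to_numpy() == pytest.approx(np.full(len(df), 7.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_monotone_and_saturating_to_slope_one(self, rng):
        # species confined to single habitats: S grows linearly with area,
        # so the log-log slope approaches 1
        lat = Lattice(8, 8)
        presence = np.zeros((64, 64), bool)
        presence[np.arange(64), np.arange(64)] = True
        snap = _occupancy_snapshot(lat, presence)
        df, _ = mac.species_area_relation([snap], lat, n_starts=5, rng=rng)
        s = df.species.to_numpy()
        assert (np.diff(s) >= -1e-9).all()
        tail = np.polyfit(np.log10(df.area[-4:]), np.log10(s[-4:]), 1)[0]
        assert tail == pytest.approx(1.0, abs=0.05)


class TestSimilarityDecay:
    def test_jaccard_reference_values(self):
        lat = Lattice(2, 2)
        # habitats: {1,2}, {2,3}, {1,2}, {} -> J({1,2},{2,3}) = 1/3
        presence = np.array(
            [[1, 1, 0], [0, 1, 1], [1, 1, 0], [0, 0, 0]], dtype=bool
        )
        snap = _occupancy_snapshot(lat, presence)
        dec = mac.similarity_decay([snap], lat)
        jac = mac._jaccard_matrix(presence)
        assert jac[0, 1] == pytest.approx(1 / 3)
        assert jac[0, 2] == pytest.approx(1.0)
        assert np.isnan(jac[3, 3]) or jac[3, 3] >= 0  # empty-vs-empty undefined
        assert ((dec.jaccard_basal.dropna() >= 0) & (dec.jaccard_basal.dropna() <= 1)).all()

    def test_symmetry_and_bounds_random(self, rng):
        P = rng.random((10, 20)) < 0.4
        jac = mac._jaccard_matrix(P)
        ok = np.isfinite(jac)
        assert np.allclose(jac[ok], jac.T[ok])
        assert (jac[ok] >= 0).all() and (jac[ok] <= 1).all()

    def test_strata_split_by_rounded_level(self):
        lat = Lattice(2, 2)
        presence = np.ones((4, 2), bool)
        tl = np.tile([1.2, 2.4], (4, 1))  # one basal, one higher species
        snap = _occupancy_snapshot(lat, presence, tl=tl)
        dec = mac.similarity_decay([snap], lat)
        assert (dec.jaccard_basal.dropna() == 1.0).all()
        assert (dec.jaccard_higher.dropna() == 1.0).all()


class TestRangeShapes:
    def test_clean_rise_and_fall_is_hat(self):
        t = np.linspace(0, 10, 50)
        c = np.concatenate([np.linspace(1, 60, 25), np.linspace(60, 0, 25)])
        traj = np.column_stack([t, np.round(c)])
        assert mac.classify_range_shape(traj, 64) == "hat"

    def test_two_prominent_peaks(self):
        t = np.linspace(0, 10, 80)
        c = np.concatenate(
            [
                np.linspace(1, 60, 20),
                np.linspace(60, 5, 20),
                np.linspace(5, 55, 20),
                np.linspace(55, 0, 20),
            ]
        )
        traj = np.column_stack([t, np.round(c)])
        assert mac.classify_range_shape(traj, 64) == "multi_peak"

    def test_plateau_at_full_grid_counts_as_hat(self):
        t = np.linspace(0, 10, 60)
        c = np.concatenate(
            [np.linspace(1, 64, 20), np.full(20, 64.0), np.linspace(64, 0, 20)]
        )
        traj = np.column_stack([t, np.round(c)])
        assert mac.classify_range_shape(traj, 64) == "hat"

    def test_small_wiggles_on_the_back_still_hat(self, rng):
        t = np.linspace(0, 10, 200)
        base = np.concatenate([np.linspace(1, 60, 100), np.linspace(60, 0, 100)])
        noisy = np.clip(base + rng.integers(-2, 3, 200), 0, 64)
        assert mac.classify_range_shape(np.column_stack([t, noisy]), 64) == "hat"

    def test_below_range_filter_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([1.0, 5.0, 0.0])
        with pytest.raises(ValueError):
            mac.classify_range_shape(np.column_stack([t, c]), 64)


class TestRangeLifetimeCurve:
    def test_proportional_histories_give_slope_one(self):
        lifetimes = np.logspace(0, 2, 300)
        df = _species_frame(lifetimes, avg_range=lifetimes, max_range=lifetimes)
        curve, slope = mac.range_lifetime_curve(df, n_habitats=10_000)
        assert slope == pytest.approx(1.0, abs=0.01)

    def test_bin_width_in_log10(self):
        lifetimes = np.array([1.0, 1.1, 10.0, 100.0])
        df = _species_frame(lifetimes)
        curve, _ = mac.range_lifetime_curve(df, n_habitats=100)
        # 1.0 and 1.1 share a 0.055-wide log bin; the others are far apart
        assert len(curve) == 3
        assert curve.n.iloc[0] == 2

    def test_identical_species_collapse_to_one_bin(self):
        df = _species_frame(np.full(20, 5.0), avg_range=np.full(20, 3.0))
        curve, slope = mac.range_lifetime_curve(df, n_habitats=100)
        assert len(curve) == 1
        assert math.isnan(slope)


class TestRangeSizeDistribution:
    def test_single_habitat_species(self):
        df = _species_frame([2.0, 3.0], avg_range=[1, 1], max_range=[1, 1])
        out = mac.range_size_distribution(df)
        assert out["basal"]["average"].bin_centers == pytest.approx([1.0])

    def test_densities_normalize(self, rng):
        ranges = rng.pareto(2.0, 400) + 1
        df = _species_frame(
            np.ones(400), avg_range=ranges, max_range=ranges * 1.5, tl=2.0
        )
        fit = mac.range_size_distribution(df)["higher"]["average"]
        widths = np.diff(np.concatenate([[0], fit.bin_centers]))  # proxy check
        assert fit.density.min() >= 0
        assert fit.exponent is not None


class TestExtinctionCauses:
    def test_hand_built_log_fractions(self):
        records = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0],
                "species_id": [2, 3, 4, 5],
                "habitat": [0, 0, 1, 2],
                "trigger": [
                    "local_speciation",
                    "local_speciation",
                    "immigration",
                    "immigration",
                ],
                "relation": ["same_level", "same_level", "secondary", "level_below"],
                "victim_tl": [1, 1, 1, 2],
            }
        )
        tab = mac.extinction_cause_summary(records)
        assert tab.loc[1, "local:same_level"] == pytest.approx(2 / 3)
        assert tab.loc[1, "immigration:secondary"] == pytest.approx(1 / 3)
        assert tab.loc[2, "immigration:level_below"] == pytest.approx(1.0)
        assert tab.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(tab)))

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            mac.extinction_cause_summary(pd.DataFrame())
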