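import dendropy
import numpy as np
import pandas as pd
import pytest

from elevdiv.acoustics import acoustic_activity_index
from elevdiv.synthetic import (ScenarioConfig, SyntheticMetacommunity,
                               generate_call_library,
                               generate_detection_stream,
                               generate_metacommunity, generate_tree)


def small(**over):
    base = dict(scenario="neutral", richness_per_location=(8, 6, 5, 4),
                pool_size=10, extreme_clade_size=3, sites_per_location=2,
                seed=0)
    base.update(over)
    return ScenarioConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(scenario="bogus"),
        dict(richness_per_location=(11, 9, 7)),
        dict(richness_per_location=(11, 9, 7, 20)),
        dict(extreme_clade_size=10),
        dict(filter_strength=-1.0),
        dict(sites_per_location=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small(**bad)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        a = generate_metacommunity(small(seed=5))
        b = generate_metacommunity(small(seed=5))
        pd.testing.assert_frame_equal(a.community.counts, b.community.counts)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        assert a.tree.as_string(schema="newick") == \
            b.tree.as_string(schema="newick")
        ea = generate_detection_stream(a, small(seed=5))
        eb = generate_detection_stream(b, small(seed=5))
        pd.testing.assert_frame_equal(ea, eb)

    def test_different_seed_differs(self):
        a = generate_metacommunity(small(seed=5))
        b = generate_metacommunity(small(seed=6))
        assert not a.community.counts.equals(b.community.counts)

    def test_zero_strength_filtering_equals_neutral(self):
        a = generate_metacommunity(small(scenario="neutral", seed=1))
        b = generate_metacommunity(small(scenario="filtering",
                                         filter_strength=0.0, seed=1))
        pd.testing.assert_frame_equal(a.community.counts, b.community.counts)


class TestStructure:
    def test_labels_consistent_across_outputs(self):
        meta = generate_metacommunity(small())
        tips = sorted(l.taxon.label for l in meta.tree.leaf_node_iter())
        assert tips == sorted(meta.traits.index)
        assert tips == sorted(meta.community.taxa)

    def test_tree_ultrametric_unit_depth(self):
        meta = generate_metacommunity(small())
        depths = [l.distance_from_root() for l in meta.tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 1.0, atol=1e-6)

    def test_extreme_clade_monophyletic(self):
        meta = generate_metacommunity(small())
        extreme = set(meta.truth["extreme_taxa"])
        taxa = [t for t in meta.tree.taxon_namespace if t.label in extreme]
        mrca = meta.tree.mrca(taxa=taxa)
        clade = {l.taxon.label for l in mrca.leaf_iter()}
        assert clade == extreme

    def test_filtered_occupants_closer_to_optimum(self):
        """At the harshest location the occupants sit nearer the community
        optimum than the non-occupants of the pool."""
        meta = generate_metacommunity(small(scenario="filtering",
                                            filter_strength=8.0, seed=7))
        d = meta.truth["trait_distance"]
        harsh_sites = [s for s in meta.community.sites if s.startswith("L3")]
        occupants = set().union(*(meta.truth["occupancy"][s]
                                  for s in harsh_sites))
        absent = [t for t in meta.community.taxa if t not in occupants]
        assert d[list(occupants)].mean() < d[absent].mean()

    def test_packing_crowds_trait_space(self):
        """Packed lowest-location assemblages have smaller nearest-neighbour
        trait distances than neutral ones (averaged over seeds)."""
        from scipy.spatial.distance import pdist, squareform

        def mean_nn(meta):
            z = (meta.traits - meta.traits.mean()) / meta.traits.std(ddof=1)
            vals = []
            for k in range(2):
                occ = meta.truth["occupancy"][f"L0S{k}"]
                d = squareform(pdist(z.loc[occ].to_numpy()))
                np.fill_diagonal(d, np.inf)
                vals.append(d.min(axis=1).mean())
            return np.mean(vals)

        packed, neutral = [], []
        for seed in range(8):
            packed.append(mean_nn(generate_metacommunity(
                small(scenario="packing", filter_strength=4.0, seed=seed))))
            neutral.append(mean_nn(generate_metacommunity(
                small(scenario="neutral", seed=seed))))
        assert np.mean(packed) < np.mean(neutral)

    def test_external_trait_matrix_only_simulates_occupancy(self, table1):
        cfg = ScenarioConfig(scenario="neutral", pool_size=13,
                             richness_per_location=(10, 8, 7, 6),
                             sites_per_location=2, seed=3)
        meta = generate_metacommunity(
            cfg, traits=table1, extreme_taxa=["Rlep", "Rluc", "Rpea", "Rsin"])
        pd.testing.assert_frame_equal(meta.traits, table1)
        assert sorted(meta.community.taxa) == sorted(table1.index)
        assert meta.truth["extreme_taxa"] == ["Rlep", "Rluc", "Rpea", "Rsin"]

    def test_external_traits_pool_size_mismatch(self, table1):
        with pytest.raises(ValueError, match="pool_size"):
            generate_metacommunity(small(pool_size=10), traits=table1)


class TestCallLibrary:
    def test_bookkeeping(self):
        lib = generate_call_library(2, 10, 5.0, seed=0)
        assert lib.shape == (20, 10)  # 9 features + 1 label column
        assert lib["species"].nunique() == 2

    @pytest.mark.parametrize("kwargs", [
        dict(n_species=1, pulses_per_species=10, separation=1.0),
        dict(n_species=2, pulses_per_species=2, separation=1.0),
        dict(n_species=2, pulses_per_species=10, separation=-1.0),
        dict(n_species=12, pulses_per_species=10, separation=1.0),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_call_library(**kwargs, seed=0)


class TestDetectionStream:
    def test_zero_abundance_zero_events(self):
        meta = generate_metacommunity(small(seed=2))
        events = generate_detection_stream(meta, small(seed=2))
        absent = meta.community.counts.loc["L3S0"]
        absent = set(absent.index[absent == 0])
        site_events = events[events["site"] == "L3S0"]
        assert not set(site_events["sonotype"]) & absent

    def test_intervals_fall_in_sampled_windows(self):
        cfg = small(seed=2)
        events = generate_detection_stream(generate_metacommunity(cfg), cfg)
        offsets = set(events["interval"] % 12)
        assert offsets <= {0, 4, 8}
        assert events["interval"].max() < cfg.hours_per_night * 12
        assert set(events["night"]) <= set(range(cfg.nights_per_site))

    def test_activity_capped_by_sampled_windows(self):
        """One species, one night, huge rate: occupied intervals cannot
        exceed three windows per recorded hour."""
        cfg = ScenarioConfig(scenario="neutral", n_locations=1,
                             richness_per_location=(1,), pool_size=2,
                             extreme_clade_size=1, sites_per_location=1,
                             nights_per_site=1, detection_rate=500.0, seed=0)
        meta = generate_metacommunity(cfg)
        events = generate_detection_stream(meta, cfg)
        aai = acoustic_activity_index(events, sites=meta.community.metadata)
        assert aai.counts.to_numpy().max() <= 3 * cfg.hours_per_night

    def test_doubling_rate_increases_interval_counts(self):
        """Monte-Carlo monotonicity: higher detection rate gives
        stochastically more occupied intervals (100 replicate pairs)."""
        lo, hi = [], []
        for seed in range(100):
            for rate, acc in ((3.0, lo), (6.0, hi)):
                cfg = ScenarioConfig(scenario="neutral", n_locations=1,
                                     richness_per_location=(3,), pool_size=4,
                                     extreme_clade_size=1,
                                     sites_per_location=1, nights_per_site=1,
                                     detection_rate=rate, seed=seed)
                meta = generate_metacommunity(cfg)
                ev = generate_detection_stream(meta, cfg)
                aai = acoustic_activity_index(ev,
                                              sites=meta.community.metadata)
                acc.append(aai.counts.to_numpy().sum())
        assert np.mean(hi) > np.mean(lo)


def test_generate_tree_respects_clade_size(rng):
    tree = generate_tree([f"t{i}" for i in range(8)], ["x1", "x2", "x3"],
                         rng, main_clade_size=4)
    assert len(list(tree.leaf_node_iter())) == 11
    taxa = [t for t in tree.taxon_namespace if t.label.startswith("x")]
    clade = {l.taxon.label for l in tree.mrca(taxa=taxa).leaf_iter()}
    assert clade == {"x1", "x2", "x3"}
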