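"""Lattice and coupling-graph generators: contact counts, dilution, growth."""

import json

import numpy as np
import pytest
from scipy import stats

import ryrspark as rs
from ryrspark.geometry import ChannelLattice


class TestBuilders:
    @pytest.mark.parametrize("builder,rows,cols,n_edges,max_deg", [
        (rs.build_adjoining, 1, 1, 0, 0),
        (rs.build_adjoining, 2, 2, 8, 2),
        (rs.build_adjoining, 10, 10, 360, 2),
        (rs.build_oblique, 1, 1, 0, 0),
        (rs.build_oblique, 2, 2, 4, 1),
        (rs.build_oblique, 10, 10, 180, 1),
    ])
    def test_edge_counts_and_degree_caps(self, builder, rows, cols, n_edges, max_deg):
        g = builder(rows, cols)
        assert len(g.inter_edges) == n_edges
        deg = g.inter_degrees()
        assert deg.max(initial=0) == max_deg

    @pytest.mark.parametrize("rows,cols", [(0, 3), (3, 0), (-1, 2)])
    def test_nonpositive_dimensions_rejected(self, rows, cols):
        with pytest.raises(ValueError):
            rs.build_adjoining(rows, cols)

    def test_edges_listed_once_per_unordered_pair(self):
        g = rs.build_adjoining(4, 5)
        keys = [frozenset({e[0], e[1]}) for e in g.inter_edges]
        assert len(keys) == len(set(keys))

    def test_adjoining_interior_subunit_has_one_horizontal_one_vertical(self):
        g = rs.build_adjoining(3, 3)
        site = {c: s for c, s in enumerate(g.lattice.sites)}
        center = g.lattice.sites.index((1, 1))
        for s in range(4):
            contacts = g.inter_contacts(center, s)
            assert len(contacts) == 2
            dirs = {tuple(np.subtract(site[c2], site[center])) for c2, _, _ in contacts}
            assert any(d[0] != 0 for d in dirs) and any(d[1] != 0 for d in dirs)

    def test_oblique_contact_pattern_is_02_13(self):
        # single diagonal contact per interface in the 0-2 / 1-3 pairing
        g = rs.build_oblique(3, 3)
        for (c1, s1), (c2, s2), _ in g.inter_edges:
            assert {s1, s2} in ({0, 2}, {1, 3})


class TestLatticeToGraph:
    def test_dispersed_lattice_has_no_inter_edges(self):
        lat = ChannelLattice(5, 5, ((0, 0), (2, 2), (4, 0), (0, 4)))
        for topo in ("adjoining", "oblique"):
            assert rs.lattice_to_graph(lat, topo).inter_edges == ()

    def test_full_20x20_oblique_count(self):
        g = rs.lattice_to_graph(rs.full_lattice(20, 20), "oblique")
        assert len(g.inter_edges) == 2 * 20 * 19

    def test_horizontal_domino_adjoining(self):
        lat = ChannelLattice(1, 2, ((0, 0), (1, 0)))
        assert len(rs.lattice_to_graph(lat, "adjoining").inter_edges) == 2

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            rs.lattice_to_graph(rs.full_lattice(2, 2), "hexagonal")


class TestDiluteBonds:
    def test_p_one_is_identity(self):
        g = rs.build_adjoining(5, 5)
        assert rs.dilute_bonds(g, 1.0, seed=0).inter_edges == g.inter_edges

    def test_p_zero_dissociates_cluster(self):
        assert rs.dilute_bonds(rs.build_adjoining(5, 5), 0.0, seed=0).inter_edges == ()

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValueError):
            rs.dilute_bonds(rs.build_adjoining(2, 2), p)

    def test_reproducible_for_fixed_seed(self):
        g = rs.build_oblique(6, 6)
        assert rs.dilute_bonds(g, 0.4, seed=11).inter_edges == rs.dilute_bonds(g, 0.4, seed=11).inter_edges

    def test_survival_fraction_converges_to_p(self):
        # Binomial(360, 0.5): mean 180, sd ~9.5; 300 seeds pin the mean to ~1.1 edges
        g = rs.build_adjoining(10, 10)
        counts = [len(rs.dilute_bonds(g, 0.5, seed=s).inter_edges) for s in range(300)]
        se = np.sqrt(360 * 0.25 / 300)
        assert np.mean(counts) == pytest.approx(180.0, abs=4 * se)

    def test_only_inter_bonds_are_diluted(self):
        # intra rings are implicit/structural: channel count is untouched
        g = rs.dilute_bonds(rs.build_adjoining(4, 4), 0.2, seed=3)
        assert g.n_channels == 16 and g.n_subunits == 64


class TestGrowPreferential:
    def test_single_channel(self):
        lat = rs.grow_preferential(1, 5, 5, alpha=3.0, seed=0)
        assert lat.n_channels == 1

    def test_occupancy_always_matches_request(self):
        for seed in range(20):
            lat = rs.grow_preferential(50, 20, 20, alpha=5.0, seed=seed)
            assert lat.n_channels == 50
            assert len(set(lat.sites)) == 50

    def test_overfull_lattice_rejected(self):
        with pytest.raises(ValueError):
            rs.grow_preferential(26, 5, 5, alpha=0.0, seed=0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            rs.grow_preferential(5, 5, 5, alpha=-1.0, seed=0)

    def test_alpha_zero_is_uniform(self):
        # chi-square on per-site occupancy over 300 morphologies of 50 channels
        rows = cols = 20
        counts = np.zeros(rows * cols)
        n_seeds = 300
        for seed in range(n_seeds):
            lat = rs.grow_preferential(50, rows, cols, alpha=0.0, seed=seed)
            for nx, ny in lat.sites:
                counts[ny * cols + nx] += 1
        expected = np.full(rows * cols, n_seeds * 50 / (rows * cols))
        # hypergeometric-ish dependence within a morphology is mild at 50/400 density
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=rows * cols - 1) > 0.01

    @staticmethod
    def _adjacent_pairs(lat):
        occ = set(lat.sites)
        return sum((nx + 1, ny) in occ for nx, ny in occ) + sum((nx, ny + 1) in occ for nx, ny in occ)

    def test_high_alpha_compacts_clusters(self):
        pairs = {a: np.mean([self._adjacent_pairs(rs.grow_preferential(50, 20, 20, a, seed=s))
                             for s in range(200)])
                 for a in (0.0, 8.0)}
        assert pairs[8.0] > pairs[0.0] * 2

    def test_adjacent_pair_count_nondecreasing_in_alpha(self):
        grid = [0.0, 2.0, 5.0, 8.0]
        means = [np.mean([self._adjacent_pairs(rs.grow_preferential(50, 20, 20, a, seed=s))
                          for s in range(200)]) for a in grid]
        assert all(b >= a - 1.0 for a, b in zip(means, means[1:]))

    def test_product_mode_alpha_zero_also_uniform(self):
        a = rs.grow_preferential(30, 10, 10, 0.0, seed=5, mode="power")
        b = rs.grow_preferential(30, 10, 10, 0.0, seed=5, mode="product")
        assert a.sites == b.sites


class TestSerialization:
    def test_round_trip_identity(self):
        g = rs.dilute_bonds(rs.build_adjoining(4, 6), 0.7, seed=9)
        doc = g.to_json()
        g2 = rs.CouplingGraph.from_json(doc)
        assert g2 == g

    def test_document_fields(self):
        doc = json.loads(rs.build_oblique(2, 3).to_json())
        assert set(doc) == {"rows", "cols", "topology", "sigma", "channels", "inter_edges", "seed"}
        assert doc["topology"] == "oblique"
        assert len(doc["channels"]) == 6

    def test_grown_cluster_round_trip(self):
        lat = rs.grow_preferential(20, 10, 10, alpha=4.0, seed=2)
        g = rs.lattice_to_graph(lat, "oblique", seed=2)
        assert rs.CouplingGraph.from_json(g.to_json()) == g
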