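import networkx as nx
import numpy as np
import pytest

from jet2dna.clustering import (
    ClusteringThresholds,
    PredictedPatch,
    adjacency_graph,
    add_outer_layer,
    detect_seeds,
    extend_clusters,
    filter_patches,
    restart_on_pockets,
    run_scheme,
)
from jet2dna.descriptors import DescriptorSet, ResidueDescriptors
from jet2dna.scoring import ExpectedSize, Layer, Scheme
from jet2dna.structure import Atom, Residue, Structure


def _key(i):
    return ("A", i, "")


def _descriptors(values):
    """values: {i: (t_jet, pc_dna, cv_local, cv_global)}"""
    return DescriptorSet(values={
        _key(i): ResidueDescriptors(*v) for i, v in values.items()
    })


def _line_graph(n):
    g = nx.Graph()
    g.add_nodes_from(_key(i) for i in range(n))
    g.add_edges_from((_key(i), _key(i + 1)) for i in range(n - 1))
    return g


def _uniform_descriptors(n, t=0.5, p=0.5, cl=0.4, cg=0.4):
    return _descriptors({i: (t, p, cl, cg) for i in range(n)})


class TestAdjacency:
    def _two_residue_structure(self, gap):
        r1 = Residue("A", 1, "", "ALA", [Atom("CA", "C", [0, 0, 0])])
        r2 = Residue("A", 2, "", "ALA", [Atom("CA", "C", [gap, 0, 0])])
        return Structure(id="t", chains={"A": [r1, r2]})

    def test_edge_below_cutoff(self):
        s = self._two_residue_structure(4.0)
        g = adjacency_graph(s, {_key(1), _key(2)}, 5.0)
        assert g.has_edge(_key(1), _key(2))

    def test_no_edge_above_cutoff(self):
        s = self._two_residue_structure(6.0)
        g = adjacency_graph(s, {_key(1), _key(2)}, 5.0)
        assert not g.has_edge(_key(1), _key(2))

    def test_chain_is_single_component(self):
        residues = [
            Residue("A", i, "", "ALA", [Atom("CA", "C", [4.0 * i, 0, 0])])
            for i in range(1, 8)
        ]
        s = Structure(id="chain", chains={"A": residues})
        g = adjacency_graph(s, {r.key for r in residues}, 5.0)
        assert nx.number_connected_components(g) == 1

    def test_invalid_cutoff(self):
        s = self._two_residue_structure(4.0)
        with pytest.raises(ValueError):
            adjacency_graph(s, {_key(1)}, 0.0)


class TestDetectSeeds:
    def test_planted_block_found_as_single_seed(self):
        n = 30
        vals = {i: (0.2, 0.2, 0.4, 0.4) for i in range(n)}
        for i in (10, 11, 12, 13):
            vals[i] = (0.9, 0.9, 0.4, 0.4)
        desc = _descriptors(vals)
        graph = _line_graph(n)
        expected = ExpectedSize(n_surface=n, fraction=0.4, count=12)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        seeds = detect_seeds(scores, desc, graph, expected,
                             ClusteringThresholds(), Scheme.DSC1)
        assert len(seeds) == 1
        assert set(seeds[0].layers) == {_key(i) for i in (10, 11, 12, 13)}
        assert all(layer == Layer.SEED.value for layer in seeds[0].layers.values())

    def test_two_separated_plants_give_two_seeds(self):
        n = 40
        vals = {i: (0.2, 0.2, 0.4, 0.4) for i in range(n)}
        for i in (5, 6, 7, 25, 26, 27):
            vals[i] = (0.9, 0.9, 0.4, 0.4)
        desc = _descriptors(vals)
        expected = ExpectedSize(n_surface=n, fraction=0.4, count=18)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        seeds = detect_seeds(scores, desc, _line_graph(n), expected,
                             ClusteringThresholds(), Scheme.DSC1)
        assert len(seeds) == 2

    def test_uniform_scores_deterministic_tiebreak(self):
        n = 20
        desc = _uniform_descriptors(n)
        expected = ExpectedSize(n_surface=n, fraction=0.3, count=6)
        scores = {k: 1.0 for k in desc.keys()}
        seeds_a = detect_seeds(scores, desc, _line_graph(n), expected,
                               ClusteringThresholds(), Scheme.DSC1)
        seeds_b = detect_seeds(scores, desc, _line_graph(n), expected,
                               ClusteringThresholds(), Scheme.DSC1)
        assert [sorted(s.layers) for s in seeds_a] == [sorted(s.layers) for s in seeds_b]
        # ties resolve to the lowest residue numbers: pool = ceil(6/3) = 2
        assert sorted(k for s in seeds_a for k in s.layers) == [_key(0), _key(1)]

    def test_small_components_discarded_only_when_large_exists(self):
        n = 30
        vals = {i: (0.2, 0.2, 0.4, 0.4) for i in range(n)}
        # one 3-block and one isolated high scorer, pool of 4
        for i in (10, 11, 12, 20):
            vals[i] = (0.9, 0.9, 0.4, 0.4)
        desc = _descriptors(vals)
        expected = ExpectedSize(n_surface=n, fraction=0.4, count=12)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        seeds = detect_seeds(scores, desc, _line_graph(n), expected,
                             ClusteringThresholds(), Scheme.DSC1)
        assert [len(s.layers) for s in seeds] == [3]  # singleton dropped


class TestPocketRestart:
    def _setup(self, buried_fraction_in_seed):
        n = 30
        vals = {i: (0.2, 0.2, 0.4, 0.4) for i in range(n)}
        n_buried = int(4 * buried_fraction_in_seed)
        for j, i in enumerate((10, 11, 12, 13)):
            cv_local = 0.95 if j < n_buried else 0.4
            vals[i] = (0.9, 0.9, cv_local, 0.4)
        desc = _descriptors(vals)
        expected = ExpectedSize(n_surface=n, fraction=0.4, count=12)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        graph = _line_graph(n)
        th = ClusteringThresholds()
        seeds = detect_seeds(scores, desc, graph, expected, th, Scheme.DSC1)
        cv_local = {k: desc[k].cv_local for k in desc.keys()}
        return seeds, cv_local, scores, desc, graph, expected, th

    def test_dsc1_restarts_above_20_percent(self):
        seeds, cv, scores, desc, graph, expected, th = self._setup(0.25)
        new_seeds, excluded, restarted = restart_on_pockets(
            seeds, Scheme.DSC1, cv, scores, desc, graph, expected, th)
        assert restarted
        assert excluded  # the buried residues are banned
        assert all((cv.get(k) or 0) <= 0.9 for s in new_seeds for k in s.layers)

    def test_dsc2_tolerates_25_percent(self):
        seeds, cv, scores, desc, graph, expected, th = self._setup(0.25)
        _, excluded, restarted = restart_on_pockets(
            seeds, Scheme.DSC2, cv, scores, desc, graph, expected, th)
        assert not restarted and not excluded

    def test_dsc3_never_restarts(self):
        seeds, cv, scores, desc, graph, expected, th = self._setup(1.0)
        _, excluded, restarted = restart_on_pockets(
            seeds, Scheme.DSC3, cv, scores, desc, graph, expected, th)
        assert not restarted and not excluded


class TestExtension:
    def test_high_score_ring_absorbed(self):
        n = 20
        vals = {i: (0.1, 0.1, 0.4, 0.4) for i in range(n)}
        for i in (8, 9, 10, 11, 12):
            vals[i] = (0.9, 0.9, 0.4, 0.4)
        desc = _descriptors(vals)
        expected = ExpectedSize(n_surface=n, fraction=0.5, count=9)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        graph = _line_graph(n)
        th = ClusteringThresholds()
        seeds = detect_seeds(scores, desc, graph, expected, th, Scheme.DSC1)
        patches = extend_clusters(seeds, scores, desc, graph, expected, th)
        assert len(patches) == 1
        grown = set(patches[0].layers) - set(seeds[0].layers) if seeds else set()
        assert set(patches[0].layers) == {_key(i) for i in (8, 9, 10, 11, 12)}

    def test_bridged_seeds_merge(self):
        n = 30
        vals = {i: (0.1, 0.1, 0.4, 0.4) for i in range(n)}
        for i in (10, 11, 12, 14, 15, 16):  # two blocks
            vals[i] = (0.95, 0.95, 0.4, 0.4)
        vals[13] = (0.85, 0.85, 0.4, 0.4)  # bridge, just below the seeds
        desc = _descriptors(vals)
        expected = ExpectedSize(n_surface=n, fraction=0.6, count=18)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        graph = _line_graph(n)
        th = ClusteringThresholds()
        seeds = detect_seeds(scores, desc, graph, expected, th, Scheme.DSC1)
        assert len(seeds) == 2
        patches = extend_clusters(seeds, scores, desc, graph, expected, th)
        assert len(patches) == 1  # merged through the bridge
        assert sum(1 for v in patches[0].layers.values() if v == Layer.SEED.value) == 6

    def test_no_admissible_neighbor_leaves_patch_unchanged(self):
        n = 20
        vals = {i: (0.05, 0.05, 0.4, 0.4) for i in range(n)}
        for i in (5, 6, 7):
            vals[i] = (0.95, 0.95, 0.4, 0.4)
        desc = _descriptors(vals)
        # pool admits three background residues, but none touches the patch
        expected = ExpectedSize(n_surface=n, fraction=0.45, count=9)
        scores = {k: desc[k].t_jet + desc[k].pc_dna for k in desc.keys()}
        graph = _line_graph(n)
        th = ClusteringThresholds()
        seeds = detect_seeds(scores, desc, graph, expected, th, Scheme.DSC1)
        before = {k for s in seeds for k in s.layers}
        patches = extend_clusters(seeds, scores, desc, graph, expected, th)
        assert {k for p in patches for k in p.layers} == before


class TestOuterLayer:
    def test_no_growth_when_expected_reached(self):
        n = 20
        desc = _uniform_descriptors(n, t=0.9, p=0.9)
        expected = ExpectedSize(n_surface=n, fraction=0.15, count=3)
        scores = {k: 1.0 for k in desc.keys()}
        patch = PredictedPatch(
            layers={_key(i): Layer.SEED.value for i in (5, 6, 7)},
            scores={_key(i): 1.8 for i in (5, 6, 7)},
            scheme=Scheme.DSC1,
        )
        out = add_outer_layer([patch], scores, desc, _line_graph(n), expected,
                              ClusteringThresholds())
        assert set(out[0].layers) == {_key(5), _key(6), _key(7)}

    def test_growth_is_monotone(self):
        n = 20
        desc = _uniform_descriptors(n, t=0.9, p=0.9)
        expected = ExpectedSize(n_surface=n, fraction=0.5, count=8)
        scores = {k: 1.5 for k in desc.keys()}
        patch = PredictedPatch(
            layers={_key(5): Layer.SEED.value},
            scores={_key(5): 1.8},
            scheme=Scheme.DSC1,
        )
        before = set(patch.layers)
        out = add_outer_layer([patch], scores, desc, _line_graph(n), expected,
                              ClusteringThresholds())
        assert before <= set(out[0].layers)
        assert sum(p.size for p in out) <= expected.count


class TestFilter:
    def _patch(self, ids, scheme=Scheme.DSC1):
        return PredictedPatch(
            layers={_key(i): Layer.SEED.value for i in ids},
            scores={_key(i): 1.0 for i in ids},
            scheme=scheme,
        )

    def test_tiny_patches_always_removed(self, rng):
        graph = _line_graph(30)
        expected = ExpectedSize(n_surface=30, fraction=0.5, count=15)
        out = filter_patches(
            [self._patch([1, 2]), self._patch([5])], expected, graph, rng,
            ClusteringThresholds())
        assert out == []

    def test_single_patch_below_70_percent_untouched(self, rng):
        graph = _line_graph(30)
        expected = ExpectedSize(n_surface=30, fraction=0.5, count=15)
        patch = self._patch(range(9))  # 60% of expected
        out = filter_patches([patch], expected, graph, rng, ClusteringThresholds())
        assert len(out) == 1 and out[0].size == 9

    def test_small_patches_filtered_against_random_null(self, rng):
        # dense surface: chance clustering of the 40-residue candidate pool
        # produces large components, so 3- and 5-patches fall below the 95th
        # percentile while the 40-patch passes
        g = nx.complete_graph(100)
        graph = nx.relabel_nodes(g, {i: _key(i) for i in range(100)})
        expected = ExpectedSize(n_surface=100, fraction=0.4, count=40)
        patches = [
            self._patch(range(3)),
            self._patch(range(10, 15)),
            self._patch(range(20, 60)),
        ]
        out = filter_patches(patches, expected, graph, rng, ClusteringThresholds())
        assert [p.size for p in out] == [40]


class TestRunScheme:
    def test_patches_connected_and_layers_partition(self, sphere_inputs, rng):
        _, _, config, desc, graph, expected = sphere_inputs
        result = run_scheme(Scheme.DSC1, desc, graph, expected,
                            config.thresholds, rng)
        assert result.patches
        for patch in result.patches:
            sub = graph.subgraph(patch.layers)
            assert nx.is_connected(sub)
            assert set(patch.layers.values()) <= {
                Layer.SEED.value, Layer.EXTENSION.value, Layer.OUTER.value}
            assert any(v == Layer.SEED.value for v in patch.layers.values())

    def test_bitwise_deterministic(self, sphere_inputs):
        _, _, config, desc, graph, expected = sphere_inputs
        a = run_scheme(Scheme.DSC1, desc, graph, expected, config.thresholds,
                       np.random.default_rng(7))
        b = run_scheme(Scheme.DSC1, desc, graph, expected, config.thresholds,
                       np.random.default_rng(7))
        assert [p.layers for p in a.patches] == [p.layers for p in b.patches]
        assert [p.scores for p in a.patches] == [p.scores for p in b.patches]

    def test_planted_patch_recovered_with_dsc1(self, rng):
        # plant sized exactly to the expected interface, so a clean
        # prediction can cover it fully
        from jet2dna.fixtures import FixtureSpec, make_pseudo_protein
        from jet2dna.pipeline import PredictionConfig, prepare_inputs
        from jet2dna.structure import parse_structure

        spec = FixtureSpec(seed=33, n_residues=150, patch_size=7)
        pdb_text, truth = make_pseudo_protein(spec)
        structure = parse_structure(pdb_text, "plant7")
        config = PredictionConfig()
        desc, graph, expected = prepare_inputs(structure, config, truth.conservation)
        assert expected.count == 7
        result = run_scheme(Scheme.DSC1, desc, graph, expected,
                            config.thresholds, rng)
        predicted = result.residues
        planted = set(truth.planted) & set(desc.keys())
        tp = len(predicted & planted)
        f1 = 2 * tp / (len(predicted) + len(planted))
        assert f1 >= 0.7

    def test_relaxation_enlarges_pools(self):
        th = ClusteringThresholds()
        expected = ExpectedSize(n_surface=100, fraction=0.1, count=10)
        for frac in (th.seed_pool_frac, th.extension_pool_frac, th.outer_pool_frac):
            assert th.pool_size(frac, expected, relaxed=True) >= th.pool_size(
                frac, expected, relaxed=False)
        assert th.floor(th.extension_floor, relaxed=True) < th.floor(
            th.extension_floor, relaxed=False)
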