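"""Engine: grouping, convolution, merging, caching, determinism, invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragprop.engine import (
    IpcCache,
    combine_distributions,
    FragmentGroup,
    graph_distribution,
    group_node,
    realize_examples,
    round_distribution,
    space_distribution,
)
from fragprop.fixtures import make_fixture
from fragprop.oracle import direct_measure, enumerate_histogram
from fragprop.properties.base import NodeContext, NumericPlugin, round_scaled
from fragprop.properties.rotbonds import RotatableBondsPlugin
from fragprop.properties.tpsa import TpsaPlugin
from fragprop.space import (
    Fragment,
    FragmentSpace,
    TopologyEdge,
    TopologyGraph,
    TopologyNode,
    assemble_product,
    space_size,
)


class StubPlugin(NumericPlugin):
    """Heavy-atom counter with a controllable boundary, for grouping tests."""

    name = "stub"
    scale = 1

    def __init__(self, boundary_fn=lambda f: ()):
        self.boundary_fn = boundary_fn
        self.ipc_calls = 0

    def measure(self, mol):
        return mol.GetNumHeavyAtoms()

    def fragment_ipc_boundary(self, fragment, ctx):
        self.ipc_calls += 1
        return fragment.num_heavy_atoms(), self.boundary_fn(fragment)


def _node_of(smiles_list, node_id="n"):
    frags = [Fragment.from_smiles(f"{node_id}{i}", s) for i, s in enumerate(smiles_list)]
    return TopologyNode(id=node_id, fragments=frags)


CTX = NodeContext(graph_id="g", node_id="n")


class TestGroupNode:
    def test_shared_boundary_counts_accumulate(self):
        # IPCs 1, 1, 2 with one shared boundary -> one group, {1: 2, 2: 1}
        node = _node_of(["C[*:1]", "N[*:1]", "CC[*:1]"])
        groups = group_node(node, StubPlugin(), CTX)
        assert len(groups) == 1
        entries = {v: c for v, (c, _) in groups[0].entries.items()}
        assert entries == {1: 2, 2: 1}
        # representative of value 1 is the FIRST fragment attaining it
        assert groups[0].entries[1][1].id == "n0"

    def test_mixed_boundaries_partition(self):
        node = _node_of(["C[*:1]", "N[*:1]", "O[*:1]", "CC[*:1]"])
        plugin = StubPlugin(boundary_fn=lambda f: f.mol.GetAtomWithIdx(0).GetAtomicNum())
        groups = group_node(node, plugin, CTX)
        brute = {f.mol.GetAtomWithIdx(0).GetAtomicNum() for f in node.fragments}
        assert len(groups) == len(brute)
        assert sum(len(g.fragments) for g in groups) == len(node.fragments)


class TestCombine:
    def _group(self, entries):
        frag = Fragment.from_smiles("x", "C[*:1]")
        return FragmentGroup(
            node_id="n",
            boundary=(),
            fragments=[frag],
            entries={v: (c, frag) for v, c in entries.items()},
        )

    def test_counts_multiply_values_add(self):
        plugin = StubPlugin()
        out = combine_distributions([self._group({1: 2, 2: 1}), self._group({10: 3})], 0, plugin)
        assert {v: c for v, (c, _) in out.items()} == {11: 6, 12: 3}

    def test_identity_epc_preserves_single_group(self):
        plugin = StubPlugin()
        out = combine_distributions([self._group({3: 2, 5: 4})], plugin.identity, plugin)
        assert {v: c for v, (c, _) in out.items()} == {3: 2, 5: 4}

    def test_epc_shifts_all_values(self):
        plugin = StubPlugin()
        out = combine_distributions([self._group({3: 2})], 7, plugin)
        assert {v: c for v, (c, _) in out.items()} == {10: 2}

    def test_matches_exhaustive_tuple_enumeration(self):
        plugin = StubPlugin()
        groups = [self._group({1: 2, 4: 1}), self._group({0: 3, 2: 2}), self._group({5: 1})]
        out = {v: c for v, (c, _) in combine_distributions(groups, 3, plugin).items()}
        brute = {}
        for vals in itertools.product(*(g.entries.items() for g in groups)):
            value = sum(v for v, _ in vals) + 3
            count = 1
            for _, (c, _f) in vals:
                count *= c
            brute[value] = brute.get(value, 0) + count
        assert out == brute


class TestSpaceDistribution:
    def test_two_identical_graphs_double_counts(self, fixture_spaces):
        base = fixture_spaces["fig4_rxn301"]
        copy = make_fixture("fig4_rxn301")
        copy.graphs[0].id = "g2"
        doubled = FragmentSpace("doubled", [base.graphs[0], copy.graphs[0]])
        plugin = TpsaPlugin()
        single = space_distribution(base, plugin)
        both = space_distribution(doubled, plugin)
        assert both.counts() == {v: 2 * c for v, c in single.counts().items()}

    def test_jobs_do_not_change_result(self, fixture_spaces, pattern_plugin):
        space = FragmentSpace(
            "multi",
            [fixture_spaces["fig4_rxn301"].graphs[0], fixture_spaces["amide_border"].graphs[0]],
        )
        d1 = space_distribution(space, pattern_plugin, jobs=1)
        d4 = space_distribution(space, pattern_plugin, jobs=4)
        assert d1.counts() == d4.counts()
        assert [d1.entries[v].examples for v in d1.sorted_values()] == [
            d4.entries[v].examples for v in d4.sorted_values()
        ]

    def test_conservation(self, fixture_spaces, all_plugins):
        for space in fixture_spaces.values():
            for plugin in all_plugins:
                dist = space_distribution(space, plugin)
                assert dist.total() == space_size(space), (space.name, plugin.name)


class TestIpcCache:
    def _reuse_space(self):
        """One fragment structure reused in all three nodes (same id)."""
        smis = ["CN[*:1]", "CO[*:1]"]

        def node(nid):
            return TopologyNode(
                id=nid, fragments=[Fragment.from_smiles(f"shared{i}", s) for i, s in enumerate(smis)]
            )

        mid = TopologyNode(
            id="m",
            fragments=[Fragment.from_smiles("mid0", "[*:1]CC[*:2]")],
        )
        graph = TopologyGraph(
            id="g",
            nodes=[node("a"), mid, node("b")],
            edges=[
                TopologyEdge("a", "m", [(1, 1, "single")]),
                TopologyEdge("m", "b", [(2, 1, "single")]),
            ],
        )
        return FragmentSpace("reuse", [graph])

    def test_cache_avoids_recomputation(self):
        space = self._reuse_space()
        plugin = StubPlugin()
        cache = IpcCache()
        graph_distribution(space.graphs[0], plugin, cache)
        # 3 distinct (fragment id, context) keys; 5 fragment slots in total
        assert plugin.ipc_calls == 3
        assert cache.hits == 2

    def test_cache_on_off_identical(self):
        space = self._reuse_space()
        on = space_distribution(space, StubPlugin(), use_cache=True)
        off = space_distribution(space, StubPlugin(), use_cache=False)
        assert on.counts() == off.counts()
        assert [on.entries[v].examples for v in on.sorted_values()] == [
            off.entries[v].examples for v in off.sorted_values()
        ]


class TestSwapInvariance:
    @pytest.mark.parametrize("plugin_factory", [TpsaPlugin, RotatableBondsPlugin])
    def test_equal_boundary_fragments_shift_by_ipc_difference(
        self, plugin_factory, fixture_spaces
    ):
        """Swapping boundary-equal fragments changes a product's property by
        exactly the IPC difference."""
        plugin = plugin_factory()
        space = fixture_spaces["amide_border"]
        graph = space.graphs[0]
        node = graph.nodes[0]
        ctx = NodeContext.for_node(graph, node)
        groups = group_node(node, plugin, ctx)
        partner_node = graph.nodes[1]
        measure = direct_measure(plugin.name)
        checked = 0
        for group in groups:
            if len(group.fragments) < 2:
                continue
            f, g = group.fragments[0], group.fragments[1]
            ipc_f = plugin.fragment_ipc_boundary(f, ctx)[0]
            ipc_g = plugin.fragment_ipc_boundary(g, ctx)[0]
            for partner in partner_node.fragments:
                pf = assemble_product(graph, [f, partner])
                pg = assemble_product(graph, [g, partner])
                assert measure(pf.mol) - measure(pg.mol) == ipc_f - ipc_g
                checked += 1
        assert checked > 0


class TestRounding:
    def test_collisions_merge(self):
        plugin = TpsaPlugin()
        dist = space_distribution(make_fixture("fig3_triazole_halves"), plugin)
        dist.entries.clear()
        from fragprop.engine import DistEntry

        dist.entries[1023] = DistEntry(count=1, examples=[("g1", ("a",))])
        dist.entries[1024] = DistEntry(count=2, examples=[("g1", ("b",))])
        rounded = round_distribution(dist, precision=1)
        assert rounded.counts() == {1020: 3}
        assert rounded.entries[1020].examples == [("g1", ("a",)), ("g1", ("b",))]

    def test_full_precision_is_identity(self, fixture_spaces):
        dist = space_distribution(fixture_spaces["fig3_triazole_halves"], TpsaPlugin())
        assert round_distribution(dist, precision=2).counts() == dist.counts()

    def test_rounded_matches_oracle_of_rounded_values(self, fixture_spaces):
        space = fixture_spaces["fig1_triazole_amide"]
        dist = round_distribution(space_distribution(space, TpsaPlugin()), precision=0)
        oracle = enumerate_histogram(
            space, direct_measure("tpsa"), precision=0, scale=TpsaPlugin.scale
        )
        assert dist.counts() == oracle

    @given(value=st.integers(min_value=0, max_value=10**7), precision=st.integers(0, 3))
    @settings(max_examples=200, deadline=None, derandomize=True, database=None)
    def test_round_scaled_properties(self, value, precision):
        out = round_scaled(value, 100, precision)
        step = 100 // 10**precision if precision < 2 else 1
        assert out % step == 0
        assert abs(out - value) * 2 <= step


class TestExamples:
    def test_examples_verify_and_respect_cap(self, fixture_spaces, all_plugins):
        space = fixture_spaces["fig4_rxn301"]
        from fragprop.properties.patterns import PatternSetPlugin

        for plugin in all_plugins:
            dist = space_distribution(space, plugin)
            if isinstance(plugin, PatternSetPlugin):
                measure = direct_measure("patterns", queries=plugin.queries)
            else:
                measure = direct_measure(plugin.name)
            from rdkit import Chem

            for value, smiles_list in realize_examples(dist, space).items():
                assert 1 <= len(smiles_list) <= 10
                for smi in smiles_list:
                    assert measure(Chem.MolFromSmiles(smi)) == value

    def test_value_hit_by_two_graphs_yields_two_examples(self, fixture_spaces):
        base = fixture_spaces["fig4_rxn301"]
        copy = make_fixture("fig4_rxn301")
        copy.graphs[0].id = "g2"
        space = FragmentSpace("two", [base.graphs[0], copy.graphs[0]])
        dist = space_distribution(space, TpsaPlugin())
        assert all(len(e.examples) == 2 for e in dist.entries.values())
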