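"""Property-agnostic distribution engine.

The algorithm computes the exact histogram of a property over every product
of a topological fragment space without enumerating the products:

1. per fragment, compute the internal property component (IPC) and the
   boundary information via the property plugin;
2. per node, group fragments by boundary information and build a value ->
   count distribution over the group's IPCs;
3. per combination of one group per node, assemble a single exemplary
   product and infer the shared external property component (EPC);
4. convolve the group distributions (values combined, counts multiplied) and
   fold in the EPC;
5. sum over group combinations, then over topology graphs.

Counts are arbitrary-precision integers: spaces can exceed 10^17 products
and floats would lose exactness.  Every histogram value keeps up to
``example_cap`` fragment choices so that representative molecules can be
assembled afterwards without enumerating the space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Hashable, Sequence

from .properties.base import NodeContext, PropertyPlugin, round_scaled
from .space import (
    Fragment,
    FragmentSpace,
    TopologyGraph,
    TopologyNode,
    assemble_product,
)

__all__ = [
    "FragmentGroup",
    "PropertyDistribution",
    "IpcCache",
    "group_node",
    "epc_for_combination",
    "combine_distributions",
    "graph_distribution",
    "space_distribution",
    "round_distribution",
    "realize_examples",
    "write_histogram_tsv",
    "write_histogram_json",
]

EXAMPLE_CAP = 10  # example molecules kept per histogram value


@dataclass
class FragmentGroup:
    """Fragments of one node sharing boundary information.

    ``entries`` maps IPC value -> (count, representative fragment); the
    representative is the first fragment in node order attaining the value.
    """

    node_id: str
    boundary: Hashable
    fragments: list[Fragment]
    entries: dict[Any, tuple[int, Fragment]]
    first_ipc: Any = None  # IPC of the first fragment (the exemplary member)

    @property
    def first(self) -> Fragment:
        return self.fragments[0]


@dataclass
class DistEntry:
    count: int
    examples: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    # each example: (graph_id, fragment ids in node order)


@dataclass
class PropertyDistribution:
    """Exact map from property value to product count, with examples."""

    plugin: PropertyPlugin
    entries: dict[Any, DistEntry]
    space_name: str = ""

    def total(self) -> int:
        return sum(e.count for e in self.entries.values())

    def counts(self) -> dict[Any, int]:
        return {v: e.count for v, e in self.entries.items()}

    def sorted_values(self) -> list:
        return sorted(self.entries, key=self.plugin.sort_key)


class IpcCache:
    """Memoizes per-fragment IPC and boundary information by fragment id.

    Fragment ids are stable across nodes and graphs, so a fragment reused in
    several reactions is processed once.  For plugins whose result depends on
    the topology context the context is part of the key, keeping the cache
    correct for any plugin.
    """

    def __init__(self) -> None:
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    def ipc_boundary(self, plugin: PropertyPlugin, fragment: Fragment, ctx: NodeContext):
        key = (
            plugin.cache_key,
            fragment.id,
            None if plugin.context_free else ctx.cycle_pairs,
        )
        try:
            result = self._store[key]
            self.hits += 1
            return result
        except KeyError:
            self.misses += 1
            result = plugin.fragment_ipc_boundary(fragment, ctx)
            self._store[key] = result
            return result


def _ipc_boundary(plugin, fragment, ctx, cache: IpcCache | None):
    if cache is not None:
        return cache.ipc_boundary(plugin, fragment, ctx)
    return plugin.fragment_ipc_boundary(fragment, ctx)


def group_node(
    node: TopologyNode,
    plugin: PropertyPlugin,
    ctx: NodeContext,
    cache: IpcCache | None = None,
) -> list[FragmentGroup]:
    """Partition a node's fragments by boundary information (node order kept)."""
    groups: dict[Hashable, FragmentGroup] = {}
    for fragment in node.fragments:
        try:
            ipc, boundary = _ipc_boundary(plugin, fragment, ctx, cache)
        except Exception as exc:
            raise RuntimeError(
                f"plugin {plugin.name!r} failed on fragment {fragment.id!r}: {exc}"
            ) from exc
        group = groups.get(boundary)
        if group is None:
            group = FragmentGroup(
                node_id=node.id, boundary=boundary, fragments=[], entries={}, first_ipc=ipc
            )
            groups[boundary] = group
        group.fragments.append(fragment)
        if ipc in group.entries:
            count, rep = group.entries[ipc]
            group.entries[ipc] = (count + 1, rep)
        else:
            group.entries[ipc] = (1, fragment)
    return list(groups.values())


def epc_for_combination(
    graph: TopologyGraph, combo: Sequence[FragmentGroup], plugin: PropertyPlugin
):
    """Shared EPC of one fragment-group combination, via an exemplary product.

    The exemplary product is assembled from each group's first fragment; any
    other members would give the same EPC by the interchangeability
    contract of the boundary information.
    """
    chosen = [group.first for group in combo]
    product = assemble_product(graph, chosen)
    chosen_ipcs = [group.first_ipc for group in combo]
    return plugin.epc(product, chosen, chosen_ipcs)


def combine_distributions(
    combo: Sequence[FragmentGroup], epc, plugin: PropertyPlugin
) -> dict[Any, tuple[int, tuple[str, ...]]]:
    """Convolve the groups' IPC distributions and fold in the shared EPC.

    Values are combined with the plugin's operation and counts multiplied.
    When several value tuples collide on one combined value their counts
    accumulate and the first fragment choice (in a deterministic left fold
    over nodes, entries in node order) is kept as the representative.
    """
    acc: dict[Any, tuple[int, tuple[str, ...]]] = {plugin.identity: (1, ())}
    for group in combo:
        nxt: dict[Any, tuple[int, tuple[str, ...]]] = {}
        for value, (count, choice) in acc.items():
            for ipc, (ipc_count, rep) in group.entries.items():
                combined = plugin.combine(value, ipc)
                new_count = count * ipc_count
                if combined in nxt:
                    prev_count, prev_choice = nxt[combined]
                    nxt[combined] = (prev_count + new_count, prev_choice)
                else:
                    nxt[combined] = (new_count, choice + (rep.id,))
        acc = nxt
    final: dict[Any, tuple[int, tuple[str, ...]]] = {}
    for value, (count, choice) in acc.items():
        combined = plugin.combine(value, epc)
        if combined in final:
            prev_count, prev_choice = final[combined]
            final[combined] = (prev_count + count, prev_choice)
        else:
            final[combined] = (count, choice)
    return final


def graph_distribution(
    graph: TopologyGraph,
    plugin: PropertyPlugin,
    cache: IpcCache | None = None,
) -> dict[Any, tuple[int, tuple[str, ...]]]:
    """Exact value -> (count, example choice) map for one topology graph."""
    per_node_groups = []
    for node in graph.nodes:
        ctx = NodeContext.for_node(graph, node)
        per_node_groups.append(group_node(node, plugin, ctx, cache))
    result: dict[Any, tuple[int, tuple[str, ...]]] = {}
    for combo in itertools.product(*per_node_groups):
        epc = epc_for_combination(graph, combo, plugin)
        for value, (count, choice) in combine_distributions(combo, epc, plugin).items():
            if value in result:
                prev_count, prev_choice = result[value]
                result[value] = (prev_count + count, prev_choice)
            else:
                result[value] = (count, choice)
    return result


def _graph_task(graph: TopologyGraph, plugin: PropertyPlugin, use_cache: bool):
    cache = IpcCache() if use_cache else None
    return graph_distribution(graph, plugin, cache)


def space_distribution(
    space: FragmentSpace,
    plugin: PropertyPlugin,
    jobs: int = 1,
    use_cache: bool | None = None,
    example_cap: int = EXAMPLE_CAP,
) -> PropertyDistribution:
    """Distribution of the entire space: topology graphs are processed
    independently (optionally in parallel) and their histograms merged.

    Counts add; example choices concatenate across graphs up to
    ``example_cap`` per value.  The result is independent of ``jobs`` and of
    whether the IPC cache is enabled.
    """
    if use_cache is None:
        use_cache = plugin.cache_by_default
    if jobs > 1 and len(space.graphs) > 1:
        from joblib import Parallel, delayed

        partials = Parallel(n_jobs=jobs)(
            delayed(_graph_task)(graph, plugin, use_cache) for graph in space.graphs
        )
    else:
        cache = IpcCache() if use_cache else None
        partials = [graph_distribution(graph, plugin, cache) for graph in space.graphs]

    entries: dict[Any, DistEntry] = {}
    for graph, partial in zip(space.graphs, partials):
        for value, (count, choice) in partial.items():
            entry = entries.get(value)
            if entry is None:
                entry = entries[value] = DistEntry(count=0)
            entry.count += count
            if len(entry.examples) < example_cap:
                entry.examples.append((graph.id, choice))
    return PropertyDistribution(plugin=plugin, entries=entries, space_name=space.name)


def round_distribution(
    dist: PropertyDistribution, precision: int, example_cap: int = EXAMPLE_CAP
) -> PropertyDistribution:
    """Round numeric values to ``precision`` decimals, merging collided bins."""
    entries: dict[Any, DistEntry] = {}
    for value in dist.sorted_values():
        src = dist.entries[value]
        rounded = round_scaled(value, dist.plugin.scale, precision)
        entry = entries.get(rounded)
        if entry is None:
            entry = entries[rounded] = DistEntry(count=0)
        entry.count += src.count
        room = example_cap - len(entry.examples)
        if room > 0:
            entry.examples.extend(src.examples[:room])
    return PropertyDistribution(plugin=dist.plugin, entries=entries, space_name=dist.space_name)


def realize_examples(
    dist: PropertyDistribution,
    space: FragmentSpace,
    values: Sequence | None = None,
) -> dict[Any, list[str]]:
    """Assemble the stored fragment choices into canonical SMILES per value."""
    frag_index: dict[tuple[str, str], dict[str, Fragment]] = {}
    for graph in space.graphs:
        for node in graph.nodes:
            frag_index[(graph.id, node.id)] = {f.id: f for f in node.fragments}
    wanted = dist.sorted_values() if values is None else list(values)
    out: dict[Any, list[str]] = {}
    for value in wanted:
        smiles = []
        for graph_id, choice in dist.entries[value].examples:
            graph = space.graph(graph_id)
            chosen = [
                frag_index[(graph_id, node.id)][frag_id]
                for node, frag_id in zip(graph.nodes, choice)
            ]
            smiles.append(assemble_product(graph, chosen).smiles())
        out[value] = smiles
    return out


# ---------------------------------------------------------------------------
# Output


def write_histogram_tsv(dist: PropertyDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("value\tcount\tn_examples\n")
        for value in dist.sorted_values():
            entry = dist.entries[value]
            fh.write(
                f"{dist.plugin.format_value(value)}\t{entry.count}\t{len(entry.examples)}\n"
            )


def write_histogram_json(
    dist: PropertyDistribution,
    path,
    space: FragmentSpace | None = None,
    config: dict | None = None,
) -> None:
    """JSON histogram; counts as decimal strings to preserve exactness.

    When ``space`` is given, example molecules are realized as SMILES.
    """
    import json

    examples = realize_examples(dist, space) if space is not None else None
    obj = {
        "property": dist.plugin.name,
        "space": dist.space_name,
        "total": str(dist.total()),
        "config": config or {},
        "entries": [
            {
                "value": dist.plugin.format_value(value),
                "count": str(dist.entries[value].count),
                **({"examples": examples[value]} if examples is not None else {}),
            }
            for value in dist.sorted_values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")
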