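"""Property-plugin contract for the decomposition engine.

A plugin splits a molecular property into per-fragment *internal property
components* (IPCs, computable without knowing the partner fragments) and a
shared *external property component* (EPC) per fragment-group combination,
inferred from one exemplary product.  Everything at a fragment's border that
the EPC may depend on is condensed into hashable *boundary information*; two
fragments with equal boundary information are interchangeable without
changing any product's EPC.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Any, Hashable, Sequence

from rdkit import Chem

from ..space import Fragment, Product, TopologyGraph, TopologyNode

__all__ = ["NodeContext", "PropertyPlugin", "NumericPlugin", "round_scaled", "format_scaled"]


@dataclass(frozen=True)
class NodeContext:
    """Topology context handed to a plugin along with each fragment.

    ``cycle_pairs`` lists pairs of this node's linker labels whose attachment
    atoms are additionally connected through the rest of the topology graph
    (the node lies on a topology cycle, or two connections of one edge close
    a ring).  Any fragment bond on a path between such a pair of attachment
    atoms is a ring bond in every product.
    """

    graph_id: str
    node_id: str
    cycle_pairs: frozenset[tuple[int, int]] = frozenset()

    @classmethod
    def for_node(cls, graph: TopologyGraph, node: TopologyNode) -> "NodeContext":
        import networkx as nx

        incident: list[tuple[int, str]] = []  # (label at this node, other node id)
        for edge in graph.edges:
            for la, lb, _ in edge.connections:
                if edge.node_a == node.id:
                    incident.append((la, edge.node_b))
                if edge.node_b == node.id:
                    incident.append((lb, edge.node_a))
        pairs = set()
        if len(incident) > 1:
            rest = graph.topology()
            rest.remove_node(node.id)
            for i, (l1, o1) in enumerate(incident):
                for l2, o2 in incident[i + 1 :]:
                    if o1 == o2 or (
                        o1 in rest and o2 in rest and nx.has_path(rest, o1, o2)
                    ):
                        pairs.add(tuple(sorted((l1, l2))))
        return cls(graph_id=graph.id, node_id=node.id, cycle_pairs=frozenset(pairs))


class PropertyPlugin(ABC):
    """Defines the five property-specific parts of the algorithm.

    value type (hashable), boundary information, fragment IPC, combination
    EPC, and the (associative, commutative) way values are combined.
    """

    name: str = "property"
    #: identity element of :meth:`combine`
    identity: Any = 0
    #: scaling factor for numeric values stored as exact integers (1 = counts)
    scale: int = 1
    #: whether IPC/boundary depend only on the fragment itself (cacheable)
    context_free: bool = True
    #: whether the engine should memoize IPC/boundary by fragment id
    cache_by_default: bool = False

    @abstractmethod
    def combine(self, a, b):
        """Combine two property values; must be associative and commutative."""

    @abstractmethod
    def fragment_ipc_boundary(self, fragment: Fragment, ctx: NodeContext) -> tuple[Any, Hashable]:
        """Return ``(ipc_value, boundary_info)`` for one fragment."""

    @abstractmethod
    def epc(self, product: Product, chosen: Sequence[Fragment], chosen_ipcs: Sequence[Any]):
        """External property component shared by one fragment-group combination."""

    # -- presentation -------------------------------------------------------
    def sort_key(self, value):
        return value

    def format_value(self, value) -> str:
        return format_scaled(value, self.scale)

    @property
    def cache_key(self) -> str:
        """Identity of this plugin configuration for the IPC cache."""
        return self.name


def round_scaled(value: int, scale: int, precision: int) -> int:
    """Round a scale-encoded numeric value to ``precision`` decimal places.

    Values are non-negative integers ``round(x * scale)``; rounding is
    half-up, and a precision at or above the intrinsic scale is the identity.
    """
    step = scale // (10**precision) if 10**precision <= scale else 1
    if step <= 1:
        return value
    q, r = divmod(value, step)
    return (q + (1 if 2 * r >= step else 0)) * step


def format_scaled(value: int, scale: int) -> str:
    if scale == 1:
        return str(value)
    digits = len(str(scale)) - 1
    q, r = divmod(value, scale)
    return f"{q}.{r:0{digits}d}"


class NumericPlugin(PropertyPlugin):
    """Base for additive numeric properties stored as exact scaled integers.

    The EPC is the direct value of the exemplary product minus the sum of the
    chosen IPCs, which for additive numeric properties equals the summed
    contribution of the atoms excluded from the IPCs.
    """

    identity = 0

    def combine(self, a: int, b: int) -> int:
        return a + b

    @abstractmethod
    def measure(self, mol: Chem.Mol) -> int:
        """Directly computed property value of a full molecule (scaled)."""

    def epc(self, product: Product, chosen, chosen_ipcs) -> int:
        return self.measure(product.mol) - sum(chosen_ipcs)
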