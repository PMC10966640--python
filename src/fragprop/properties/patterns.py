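"""SMARTS-pattern occurrence plugin.

The property value of a product is the subset of query patterns it contains,
encoded as a bitmask over the query list; values combine by set union.  A
query either matches entirely inside one fragment (it is then part of that
fragment's IPC) or it matches across fragment borders (a *crossing pattern*,
part of the EPC of the fragment-group combination).

Crossing matches are anticipated at fragment level by matching *saturated
subpatterns*: every connected induced subgraph of a query, with each open
bond capped by a node that matches only linker (dummy) atoms.  A fragment's
boundary information is the set of subpatterns it contains anchored at its
linkers, together with the mapping of saturated positions to linker labels;
fragments that agree on this are interchangeable for every possible crossing
match.  The actual EPC is decided on an exemplary product by enumerating all
embeddings of each query and checking atom provenance for matches that span
more than one fragment.

Ring-membership primitives in queries are honoured only for rings that are
complete at fragment level or closed directly across borders via ring
dummies; membership in a macrocycle closed through a topology cycle is not
visible to fragment-level matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem

from ..space import Fragment, Product
from .base import NodeContext, PropertyPlugin

__all__ = [
    "Query",
    "QueryError",
    "load_queries",
    "parse_query_lines",
    "Subpattern",
    "SubpatternLibrary",
    "enumerate_subpatterns",
    "PatternSetPlugin",
    "aggregate_by_size",
    "aggregate_per_pattern",
    "aggregate_at_least_one",
]

MAX_MATCHES = 100_000


class QueryError(ValueError):
    """Raised for unparsable or unsupported SMARTS queries."""


@dataclass(frozen=True)
class Query:
    name: str
    smarts: str
    mol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @classmethod
    def parse(cls, smarts: str, name: str | None = None) -> "Query":
        if "$(" in smarts:
            raise QueryError(f"query {name or smarts!r}: recursive SMARTS are not supported")
        mol = Chem.MolFromSmarts(smarts)
        if mol is None:
            raise QueryError(f"query {name or smarts!r}: cannot parse SMARTS {smarts!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise QueryError(f"query {name or smarts!r}: disconnected SMARTS are not supported")
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)  # maps are reserved for saturation markers
        return cls(name=name or smarts, smarts=smarts, mol=mol)


def parse_query_lines(lines: Iterable[str]) -> list[Query]:
    """One SMARTS per line, optional tab-separated name.

    Lines starting with ``#`` are comments ('#' inside a line is SMARTS
    syntax, e.g. ``C#N``).
    """
    queries = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smarts = parts[0].strip()
        name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        queries.append(Query.parse(smarts, name))
    if len({q.name for q in queries}) != len(queries):
        raise QueryError("duplicate query names in query file")
    return queries


def load_queries(path) -> list[Query]:
    with open(path) as fh:
        return parse_query_lines(fh)


# ---------------------------------------------------------------------------
# Subpattern enumeration


def _connected_subsets(adj: list[set[int]], cap: int) -> list[frozenset[int]]:
    """All connected vertex subsets, each exactly once (ESU enumeration)."""
    n = len(adj)
    out: list[frozenset[int]] = []

    def extend(sub: set[int], ext: set[int], v: int) -> None:
        out.append(frozenset(sub))
        if len(out) > cap:
            raise QueryError(f"subpattern enumeration exceeded cap of {cap}")
        ext = set(ext)
        while ext:
            w = ext.pop()
            nbh = {u for s in sub for u in adj[s]}
            new_ext = ext | {u for u in adj[w] if u > v and u not in sub and u not in nbh}
            extend(sub | {w}, new_ext, v)

    for v in range(n):
        extend({v}, {u for u in adj[v] if u > v}, v)
    return out


@dataclass
class Subpattern:
    """A saturated connected subgraph of one or more queries.

    ``mol`` carries the original atom and bond expressions plus one
    ``[#0:k]`` saturation atom per open bond (k = 1-based slot); a match is
    valid only when each saturation atom lands on a dummy and each core atom
    on a real atom.
    """

    id: int
    smarts: str
    mol: Chem.Mol = field(repr=False)
    sat_slots: list[int] = field(default_factory=list)  # atom idx per slot
    origins: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)

    def core_atoms(self) -> list[int]:
        sat = set(self.sat_slots)
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetIdx() not in sat]


def _saturated_subquery(qmol: Chem.Mol, subset: frozenset[int]) -> tuple[Chem.Mol, list[int]]:
    """Build the saturated query for one induced connected subset."""
    rw = Chem.RWMol(qmol)
    sat_anchor: list[tuple[int, int]] = []  # (new atom idx, slot)
    slot = 0
    for bond in qmol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for a, o in ((u, v), (v, u)):
            if a in subset and o not in subset:
                slot += 1
                cap = Chem.AtomFromSmarts("[#0]")
                cap.SetAtomMapNum(slot)
                w = rw.AddAtom(cap)
                rw.AddBond(a, w, Chem.BondType.SINGLE)
                # carry the original bond expression over to the capped bond
                rw.ReplaceBond(rw.GetBondBetweenAtoms(a, w).GetIdx(), bond)
                sat_anchor.append(w)
    removed = sorted((i for i in range(qmol.GetNumAtoms()) if i not in subset), reverse=True)
    for idx in removed:
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    sat_slots = sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0),
        key=lambda i: mol.GetAtomWithIdx(i).GetAtomMapNum(),
    )
    return mol, sat_slots


def _pattern_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        label = "[#0]" if atom.GetAtomMapNum() > 0 else atom.GetSmarts()
        g.add_node(atom.GetIdx(), sm=label)
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), sm=bond.GetSmarts())
    return g


def _patterns_equivalent(a: nx.Graph, b: nx.Graph) -> bool:
    gm = isomorphism.GraphMatcher(
        a,
        b,
        node_match=isomorphism.categorical_node_match("sm", None),
        edge_match=isomorphism.categorical_edge_match("sm", None),
    )
    return gm.is_isomorphic()


@dataclass
class SubpatternLibrary:
    """Deduplicated saturated subpatterns of a query set, reusable on disk."""

    queries: list[Query]
    subpatterns: list[Subpattern]

    def to_json(self) -> str:
        return json.dumps(
            {
                "queries": [{"name": q.name, "smarts": q.smarts} for q in self.queries],
                "subpatterns": [
                    {"id": sp.id, "smarts": sp.smarts, "origins": sp.origins}
                    for sp in self.subpatterns
                ],
            },
            indent=1,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "SubpatternLibrary":
        data = json.loads(text)
        queries = [Query.parse(q["smarts"], q["name"]) for q in data["queries"]]
        subs = []
        for entry in data["subpatterns"]:
            mol = Chem.MolFromSmarts(entry["smarts"])
            if mol is None:
                raise QueryError(f"library subpattern {entry['smarts']!r} failed to parse")
            sat_slots = sorted(
                (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0),
                key=lambda i: mol.GetAtomWithIdx(i).GetAtomMapNum(),
            )
            subs.append(
                Subpattern(
                    id=entry["id"],
                    smarts=entry["smarts"],
                    mol=mol,
                    sat_slots=sat_slots,
                    origins=[tuple((o[0], tuple(o[1]))) for o in entry.get("origins", [])],
                )
            )
        return cls(queries=queries, subpatterns=subs)

    @classmethod
    def load(cls, path) -> "SubpatternLibrary":
        with open(path) as fh:
            return cls.from_json(fh.read())


def enumerate_subpatterns(
    queries: Sequence[Query], cap_per_query: int = 100_000
) -> SubpatternLibrary:
    """All saturated connected induced subgraphs of all queries, deduplicated.

    Every proper connected subset of a (connected) query has at least one
    open bond and therefore at least one saturation node.  Equivalence for
    deduplication is graph isomorphism on raw atom/bond expression strings:
    conservative, so distinct-looking but equivalent expressions are kept
    separately (costs speed, never correctness).
    """
    subpatterns: list[Subpattern] = []
    buckets: dict[tuple, list[int]] = {}
    graphs: dict[int, nx.Graph] = {}
    for qi, query in enumerate(queries):
        n = query.mol.GetNumAtoms()
        adj: list[set[int]] = [set() for _ in range(n)]
        for bond in query.mol.GetBonds():
            adj[bond.GetBeginAtomIdx()].add(bond.GetEndAtomIdx())
            adj[bond.GetEndAtomIdx()].add(bond.GetBeginAtomIdx())
        for subset in _connected_subsets(adj, cap_per_query):
            if len(subset) == n:
                continue  # no open bond
            mol, sat_slots = _saturated_subquery(query.mol, subset)
            graph = _pattern_graph(mol)
            key = (
                tuple(sorted(d["sm"] for _, d in graph.nodes(data=True))),
                tuple(sorted(d["sm"] for _, _, d in graph.edges(data=True))),
            )
            origin = (qi, tuple(sorted(subset)))
            for sid in buckets.get(key, ()):
                if _patterns_equivalent(graphs[sid], graph):
                    subpatterns[sid].origins.append(origin)
                    break
            else:
                sid = len(subpatterns)
                subpatterns.append(
                    Subpattern(
                        id=sid,
                        smarts=Chem.MolToSmarts(mol),
                        mol=mol,
                        sat_slots=sat_slots,
                        origins=[origin],
                    )
                )
                graphs[sid] = graph
                buckets.setdefault(key, []).append(sid)
    return SubpatternLibrary(queries=list(queries), subpatterns=subpatterns)


# ---------------------------------------------------------------------------
# Plugin


def _dummy_labels(mol: Chem.Mol) -> dict[int, int]:
    return {
        a.GetIdx(): a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    }


class PatternSetPlugin(PropertyPlugin):
    """Subset-of-queries property; bitmask values, union combination."""

    name = "patterns"
    identity = 0
    scale = 1
    cache_by_default = True

    def __init__(self, queries: Sequence[Query], library: SubpatternLibrary | None = None):
        self.queries = list(queries)
        self.library = library if library is not None else enumerate_subpatterns(queries)
        if [q.smarts for q in self.library.queries] != [q.smarts for q in self.queries]:
            raise QueryError("subpattern library was built for a different query set")

    @property
    def cache_key(self) -> str:
        return "patterns:" + "|".join(q.smarts for q in self.queries)

    def combine(self, a: int, b: int) -> int:
        return a | b

    # -- fragment level -----------------------------------------------------
    def fragment_ipc_boundary(self, fragment: Fragment, ctx: NodeContext):
        mol = fragment.mol
        dummies = set(fragment.dummy_atoms())
        ipc = 0
        for qi, query in enumerate(self.queries):
            for match in mol.GetSubstructMatches(query.mol, maxMatches=MAX_MATCHES):
                if not dummies.intersection(match):
                    ipc |= 1 << qi
                    break
        return ipc, self._boundary(fragment, dummies)

    def _boundary(self, fragment: Fragment, dummies: set[int]) -> frozenset:
        mol = fragment.mol
        labels = _dummy_labels(mol)
        entries = set()
        for sp in self.library.subpatterns:
            sat = set(sp.sat_slots)
            for match in mol.GetSubstructMatches(sp.mol, uniquify=False, maxMatches=MAX_MATCHES):
                placement = []
                ok = True
                for q_idx, m_idx in enumerate(match):
                    if q_idx in sat:
                        label = labels.get(m_idx)
                        if label is None:
                            ok = False
                            break
                        placement.append((sp.sat_slots.index(q_idx), label))
                    elif m_idx in dummies:
                        ok = False
                        break
                if ok:
                    entries.add((sp.id, tuple(sorted(placement))))
        return frozenset(entries)

    # -- product level ------------------------------------------------------
    def epc(self, product: Product, chosen, chosen_ipcs) -> int:
        mol = product.mol
        value = 0
        for qi, query in enumerate(self.queries):
            for match in mol.GetSubstructMatches(query.mol, maxMatches=MAX_MATCHES):
                if len(product.source_nodes(match)) > 1:
                    value |= 1 << qi
                    break
        return value

    def measure(self, mol: Chem.Mol) -> int:
        """Direct subset-of-queries value of a full molecule."""
        value = 0
        for qi, query in enumerate(self.queries):
            if mol.HasSubstructMatch(query.mol):
                value |= 1 << qi
        return value

    # -- presentation -------------------------------------------------------
    def sort_key(self, value: int):
        return (bin(value).count("1"), value)

    def format_value(self, value: int) -> str:
        if value == 0:
            return "-"
        return "|".join(q.name for qi, q in enumerate(self.queries) if value >> qi & 1)


# ---------------------------------------------------------------------------
# Aggregations


def aggregate_by_size(entries: dict[int, int]) -> dict[int, int]:
    """Counts of products containing 0, 1, 2, ... query patterns."""
    out: dict[int, int] = {}
    for value, count in entries.items():
        size = bin(value).count("1")
        out[size] = out.get(size, 0) + count
    return dict(sorted(out.items()))


def aggregate_per_pattern(entries: dict[int, int], queries: Sequence[Query]) -> dict[str, int]:
    """Per-query product counts (not disjoint: a product counts once per query)."""
    out = {q.name: 0 for q in queries}
    for value, count in entries.items():
        for qi, q in enumerate(queries):
            if value >> qi & 1:
                out[q.name] += count
    return out


def aggregate_at_least_one(entries: dict[int, int]) -> int:
    return sum(count for value, count in entries.items() if value != 0)
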