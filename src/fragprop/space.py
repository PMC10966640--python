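"""Data model and I/O for topological fragment spaces.

A topological fragment space describes a combinatorial compound library
implicitly: each topology graph models one combinatorial reaction, its nodes
hold interchangeable molecular fragments (synthons) and its edges say which
fragments are bonded together.  A product molecule is obtained by picking one
fragment per node and forming the bonds listed on the edges.

Fragments are stored as SMILES with two kinds of placeholder ("dummy") atoms:

* **linker dummies** ``[*:L]`` -- mark a connection point; the atom-map number
  ``L`` is the linker label referenced by edge connections.
* **ring dummies** ``[1*:L]`` (isotope 1) -- stand in for atoms contributed by
  a partner fragment to a ring that is formed across the fragment border.
  They complete the ring at fragment level so that ring perception and
  aromaticity of the real atoms are already correct in the fragment.  A ring
  dummy with no real-atom neighbour mirrors an interior partner atom and
  carries no label (``[1*]``).

Because every dummy is replaced by exactly one real partner atom on assembly,
every non-dummy atom keeps its element, charge, aromaticity and
degree-counting-dummies when it appears in a product.  The one deliberate
exception is hydrogen count: the electron localization of a fragment is chosen
so that the number of hydrogens is minimal, and assembly re-localizes
(possibly adding a hydrogen, e.g. the N-H of an azole formed across a border).

The on-disk format is a small JSON dialect::

    {"name": ..., "graphs": [
        {"id": ..., "nodes": [{"id": ..., "fragments": [{"id": ..., "smiles": ...}]}],
         "edges": [{"a": ..., "b": ..., "connections": [[la, lb, "single"], ...]}]}]}
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem.rdchem import AtomKekulizeException, AtomValenceException, KekulizeException

__all__ = [
    "SpaceError",
    "AssemblyError",
    "Fragment",
    "TopologyNode",
    "TopologyEdge",
    "TopologyGraph",
    "FragmentSpace",
    "Product",
    "read_space",
    "write_space",
    "space_from_dict",
    "space_to_dict",
    "space_size",
    "assemble_product",
    "write_examples",
    "BOND_ORDERS",
]

BOND_ORDERS = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "aromatic": Chem.BondType.AROMATIC,
}

_STEREO_CHARS = ("@", "/", "\\")


class SpaceError(ValueError):
    """Raised for malformed space files or invariant violations."""


class AssemblyError(RuntimeError):
    """Raised when a fragment choice cannot be assembled into a valid molecule."""


@dataclass
class Fragment:
    """One synthon: a molecular graph with labelled dummy atoms.

    ``linkers`` maps each linker label to ``(attachment_atom_idx, dummy_idx)``
    where *attachment* is the unique real neighbour of the labelled dummy.
    """

    id: str
    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    linkers: dict[int, tuple[int, int]] = field(default_factory=dict, compare=False)

    @classmethod
    def from_smiles(cls, frag_id: str, smiles: str) -> "Fragment":
        if any(c in smiles for c in _STEREO_CHARS):
            warnings.warn(
                f"fragment {frag_id!r}: stereochemistry in {smiles!r} is ignored",
                stacklevel=2,
            )
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SpaceError(f"fragment {frag_id!r}: cannot parse SMILES {smiles!r}")
        Chem.RemoveStereochemistry(mol)
        canonical_in = Chem.MolToSmiles(mol)
        # stereo-free round trip keeps write(read(s)) stable
        if any(c in smiles for c in _STEREO_CHARS):
            smiles = canonical_in
        frag = cls(id=frag_id, smiles=smiles, mol=mol)
        frag._index_dummies()
        return frag

    def _index_dummies(self) -> None:
        linkers: dict[int, tuple[int, int]] = {}
        for atom in self.mol.GetAtoms():
            if atom.GetAtomicNum() != 0:
                continue
            label = atom.GetAtomMapNum()
            real_nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() != 0]
            if label == 0:
                if real_nbrs:
                    raise SpaceError(
                        f"fragment {self.id!r}: unlabelled dummy atom with a real "
                        f"neighbour in {self.smiles!r}"
                    )
                continue
            if label in linkers:
                raise SpaceError(
                    f"fragment {self.id!r}: linker label {label} appears more than once"
                )
            if atom.GetDegree() == 0:
                # degenerate single-dummy connector: measurable but not assemblable
                linkers[label] = (-1, atom.GetIdx())
                continue
            if len(real_nbrs) != 1:
                raise SpaceError(
                    f"fragment {self.id!r}: dummy with label {label} must have exactly "
                    f"one real neighbour (found {len(real_nbrs)})"
                )
            linkers[label] = (real_nbrs[0].GetIdx(), atom.GetIdx())
        self.linkers = linkers

    @property
    def linker_labels(self) -> frozenset[int]:
        return frozenset(self.linkers)

    def attachment(self, label: int) -> int:
        """Index of the real atom bonded across the border for ``label``."""
        try:
            idx = self.linkers[label][0]
        except KeyError:
            raise SpaceError(f"fragment {self.id!r} has no linker label {label}") from None
        if idx < 0:
            raise SpaceError(
                f"fragment {self.id!r}: linker {label} has no attachment atom"
            )
        return idx

    def dummy_atoms(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() == 0]

    def ring_dummy_atoms(self) -> list[int]:
        return [
            a.GetIdx()
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetIsotope() != 0
        ]

    def num_heavy_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fragment):
            return NotImplemented
        return self.id == other.id and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash((self.id, self.smiles))


@dataclass
class TopologyNode:
    """A reactant slot: an ordered list of interchangeable fragments.

    Fragment order is part of the space definition; it fixes which example
    molecule represents a histogram bin.
    """

    id: str
    fragments: list[Fragment]

    def validate(self) -> None:
        if not self.fragments:
            raise SpaceError(f"node {self.id!r} has no fragments")
        labels = self.fragments[0].linker_labels
        for frag in self.fragments[1:]:
            if frag.linker_labels != labels:
                raise SpaceError(
                    f"node {self.id!r}: fragment {frag.id!r} exposes linker labels "
                    f"{sorted(frag.linker_labels)} but {self.fragments[0].id!r} "
                    f"exposes {sorted(labels)}"
                )

    @property
    def linker_labels(self) -> frozenset[int]:
        return self.fragments[0].linker_labels


@dataclass
class TopologyEdge:
    """Bonds formed between the fragments of two nodes.

    Each connection ``(label_a, label_b, order)`` forms one bond between the
    attachment atoms for those labels.  Several connections on one edge close
    a ring across the border.
    """

    node_a: str
    node_b: str
    connections: list[tuple[int, int, str]]

    def validate(self) -> None:
        if not self.connections:
            raise SpaceError(f"edge {self.node_a!r}-{self.node_b!r} has no connections")
        if self.node_a == self.node_b:
            raise SpaceError(f"edge {self.node_a!r}-{self.node_b!r} is a self loop")
        for la, lb, order in self.connections:
            if order not in BOND_ORDERS:
                raise SpaceError(
                    f"edge {self.node_a!r}-{self.node_b!r}: unknown bond order {order!r}"
                )


@dataclass
class TopologyGraph:
    id: str
    nodes: list[TopologyNode]
    edges: list[TopologyEdge]

    def validate(self) -> None:
        if not self.nodes:
            raise SpaceError(f"graph {self.id!r} has no nodes")
        node_ids = [n.id for n in self.nodes]
        if len(set(node_ids)) != len(node_ids):
            raise SpaceError(f"graph {self.id!r} has duplicate node ids")
        for node in self.nodes:
            node.validate()
        known = set(node_ids)
        used: dict[str, list[int]] = {nid: [] for nid in node_ids}
        for edge in self.edges:
            edge.validate()
            for nid in (edge.node_a, edge.node_b):
                if nid not in known:
                    raise SpaceError(f"graph {self.id!r}: edge references unknown node {nid!r}")
            for la, lb, _ in edge.connections:
                used[edge.node_a].append(la)
                used[edge.node_b].append(lb)
        for node in self.nodes:
            declared = sorted(node.linker_labels)
            consumed = sorted(used[node.id])
            if declared != consumed:
                raise SpaceError(
                    f"graph {self.id!r}, node {node.id!r}: fragments declare linker "
                    f"labels {declared} but edges use {consumed}"
                )
        if len(self.nodes) > 1:
            g = nx.Graph()
            g.add_nodes_from(node_ids)
            g.add_edges_from((e.node_a, e.node_b) for e in self.edges)
            if not nx.is_connected(g):
                raise SpaceError(f"graph {self.id!r} is not connected")

    def node(self, node_id: str) -> TopologyNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise SpaceError(f"graph {self.id!r} has no node {node_id!r}")

    def size(self) -> int:
        total = 1
        for node in self.nodes:
            total *= len(node.fragments)
        return total

    def topology(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.id for n in self.nodes)
        g.add_edges_from((e.node_a, e.node_b) for e in self.edges)
        return g


@dataclass
class FragmentSpace:
    name: str
    graphs: list[TopologyGraph]

    def validate(self) -> None:
        if not self.graphs:
            raise SpaceError("space has no topology graphs")
        gids = [g.id for g in self.graphs]
        if len(set(gids)) != len(gids):
            raise SpaceError("space has duplicate graph ids")
        seen: dict[str, str] = {}
        for graph in self.graphs:
            graph.validate()
            for node in graph.nodes:
                for frag in node.fragments:
                    prev = seen.setdefault(frag.id, frag.smiles)
                    if prev != frag.smiles:
                        raise SpaceError(
                            f"fragment id {frag.id!r} maps to two different structures "
                            f"({prev!r} vs {frag.smiles!r}); ids must be stable"
                        )

    def graph(self, graph_id: str) -> TopologyGraph:
        for g in self.graphs:
            if g.id == graph_id:
                return g
        raise SpaceError(f"space has no graph {graph_id!r}")


def space_size(space: FragmentSpace) -> int:
    """Number of encoded products: sum over graphs of the node-size product.

    Exact integer arithmetic; two fragment choices that happen to build the
    same structure count twice (combination semantics).
    """
    return sum(g.size() for g in space.graphs)


# ---------------------------------------------------------------------------
# JSON I/O


def space_from_dict(data: Mapping, name: str = "space") -> FragmentSpace:
    graphs = []
    for gdata in data.get("graphs", []):
        nodes = []
        for ndata in gdata.get("nodes", []):
            frags = [
                Fragment.from_smiles(f["id"], f["smiles"]) for f in ndata.get("fragments", [])
            ]
            nodes.append(TopologyNode(id=ndata["id"], fragments=frags))
        edges = [
            TopologyEdge(
                node_a=edata["a"],
                node_b=edata["b"],
                connections=[(int(la), int(lb), order) for la, lb, order in edata["connections"]],
            )
            for edata in gdata.get("edges", [])
        ]
        graphs.append(TopologyGraph(id=gdata["id"], nodes=nodes, edges=edges))
    space = FragmentSpace(name=data.get("name", name), graphs=graphs)
    space.validate()
    return space


def space_to_dict(space: FragmentSpace) -> dict:
    return {
        "name": space.name,
        "graphs": [
            {
                "id": g.id,
                "nodes": [
                    {
                        "id": n.id,
                        "fragments": [{"id": f.id, "smiles": f.smiles} for f in n.fragments],
                    }
                    for n in g.nodes
                ],
                "edges": [
                    {"a": e.node_a, "b": e.node_b, "connections": [list(c) for c in e.connections]}
                    for e in g.edges
                ],
            }
            for g in space.graphs
        ],
    }


def read_space(path) -> FragmentSpace:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SpaceError(f"{path}: not valid JSON ({exc})") from exc
    return space_from_dict(data)


def write_space(space: FragmentSpace, path) -> None:
    with open(path, "w") as fh:
        json.dump(space_to_dict(space), fh, indent=1)
        fh.write("\n")


def write_examples(smiles: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for smi in smiles:
            fh.write(smi + "\n")


# ---------------------------------------------------------------------------
# Product assembly


@dataclass
class Product:
    """An assembled product with per-atom provenance.

    ``source[i]`` is ``(node_position, fragment_atom_idx)`` for product atom
    ``i``; the same information is mirrored in the atom properties
    ``srcNode`` / ``srcAtom``.
    """

    mol: Chem.Mol
    source: list[tuple[int, int]]

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def source_nodes(self, atom_indices: Iterable[int]) -> set[int]:
        return {self.source[i][0] for i in atom_indices}


def _resanitize(mol: Chem.Mol) -> Chem.Mol | None:
    """Sanitize a copy; return it, or None on a kekulization failure."""
    from rdkit import rdBase

    probe = Chem.Mol(mol)
    try:
        with rdBase.BlockLogs():
            Chem.SanitizeMol(probe)
    except (AtomKekulizeException, KekulizeException):
        return None
    return probe


def _kekulize_candidates(mol: Chem.Mol) -> list[int]:
    work = Chem.Mol(mol)
    work.UpdatePropertyCache(strict=False)
    out = []
    for atom in work.GetAtoms():
        if (
            atom.GetAtomicNum() == 7
            and atom.GetIsAromatic()
            and atom.GetFormalCharge() == 0
            and atom.GetTotalNumHs() == 0
            and atom.GetDegree() == 2
        ):
            out.append(atom.GetIdx())
    return out


def _localize_hydrogens(mol: Chem.Mol, depth: int = 3) -> Chem.Mol | None:
    """Pick one valid electron localization for the assembled molecule.

    Fragments are stored with minimal hydrogen counts, so an aromatic ring
    formed across a border may need one extra hydrogen on a ring nitrogen
    before it can kekulize.  Candidates are tried in atom-index order
    (deterministic), backtracking over up to ``depth`` added hydrogens.
    """
    done = _resanitize(mol)
    if done is not None:
        return done
    if depth == 0:
        return None
    for idx in _kekulize_candidates(mol):
        trial = Chem.Mol(mol)
        trial.GetAtomWithIdx(idx).SetNumExplicitHs(1)
        fixed = _localize_hydrogens(trial, depth - 1)
        if fixed is not None:
            return fixed
    return None


def assemble_product(
    graph: TopologyGraph, choice: Mapping[str, Fragment] | Sequence[Fragment]
) -> Product:
    """Combine one fragment per node into a full, sanitized molecule.

    All dummy atoms are deleted; for every edge connection one bond is formed
    between the two attachment atoms.  Bonds a ring dummy mirrored (its bonds
    to other dummies or to real atoms) are either re-formed as border bonds or
    already present as real bonds of the partner fragment, so plain deletion
    is loss-free.  Aromaticity is re-perceived and hydrogens re-localized on
    the assembled molecule.
    """
    if not isinstance(choice, Mapping):
        choice = {node.id: frag for node, frag in zip(graph.nodes, choice)}
    for node in graph.nodes:
        if node.id not in choice:
            raise AssemblyError(f"graph {graph.id!r}: no fragment chosen for node {node.id!r}")

    rw = Chem.RWMol()
    amap: dict[tuple[str, int], int] = {}
    source: list[tuple[int, int]] = []
    for pos, node in enumerate(graph.nodes):
        frag = choice[node.id]
        for atom in frag.mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            na = Chem.Atom(atom.GetAtomicNum())
            na.SetFormalCharge(atom.GetFormalCharge())
            na.SetIsAromatic(atom.GetIsAromatic())
            na.SetNumExplicitHs(atom.GetNumExplicitHs())
            na.SetIsotope(atom.GetIsotope())
            na.SetIntProp("srcNode", pos)
            na.SetIntProp("srcAtom", atom.GetIdx())
            amap[(node.id, atom.GetIdx())] = rw.AddAtom(na)
            source.append((pos, atom.GetIdx()))
        for bond in frag.mol.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
                continue
            rw.AddBond(amap[(node.id, a.GetIdx())], amap[(node.id, b.GetIdx())], bond.GetBondType())

    for edge in graph.edges:
        fa, fb = choice[edge.node_a], choice[edge.node_b]
        for la, lb, order in edge.connections:
            try:
                u = amap[(edge.node_a, fa.attachment(la))]
                v = amap[(edge.node_b, fb.attachment(lb))]
            except SpaceError as exc:
                raise AssemblyError(
                    f"graph {graph.id!r}: unresolved linker on edge "
                    f"{edge.node_a!r}-{edge.node_b!r}: {exc}"
                ) from exc
            if rw.GetBondBetweenAtoms(u, v) is None:
                rw.AddBond(u, v, BOND_ORDERS[order])

    raw = rw.GetMol()
    try:
        mol = _localize_hydrogens(raw)
    except AtomValenceException as exc:
        raise AssemblyError(
            f"graph {graph.id!r}: valence violation after assembly "
            f"({ {n.id: choice[n.id].id for n in graph.nodes} }): {exc}"
        ) from exc
    if mol is None:
        raise AssemblyError(
            f"graph {graph.id!r}: no valid electron localization found for "
            f"{ {n.id: choice[n.id].id for n in graph.nodes} }"
        )
    return Product(mol=mol, source=source)
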