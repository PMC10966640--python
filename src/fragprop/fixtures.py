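"""Deterministic fixture spaces and a randomized space generator.

The named fixtures mirror the situations the algorithm must get right:

* ``fig1_triazole_amide`` -- three nodes: a 1,2,4-triazole ring closure
  (one edge with two aromatic connections, ring dummies on both sides)
  followed by an amide coupling.
* ``fig3_triazole_halves`` / ``fig4_rxn301`` -- the two-node triazole ring
  closure alone; the assembled ring carries one more hydrogen than the
  fragments (the N-H of the azole), the edge case behind the TPSA and MW
  corrections, and the canonical crossing-pattern example.
* ``macrocycle_loop`` -- a cyclic three-node topology forming macrocycles;
  ring perception of the macro ring only exists at product level.
* ``amide_border`` -- amine x acid coupling with terminal, amide and plain
  C-C border cases for the rotatable-bond boundary descriptors.
* ``both_sites_pattern`` -- lactam and open-chain amide carriers, so that
  some products match a ring-constrained and a ring-forbidden variant of
  the amide pattern at two different sites.

Randomized spaces are built from a curated motif alphabet (amides, esters,
aromatic N-heterocycles, halides, nitriles, Michael acceptors, ...) rather
than uniform random graphs, guaranteeing boundary-case coverage.  The same
recipe and seed always produce a byte-identical space.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

from .properties.patterns import Query, parse_query_lines
from .space import (
    Fragment,
    FragmentSpace,
    TopologyEdge,
    TopologyGraph,
    TopologyNode,
)

__all__ = [
    "FIXTURE_NAMES",
    "make_fixture",
    "SpaceRecipe",
    "make_random_space",
    "make_scale_space",
    "demo_queries",
    "demo_query_lines",
]


def _node(node_id: str, smiles_list: list[str], prefix: str) -> TopologyNode:
    frags = [
        Fragment.from_smiles(f"{prefix}{node_id}_{i:02d}", smi)
        for i, smi in enumerate(smiles_list)
    ]
    return TopologyNode(id=node_id, fragments=frags)


# -- triazole ring-closure halves -------------------------------------------
# A side contributes C-N-N of the ring (labels 1, 2 on the aromatic edge),
# B side contributes N-C; both carry ring dummies completing the aromatic
# ring, written with minimal hydrogens (no N-H at fragment level).

def _tria_a(sub: str) -> str:
    return f"{sub}c1nn:[1*:2]:[1*:1]:1"


def _tria_b(sub: str) -> str:
    return f"{sub}c1n:[1*:1]:[1*]:[1*:2]:1"


_TRIA_EDGE = [(1, 1, "aromatic"), (2, 2, "aromatic")]


def _fig3() -> FragmentSpace:
    node_a = _node("A", [_tria_a(s) for s in ("C", "CC", "CCC", "CC(C)C")], "fig3_")
    node_b = _node("B", [_tria_b(s) for s in ("C", "CC", "OC")], "fig3_")
    graph = TopologyGraph(
        id="g1",
        nodes=[node_a, node_b],
        edges=[TopologyEdge("A", "B", list(_TRIA_EDGE))],
    )
    return FragmentSpace(name="fig3_triazole_halves", graphs=[graph])


def _fig4() -> FragmentSpace:
    node_a = _node("A", [_tria_a(s) for s in ("C", "CC", "N#CC")], "fig4_")
    node_b = _node("B", [_tria_b(s) for s in ("C", "OC", "CCC")], "fig4_")
    graph = TopologyGraph(
        id="g1",
        nodes=[node_a, node_b],
        edges=[TopologyEdge("A", "B", list(_TRIA_EDGE))],
    )
    return FragmentSpace(name="fig4_rxn301", graphs=[graph])


def _fig1() -> FragmentSpace:
    node_a = _node("A", [_tria_a(s) for s in ("C", "CC", "CCO")], "fig1_")
    node_b = _node(
        "B",
        [f"[*:3]{t}c1n:[1*:1]:[1*]:[1*:2]:1" for t in ("NC", "NCC", "N(C)C")],
        "fig1_",
    )
    node_c = _node(
        "C",
        ["CC(=O)[*:4]", "CCC(=O)[*:4]", "O=C([*:4])c1ccccc1", "O=C([*:4])C1CC1"],
        "fig1_",
    )
    graph = TopologyGraph(
        id="g1",
        nodes=[node_a, node_b, node_c],
        edges=[
            TopologyEdge("A", "B", list(_TRIA_EDGE)),
            TopologyEdge("B", "C", [(3, 4, "single")]),
        ],
    )
    return FragmentSpace(name="fig1_triazole_amide", graphs=[graph])


def _macrocycle() -> FragmentSpace:
    n1 = _node("M1", ["[*:1]CC[*:2]", "[*:1]CCC[*:2]", "[*:1]CC(C)[*:2]"], "mac_")
    n2 = _node("M2", ["[*:1]CNC(=O)C[*:2]", "[*:1]COC[*:2]", "[*:1]CN(C)C[*:2]"], "mac_")
    n3 = _node("M3", ["[*:1]CCOC[*:2]", "[*:1]CCCC[*:2]", "[*:1]CC(=O)NC[*:2]"], "mac_")
    graph = TopologyGraph(
        id="g1",
        nodes=[n1, n2, n3],
        edges=[
            TopologyEdge("M1", "M2", [(2, 1, "single")]),
            TopologyEdge("M2", "M3", [(2, 1, "single")]),
            TopologyEdge("M3", "M1", [(2, 1, "single")]),
        ],
    )
    return FragmentSpace(name="macrocycle_loop", graphs=[graph])


def _amide_border() -> FragmentSpace:
    amines = ["CN[*:1]", "CCN[*:1]", "CN(C)[*:1]", "C[*:1]", "CC[*:1]", "c1ccc(N[*:1])cc1"]
    acids = ["CC(=O)[*:2]", "CCC(=O)[*:2]", "O=C([*:2])c1ccccc1", "CC[*:2]", "OC[*:2]", "C[*:2]"]
    graph = TopologyGraph(
        id="g1",
        nodes=[_node("N", amines, "amb_"), _node("C", acids, "amb_")],
        edges=[TopologyEdge("N", "C", [(1, 2, "single")])],
    )
    return FragmentSpace(name="amide_border", graphs=[graph])


def _both_sites() -> FragmentSpace:
    left = ["O=C1CCCN1C[*:1]", "CCC[*:1]", "c1ccccc1C[*:1]"]
    right = ["CC(=O)NC[*:2]", "CC[*:2]", "OCC[*:2]"]
    graph = TopologyGraph(
        id="g1",
        nodes=[_node("L", left, "bsp_"), _node("R", right, "bsp_")],
        edges=[TopologyEdge("L", "R", [(1, 2, "single")])],
    )
    return FragmentSpace(name="both_sites_pattern", graphs=[graph])


_FIXTURES = {
    "fig1_triazole_amide": _fig1,
    "fig3_triazole_halves": _fig3,
    "fig4_rxn301": _fig4,
    "macrocycle_loop": _macrocycle,
    "amide_border": _amide_border,
    "both_sites_pattern": _both_sites,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str) -> FragmentSpace:
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}") from None
    return builder()


# ---------------------------------------------------------------------------
# Randomized spaces

# Template alphabet.  ``{l}``/``{l1}``/``{l2}`` take linker labels, ``{r}``
# an optional alkyl decoration.  Tags: "plain", "polar", "warhead".
_END_TEMPLATES: list[tuple[str, str]] = [
    ("C{r}[*:{l}]", "plain"),
    ("CC{r}[*:{l}]", "plain"),
    ("CC(C){r}[*:{l}]", "plain"),
    ("OC{r}[*:{l}]", "polar"),
    ("COC{r}[*:{l}]", "polar"),
    ("CN[*:{l}]", "polar"),
    ("CCN[*:{l}]", "polar"),
    ("CN(C)[*:{l}]", "polar"),
    ("CC(=O)[*:{l}]", "polar"),
    ("CCC(=O)[*:{l}]", "polar"),
    ("O=C([*:{l}])c1ccccc1", "polar"),
    ("NC(=O)C{r}[*:{l}]", "polar"),
    ("CC(=O)N(C)[*:{l}]", "polar"),
    ("CC(=O)OC{r}[*:{l}]", "polar"),
    ("c1cc([*:{l}])ccn1", "polar"),
    ("Cn1nc(C[*:{l}])nc1", "polar"),
    ("N#CC{r}[*:{l}]", "warhead"),
    ("C=CC(=O)NC{r}[*:{l}]", "warhead"),
    ("C=CC(=O)[*:{l}]", "warhead"),
    ("Fc1ccc([*:{l}])cc1", "warhead"),
    ("ClCC(=O)NC[*:{l}]", "warhead"),
    ("C1OC1C[*:{l}]", "warhead"),
    ("O=CCC{r}[*:{l}]", "warhead"),
    ("CS(=O)(=O)C{r}[*:{l}]", "warhead"),
]

_MID_TEMPLATES: list[tuple[str, str]] = [
    ("[*:{l1}]C{r}C[*:{l2}]", "plain"),
    ("[*:{l1}]CC{r}C[*:{l2}]", "plain"),
    ("[*:{l1}]CC(F)(F)C[*:{l2}]", "plain"),
    ("[*:{l1}]c1ccc([*:{l2}])cc1", "plain"),
    ("[*:{l1}]Cc1ccc(C[*:{l2}])cc1", "plain"),
    ("[*:{l1}]COC{r}[*:{l2}]", "polar"),
    ("[*:{l1}]CN(C)C{r}[*:{l2}]", "polar"),
    ("[*:{l1}]NC(=O)C{r}[*:{l2}]", "polar"),
    ("[*:{l1}]CC(=O)N(C)C[*:{l2}]", "polar"),
    ("[*:{l1}]CC(=O)[*:{l2}]", "polar"),
    ("[*:{l1}]C(=O)N(C{r}[*:{l2}])C", "polar"),
    ("[*:{l1}]CSC{r}[*:{l2}]", "polar"),
    ("[*:{l1}]Cc1ccnc(C[*:{l2}])c1", "polar"),
]

_TRIA_A_SUBS = [
    "C", "CC", "CCC", "CCO", "N#CC", "CC(C)C", "OC",
    "CN(C)C", "COC", "CCCC", "OCC", "CCCCC",
]
_TRIA_B_SUBS = [
    "C", "CC", "OC", "CCC", "N#CC",
    "CN(C)C", "CCCC", "COC", "OCC", "N#CCC", "CCO",
]
_TRIA_B_TAILS = ["NC", "NCC", "N(C)C", "OC", "CC", "NCCC", "N(CC)C", "OCC"]
_DECORATIONS = ["", "C", "CC", "C(C)"]


@dataclass(frozen=True)
class SpaceRecipe:
    """Deterministic description of a randomized space."""

    seed: int
    n_graphs: int = 1
    min_nodes: int = 2
    max_nodes: int = 3
    min_frags: int = 3
    max_frags: int = 6
    ring_closure_p: float = 0.0
    cyclic_p: float = 0.0
    polar_weight: float = 1.0
    warhead_weight: float = 1.0


def _weight(tag: str, recipe: SpaceRecipe) -> float:
    if tag == "polar":
        return recipe.polar_weight
    if tag == "warhead":
        return recipe.warhead_weight
    return 1.0


def _sample_templates(
    templates: list[tuple[str, str]], count: int, rng: random.Random, recipe: SpaceRecipe
) -> list[str]:
    weights = [_weight(tag, recipe) for _, tag in templates]
    out: list[str] = []
    seen: set[str] = set()
    for _ in range(count * 4):
        if len(out) >= count:
            break
        template = rng.choices([t for t, _ in templates], weights=weights)[0]
        smi = template.format(
            l=1, l1=1, l2=2, r=rng.choice(_DECORATIONS) if "{r}" in template else ""
        )
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


def _frag_node(node_id: str, smiles_list: list[str]) -> TopologyNode:
    # ids derive from the structure, so the same synthon reused anywhere in
    # the space carries the same id (what the IPC cache keys on)
    frags = [
        Fragment.from_smiles("f" + hashlib.md5(smi.encode()).hexdigest()[:10], smi)
        for smi in smiles_list
    ]
    return TopologyNode(id=node_id, fragments=frags)


def make_random_space(recipe: SpaceRecipe) -> FragmentSpace:
    rng = random.Random(recipe.seed)
    graphs = []
    for gi in range(recipe.n_graphs):
        k = rng.randint(recipe.min_nodes, recipe.max_nodes)
        cyclic = k >= 3 and rng.random() < recipe.cyclic_p
        ring_closure = not cyclic and rng.random() < recipe.ring_closure_p
        nodes: list[TopologyNode] = []
        edges: list[TopologyEdge] = []
        counts = [rng.randint(recipe.min_frags, recipe.max_frags) for _ in range(k)]
        names = [f"n{i}" for i in range(k)]
        if cyclic:
            for i in range(k):
                smis = _sample_templates(_MID_TEMPLATES, counts[i], rng, recipe)
                nodes.append(_frag_node(names[i], smis))
                edges.append(TopologyEdge(names[i], names[(i + 1) % k], [(2, 1, "single")]))
        else:
            right_label = []  # label each node exposes towards its right edge
            for i in range(k):
                if ring_closure and i == 0:
                    subs = rng.sample(_TRIA_A_SUBS, min(counts[i], len(_TRIA_A_SUBS)))
                    smis = sorted(_tria_a(s) for s in subs)
                    right_label.append(None)
                elif ring_closure and i == 1:
                    if k > 2:
                        tails = rng.sample(
                            _TRIA_B_TAILS, min(counts[i], len(_TRIA_B_TAILS))
                        )
                        smis = sorted(
                            f"[*:3]{t}c1n:[1*:1]:[1*]:[1*:2]:1" for t in tails
                        )
                        right_label.append(3)
                    else:
                        subs = rng.sample(
                            _TRIA_B_SUBS, min(counts[i], len(_TRIA_B_SUBS))
                        )
                        smis = sorted(_tria_b(s) for s in subs)
                        right_label.append(None)
                else:
                    interior = 0 < i < k - 1
                    templates = _MID_TEMPLATES if interior else _END_TEMPLATES
                    smis = _sample_templates(templates, counts[i], rng, recipe)
                    right_label.append(2 if interior else 1)
                nodes.append(_frag_node(names[i], smis))
            for i in range(k - 1):
                if ring_closure and i == 0:
                    edges.append(TopologyEdge(names[0], names[1], list(_TRIA_EDGE)))
                else:
                    edges.append(
                        TopologyEdge(names[i], names[i + 1], [(right_label[i], 1, "single")])
                    )
        graphs.append(TopologyGraph(id=f"g{gi}", nodes=nodes, edges=edges))
    space = FragmentSpace(name=f"random_{recipe.seed}", graphs=graphs)
    space.validate()
    return space


def make_scale_space(frags_per_node: int = 1000, n_nodes: int = 3) -> FragmentSpace:
    """A large linear space (frags_per_node ** n_nodes products) for
    demonstrating enumeration-free computation; never enumerated."""
    bases_end = [
        "C{c}[*:1]",
        "OC{c}[*:1]",
        "NC(=O)C{c}[*:1]",
        "N#CC{c}[*:1]",
        "CC(=O)OC{c}[*:1]",
        "CN(C)C{c}[*:1]",
        "O=CC{c}[*:1]",
        "c1cc(C{c}[*:1])ccn1",
        "Fc1ccc(C{c}[*:1])cc1",
        "CS(=O)(=O)C{c}[*:1]",
    ]
    bases_mid = [
        "[*:1]CC{c}C[*:2]",
        "[*:1]COC{c}C[*:2]",
        "[*:1]CNC(=O)C{c}C[*:2]",
        "[*:1]Cc1ccc(C{c}C[*:2])cc1",
        "[*:1]CN(C)C{c}C[*:2]",
    ]

    def build(bases: list[str], node_id: str) -> TopologyNode:
        frags = []
        i = 0
        while len(frags) < frags_per_node:
            base = bases[i % len(bases)]
            chain = "C" * (i // len(bases))
            frags.append(Fragment.from_smiles(f"{node_id}_{i:05d}", base.format(c=chain)))
            i += 1
        return TopologyNode(id=node_id, fragments=frags)

    nodes = [build(bases_end, "n0")]
    for j in range(1, n_nodes - 1):
        nodes.append(build(bases_mid, f"n{j}"))
    nodes.append(build(bases_end, f"n{n_nodes - 1}"))
    edges = []
    for i in range(n_nodes - 1):
        la = 1 if i == 0 else 2
        edges.append(TopologyEdge(f"n{i}", f"n{i + 1}", [(la, 1, "single")]))
    space = FragmentSpace(name="scale_demo", graphs=[TopologyGraph("g0", nodes, edges)])
    space.validate()
    return space


def validation_recipes(base_seed: int = 0) -> list[SpaceRecipe]:
    """Twenty seeded recipes spanning roughly 10^2 to a few 10^4 products,
    mixing plain couplings, triazole ring closures and cyclic topologies."""
    recipes: list[SpaceRecipe] = []
    for i in range(10):
        recipes.append(
            SpaceRecipe(
                seed=base_seed + i + 1,
                min_nodes=2,
                max_nodes=3,
                min_frags=10,
                max_frags=12,
                ring_closure_p=0.4,
                cyclic_p=0.25,
                polar_weight=1.3,
                warhead_weight=1.2,
            )
        )
    for i in range(4):
        recipes.append(
            SpaceRecipe(
                seed=base_seed + 11 + i,
                min_nodes=3,
                max_nodes=3,
                min_frags=12,
                max_frags=16,
                ring_closure_p=0.5,
                cyclic_p=0.3,
                polar_weight=1.5,
                warhead_weight=1.0,
            )
        )
    for i in range(3):
        recipes.append(
            SpaceRecipe(
                seed=base_seed + 15 + i,
                min_nodes=2,
                max_nodes=2,
                min_frags=25,
                max_frags=35,
                ring_closure_p=0.3,
                warhead_weight=1.5,
            )
        )
    for i in range(2):
        recipes.append(
            SpaceRecipe(
                seed=base_seed + 18 + i,
                min_nodes=3,
                max_nodes=3,
                min_frags=20,
                max_frags=26,
                cyclic_p=0.3,
                polar_weight=1.2,
            )
        )
    recipes.append(
        SpaceRecipe(
            seed=base_seed + 20,
            min_nodes=3,
            max_nodes=3,
            min_frags=30,
            max_frags=34,
            polar_weight=1.4,
            warhead_weight=1.3,
        )
    )
    return recipes


# ---------------------------------------------------------------------------
# Query demo set

#: Small curated demo set of electrophilic-warhead-style SMARTS (synthetic
#: demo list assembled for this package; not a published warhead collection).
_DEMO_QUERY_LINES = [
    "C=CC(=O)N\tunsat_amide",
    "C=CC=O\tunsat_ketone",
    "C#N\tnitrile",
    "Fc1ccccc1\tfluorobenzene",
    "ClCC(=O)N\tchloroacetamide",
    "C1OC1\tepoxide",
    "[CX3H1]=O\taldehyde",
    "C=CS(=O)(=O)\tvinyl_sulfone",
    "[SX4](=O)(=O)\tsulfonyl",
    "C(=O)OC\tester",
    "c1nncn1\ttriazole",
    "C=CC#N\tacrylonitrile",
]


def demo_query_lines() -> list[str]:
    return list(_DEMO_QUERY_LINES)


def demo_queries() -> list[Query]:
    return parse_query_lines(_DEMO_QUERY_LINES)
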