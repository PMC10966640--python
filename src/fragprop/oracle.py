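"""Brute-force enumeration oracle.

Validation surface for the decomposition engine: enumerate every fragment
combination of a (small) space, assemble the product, measure the property
*directly* on the full molecule, and histogram the results.  The direct
measurements never touch the plugins' IPC/EPC machinery:

* TPSA / molecular weight: RDKit whole-molecule descriptors;
* rotatable bonds: candidate single bonds filtered with a SMARTS-based
  amide exclusion;
* patterns: plain substructure matching of each query on the product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Callable

from rdkit import Chem
from rdkit.Chem import Descriptors

from .properties.base import round_scaled
from .space import FragmentSpace, assemble_product, space_size

__all__ = [
    "OracleReport",
    "enumerate_histogram",
    "compare",
    "direct_tpsa",
    "direct_molwt",
    "direct_heavy_atoms",
    "direct_rotatable_bonds",
    "direct_pattern_set",
    "direct_measure",
]

DEFAULT_CAP = 100_000

_AMIDE_QUERY = Chem.MolFromSmarts("[#6](=[OX1D1])-[#7;!a;!D1]")


def direct_tpsa(mol: Chem.Mol, include_s_and_p: bool = False) -> int:
    return round(Descriptors.TPSA(mol, includeSandP=include_s_and_p) * 100)


def direct_molwt(mol: Chem.Mol) -> int:
    return round(Descriptors.MolWt(mol) * 1000)


def direct_heavy_atoms(mol: Chem.Mol) -> int:
    return mol.GetNumHeavyAtoms()


def direct_rotatable_bonds(mol: Chem.Mol) -> int:
    """Single, non-ring, non-terminal bonds minus C-N amide bonds."""
    amide_bonds = set()
    for c_idx, _o, n_idx in mol.GetSubstructMatches(_AMIDE_QUERY):
        amide_bonds.add(frozenset((c_idx, n_idx)))
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() <= 1 or b.GetDegree() <= 1:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_bonds:
            continue
        count += 1
    return count


def direct_pattern_set(mol: Chem.Mol, query_mols: list[Chem.Mol]) -> int:
    value = 0
    for qi, qmol in enumerate(query_mols):
        if mol.HasSubstructMatch(qmol):
            value |= 1 << qi
    return value


def direct_measure(property_name: str, **kwargs) -> Callable[[Chem.Mol], Any]:
    """Direct per-product measurement function for a property name."""
    if property_name == "tpsa":
        include = kwargs.get("include_s_and_p", False)
        return lambda mol: direct_tpsa(mol, include)
    if property_name == "mw":
        return direct_molwt
    if property_name == "heavyatoms":
        return direct_heavy_atoms
    if property_name == "rotbonds":
        return direct_rotatable_bonds
    if property_name == "patterns":
        queries = kwargs["queries"]
        query_mols = [q.mol for q in queries]
        return lambda mol: direct_pattern_set(mol, query_mols)
    raise ValueError(f"no direct measurement for property {property_name!r}")


def enumerate_histogram(
    space: FragmentSpace,
    measure: Callable[[Chem.Mol], Any],
    cap: int = DEFAULT_CAP,
    precision: int | None = None,
    scale: int = 1,
) -> dict[Any, int]:
    """Assemble and measure every product; exact value -> count histogram."""
    n = space_size(space)
    if n > cap:
        raise ValueError(f"space encodes {n} products, above the enumeration cap {cap}")
    hist: dict[Any, int] = {}
    for graph in space.graphs:
        for combo in itertools.product(*(node.fragments for node in graph.nodes)):
            product = assemble_product(graph, combo)
            value = measure(product.mol)
            if precision is not None:
                value = round_scaled(value, scale, precision)
            hist[value] = hist.get(value, 0) + 1
    return hist


def enumerate_histograms(
    space: FragmentSpace,
    measures: dict[str, Callable[[Chem.Mol], Any]],
    cap: int = DEFAULT_CAP,
) -> dict[str, dict[Any, int]]:
    """Like :func:`enumerate_histogram` for several measures, assembling each
    product only once."""
    n = space_size(space)
    if n > cap:
        raise ValueError(f"space encodes {n} products, above the enumeration cap {cap}")
    hists: dict[str, dict[Any, int]] = {name: {} for name in measures}
    for graph in space.graphs:
        for combo in itertools.product(*(node.fragments for node in graph.nodes)):
            mol = assemble_product(graph, combo).mol
            for name, measure in measures.items():
                value = measure(mol)
                hists[name][value] = hists[name].get(value, 0) + 1
    return hists


@dataclass
class OracleReport:
    match: bool
    first_divergence: Any = None
    detail: str = ""

    def __bool__(self) -> bool:
        return self.match


def compare(
    engine_counts: dict[Any, int],
    oracle_counts: dict[Any, int],
    value_tolerance: int = 0,
) -> OracleReport:
    """Exact count comparison; numeric keys may differ by ``value_tolerance``
    scaled units (0 for integer properties, 1 centi-Å² for TPSA)."""
    if engine_counts == oracle_counts:
        return OracleReport(match=True)
    if value_tolerance:
        remaining = dict(oracle_counts)
        for value, count in sorted(engine_counts.items()):
            hit = None
            for cand in sorted(remaining):
                if isinstance(cand, int) and abs(cand - value) <= value_tolerance:
                    if remaining[cand] == count:
                        hit = cand
                        break
            if hit is None:
                return OracleReport(
                    match=False,
                    first_divergence=value,
                    detail=f"value {value}: engine count {count} has no oracle match",
                )
            del remaining[hit]
        if remaining:
            value = sorted(remaining)[0]
            return OracleReport(
                match=False,
                first_divergence=value,
                detail=f"value {value}: oracle count {remaining[value]} unmatched",
            )
        return OracleReport(match=True)
    for value in sorted(set(engine_counts) | set(oracle_counts), key=repr):
        ec = engine_counts.get(value, 0)
        oc = oracle_counts.get(value, 0)
        if ec != oc:
            return OracleReport(
                match=False,
                first_divergence=value,
                detail=f"value {value}: engine count {ec} != oracle count {oc}",
            )
    return OracleReport(match=True)
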