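"""Rotatable-bond plugin (Veber definition).

A rotatable bond is any single bond that is neither part of a ring, nor
terminal, nor a C-N amide bond (carbon bearing a double-bonded terminal
oxygen, nitrogen non-aromatic and non-terminal).  Because every dummy atom
is replaced by exactly one real atom on assembly, an atom's heavy degree --
counting dummies -- is the same in fragment and product, so terminality and
aromaticity are decidable at fragment level.

The fragment IPC counts every internal bond whose status is locally
decidable.  Excluded (settled by the EPC instead) are:

* bonds incident to a dummy atom (border bonds);
* internal N-C single bonds whose carbon has a double bond to a linker: the
  bond is rotatable unless the partner turns the linker into a terminal
  oxygen (i.e. the bond becomes an amide);
* bonds on a path between two attachment atoms that the topology connects
  externally (``NodeContext.cycle_pairs``): such bonds lie on a macrocycle
  in every product and are never rotatable.

The boundary information records, per outgoing connection, a descriptor of
the linker-adjacent atom: terminality plus the five amide-relevant cases
(non-terminal aliphatic N; acyl carbon; carbon with single+double bond to
two linkers; terminal oxygen double-bonded to the linker; carbon
double-bonded to the linker carrying single bonds to non-terminal aliphatic
nitrogens -- stored as a count, since each such nitrogen contributes one
undecidable bond).  Fragments with equal descriptors are interchangeable
without changing the EPC.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

from ..space import Fragment
from .base import NodeContext, NumericPlugin

__all__ = ["RotatableBondsPlugin", "is_rotatable", "count_rotatable"]


def _is_terminal(atom: Chem.Atom) -> bool:
    """Heavy-atom degree 1, counting dummy atoms."""
    return atom.GetDegree() <= 1


def _has_terminal_double_oxygen(atom: Chem.Atom) -> bool:
    mol = atom.GetOwningMol()
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() != 8 or nbr.GetDegree() != 1:
            continue
        bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def _is_amide(begin: Chem.Atom, end: Chem.Atom) -> bool:
    for c, n in ((begin, end), (end, begin)):
        if (
            c.GetAtomicNum() == 6
            and n.GetAtomicNum() == 7
            and not n.GetIsAromatic()
            and not _is_terminal(n)
            and _has_terminal_double_oxygen(c)
        ):
            return True
    return False


def is_rotatable(mol: Chem.Mol, bond: Chem.Bond) -> bool:
    """Veber rotatability of one bond in a full molecule."""
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if _is_terminal(a) or _is_terminal(b):
        return False
    return not _is_amide(a, b)


def count_rotatable(mol: Chem.Mol) -> int:
    return sum(1 for bond in mol.GetBonds() if is_rotatable(mol, bond))


def _external_ring_bonds(fragment: Fragment, ctx: NodeContext) -> set[int]:
    """Bond indices that lie on a macrocycle closed through the topology.

    For each externally connected pair of linker labels, a bond belongs to
    some simple path between the two attachment atoms iff, after adding a
    virtual edge between them, it shares a biconnected component with that
    edge.  All such bonds are ring bonds in every product.
    """
    if not ctx.cycle_pairs:
        return set()
    mol = fragment.mol
    out: set[int] = set()
    base = nx.Graph()
    base.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    for bond in mol.GetBonds():
        base.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), idx=bond.GetIdx())
    for la, lb in ctx.cycle_pairs:
        u, v = fragment.attachment(la), fragment.attachment(lb)
        g = base.copy()
        virtual = not g.has_edge(u, v)
        if virtual:
            g.add_edge(u, v, idx=-1)
        for comp in nx.biconnected_component_edges(g):
            comp = list(comp)
            if any({x, y} == {u, v} for x, y in comp):
                for x, y in comp:
                    idx = g.edges[x, y]["idx"]
                    if idx >= 0:
                        out.add(idx)
    return out


def _double_bond_dummies(atom: Chem.Atom) -> list[Chem.Atom]:
    mol = atom.GetOwningMol()
    out = []
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() != 0:
            continue
        bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            out.append(nbr)
    return out


def _amide_sensitive_nitrogens(carbon: Chem.Atom) -> int:
    """Single-bonded non-terminal aliphatic N neighbours of a carbon."""
    mol = carbon.GetOwningMol()
    count = 0
    for nbr in carbon.GetNeighbors():
        if nbr.GetAtomicNum() != 7 or nbr.GetIsAromatic() or _is_terminal(nbr):
            continue
        bond = mol.GetBondBetweenAtoms(carbon.GetIdx(), nbr.GetIdx())
        if bond.GetBondType() == Chem.BondType.SINGLE:
            count += 1
    return count


class RotatableBondsPlugin(NumericPlugin):
    name = "rotbonds"
    scale = 1
    context_free = False

    def measure(self, mol: Chem.Mol) -> int:
        return count_rotatable(mol)

    def fragment_ipc_boundary(self, fragment: Fragment, ctx: NodeContext):
        mol = fragment.mol
        macro_ring = _external_ring_bonds(fragment, ctx)
        ipc = 0
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
                continue  # border bond: EPC territory
            if bond.GetIdx() in macro_ring:
                continue  # in a topology-closed ring in every product
            if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                continue
            if _is_terminal(a) or _is_terminal(b):
                continue
            if _is_amide(a, b):
                continue
            # N-C single bond whose C is double-bonded to a linker: amide-ness
            # depends on the partner fragment
            undecidable = False
            for c, n in ((a, b), (b, a)):
                if (
                    c.GetAtomicNum() == 6
                    and n.GetAtomicNum() == 7
                    and not n.GetIsAromatic()
                    and not _is_terminal(n)
                    and _double_bond_dummies(c)
                ):
                    undecidable = True
            if not undecidable:
                ipc += 1
        return ipc, self._boundary(fragment)

    @staticmethod
    def _boundary(fragment: Fragment) -> tuple:
        mol = fragment.mol
        descriptors = []
        for label in sorted(fragment.linker_labels):
            attach_idx, dummy_idx = fragment.linkers[label]
            atom = mol.GetAtomWithIdx(attach_idx)
            bond = mol.GetBondBetweenAtoms(attach_idx, dummy_idx)
            single = bond.GetBondType() == Chem.BondType.SINGLE
            double = bond.GetBondType() == Chem.BondType.DOUBLE
            aliphatic = not atom.GetIsAromatic()
            n_dummy_singles = sum(
                1
                for nbr in atom.GetNeighbors()
                if nbr.GetAtomicNum() == 0
                and mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx()).GetBondType()
                == Chem.BondType.SINGLE
            )
            descriptor = (
                label,
                _is_terminal(atom),
                # 1: non-terminal aliphatic N, single bond to the linker
                atom.GetAtomicNum() == 7 and aliphatic and not _is_terminal(atom) and single,
                # 2: aliphatic C, double bond to terminal O, single bond to linker
                atom.GetAtomicNum() == 6
                and aliphatic
                and single
                and _has_terminal_double_oxygen(atom),
                # 3: aliphatic C with a single and a double bond to two linkers
                atom.GetAtomicNum() == 6
                and aliphatic
                and bool(_double_bond_dummies(atom))
                and n_dummy_singles >= 1,
                # 4: terminal O, double bond to the linker
                atom.GetAtomicNum() == 8 and _is_terminal(atom) and double,
                # 5: aliphatic C double-bonded to the linker; count of
                # single-bonded non-terminal aliphatic N neighbours
                (
                    _amide_sensitive_nitrogens(atom)
                    if atom.GetAtomicNum() == 6 and aliphatic and double
                    else 0
                ),
            )
            descriptors.append(descriptor)
        return tuple(descriptors)
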