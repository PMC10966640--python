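"""Aromatic ring-system detection shared by the hydrogen-sensitive plugins.

An aromatic ring system is the union of fused aromatic rings (rings sharing
at least one bond).  A system that contains both a nitrogen atom and a dummy
atom spans a fragment border and its electron localization — hence hydrogen
count — is only fixed once the product is assembled.  Plugins whose value
depends on hydrogens (TPSA, molecular weight) exclude the atoms of such
systems from the fragment IPC and identify the system in the boundary
information instead.
"""

from __future__ import annotations

from rdkit import Chem

from ..space import Fragment

__all__ = ["aromatic_ring_systems", "excluded_systems", "system_identifier"]


def aromatic_ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of fused aromatic ring systems."""
    info = mol.GetRingInfo()
    systems: list[tuple[set[int], set[int]]] = []  # (atoms, bonds)
    for atom_ring, bond_ring in zip(info.AtomRings(), info.BondRings()):
        if not all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            continue
        atoms, bonds = set(atom_ring), set(bond_ring)
        keep = []
        for satoms, sbonds in systems:
            if sbonds & bonds:
                atoms |= satoms
                bonds |= sbonds
            else:
                keep.append((satoms, sbonds))
        keep.append((atoms, bonds))
        systems = keep
    return [atoms for atoms, _ in systems]


def excluded_systems(fragment: Fragment) -> list[set[int]]:
    """Aromatic ring systems with >=1 nitrogen and >=1 dummy atom."""
    mol = fragment.mol
    out = []
    for atoms in aromatic_ring_systems(mol):
        has_n = any(mol.GetAtomWithIdx(i).GetAtomicNum() == 7 for i in atoms)
        has_dummy = any(mol.GetAtomWithIdx(i).GetAtomicNum() == 0 for i in atoms)
        if has_n and has_dummy:
            out.append(atoms)
    return out


def system_identifier(fragment: Fragment, atoms: set[int]) -> tuple[str, tuple[int, ...]]:
    """Structural identifier of one border-crossing aromatic ring system.

    Canonical SMILES of the extracted system with dummy placeholders
    normalized (atom maps cleared, ring-dummy isotopes kept) plus the sorted
    linker labels whose dummies belong to or touch the system.  Equal
    identifiers mean structurally identical systems with identical linker
    placement, which is what interchangeability requires.
    """
    mol = Chem.Mol(fragment.mol)
    labels = []
    for idx in atoms:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 0:
            if atom.GetAtomMapNum():
                labels.append(atom.GetAtomMapNum())
            atom.SetAtomMapNum(0)
    smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)
    return (smiles, tuple(sorted(labels)))
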