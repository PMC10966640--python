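"""Simple additive plugins: heavy-atom count and molecular weight.

Heavy atoms are exactly fragment-additive (dummies contribute nothing), so
the boundary information is empty and the EPC is always zero.  Molecular
weight includes hydrogens, whose count in border-crossing aromatic nitrogen
heterocycles is only fixed on assembly, so the MW plugin reuses the TPSA
plugin's ring-system exclusion and boundary identifier.

Masses use the toolkit's standard atomic weights; values are exact integers
in milli-Dalton, rounded to two decimals at output by default.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import Descriptors

from ..space import Fragment
from .base import NodeContext, NumericPlugin
from .ringsystems import excluded_systems, system_identifier

__all__ = ["HeavyAtomsPlugin", "MolWeightPlugin"]

_H_MASS = Chem.GetPeriodicTable().GetAtomicWeight(1)


class HeavyAtomsPlugin(NumericPlugin):
    name = "heavyatoms"
    scale = 1

    def measure(self, mol: Chem.Mol) -> int:
        return mol.GetNumHeavyAtoms()

    def fragment_ipc_boundary(self, fragment: Fragment, ctx: NodeContext):
        return fragment.num_heavy_atoms(), ()


def _atom_mass_milli(atom: Chem.Atom) -> int:
    if atom.GetAtomicNum() == 0:
        return 0
    return round((atom.GetMass() + atom.GetTotalNumHs() * _H_MASS) * 1000)


class MolWeightPlugin(NumericPlugin):
    name = "mw"
    scale = 1000

    def measure(self, mol: Chem.Mol) -> int:
        return round(Descriptors.MolWt(mol) * 1000)

    def fragment_ipc_boundary(self, fragment: Fragment, ctx: NodeContext):
        mol = fragment.mol
        systems = excluded_systems(fragment)
        skipped = set().union(*systems) if systems else set()
        ipc = sum(
            _atom_mass_milli(a) for a in mol.GetAtoms() if a.GetIdx() not in skipped
        )
        boundary = frozenset(system_identifier(fragment, s) for s in systems)
        return ipc, boundary
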