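"""Stage 5 — Abstract Compound generation.

The abstract structure is the family key: all stereoisomers, double-bond
isomers (cis/trans flags and E/Z specifications alike) and isotopologues
of one constitution collapse onto a single FixedH InChIKey.  Tautomer
state is inherited from the Canonical Representative — the hierarchy
already canonicalized at stage 3 and does not re-canonicalize here.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem

from .identifiers import IdentifierBundle, identifier_bundle
from .saltstrip import UnsaltedCanonicalRepresentative


@dataclass
class AbstractCompound:
    structure: Chem.Mol
    ids: IdentifierBundle
    ucr: UnsaltedCanonicalRepresentative | None = None


def make_abstract(
    ucr: UnsaltedCanonicalRepresentative | Chem.Mol,
) -> AbstractCompound:
    """Clear all stereo parities, double-bond stereo and isotope labels.

    After clearing, the canonical SMILES is re-parsed with any residual
    directional-bond slashes removed as a belt-and-braces guarantee, and
    2D coordinates are regenerated so wedge artifacts cannot survive in
    the written molblock.
    """
    mol = ucr.structure if isinstance(ucr, UnsaltedCanonicalRepresentative) \
        else ucr
    work = Chem.Mol(mol)
    for atom in work.GetAtoms():
        atom.SetIsotope(0)
    Chem.RemoveStereochemistry(work)
    for bond in work.GetBonds():
        bond.SetBondDir(Chem.BondDir.NONE)

    smiles = Chem.MolToSmiles(work)
    smiles = smiles.replace("/", "").replace("\\", "")
    out = Chem.MolFromSmiles(smiles)
    if out is None:  # should not happen; fall back to the edited mol
        out = work
    AllChem.Compute2DCoords(out)
    return AbstractCompound(
        structure=out,
        ids=identifier_bundle(out),
        ucr=ucr if isinstance(ucr, UnsaltedCanonicalRepresentative) else None,
    )
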