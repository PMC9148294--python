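"""Stage 2 — Standard Compound generation.

Rule-based cleanup (functional-group normalization, recombination of
artificially separated charges such as O(-)-S(2+)-O(-) -> O=S=O, metal
disconnection, re-ionization so the strongest acid ionizes first, and
neutralization), followed by two safety nets the cleanup rules miss in
practice: a second neutralization pass for structures left with an
unbalanced net charge, and breaking of residual covalent metal-O/N/S
bonds.  Stereochemistry is assigned preferentially from 3D coordinates
when the input provides them.

Balanced ion pairs (e.g. carboxylate + Na+) are deliberately kept intact
at this level: the free acid/base only emerges after the salt-strip
stage, so the Standard Compound stays faithful to the registered salt
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chemio import MoleculeRecord, RejectionRecord, RejectionStage
from .checker import CheckedMolecule
from .identifiers import IdentifierBundle, identifier_bundle

# Metals whose residual covalent bonds to O/N/S are broken into ion pairs:
# alkali & alkaline-earth, transition rows, and the common p-block metals.
_METALS = frozenset(
    [3, 4, 11, 12, 13, 19, 20, 31, 37, 38, 49, 50, 55, 56, 81, 82, 83]
    + list(range(21, 31))   # Sc..Zn
    + list(range(39, 49))   # Y..Cd
    + list(range(57, 81))   # La..Hg
)
_HETERO = frozenset([7, 8, 16])  # N, O, S


@dataclass
class StandardCompound:
    structure: Chem.Mol
    ids: IdentifierBundle
    record: MoleculeRecord | None = None
    flags: dict = field(default_factory=dict)


def cleanup(checked: CheckedMolecule | Chem.Mol) -> Chem.Mol | RejectionRecord:
    """Library cleanup rules; failures become STANDARDIZATION rejections."""
    mol = checked.structure if isinstance(checked, CheckedMolecule) else checked
    try:
        return rdMolStandardize.Cleanup(mol)
    except Exception as exc:
        if isinstance(checked, CheckedMolecule):
            return RejectionRecord(
                checked.record, RejectionStage.STANDARDIZATION,
                f"cleanup failed: {exc}",
            )
        raise


def extra_neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Second neutralization pass for charges the cleanup rules leave.

    Structures whose net formal charge is already zero — neutral
    molecules, zwitterions, and balanced ion pairs — are untouched;
    otherwise remaining protonatable/deprotonatable atoms are neutralized
    (permanent charges such as quaternary nitrogen survive, flagged).
    """
    if Chem.GetFormalCharge(mol) == 0:
        return mol, False
    uncharger = rdMolStandardize.Uncharger()
    out = uncharger.uncharge(Chem.Mol(mol))
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return mol, False
    changed = Chem.MolToSmiles(out) != Chem.MolToSmiles(mol)
    return (out, True) if changed else (mol, False)


def break_residual_metal_bonds(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Break covalent metal-O/N/S single bonds the cleanup rules missed.

    Each broken bond becomes an ion pair (+1 on the metal, -1 on the
    heteroatom) so the total formal charge is conserved.  Metal-carbon
    bonds (organometallics proper) are left alone.
    """
    to_break = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        za, zb = a.GetAtomicNum(), b.GetAtomicNum()
        if (za in _METALS and zb in _HETERO) or (zb in _METALS and za in _HETERO):
            to_break.append(bond.GetIdx())
    if not to_break:
        return mol, False
    rw = Chem.RWMol(mol)
    for idx in sorted(to_break, reverse=True):
        bond = rw.GetBondWithIdx(idx)
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        metal, hetero = (a, b) if a.GetAtomicNum() in _METALS else (b, a)
        rw.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        metal.SetFormalCharge(metal.GetFormalCharge() + 1)
        hetero.SetFormalCharge(hetero.GetFormalCharge() - 1)
        hetero.SetNoImplicit(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    out, _ = extra_neutralize(out)
    return out, True


def assign_stereo(record: MoleculeRecord, mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Assign stereo, preferring 3D geometry over wedge-derived marks.

    If the original record carried 3D coordinates and the working
    structure still has a 3D conformer, tetrahedral and double-bond
    stereo are perceived from geometry (degenerate neighborhoods are
    left unassigned by the perception routine); otherwise the
    wedge/2D-derived assignments already present are kept.
    """
    if record is not None and record.dimensionality == "3D":
        work = Chem.Mol(mol)
        if work.GetNumConformers() > 0 and work.GetConformer().Is3D():
            try:
                Chem.AssignStereochemistryFrom3D(work)
                return work, True
            except Exception:
                return mol, False
    return mol, False


def standardize(checked: CheckedMolecule) -> StandardCompound | RejectionRecord:
    """Full stage-2 run: cleanup, extra neutralization, residual metal
    bond breaking, stereo assignment, then validation (round-trippable
    molblock and identifier generation)."""
    record = checked.record
    structure, stereo_from_3d = assign_stereo(record, checked.structure)
    result = cleanup(CheckedMolecule(record=record, structure=structure,
                                     had_kekulization_fix=checked.had_kekulization_fix,
                                     coordinates_generated=checked.coordinates_generated))
    if isinstance(result, RejectionRecord):
        return result
    mol = result
    n_frags_in = len(Chem.GetMolFrags(structure)) if structure.GetNumAtoms() else 0
    mol, residual_metal_broken = break_residual_metal_bonds(mol)
    metal_disconnected = residual_metal_broken or (
        len(Chem.GetMolFrags(mol)) > n_frags_in
    )
    mol, extra_neutralized = extra_neutralize(mol)

    # validation: the structure must round-trip and yield identifiers
    try:
        Chem.MolToMolBlock(mol)
        ids = identifier_bundle(mol)
    except Exception as exc:
        return RejectionRecord(record, RejectionStage.STANDARDIZATION,
                               f"validation failed: {exc}")
    return StandardCompound(
        structure=mol,
        ids=ids,
        record=record,
        flags={
            "extra_neutralized": extra_neutralized,
            "metal_disconnected": metal_disconnected,
            "residual_metal_broken": residual_metal_broken,
            "stereo_from_3d": stereo_from_3d,
        },
    )
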