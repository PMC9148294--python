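"""Stage 1 — structure checker.

Filters or repairs problematic inputs before standardization: records
with an empty molblock are removed, a kekulization pass is attempted
ahead of sanitization (this rescues molblocks whose aromatic bond flags
would otherwise trip aromaticity perception), and wedge marks that do
not correspond to a real stereocenter are dropped rather than the whole
record being rejected.  Functional-group normalization is deliberately
NOT done here; that is the standardizer's job.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import MoleculeRecord, RejectionRecord, RejectionStage


@dataclass
class CheckedMolecule:
    record: MoleculeRecord
    structure: Chem.Mol
    had_kekulization_fix: bool = False
    coordinates_generated: bool = False


def _has_aromatic_flags(mol: Chem.Mol) -> bool:
    return any(b.GetIsAromatic() for b in mol.GetBonds())


def _sanitize_kekulize_first(mol: Chem.Mol) -> Chem.Mol:
    """Kekulize aromatic flags away, then run full sanitization."""
    work = Chem.Mol(mol)
    work.UpdatePropertyCache(strict=False)
    Chem.Kekulize(work, clearAromaticFlags=True)
    Chem.SanitizeMol(work)
    return work


def _sanitize_direct(mol: Chem.Mol) -> Chem.Mol:
    work = Chem.Mol(mol)
    Chem.SanitizeMol(work)
    return work


def check_structure(record: MoleculeRecord) -> CheckedMolecule | RejectionRecord:
    """Validate one record; returns the sanitized structure or a rejection.

    Acceptance requires surviving either the kekulize-first path or, as a
    fallback, direct sanitization (a structure is only rejected when both
    fail).  Wedge-derived stereo marks on non-stereocenters are cleaned,
    and 2D coordinates are generated when the molblock carries none.
    """
    mol = record.parsed
    if mol is None:
        mol = Chem.MolFromMolBlock(record.molblock, sanitize=False,
                                   removeHs=False)
    if mol is None:
        return RejectionRecord(record, RejectionStage.PARSING,
                               "molblock could not be parsed")
    if mol.GetNumAtoms() == 0:
        return RejectionRecord(record, RejectionStage.EMPTY_MOLBLOCK,
                               "molblock has no atoms")

    had_aromatic = _has_aromatic_flags(mol)
    structure = None
    had_kekulization_fix = False
    first_error = None
    try:
        structure = _sanitize_kekulize_first(mol)
        had_kekulization_fix = had_aromatic
    except Exception as exc:  # kekulization path failed; try direct
        first_error = exc
        try:
            structure = _sanitize_direct(mol)
            had_kekulization_fix = False
        except Exception as exc2:
            reason = f"{exc2}" or f"{first_error}"
            kind = "valence" if "valence" in reason.lower() else "aromaticity" \
                if "kekulize" in reason.lower() or "aromatic" in reason.lower() \
                else "sanitization"
            return RejectionRecord(
                record, RejectionStage.SANITIZATION, f"{kind}: {reason}"
            )

    # drop geometrically impossible stereo marks, keep the atoms
    Chem.AssignStereochemistry(structure, cleanIt=True, force=True)

    coordinates_generated = False
    if structure.GetNumConformers() == 0 or record.dimensionality == "none":
        AllChem.Compute2DCoords(structure)
        coordinates_generated = True

    return CheckedMolecule(
        record=record,
        structure=structure,
        had_kekulization_fix=had_kekulization_fix,
        coordinates_generated=coordinates_generated,
    )
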