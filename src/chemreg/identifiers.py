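"""Identifier bundle generation.

Every registered structure carries five string representations: an
isomeric canonical SMILES, the Standard InChI/InChIKey, and a
non-standard InChI/InChIKey generated with the fixed-hydrogen option
(``/FixedH``).  The fixed-H layer makes the InChI tautomer-sensitive:
tautomers that collapse to one Standard InChI receive distinct
non-standard keys.  The non-standard InChIKey is the uniqueness key for
all deduplication; SMILES is informational only and never an identity
key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import inchi

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class IdentifierError(RuntimeError):
    """Raised when the InChI engine cannot produce an identifier."""


@dataclass(frozen=True)
class IdentifierBundle:
    canonical_smiles: str
    std_inchi: str
    std_inchikey: str
    nonstd_inchi: str
    nonstd_inchikey: str


def identifier_bundle(mol: Chem.Mol) -> IdentifierBundle:
    """Compute all five identifiers for a sanitized structure.

    Identifiers are a function of the molecular graph and its assigned
    stereo tags only: conformers are stripped from the working copy
    because the InChI engine would otherwise re-perceive stereo from raw
    coordinates, making the key depend on whether a structure happens to
    carry a drawing.  Stereo a record legitimately has is already in the
    tags by the time identifiers are generated (wedge and 3D perception
    happen in the checker/standardizer).
    """
    work = Chem.Mol(mol)
    work.RemoveAllConformers()
    smiles = Chem.MolToSmiles(work)
    std = inchi.MolToInchi(work)
    nonstd = inchi.MolToInchi(work, options="/FixedH")
    if not std or not nonstd:
        raise IdentifierError(
            f"InChI generation failed for SMILES {smiles!r}"
        )
    std_key = inchi.InchiToInchiKey(std)
    nonstd_key = inchi.InchiToInchiKey(nonstd)
    if not std_key or not nonstd_key:
        raise IdentifierError(
            f"InChIKey generation failed for SMILES {smiles!r}"
        )
    return IdentifierBundle(
        canonical_smiles=smiles,
        std_inchi=std,
        std_inchikey=std_key,
        nonstd_inchi=nonstd,
        nonstd_inchikey=nonstd_key,
    )


def uniqueness_key(mol: Chem.Mol) -> str:
    """The FixedH non-standard InChIKey — the registry uniqueness key."""
    return identifier_bundle(mol).nonstd_inchikey
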