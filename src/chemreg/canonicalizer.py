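"""Stage 3 — canonical tautomer selection (Canonical Representative).

All tautomers of a Standard Compound must register under one structure,
so a deterministic canonical tautomer is selected.  Selection protects
what the registry promises to preserve: net formal charge, aromaticity,
assigned tetrahedral stereocenters and assigned double-bond stereo.  The
enumerator's protection flags alone do not guarantee this (proton shifts
can still run through a stereocenter), so enumerants that change any
protected count are filtered out before scoring; if nothing survives the
filter, the input tautomer passes through unchanged.

Very large structures (more than ``heavy_atom_limit`` non-hydrogen
atoms, default 100) skip canonicalization entirely, and a per-record
wall-clock budget caps enumeration time; in both cases the Standard
Compound passes through flagged rather than rejected.  Salted records
whose organic part changes net charge during canonicalization are
registry artefacts and are rejected.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chemio import RejectionRecord, RejectionStage
from .identifiers import IdentifierBundle, identifier_bundle
from .standardizer import StandardCompound


@dataclass(frozen=True)
class CanonicalizationConfig:
    heavy_atom_limit: int = 100
    max_tautomers: int = 30
    timeout_ms: float = 250.0
    protect_charge: bool = True
    protect_aromaticity: bool = True
    protect_chiral_centers: bool = True
    protect_double_bond_stereo: bool = True

    def __post_init__(self):
        if self.heavy_atom_limit <= 0 or self.max_tautomers <= 0 \
                or self.timeout_ms <= 0:
            raise ValueError("all canonicalization limits must be positive")


@dataclass
class CanonicalRepresentative:
    structure: Chem.Mol
    ids: IdentifierBundle
    skipped_large: bool = False
    timed_out: bool = False
    modified: bool = False
    sc: StandardCompound | None = None
    flags: dict = field(default_factory=dict)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Non-hydrogen atom count over all fragments."""
    return mol.GetNumHeavyAtoms()


def _stereo_counts(mol: Chem.Mol) -> tuple[int, int]:
    """(assigned tetrahedral centers, assigned double-bond stereo marks)."""
    centers = len(Chem.FindMolChiralCenters(mol, includeUnassigned=False,
                                            useLegacyImplementation=False))
    dbl = sum(
        1 for b in mol.GetBonds()
        if b.GetStereo() not in (Chem.BondStereo.STEREONONE,
                                 Chem.BondStereo.STEREOANY)
    )
    return centers, dbl


def _aromatic_atom_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def _make_enumerator(cfg: CanonicalizationConfig) -> rdMolStandardize.TautomerEnumerator:
    te = rdMolStandardize.TautomerEnumerator()
    te.SetMaxTautomers(cfg.max_tautomers)
    # "remove sp3 stereo" / "remove bond stereo" are kept off so assigned
    # stereo survives enumeration
    te.SetRemoveSp3Stereo(False)
    te.SetRemoveBondStereo(False)
    return te


def enumerate_tautomers(
    mol: Chem.Mol, cfg: CanonicalizationConfig | None = None
) -> tuple[list[Chem.Mol], bool]:
    """Enumerate protected tautomers of ``mol``; returns (tautomers, timed_out).

    The result always contains the input and never a member that alters
    net formal charge, assigned stereocenter count, or assigned
    double-bond stereo count.  On budget expiry only the input is
    returned, flagged.
    """
    cfg = cfg or CanonicalizationConfig()
    t0 = time.monotonic()
    budget = cfg.timeout_ms / 1000.0
    try:
        result = _make_enumerator(cfg).Enumerate(mol)
    except Exception:
        return [Chem.Mol(mol)], False
    if time.monotonic() - t0 > budget:
        return [Chem.Mol(mol)], True

    ref_charge = Chem.GetFormalCharge(mol)
    ref_stereo = _stereo_counts(mol)
    in_smiles = Chem.MolToSmiles(mol)
    keep: dict[str, Chem.Mol] = {in_smiles: Chem.Mol(mol)}
    for taut in result:
        if time.monotonic() - t0 > budget:
            return [Chem.Mol(mol)], True
        if cfg.protect_charge and Chem.GetFormalCharge(taut) != ref_charge:
            continue
        if (cfg.protect_chiral_centers or cfg.protect_double_bond_stereo):
            centers, dbl = _stereo_counts(taut)
            if cfg.protect_chiral_centers and centers != ref_stereo[0]:
                continue
            if cfg.protect_double_bond_stereo and dbl != ref_stereo[1]:
                continue
        # drop enumerants that do not survive a canonical-SMILES round
        # trip (the enumerator can emit chemically invalid states)
        smiles = Chem.MolToSmiles(taut)
        reparsed = Chem.MolFromSmiles(smiles)
        if reparsed is None:
            continue
        keep.setdefault(smiles, reparsed)
    return list(keep.values()), False


def _score(mol: Chem.Mol) -> int:
    return rdMolStandardize.TautomerEnumerator.ScoreTautomer(mol)


def pick_canonical(tautomers: list[Chem.Mol]) -> Chem.Mol:
    """Deterministic pick: maximum tautomer score, ties broken by
    lexicographically smallest canonical SMILES."""
    scored = [(-_score(t), Chem.MolToSmiles(t), t) for t in tautomers]
    scored.sort(key=lambda x: (x[0], x[1]))
    return scored[0][2]


def _organic_fragment_charge(mol: Chem.Mol) -> int:
    """Net formal charge summed over carbon-containing fragments."""
    total = 0
    for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False):
        if any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            total += sum(a.GetFormalCharge() for a in frag.GetAtoms())
    return total


def canonical_representative(
    sc: StandardCompound, cfg: CanonicalizationConfig | None = None
) -> CanonicalRepresentative | RejectionRecord:
    """Select the Canonical Representative for a Standard Compound."""
    cfg = cfg or CanonicalizationConfig()
    mol = sc.structure

    if heavy_atom_count(mol) > cfg.heavy_atom_limit:
        return CanonicalRepresentative(
            structure=Chem.Mol(mol), ids=sc.ids, skipped_large=True,
            modified=False, sc=sc,
        )

    tautomers, timed_out = enumerate_tautomers(mol, cfg)
    chosen = Chem.Mol(mol) if timed_out else pick_canonical(tautomers)
    # round-trip through canonical SMILES: enumerant mols can carry
    # internal hydrogen-layer artifacts that would leak into the FixedH
    # InChI and break canonical invariance
    reparsed = Chem.MolFromSmiles(Chem.MolToSmiles(chosen))
    if reparsed is not None:
        chosen = reparsed

    multi_fragment = len(Chem.GetMolFrags(mol)) > 1
    if multi_fragment and _organic_fragment_charge(chosen) != \
            _organic_fragment_charge(mol):
        return RejectionRecord(
            sc.record, RejectionStage.CHARGED_AFTER_CANONICALIZATION,
            "organic fragment net charge changed during canonicalization",
        )

    ids = identifier_bundle(chosen)
    return CanonicalRepresentative(
        structure=chosen,
        ids=ids,
        skipped_large=False,
        timed_out=timed_out,
        modified=ids.nonstd_inchikey != sc.ids.nonstd_inchikey,
        sc=sc,
    )
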