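import pytest
from rdkit import Chem

from chemreg import (
    CanonicalizationConfig,
    canonical_representative,
    check_structure,
    enumerate_tautomers,
    heavy_atom_count,
    standardize,
    uniqueness_key,
)
from chemreg.canonicalizer import _stereo_counts, pick_canonical
from chemreg.chemio import RejectionRecord, RejectionStage

from conftest import make_record, mol_from_smiles


def _sc(smiles):
    sc = standardize(check_structure(make_record(smiles)))
    assert not isinstance(sc, RejectionRecord)
    return sc


@pytest.mark.parametrize("smiles,expected", [
    ("C", 1),
    ("c1ccccc1", 6),
    ("O.CCO", 4),  # counts across all fragments
])
def test_heavy_atom_count(smiles, expected):
    assert heavy_atom_count(mol_from_smiles(smiles)) == expected


def _pyridone_proton_shift_oracle():
    """Brute-force 1,3/1,5 proton-shift enumeration on the 2-pyridone
    scaffold: place the single mobile hydrogen on either terminus of the
    O=C-N system and keep placements RDKit accepts as valid molecules."""
    candidates = [
        "Oc1ccccn1",        # H on O (1,3 shift from N)
        "O=c1cccc[nH]1",    # H on N
        "O=C1C=CC=CN1",     # equivalent kekule drawing of the N-H form
    ]
    keys = set()
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            keys.add(uniqueness_key(mol))
    assert len(keys) == 2  # the two drawings of the amide form collapse
    return keys


def test_hydroxypyridine_enumeration_contains_both_tautomers():
    expected = _pyridone_proton_shift_oracle()
    tautomers, timed_out = enumerate_tautomers(mol_from_smiles("Oc1ccccn1"))
    assert not timed_out
    keys = {uniqueness_key(t) for t in tautomers}
    assert expected <= keys


def test_methane_has_no_tautomers():
    tautomers, _ = enumerate_tautomers(mol_from_smiles("C"))
    assert len(tautomers) == 1


def test_enumeration_never_alters_protected_counts():
    for smiles in ("C[C@H](N)C(C)=O", "C/C=C/C(=O)O", "CC(=O)[O-]",
                   "Oc1ccccn1"):
        mol = mol_from_smiles(smiles)
        ref_charge = Chem.GetFormalCharge(mol)
        ref_stereo = _stereo_counts(mol)
        tautomers, _ = enumerate_tautomers(mol)
        for t in tautomers:
            assert Chem.GetFormalCharge(t) == ref_charge
            assert _stereo_counts(t) == ref_stereo


def test_stereocenter_survives_keto_enol_canonicalization():
    """Enolization through the alpha stereocenter must not erase it."""
    sc = _sc("C[C@H](N)C(C)=O")
    cr = canonical_representative(sc)
    assert _stereo_counts(cr.structure) == _stereo_counts(sc.structure) == (1, 0)


@pytest.mark.parametrize("pair", [
    ("Oc1ccccn1", "O=c1cccc[nH]1"),
    ("CC(O)=CC(C)=O", "CC(=O)CC(C)=O"),
    ("Oc1ccc(N=Nc2ccccc2)cc1", "O=C1C=CC(=NNc2ccccc2)C=C1"),
])
def test_tautomer_pair_converges_to_one_representative(pair):
    keys = set()
    for smiles in pair:
        cr = canonical_representative(_sc(smiles))
        keys.add(cr.ids.nonstd_inchikey)
    assert len(keys) == 1


def test_oversized_structure_skips_canonicalization():
    sc = _sc("C" * 102)
    cr = canonical_representative(sc)
    assert cr.skipped_large
    assert not cr.modified
    # gate leaves the structure bit-identical modulo coordinates
    assert Chem.MolToSmiles(cr.structure) == Chem.MolToSmiles(sc.structure)
    assert cr.ids.nonstd_inchikey == sc.ids.nonstd_inchikey


def test_canonical_invariance_over_enumerated_tautomers():
    """Every enumerated tautomer canonicalizes to the same representative."""
    for smiles in ("Oc1ccccn1", "CC(=O)CC(C)=O", "CC(=O)Nc1ccccc1"):
        sc = _sc(smiles)
        ref = canonical_representative(sc).ids.nonstd_inchikey
        tautomers, _ = enumerate_tautomers(sc.structure)
        for t in tautomers:
            t_cr = canonical_representative(_sc(Chem.MolToSmiles(t)))
            assert t_cr.ids.nonstd_inchikey == ref, Chem.MolToSmiles(t)


def test_charged_after_canonicalization_rejection_rule():
    """A salted record whose organic fragment changes net charge during
    canonicalization is an artefact and is expelled with its own stage."""
    from chemreg.canonicalizer import _organic_fragment_charge

    sc = _sc("CC(=O)[O-].[Na+]")
    assert _organic_fragment_charge(sc.structure) == -1
    # the real enumerator conserves charge here, so the accepted CR exists
    cr = canonical_representative(sc)
    assert not isinstance(cr, RejectionRecord)

    # force the rule: a canonicalizer output whose organic charge differs
    import chemreg.canonicalizer as canon

    class _BadPick:
        def __call__(self, tautomers):
            return mol_from_smiles("CC(=O)O.[Na+]")  # organic charge 0 != -1

    original = canon.pick_canonical
    canon.pick_canonical = _BadPick()
    try:
        result = canonical_representative(sc)
    finally:
        canon.pick_canonical = original
    assert isinstance(result, RejectionRecord)
    assert result.stage is RejectionStage.CHARGED_AFTER_CANONICALIZATION


def test_determinism_of_pick():
    tautomers, _ = enumerate_tautomers(mol_from_smiles("Oc1ccccn1"))
    first = Chem.MolToSmiles(pick_canonical(tautomers))
    for perm in (tautomers[::-1], tautomers[1:] + tautomers[:1]):
        assert Chem.MolToSmiles(pick_canonical(perm)) == first


def test_config_rejects_nonpositive_limits():
    with pytest.raises(ValueError):
        CanonicalizationConfig(heavy_atom_limit=0)
    with pytest.raises(ValueError):
        CanonicalizationConfig(timeout_ms=-1)


def test_timeout_passes_structure_through_flagged():
    cfg = CanonicalizationConfig(timeout_ms=1e-6)
    sc = _sc("Oc1ccccn1")
    cr = canonical_representative(sc, cfg)
    assert cr.timed_out
    assert cr.ids.nonstd_inchikey == sc.ids.nonstd_inchikey
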