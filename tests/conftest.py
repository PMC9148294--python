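import pandas as pd
import pytest
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from chemreg import (
    PipelineConfig,
    default_mixed_spec,
    generate_fixtures,
    run_pipeline,
)

RDLogger.DisableLog("rdApp.*")

MIXED_SEED = 11


def mol_from_smiles(smiles, sanitize=True):
    mol = Chem.MolFromSmiles(smiles, sanitize=sanitize)
    assert mol is not None, smiles
    if not sanitize:
        mol.UpdatePropertyCache(strict=False)
    return mol


def make_record(smiles, index=0, source_id="r0", kekulize=True, coords=True):
    """Build a MoleculeRecord the way read_sdf would, from a SMILES."""
    from chemreg.chemio import MoleculeRecord, _dimensionality

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        mol.UpdatePropertyCache(strict=False)
        kekulize = False
    AllChem.Compute2DCoords(mol)
    if not coords:  # zero out coordinates so the record carries none
        conf = mol.GetConformer()
        from rdkit.Geometry import Point3D
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, Point3D(0.0, 0.0, 0.0))
    molblock = Chem.MolToMolBlock(mol, kekulize=kekulize)
    parsed = Chem.MolFromMolBlock(molblock, sanitize=False, removeHs=False)
    return MoleculeRecord(
        record_index=index, source_id=source_id, source_file="<memory>",
        molblock=molblock, parsed=parsed,
        dimensionality=_dimensionality(parsed), raw_record=molblock,
    )


@pytest.fixture(scope="session")
def mixed_corpus(tmp_path_factory):
    """Seed-deterministic mixed fixture corpus touching every branch."""
    out = tmp_path_factory.mktemp("mixed_in")
    sdf, manifest = generate_fixtures(default_mixed_spec(), out,
                                      seed=MIXED_SEED)
    return sdf, pd.read_csv(manifest, sep="\t").fillna("")


@pytest.fixture(scope="session")
def mixed_run(mixed_corpus, tmp_path_factory):
    """One serial pipeline run over the mixed corpus, shared by tests."""
    sdf, manifest = mixed_corpus
    out_root = tmp_path_factory.mktemp("mixed_out")
    registry, report = run_pipeline(
        PipelineConfig(input_glob=str(sdf), output_root=out_root, jobs=1))
    return {
        "sdf": sdf,
        "manifest": manifest,
        "out_root": out_root,
        "registry": registry,
        "report": report,
        "entries": {e.source_id: e for e in registry.entries},
        "rejections": {r.record.source_id: r for r in registry.rejections},
    }
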