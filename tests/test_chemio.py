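import gzip

import pytest
from rdkit import Chem

from chemreg import (
    HierarchyCompound,
    Level,
    OutputPlan,
    identifier_bundle,
    read_sdf,
    write_level_file,
)
from chemreg.chemio import RejectionStage, count_sdf_records

from conftest import make_record


def _sdf_bytes(molblocks, ids=None):
    parts = []
    for i, mb in enumerate(molblocks):
        text = mb if mb.endswith("\n") else mb + "\n"
        if ids:
            text += f"> <ID>\n{ids[i]}\n\n"
        parts.append(text + "$$$$\n")
    return "".join(parts).encode()


def _molblock(smiles):
    return make_record(smiles).molblock


@pytest.fixture
def three_record_file(tmp_path):
    mbs = [_molblock(s) for s in ("CCO", "c1ccccc1", "CC(=O)O")]
    path = tmp_path / "three.sdf.gz"
    path.write_bytes(gzip.compress(_sdf_bytes(mbs, ids=["a", "b", "c"])))
    return path


def test_well_formed_file_parses_every_record(three_record_file):
    records, rejections = read_sdf(three_record_file)
    assert [r.source_id for r in records] == ["a", "b", "c"]
    assert rejections == []
    assert all(r.parsed is not None for r in records)
    assert [r.record_index for r in records] == [0, 1, 2]


def test_garbled_counts_line_rejects_only_that_record(tmp_path):
    mbs = [_molblock("CCO"), _molblock("c1ccccc1"), _molblock("CC(=O)O")]
    # corrupt the counts line (4th line) of the middle record
    lines = mbs[1].splitlines()
    lines[3] = "garbage counts line"
    mbs[1] = "\n".join(lines) + "\n"
    path = tmp_path / "broken.sdf"
    path.write_bytes(_sdf_bytes(mbs))
    records, rejections = read_sdf(path)
    # independent framing oracle: the file still has three $$$$ records
    assert count_sdf_records(path) == 3
    assert len(records) == 2
    assert len(rejections) == 1
    assert rejections[0].stage is RejectionStage.PARSING
    assert rejections[0].record.record_index == 1


def test_empty_file_yields_nothing(tmp_path):
    path = tmp_path / "empty.sdf.gz"
    path.write_bytes(gzip.compress(b""))
    records, rejections = read_sdf(path)
    assert records == [] and rejections == []


def test_missing_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_sdf(tmp_path / "nope.sdf.gz")


def test_truncated_final_record_terminates_cleanly(tmp_path):
    data = _sdf_bytes([_molblock("CCO")]) + b"\n  partial\n  garbage\n"
    path = tmp_path / "trunc.sdf"
    path.write_bytes(data)
    records, rejections = read_sdf(path)
    assert len(records) + len(rejections) == count_sdf_records(path) == 2
    assert len(records) == 1
    assert rejections[0].stage is RejectionStage.PARSING


def test_records_without_id_tag_get_synthetic_ids(tmp_path):
    path = tmp_path / "noid.sdf"
    path.write_bytes(_sdf_bytes([_molblock("CCO")]))
    records, _ = read_sdf(path)
    assert records[0].source_id == "noid.sdf:0"


def test_conservation_over_mixed_content(tmp_path):
    """Every $$$$-delimited record lands in exactly one output stream."""
    good = [_molblock(s) for s in ("CCO", "CCN", "c1ccccc1")]
    bad = good[0].replace("V2000", "VXXXX")
    mbs = [good[0], bad, good[1], bad, good[2]]
    path = tmp_path / "mix.sdf"
    path.write_bytes(_sdf_bytes(mbs))
    records, rejections = read_sdf(path)
    assert len(records) + len(rejections) == count_sdf_records(path) == 5
    indices = sorted([r.record_index for r in records]
                     + [r.record.record_index for r in rejections])
    assert indices == [0, 1, 2, 3, 4]


class TestOutputPlan:
    def test_level_file_naming_follows_contract(self, tmp_path):
        plan = OutputPlan(output_root=tmp_path, base_name="batch_demo",
                          iteration=0)
        assert plan.level_path(Level.SC).name == "batch_demo_CH_SC_0.sdf.gz"
        assert plan.level_path(Level.AC).name == "batch_demo_CH_AC_0.sdf.gz"
        assert plan.error_path(RejectionStage.PARSING).name == \
            "batch_demo_SDF_Parsing_Errors.sdf.gz"
        assert plan.error_path(RejectionStage.SANITIZATION).name == \
            "batch_demo_Sanitisation_Errors.sdf.gz"
        assert plan.error_path(RejectionStage.STANDARDIZATION).name == \
            "batch_demo_Standardization_Errors.sdf.gz"
        assert plan.error_path(RejectionStage.EMPTY_MOLBLOCK).parent.name == \
            "No_structures"

    def test_empty_record_list_writes_nothing(self, tmp_path):
        plan = OutputPlan(output_root=tmp_path, base_name="x", iteration=0)
        assert write_level_file([], plan, Level.SC) is None
        assert not plan.level_path(Level.SC).exists()


def test_written_level_file_roundtrips_fixedh_key(tmp_path):
    mol = Chem.MolFromSmiles("C[C@H](N)C(=O)O")
    ids = identifier_bundle(mol)
    hc = HierarchyCompound(Level.SC, mol, "rt1", ids)
    plan = OutputPlan(output_root=tmp_path, base_name="rt", iteration=0)
    path = write_level_file([hc], plan, Level.SC)
    assert path.name == "rt_CH_SC_0.sdf.gz"
    records, rejections = read_sdf(path)
    assert rejections == []
    back = Chem.MolFromMolBlock(records[0].molblock)
    assert identifier_bundle(back).nonstd_inchikey == ids.nonstd_inchikey
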