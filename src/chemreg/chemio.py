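"""Gzipped SDF batch I/O with per-record provenance.

Records are framed on ``$$$$`` delimiter lines so that the raw V2000
molblock of every record is byte-preserved, including records RDKit
cannot parse: those are routed to error files verbatim rather than
silently dropped.  Chemical interpretation of each molblock is done by
RDKit; this module only handles record framing, SD-tag extraction for
the source identifier, and the output directory/file-naming contract.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import AllChem


class Level(str, Enum):
    """The four hierarchy levels a structure is registered at."""

    SC = "SC"    # Standard Compound
    CR = "CR"    # Canonical Representative (canonical tautomer)
    UCR = "UCR"  # Unsalted Canonical Representative (free base/acid)
    AC = "AC"    # Abstract Compound (stereo/isotope-agnostic family key)


class RejectionStage(str, Enum):
    PARSING = "PARSING"
    SANITIZATION = "SANITIZATION"
    EMPTY_MOLBLOCK = "EMPTY_MOLBLOCK"
    STANDARDIZATION = "STANDARDIZATION"
    CHARGED_AFTER_CANONICALIZATION = "CHARGED_AFTER_CANONICALIZATION"


DEFAULT_ID_TAG = "ID"

#: error-file suffix per rejection stage (EMPTY_MOLBLOCK goes to No_structures/)
ERROR_SUFFIXES = {
    RejectionStage.PARSING: "_SDF_Parsing_Errors.sdf.gz",
    RejectionStage.SANITIZATION: "_Sanitisation_Errors.sdf.gz",
    RejectionStage.STANDARDIZATION: "_Standardization_Errors.sdf.gz",
    RejectionStage.CHARGED_AFTER_CANONICALIZATION: "_Canonicalization_Errors.sdf.gz",
    RejectionStage.EMPTY_MOLBLOCK: "_No_Structures.sdf.gz",
}


@dataclass
class MoleculeRecord:
    """One input structure with its provenance.

    ``molblock`` is the raw V2000 text exactly as read from the file;
    ``parsed`` is the unsanitized RDKit molecule when parsing succeeded.
    """

    record_index: int
    source_id: str
    source_file: str
    molblock: str
    parsed: Optional[Chem.Mol] = None
    dimensionality: str = "none"  # {"none", "2D", "3D"}
    raw_record: str = ""  # full SDF record text incl. tags, no terminator


@dataclass
class RejectionRecord:
    record: MoleculeRecord
    stage: RejectionStage
    reason: str = ""


@dataclass
class HierarchyCompound:
    """A structure registered at one hierarchy level."""

    level: Level
    structure: Chem.Mol
    source_id: str
    ids: "IdentifierBundle"  # noqa: F821 - see identifiers module
    flags: dict = field(default_factory=dict)


@dataclass
class OutputPlan:
    """Output layout: Results/, Errors/ and No_structures/ under one root.

    Result file names follow ``<base>_CH_<LEVEL>_<iteration>.sdf.gz``;
    error file names use fixed per-stage suffixes.
    """

    output_root: Path
    base_name: str
    iteration: int = 0

    @property
    def results_dir(self) -> Path:
        return Path(self.output_root) / "Results"

    @property
    def errors_dir(self) -> Path:
        return Path(self.output_root) / "Errors"

    @property
    def nostruct_dir(self) -> Path:
        return Path(self.output_root) / "No_structures"

    def level_path(self, level: Level) -> Path:
        name = f"{self.base_name}_CH_{Level(level).value}_{self.iteration}.sdf.gz"
        return self.results_dir / name

    def error_path(self, stage: RejectionStage) -> Path:
        suffix = ERROR_SUFFIXES[RejectionStage(stage)]
        directory = (
            self.nostruct_dir
            if RejectionStage(stage) is RejectionStage.EMPTY_MOLBLOCK
            else self.errors_dir
        )
        return directory / f"{self.base_name}{suffix}"

    def ensure_dirs(self) -> None:
        for d in (self.results_dir, self.errors_dir, self.nostruct_dir):
            d.mkdir(parents=True, exist_ok=True)


def _open_text(path: os.PathLike) -> io.TextIOBase:
    """Open plain or gzipped SDF transparently (sniffs the gzip magic)."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8",
                                errors="replace")
    return io.TextIOWrapper(raw, encoding="utf-8", errors="replace")


def _split_records(stream: io.TextIOBase) -> Iterable[str]:
    """Yield raw SDF record texts (without the ``$$$$`` terminator line).

    A truncated final record (content after the last ``$$$$``) is yielded
    too; whether it is usable is decided by the molblock parser.
    """
    buf: list[str] = []
    for line in stream:
        if line.rstrip("\r\n") == "$$$$":
            yield "".join(buf)
            buf = []
        else:
            buf.append(line)
    tail = "".join(buf)
    if tail.strip():
        yield tail


_TAG_RE = re.compile(r"^>\s*<(.*?)>")


def _record_parts(record_text: str) -> tuple[str, dict]:
    """Split one SDF record into (molblock, sd_tags)."""
    lines = record_text.splitlines(keepends=True)
    mol_end = None
    for i, line in enumerate(lines):
        if line.strip() == "M  END":
            mol_end = i
            break
    if mol_end is None:
        return record_text, {}
    molblock = "".join(lines[: mol_end + 1])
    tags: dict[str, str] = {}
    i = mol_end + 1
    while i < len(lines):
        m = _TAG_RE.match(lines[i])
        if m:
            name = m.group(1)
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                vals.append(lines[i].rstrip("\r\n"))
                i += 1
            tags[name] = "\n".join(vals)
        else:
            i += 1
    return molblock, tags


def _dimensionality(mol: Chem.Mol) -> str:
    if mol is None or mol.GetNumConformers() == 0 or mol.GetNumAtoms() == 0:
        return "none"
    conf = mol.GetConformer()
    xs = [conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms())]
    if any(abs(p.z) > 1e-4 for p in xs):
        return "3D"
    if any(abs(p.x) > 1e-4 or abs(p.y) > 1e-4 for p in xs):
        return "2D"
    return "none"


def count_sdf_records(path: os.PathLike) -> int:
    """Number of ``$$$$``-delimited records in a file (conservation oracle)."""
    with _open_text(path) as fh:
        return sum(1 for _ in _split_records(fh))


def read_sdf(
    path: os.PathLike, id_tag: str = DEFAULT_ID_TAG
) -> tuple[list[MoleculeRecord], list[RejectionRecord]]:
    """Read an SDF (gzipped or plain) into records plus parse rejections.

    Every ``$$$$``-delimited record appears exactly once in exactly one of
    the two returned lists, in input order.  Records lacking the
    configured identifier tag get a synthetic ``<file>:<index>`` id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input SDF not found: {path}")
    records: list[MoleculeRecord] = []
    rejections: list[RejectionRecord] = []
    with _open_text(path) as fh:
        for idx, raw in enumerate(_split_records(fh)):
            molblock, tags = _record_parts(raw)
            source_id = tags.get(id_tag, f"{path.name}:{idx}")
            mol = Chem.MolFromMolBlock(molblock, sanitize=False, removeHs=False)
            rec = MoleculeRecord(
                record_index=idx,
                source_id=source_id,
                source_file=str(path),
                molblock=molblock,
                parsed=mol,
                dimensionality=_dimensionality(mol),
                raw_record=raw,
            )
            if mol is None:
                rejections.append(
                    RejectionRecord(rec, RejectionStage.PARSING,
                                    "molblock could not be parsed")
                )
            else:
                records.append(rec)
    return records, rejections


# SD tags written to every level file, in fixed order for reproducibility.
_ID_TAGS = (
    ("Canonical_SMILES", "canonical_smiles"),
    ("Standard_InChI", "std_inchi"),
    ("Standard_InChIKey", "std_inchikey"),
    ("NonStandard_InChI", "nonstd_inchi"),
    ("NonStandard_InChIKey", "nonstd_inchikey"),
)


def write_level_file(
    records: list[HierarchyCompound],
    plan: OutputPlan,
    level: Level,
    id_tag: str = DEFAULT_ID_TAG,
) -> Optional[Path]:
    """Write one hierarchy level as a gzipped SDF; returns the path.

    Nothing is written (and ``None`` returned) for an empty record list,
    so clean runs emit exactly four files per iteration.
    """
    if not records:
        return None
    level = Level(level)
    if any(Level(r.level) is not level for r in records):
        raise ValueError("all records must be at the written level")
    plan.ensure_dirs()
    out_path = plan.level_path(level)
    with gzip.open(out_path, "wt", encoding="utf-8") as fh:
        writer = Chem.SDWriter(fh)
        for hc in records:
            mol = Chem.Mol(hc.structure)
            if mol.GetNumConformers() == 0:
                AllChem.Compute2DCoords(mol)
            mol.SetProp(id_tag, hc.source_id)
            for tag, attr in _ID_TAGS:
                mol.SetProp(tag, getattr(hc.ids, attr))
            writer.write(mol)
        writer.close()
    return out_path


def write_rejection_files(
    rejections: list[RejectionRecord], plan: OutputPlan
) -> dict[RejectionStage, Path]:
    """Write rejected records, grouped by stage, as raw SDF passthrough.

    Raw record text is written verbatim (it may be unparseable), one file
    per stage, only when that stage has members.
    """
    written: dict[RejectionStage, Path] = {}
    by_stage: dict[RejectionStage, list[RejectionRecord]] = {}
    for rej in rejections:
        by_stage.setdefault(RejectionStage(rej.stage), []).append(rej)
    for stage, items in by_stage.items():
        plan.ensure_dirs()
        out_path = plan.error_path(stage)
        with gzip.open(out_path, "wt", encoding="utf-8") as fh:
            for rej in items:
                text = rej.record.raw_record or rej.record.molblock
                fh.write(text)
                if not text.endswith("\n"):
                    fh.write("\n")
                fh.write(f"> <Rejection_Stage>\n{stage.value}\n\n")
                fh.write(f"> <Rejection_Reason>\n{rej.reason}\n\n")
                fh.write("$$$$\n")
        written[stage] = out_path
    return written


def discover_inputs(pattern: str) -> list[Path]:
    """Expand an input glob; defaults favour ``*.sdf.gz`` but plain ``.sdf``
    files are accepted when named explicitly."""
    import glob as _glob

    paths = sorted(Path(p) for p in _glob.glob(pattern))
    return [p for p in paths if p.suffix in (".gz", ".sdf")]
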