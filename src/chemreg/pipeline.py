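"""Pipeline orchestration, chunking, reports and enrichment statistics.

Input files are processed in chunks (default 3000 records per
iteration); each chunk is independent — no operation may depend on
cross-record state — so chunks can be dispatched to parallel workers
while outputs stay deterministic regardless of worker count.  Every
iteration emits four result files (CH_SC, CH_CR, CH_UCR, CH_AC); error
files are written once per input file and only when non-empty.

The module also implements the canonicalization-enrichment analysis: a
Pearson chi-squared test (df=1, no continuity correction) on the 2x2
table of compounds whose unsalted Standard Compound differs from their
unsalted Canonical Representative, compared between two groups of
registry entries (e.g. approved drugs vs everything else).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from joblib import Parallel, delayed
from rdkit import Chem
from rdkit import RDLogger
from scipy import stats as _stats

from . import chemio
from .abstractor import make_abstract
from .canonicalizer import CanonicalizationConfig, canonical_representative
from .chemio import (
    HierarchyCompound,
    Level,
    MoleculeRecord,
    OutputPlan,
    RejectionRecord,
    RejectionStage,
)
from .checker import check_structure
from .hierarchy import Registry, RegistryEntry, register, write_registry
from .saltstrip import SaltDictionary, strip_salts
from .standardizer import standardize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_glob: str
    output_root: Path
    id_tag: str = chemio.DEFAULT_ID_TAG
    chunk_size: int = 3000
    jobs: int = 1
    canonicalization: CanonicalizationConfig = field(
        default_factory=CanonicalizationConfig)
    salts_file: Optional[Path] = None
    solvents_file: Optional[Path] = None
    seed: int = 0  # consumed by fixture generation only

    def __post_init__(self):
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass
class StageReport:
    input_records: int = 0
    parsed: int = 0
    parsing_errors: int = 0
    sanitization_errors: int = 0
    empty_molblock: int = 0
    standardization_errors: int = 0
    standardized: int = 0
    canonicalization_modified: int = 0
    new_structures: int = 0
    rejected_charged: int = 0
    salt_stripped: int = 0
    abstract_modified: int = 0
    registered: int = 0

    def reconciles(self) -> bool:
        """Per-stage counts must account for every input record."""
        return (
            self.input_records == self.parsed + self.parsing_errors
            and self.parsed == (self.standardized + self.sanitization_errors
                                + self.empty_molblock
                                + self.standardization_errors)
            and self.registered == self.standardized - self.rejected_charged
        )


def plan_chunks(n_records: int, chunk_size: int) -> tuple[int, int]:
    """(iterations, result files): four result files per iteration."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    iterations = math.ceil(n_records / chunk_size)
    return iterations, 4 * iterations


def config_from_yaml(path: Path, **overrides) -> PipelineConfig:
    """Load a YAML config mirroring the CLI flags; overrides win."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    canon_keys = {"heavy_atom_limit", "max_tautomers", "timeout_ms"}
    canon = {k: v for k, v in data.items() if k in canon_keys}
    base = {k: v for k, v in data.items() if k not in canon_keys}
    base.update({k: v for k, v in overrides.items() if v is not None})
    canon.update({k: overrides[k] for k in canon_keys
                  if overrides.get(k) is not None})
    base["canonicalization"] = CanonicalizationConfig(**canon)
    return PipelineConfig(**base)


# ---------------------------------------------------------------------------
# per-record / per-chunk processing


def process_record(
    record: MoleculeRecord,
    canon_cfg: CanonicalizationConfig,
    salt_dict: SaltDictionary,
) -> tuple[RegistryEntry, dict] | RejectionRecord:
    """Run stages 1-5 on one record.

    Returns the registry entry plus the four per-level structures (for
    file output), or the rejection that expelled the record.
    """
    checked = check_structure(record)
    if isinstance(checked, RejectionRecord):
        return checked
    sc = standardize(checked)
    if isinstance(sc, RejectionRecord):
        return sc
    cr = canonical_representative(sc, canon_cfg)
    if isinstance(cr, RejectionRecord):
        return cr
    ucr = strip_salts(cr, salt_dict)
    ac = make_abstract(ucr)
    usc = strip_salts(sc.structure, salt_dict)

    chiral = bool(Chem.FindMolChiralCenters(
        sc.structure, includeUnassigned=False,
        useLegacyImplementation=False))
    flags = dict(sc.flags)
    flags.update({
        "had_kekulization_fix": checked.had_kekulization_fix,
        "coordinates_generated": checked.coordinates_generated,
        "skipped_large": cr.skipped_large,
        "timed_out": cr.timed_out,
        "canonicalization_modified": cr.modified,
        "salt_stripped": ucr.stripped,
        "abstract_modified": ac.ids.nonstd_inchikey != ucr.ids.nonstd_inchikey,
    })
    flags.update(ucr.flags)
    entry = RegistryEntry(
        source_id=record.source_id,
        source_file=record.source_file,
        record_index=record.record_index,
        sc_key=sc.ids.nonstd_inchikey,
        cr_key=cr.ids.nonstd_inchikey,
        ucr_key=ucr.ids.nonstd_inchikey,
        ac_key=ac.ids.nonstd_inchikey,
        usc_key=usc.ids.nonstd_inchikey,
        chiral=chiral,
        flags=flags,
    )
    levels = {
        Level.SC: HierarchyCompound(Level.SC, sc.structure, record.source_id,
                                    sc.ids, flags),
        Level.CR: HierarchyCompound(Level.CR, cr.structure, record.source_id,
                                    cr.ids, flags),
        Level.UCR: HierarchyCompound(Level.UCR, ucr.structure,
                                     record.source_id, ucr.ids, flags),
        Level.AC: HierarchyCompound(Level.AC, ac.structure, record.source_id,
                                    ac.ids, flags),
    }
    return entry, levels


def _process_chunk(
    chunk: list[tuple[int, str, str, str, str]],
    output_root: str,
    base_name: str,
    iteration: int,
    id_tag: str,
    canon_cfg: CanonicalizationConfig,
    salt_dict: SaltDictionary,
) -> dict:
    """Worker: process one chunk and write its four level files.

    Records travel as (index, source_id, source_file, molblock, raw)
    tuples so the payload is cheap to pickle; rejections are returned the
    same way.
    """
    RDLogger.DisableLog("rdApp.*")
    entries: list[RegistryEntry] = []
    level_records: dict[Level, list[HierarchyCompound]] = {
        lv: [] for lv in Level}
    rejections: list[tuple[int, str, str, str, str, str, str]] = []

    for idx, source_id, source_file, molblock, raw in chunk:
        mol = Chem.MolFromMolBlock(molblock, sanitize=False, removeHs=False)
        record = MoleculeRecord(
            record_index=idx, source_id=source_id, source_file=source_file,
            molblock=molblock, parsed=mol,
            dimensionality=chemio._dimensionality(mol), raw_record=raw,
        )
        result = process_record(record, canon_cfg, salt_dict)
        if isinstance(result, RejectionRecord):
            rejections.append((idx, source_id, source_file, molblock, raw,
                               RejectionStage(result.stage).value,
                               result.reason))
            continue
        entry, levels = result
        entries.append(entry)
        for lv in Level:
            level_records[lv].append(levels[lv])

    plan = OutputPlan(output_root=Path(output_root), base_name=base_name,
                      iteration=iteration)
    written = []
    for lv in Level:
        path = chemio.write_level_file(level_records[lv], plan, lv, id_tag)
        if path is not None:
            written.append(str(path))
    return {
        "entries": entries,
        "rejections": rejections,
        "written": written,
        "iteration": iteration,
    }


def _rebuild_rejection(payload) -> RejectionRecord:
    idx, source_id, source_file, molblock, raw, stage, reason = payload
    rec = MoleculeRecord(record_index=idx, source_id=source_id,
                         source_file=source_file, molblock=molblock,
                         parsed=None, raw_record=raw)
    return RejectionRecord(rec, RejectionStage(stage), reason)


def run_pipeline(cfg: PipelineConfig) -> tuple[Registry, StageReport]:
    """Run the full five-stage pipeline over all matching input files."""
    RDLogger.DisableLog("rdApp.*")
    inputs = chemio.discover_inputs(cfg.input_glob)
    if not inputs:
        raise FileNotFoundError(f"no input files match {cfg.input_glob!r}")
    salt_dict = SaltDictionary.from_files(cfg.salts_file, cfg.solvents_file)
    output_root = Path(cfg.output_root)
    output_root.mkdir(parents=True, exist_ok=True)

    report = StageReport()
    all_entries: list[RegistryEntry] = []
    all_rejections: list[RejectionRecord] = []

    for path in inputs:
        base_name = path.name
        for suffix in (".sdf.gz", ".sdf"):
            if base_name.endswith(suffix):
                base_name = base_name[: -len(suffix)]
                break
        records, parse_rejections = chemio.read_sdf(path, cfg.id_tag)
        report.input_records += len(records) + len(parse_rejections)
        report.parsed += len(records)
        report.parsing_errors += len(parse_rejections)
        file_rejections = list(parse_rejections)

        payload = [
            (r.record_index, r.source_id, r.source_file, r.molblock,
             r.raw_record)
            for r in records
        ]
        chunks = [payload[i: i + cfg.chunk_size]
                  for i in range(0, len(payload), cfg.chunk_size)]
        results = Parallel(n_jobs=cfg.jobs)(
            delayed(_process_chunk)(
                chunk, str(output_root), base_name, iteration, cfg.id_tag,
                cfg.canonicalization, salt_dict,
            )
            for iteration, chunk in enumerate(chunks)
        )
        for res in results:
            all_entries.extend(res["entries"])
            file_rejections.extend(
                _rebuild_rejection(p) for p in res["rejections"])

        plan = OutputPlan(output_root=output_root, base_name=base_name)
        chemio.write_rejection_files(file_rejections, plan)
        all_rejections.extend(file_rejections)
        for rej in file_rejections:
            logger.info("rejected %s at %s: %s", rej.record.source_id,
                        RejectionStage(rej.stage).value, rej.reason)

    for rej in all_rejections:
        stage = RejectionStage(rej.stage)
        if stage is RejectionStage.SANITIZATION:
            report.sanitization_errors += 1
        elif stage is RejectionStage.EMPTY_MOLBLOCK:
            report.empty_molblock += 1
        elif stage is RejectionStage.STANDARDIZATION:
            report.standardization_errors += 1
        elif stage is RejectionStage.CHARGED_AFTER_CANONICALIZATION:
            report.rejected_charged += 1

    report.standardized = len(all_entries) + report.rejected_charged
    report.registered = len(all_entries)
    report.canonicalization_modified = sum(
        1 for e in all_entries if e.flags.get("canonicalization_modified"))
    sc_keys = {e.sc_key for e in all_entries}
    report.new_structures = len(
        {e.cr_key for e in all_entries
         if e.flags.get("canonicalization_modified")} - sc_keys)
    report.salt_stripped = sum(
        1 for e in all_entries if e.flags.get("salt_stripped"))
    report.abstract_modified = sum(
        1 for e in all_entries if e.flags.get("abstract_modified"))

    registry = register(all_entries, all_rejections)
    write_registry(registry, output_root)
    (output_root / "stage_report.json").write_text(
        json.dumps(asdict(report), indent=2) + "\n")
    return registry, report


# ---------------------------------------------------------------------------
# enrichment statistics


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: (a, b) = modified/unmodified in group 1; (c, d) in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def chi_squared_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) and upper-tail
    p-value; raises on a zero margin."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("chi-squared undefined: zero margin in the table")
    stat, p, dof, _ = _stats.chi2_contingency([[a, b], [c, d]],
                                              correction=False)
    assert dof == 1
    return float(stat), float(p)


@dataclass
class EnrichmentReport:
    n_a: int
    modified_a: int
    chiral_a: int
    n_b: int
    modified_b: int
    chiral_b: int
    chi2: float
    p_value: float

    @property
    def fraction_modified_a(self) -> float:
        return self.modified_a / self.n_a

    @property
    def fraction_modified_b(self) -> float:
        return self.modified_b / self.n_b

    @property
    def fraction_chiral_a(self) -> float:
        return self.chiral_a / self.n_a

    @property
    def fraction_chiral_b(self) -> float:
        return self.chiral_b / self.n_b


def enrichment_from_counts(
    n_a: int, modified_a: int, n_b: int, modified_b: int,
    chiral_a: int = 0, chiral_b: int = 0,
) -> EnrichmentReport:
    """Enrichment report straight from group totals and modified counts."""
    chi2, p = chi_squared_2x2(ContingencyTable2x2(
        modified_a, n_a - modified_a, modified_b, n_b - modified_b))
    return EnrichmentReport(n_a=n_a, modified_a=modified_a, chiral_a=chiral_a,
                            n_b=n_b, modified_b=modified_b, chiral_b=chiral_b,
                            chi2=chi2, p_value=p)


def canonicalization_enrichment(
    group_a: Iterable[RegistryEntry], group_b: Iterable[RegistryEntry]
) -> EnrichmentReport:
    """Compare canonicalization sensitivity between two entry groups.

    Structure uniqueness is taken at the unsalted-Standard-Compound level
    (so different salt forms of one compound count once); "modified" means
    the unsalted SC key differs from the unsalted CR key, i.e. the record
    was registered as a non-canonical tautomeric form.
    """
    def summarize(group: Iterable[RegistryEntry]) -> tuple[int, int, int]:
        unique: dict[str, RegistryEntry] = {}
        for e in group:
            unique.setdefault(e.usc_key or e.sc_key, e)
        n = len(unique)
        modified = sum(1 for k, e in unique.items() if k != e.ucr_key)
        chiral = sum(1 for e in unique.values() if e.chiral)
        return n, modified, chiral

    n_a, mod_a, chi_a = summarize(group_a)
    n_b, mod_b, chi_b = summarize(group_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    return enrichment_from_counts(n_a, mod_a, n_b, mod_b, chi_a, chi_b)
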