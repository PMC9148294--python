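"""Registry of per-record hierarchy keys and compound families.

Each accepted record is registered at all four levels (SC, CR, UCR, AC)
by its FixedH non-standard InChIKey; families are the partition of the
registry by abstract-level key.  Rejected records never enter the
registry — they live in the rejection log only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chemio import RejectionRecord

logger = logging.getLogger(__name__)


@dataclass
class RegistryEntry:
    source_id: str
    source_file: str
    record_index: int
    sc_key: str
    cr_key: str
    ucr_key: str
    ac_key: str
    usc_key: str = ""  # ad-hoc unsalted Standard Compound (for statistics)
    chiral: bool = False  # >=1 assigned tetrahedral stereocenter in the SC
    flags: dict = field(default_factory=dict)


@dataclass
class CompoundFamily:
    family_key: str
    members: list[RegistryEntry]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Registry:
    entries: list[RegistryEntry] = field(default_factory=list)
    rejections: list[RejectionRecord] = field(default_factory=list)

    def unique_count(self, level: str) -> int:
        attr = {"SC": "sc_key", "CR": "cr_key",
                "UCR": "ucr_key", "AC": "ac_key"}[level]
        return len({getattr(e, attr) for e in self.entries})


def register(
    entries: list[RegistryEntry], rejections: list[RejectionRecord]
) -> Registry:
    """Assemble the registry; duplicate source ids are kept with a warning."""
    seen: set[str] = set()
    for e in entries:
        if e.source_id in seen:
            logger.warning("duplicate source_id %r kept", e.source_id)
        seen.add(e.source_id)
    return Registry(entries=list(entries), rejections=list(rejections))


def build_families(registry: Registry) -> list[CompoundFamily]:
    """Partition registry entries by abstract-level FixedH InChIKey."""
    by_key: dict[str, list[RegistryEntry]] = {}
    for entry in registry.entries:
        by_key.setdefault(entry.ac_key, []).append(entry)
    return [CompoundFamily(k, members) for k, members in sorted(by_key.items())]


_REGISTRY_COLUMNS = [
    "source_id", "source_file", "record_index",
    "sc_key", "cr_key", "ucr_key", "ac_key", "family_key",
    "usc_key", "chiral", "flags",
]


def registry_frame(registry: Registry) -> pd.DataFrame:
    rows = []
    for e in registry.entries:
        rows.append({
            "source_id": e.source_id,
            "source_file": e.source_file,
            "record_index": e.record_index,
            "sc_key": e.sc_key,
            "cr_key": e.cr_key,
            "ucr_key": e.ucr_key,
            "ac_key": e.ac_key,
            "family_key": e.ac_key,
            "usc_key": e.usc_key,
            "chiral": e.chiral,
            "flags": ";".join(sorted(k for k, v in e.flags.items() if v)),
        })
    return pd.DataFrame(rows, columns=_REGISTRY_COLUMNS)


def families_frame(families: list[CompoundFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        rows.append({
            "family_key": fam.family_key,
            "n_members": len(fam),
            "n_unique_sc": len({m.sc_key for m in fam.members}),
            "n_unique_cr": len({m.cr_key for m in fam.members}),
            "n_unique_ucr": len({m.ucr_key for m in fam.members}),
            "member_source_ids": ";".join(m.source_id for m in fam.members),
        })
    return pd.DataFrame(rows, columns=[
        "family_key", "n_members", "n_unique_sc", "n_unique_cr",
        "n_unique_ucr", "member_source_ids",
    ])


def write_registry(registry: Registry, out_dir: Path) -> tuple[Path, Path]:
    """Write registry.tsv (one row per entry) and families.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reg_path = out_dir / "registry.tsv"
    fam_path = out_dir / "families.tsv"
    registry_frame(registry).to_csv(reg_path, sep="\t", index=False)
    families_frame(build_families(registry)).to_csv(fam_path, sep="\t",
                                                    index=False)
    return reg_path, fam_path
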