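"""Deterministic synthetic SDF corpora exercising every pipeline branch.

Each category is built from small hand-written SMILES templates — a
tautomer pair that must converge at the canonical-representative level,
salt forms that must converge after salt strip, stereo/E-Z/isotope
variants that must converge at the abstract level, structures the
checker must reject, and so on.  ``clean`` records are decorated
aromatics/aliphatics drawn deterministically from a seeded generator;
category-defining templates are never decorated, so every manifest
expectation holds by construction.  Generation is a pure function of
(seed, spec): the output file is byte-identical across runs.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem


@dataclass(frozen=True)
class FixtureSpec:
    clean: int = 0
    tautomer_pairs: int = 0
    salt_forms: int = 0
    stereo_pairs: int = 0
    ez_pairs: int = 0
    isotope_variants: int = 0
    charge_separated: int = 0
    metal_bonded: int = 0
    hypervalent_nitro: int = 0
    empty_molblock: int = 0
    bad_valence: int = 0
    bad_aromaticity: int = 0
    oversized: int = 0
    identical_fragment_pairs: int = 0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @property
    def total_records(self) -> int:
        pairs = (self.tautomer_pairs + self.salt_forms + self.stereo_pairs
                 + self.ez_pairs + self.isotope_variants)
        singles = (self.clean + self.charge_separated + self.metal_bonded
                   + self.hypervalent_nitro + self.empty_molblock
                   + self.bad_valence + self.bad_aromaticity + self.oversized
                   + self.identical_fragment_pairs)
        return 2 * pairs + singles


# --- category templates ----------------------------------------------------

# pairs converging at the Canonical Representative (distinct SC keys).
# All four are heteroatom proton-shift pairs that Standard InChI merges,
# so they also witness the FixedH layer's tautomer sensitivity.
TAUTOMER_PAIRS = [
    ("Oc1ccccn1", "O=c1cccc[nH]1"),        # 2-hydroxypyridine / 2-pyridone
    ("Oc1ccncc1", "O=c1cc[nH]cc1"),        # 4-hydroxypyridine / 4-pyridone
    ("Sc1ccccn1", "S=c1cccc[nH]1"),        # thiol / thione
    ("CC(N)=Nc1ccccc1", "CC(=N)Nc1ccccc1"),  # amidine drawings
]

# parent / salt form pairs converging at the UCR (free base/acid)
SALT_FORM_PAIRS = [
    ("CCN", "CCN.Cl"),
    ("OC(=O)c1ccccc1", "[O-]C(=O)c1ccccc1.[Na+]"),
    ("NCCc1ccccc1", "NCCc1ccccc1.Cc1ccc(S(=O)(=O)O)cc1"),
]

# enantiomer / unspecified pairs converging at the Abstract Compound
STEREO_PAIRS = [
    ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"),
    ("O[C@H](C)c1ccccc1", "OC(C)c1ccccc1"),
]

EZ_PAIRS = [
    ("C/C=C/C(=O)O", "C/C=C\\C(=O)O"),
    ("C/C=C/c1ccccc1", "C/C=C\\c1ccccc1"),
]

ISOTOPE_PAIRS = [
    ("CCO", "[13CH3]CO"),
    ("CC(=O)Nc1ccccc1", "[2H]C([2H])([2H])C(=O)Nc1ccccc1"),
]

CHARGE_SEPARATED = ["C[S+2]([O-])([O-])C", "CC[S+2]([O-])([O-])c1ccccc1"]
METAL_BONDED = ["CC(=O)O[Na]", "CC(=O)O[Bi](OC(C)=O)OC(C)=O"]
HYPERVALENT_NITRO = ["Cc1ccc(cc1)N(=O)=O", "O=N(=O)c1ccccc1"]
BAD_VALENCE = ["CN(C)(C)(C)=O"]          # hexavalent neutral nitrogen
BAD_AROMATICITY = ["c1cccc1"]            # unkekulizable all-carbon 5-ring
OVERSIZED = ["C" * 102]                  # 102 heavy atoms: above the gate
IDENTICAL_FRAGMENTS = ["CC(=O)Oc1ccccc1C(=O)O.CC(=O)Oc1ccccc1C(=O)O"]

_CLEAN_SCAFFOLDS = [
    "c1ccc({sub})cc1", "Cc1ccc({sub})cc1", "c1ccnc({sub})c1",
    "CCC({sub})CC", "CC(=O)N{sub_n}", "O=C(O)CC{sub_c}",
]
_CLEAN_SUBS = ["F", "Cl", "Br", "C", "CC", "CCC", "OC", "C#N", "C(F)(F)F",
               "CO", "CN", "SC", "CCO"]

EMPTY_MOLBLOCK_TEXT = """
  chemreg

  0  0  0  0  0  0  0  0  0  0999 V2000
M  END
"""


def _molblock(smiles: str) -> str:
    """SMILES -> V2000 molblock; falls back to the unsanitized route for
    deliberately broken templates (those keep their aromatic flags, which
    is part of what makes them broken)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        mol.UpdatePropertyCache(strict=False)
        AllChem.Compute2DCoords(mol)
        return Chem.MolToMolBlock(mol, kekulize=False)
    AllChem.Compute2DCoords(mol)
    return Chem.MolToMolBlock(mol)


def _clean_smiles(rng: random.Random) -> str:
    scaffold = rng.choice(_CLEAN_SCAFFOLDS)
    sub = rng.choice(_CLEAN_SUBS)
    return scaffold.format(sub=sub, sub_n=f"C{sub}" if not sub.startswith("C")
                           else sub, sub_c=sub if sub.startswith("C") else "C")


@dataclass
class _FixtureRecord:
    category: str
    smiles: str          # empty for the empty-molblock category
    molblock: str
    expected: str        # "ACCEPT" or a rejection stage name
    pair_id: str = ""
    pair_relation: str = ""   # same_cr | same_ucr | same_ac
    expect_flag: str = ""     # flag expected true on the registry entry


def _build_records(spec: FixtureSpec, rng: random.Random) -> list[_FixtureRecord]:
    records: list[_FixtureRecord] = []

    def add(category, smiles, expected="ACCEPT", **kw):
        mb = EMPTY_MOLBLOCK_TEXT if not smiles else _molblock(smiles)
        records.append(_FixtureRecord(category=category, smiles=smiles,
                                      molblock=mb, expected=expected, **kw))

    for i in range(spec.clean):
        add("clean", _clean_smiles(rng))
    pair_specs = [
        ("tautomer_pairs", spec.tautomer_pairs, TAUTOMER_PAIRS, "same_cr"),
        ("salt_forms", spec.salt_forms, SALT_FORM_PAIRS, "same_ucr"),
        ("stereo_pairs", spec.stereo_pairs, STEREO_PAIRS, "same_ac"),
        ("ez_pairs", spec.ez_pairs, EZ_PAIRS, "same_ac"),
        ("isotope_variants", spec.isotope_variants, ISOTOPE_PAIRS, "same_ac"),
    ]
    for category, count, templates, relation in pair_specs:
        for i in range(count):
            a, b = templates[i % len(templates)]
            pid = f"{category}_{i}"
            add(category, a, pair_id=pid, pair_relation=relation)
            add(category, b, pair_id=pid, pair_relation=relation)
    for i in range(spec.charge_separated):
        add("charge_separated", CHARGE_SEPARATED[i % len(CHARGE_SEPARATED)])
    for i in range(spec.metal_bonded):
        add("metal_bonded", METAL_BONDED[i % len(METAL_BONDED)])
    for i in range(spec.hypervalent_nitro):
        add("hypervalent_nitro",
            HYPERVALENT_NITRO[i % len(HYPERVALENT_NITRO)])
    for i in range(spec.empty_molblock):
        add("empty_molblock", "", expected="EMPTY_MOLBLOCK")
    for i in range(spec.bad_valence):
        add("bad_valence", BAD_VALENCE[i % len(BAD_VALENCE)],
            expected="SANITIZATION")
    for i in range(spec.bad_aromaticity):
        add("bad_aromaticity", BAD_AROMATICITY[i % len(BAD_AROMATICITY)],
            expected="SANITIZATION")
    for i in range(spec.oversized):
        add("oversized", OVERSIZED[i % len(OVERSIZED)],
            expect_flag="skipped_large")
    for i in range(spec.identical_fragment_pairs):
        add("identical_fragment_pairs",
            IDENTICAL_FRAGMENTS[i % len(IDENTICAL_FRAGMENTS)],
            expect_flag="salt_stripped")
    return records


def generate_fixtures(
    spec: FixtureSpec,
    out_dir: Path | str,
    seed: int = 0,
    base_name: str = "fixture",
    id_tag: str = "ID",
) -> tuple[Path, Path]:
    """Write ``<base_name>.sdf.gz`` and its manifest TSV; returns both paths.

    Records are shuffled into a seed-deterministic order; the manifest
    states each record's category and expected fate so a pipeline run
    over the file can be checked assertion by assertion.
    """
    RDLogger.DisableLog("rdApp.*")
    rng = random.Random(seed)
    records = _build_records(spec, rng)
    rng.shuffle(records)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sdf_path = out_dir / f"{base_name}.sdf.gz"
    manifest_path = out_dir / f"{base_name}_manifest.tsv"

    rows = []
    # mtime=0 keeps the gzip output byte-identical across runs
    with open(sdf_path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            for i, rec in enumerate(records):
                source_id = f"FX{i:06d}"
                text = rec.molblock
                if not text.endswith("\n"):
                    text += "\n"
                gz.write(text.encode("utf-8"))
                gz.write(f"> <{id_tag}>\n{source_id}\n\n$$$$\n".encode("utf-8"))
                rows.append({
                    "source_id": source_id,
                    "category": rec.category,
                    "smiles": rec.smiles,
                    "expected": rec.expected,
                    "pair_id": rec.pair_id,
                    "pair_relation": rec.pair_relation,
                    "expect_flag": rec.expect_flag,
                })
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return sdf_path, manifest_path


def default_mixed_spec() -> FixtureSpec:
    """A small corpus touching every pipeline branch (used by tests and
    the worked examples)."""
    return FixtureSpec(
        clean=12, tautomer_pairs=3, salt_forms=3, stereo_pairs=2, ez_pairs=2,
        isotope_variants=2, charge_separated=2, metal_bonded=2,
        hypervalent_nitro=2, empty_molblock=2, bad_valence=1,
        bad_aromaticity=1, oversized=1, identical_fragment_pairs=1,
    )
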