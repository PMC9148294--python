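"""Stage 4 — salt/solvent stripping (Unsalted Canonical Representative).

Multi-fragment organic records are reduced to their parent fragment in
four ordered moves: (1) every fragment found in the salt/solvent
dictionaries is removed regardless of size — this is what rescues cases
where the counterion is larger than the compound of interest, e.g. an
ethylamine tosylate; (2) of the survivors, fragments with strictly fewer
heavy atoms than the largest are dropped; (3) identical duplicate
fragments collapse to the first; (4) the surviving parent is
neutralized.  Inorganic records (no C-C or C-H bond anywhere) and
single-fragment organics are passed through untouched, and stripping
never deletes everything: if it would, the first original fragment is
kept and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem

from .canonicalizer import CanonicalRepresentative
from .identifiers import IdentifierBundle, identifier_bundle
from .standardizer import extra_neutralize


def _canon(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _load_smiles_list(lines: Iterable[str]) -> list[str]:
    out = []
    for line in lines:
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        canon = _canon(entry)
        if canon is not None:
            out.append(canon)
    return out


@dataclass(frozen=True)
class SaltDictionary:
    """Canonical-SMILES membership lists for counterions and solvents."""

    inorganic_ions: frozenset[str]
    organic_salts: frozenset[str]
    solvents: frozenset[str]

    @property
    def all_entries(self) -> frozenset[str]:
        return self.inorganic_ions | self.organic_salts | self.solvents

    @classmethod
    def from_lists(cls, salts: Iterable[str], solvents: Iterable[str]
                   ) -> "SaltDictionary":
        """Build from SMILES lists; salt entries are routed to the
        inorganic or organic set by the carbon-skeleton rule."""
        inorganic, organic = [], []
        for smi in _load_smiles_list(salts):
            mol = Chem.MolFromSmiles(smi)
            (organic if is_organic(mol) else inorganic).append(smi)
        return cls(
            inorganic_ions=frozenset(inorganic),
            organic_salts=frozenset(organic),
            solvents=frozenset(_load_smiles_list(solvents)),
        )

    @classmethod
    def from_files(cls, salts_file: Path | str | None = None,
                   solvents_file: Path | str | None = None
                   ) -> "SaltDictionary":
        """Load from plain-text SMILES files (one per line, ``#`` comments);
        packaged seed lists are used where a file is not given."""
        if salts_file is None:
            salts = resources.files("chemreg.data").joinpath(
                "salts.smi").read_text().splitlines()
        else:
            salts = Path(salts_file).read_text().splitlines()
        if solvents_file is None:
            solvents = resources.files("chemreg.data").joinpath(
                "solvents.smi").read_text().splitlines()
        else:
            solvents = Path(solvents_file).read_text().splitlines()
        return cls.from_lists(salts, solvents)

    @classmethod
    def default(cls) -> "SaltDictionary":
        return cls.from_files()


@dataclass
class UnsaltedCanonicalRepresentative:
    structure: Chem.Mol
    ids: IdentifierBundle
    stripped: bool = False
    stripped_fragments: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    cr: CanonicalRepresentative | None = None


def is_organic(mol: Chem.Mol) -> bool:
    """True iff any fragment has a carbon-hydrogen or carbon-carbon bond."""
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetTotalNumHs() > 0:
            return True
        if any(n.GetAtomicNum() == 6 for n in atom.GetNeighbors()):
            return True
    return False


def strip_salts(
    cr: CanonicalRepresentative | Chem.Mol,
    dictionary: SaltDictionary | None = None,
) -> UnsaltedCanonicalRepresentative:
    """Strip salts/solvents from a canonical representative.

    Also applicable directly to any standardized structure (a plain Mol),
    which is how the ad-hoc "unsalted Standard Compound" used by the
    enrichment statistics is produced.
    """
    dictionary = dictionary or SaltDictionary.default()
    mol = cr.structure if isinstance(cr, CanonicalRepresentative) else cr
    flags: dict = {}
    stripped_fragments: list[str] = []

    frags = list(Chem.GetMolFrags(mol, asMols=True))
    if not is_organic(mol) or len(frags) <= 1:
        out = Chem.Mol(mol)
        return UnsaltedCanonicalRepresentative(
            structure=out, ids=identifier_bundle(out), stripped=False,
            cr=cr if isinstance(cr, CanonicalRepresentative) else None,
        )

    frag_smiles = [Chem.MolToSmiles(f) for f in frags]

    # 1. dictionary strip — removes matching fragments regardless of size
    survivors = []
    for frag, smi in zip(frags, frag_smiles):
        if smi in dictionary.all_entries:
            stripped_fragments.append(smi)
        else:
            survivors.append((frag, smi))

    if not survivors:
        # stripping would delete everything: keep the first original fragment
        survivors = [(frags[0], frag_smiles[0])]
        stripped_fragments = frag_smiles[1:]
        flags["kept_first_fallback"] = True

    # 2. size fallback — drop fragments strictly smaller than the largest
    if len(survivors) > 1:
        largest = max(f.GetNumHeavyAtoms() for f, _ in survivors)
        smaller = [s for f, s in survivors if f.GetNumHeavyAtoms() < largest]
        stripped_fragments.extend(smaller)
        survivors = [(f, s) for f, s in survivors
                     if f.GetNumHeavyAtoms() == largest]

    # 3. identical fragments collapse to the first; distinct equal-sized
    #    fragments have no principled winner — pick deterministically, flag
    if len(survivors) > 1:
        distinct = sorted(set(s for _, s in survivors))
        if len(distinct) > 1:
            flags["ambiguous_parent"] = True
        winner_smiles = distinct[0]
        keep = next(f for f, s in survivors if s == winner_smiles)
        stripped_fragments.extend(s for f, s in survivors if f is not keep)
        survivors = [(keep, winner_smiles)]

    parent = Chem.Mol(survivors[0][0])

    # 4. neutralize the survivor (no counterions remain to balance it)
    if Chem.GetFormalCharge(parent) != 0:
        parent, neutralized = extra_neutralize(parent)
        flags["neutralized_after_strip"] = neutralized

    stripped = bool(stripped_fragments)
    return UnsaltedCanonicalRepresentative(
        structure=parent,
        ids=identifier_bundle(parent),
        stripped=stripped,
        stripped_fragments=stripped_fragments,
        flags=flags,
        cr=cr if isinstance(cr, CanonicalRepresentative) else None,
    )
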