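"""Tautomer-sensitive identity: Standard vs FixedH non-standard InChIKey.

2-hydroxypyridine and 2-pyridone are one compound drawn as two
tautomers.  Standard InChI merges them (one key), so it cannot tell the
registered forms apart; the non-standard FixedH InChI adds a fixed-
hydrogen layer that distinguishes them.  The canonicalizer then picks
one deterministic representative so both register under one Canonical
Representative key.
"""

from rdkit import Chem

from chemreg import (
    canonical_representative,
    check_structure,
    identifier_bundle,
    standardize,
)
from chemreg.chemio import MoleculeRecord
from rdkit.Chem import AllChem

PAIR = ("Oc1ccccn1", "O=c1cccc[nH]1")

for smiles in PAIR:
    mol = Chem.MolFromSmiles(smiles)
    ids = identifier_bundle(mol)
    print(f"{smiles:16s} Standard: {ids.std_inchikey}   "
          f"FixedH: {ids.nonstd_inchikey}")

print()
for smiles in PAIR:
    mol = Chem.MolFromSmiles(smiles)
    AllChem.Compute2DCoords(mol)
    molblock = Chem.MolToMolBlock(mol)
    record = MoleculeRecord(0, smiles, "<demo>", molblock,
                            Chem.MolFromMolBlock(molblock, sanitize=False))
    sc = standardize(check_structure(record))
    cr = canonical_representative(sc)
    print(f"{smiles:16s} -> canonical representative "
          f"{Chem.MolToSmiles(cr.structure):16s} {cr.ids.nonstd_inchikey}"
          f"{'   (modified)' if cr.modified else ''}")

# The Standard keys above are identical and the FixedH keys differ,
# while both inputs converge to a single Canonical Representative key:
# that key is what links the two registered forms into one hierarchy.
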