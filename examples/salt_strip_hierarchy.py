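"""Four-level hierarchy of a salt form: sodium benzoate to benzoic acid.

A covalently drawn sodium benzoate is standardized to a preserved ion
pair (Standard Compound), canonicalized (Canonical Representative),
stripped of the sodium counterion and neutralized (Unsalted Canonical
Representative), and finally cleared of stereo/isotopes (Abstract
Compound) — the level at which salt forms of one parent share a key.
"""

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")  # silence per-rule standardization chatter

from chemreg import (
    SaltDictionary,
    canonical_representative,
    check_structure,
    make_abstract,
    standardize,
    strip_salts,
)
from chemreg.chemio import MoleculeRecord

smiles = "O=C(O[Na])c1ccccc1"   # covalent O-Na bond, as often deposited
mol = Chem.MolFromSmiles(smiles)
AllChem.Compute2DCoords(mol)
molblock = Chem.MolToMolBlock(mol)
record = MoleculeRecord(0, "sodium-benzoate", "<demo>", molblock,
                        Chem.MolFromMolBlock(molblock, sanitize=False))

sc = standardize(check_structure(record))
cr = canonical_representative(sc)
ucr = strip_salts(cr, SaltDictionary.default())
ac = make_abstract(ucr)

print(f"input:                      {smiles}")
print(f"SC  (standard compound):    {Chem.MolToSmiles(sc.structure):28s}"
      f" {sc.ids.nonstd_inchikey}")
print(f"CR  (canonical tautomer):   {Chem.MolToSmiles(cr.structure):28s}"
      f" {cr.ids.nonstd_inchikey}")
print(f"UCR (free acid):            {Chem.MolToSmiles(ucr.structure):28s}"
      f" {ucr.ids.nonstd_inchikey}")
print(f"AC  (family key structure): {Chem.MolToSmiles(ac.structure):28s}"
      f" {ac.ids.nonstd_inchikey}")
print(f"stripped fragments:         {ucr.stripped_fragments}")

# The SC keeps the balanced ion pair (faithful to the registered salt
# form); the free acid only appears at the UCR level, and the AC key is
# what benzoic acid itself would also receive.
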