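# Methods

## Problem and model

Public bioactivity resources register the "same" compound in different
forms: tautomeric drawings, salt forms and solvates, defined and
undefined stereochemistry, isotope labels. A registry that keys
structures naively (by SMILES, or by Standard InChI) either splits one
compound's data across several entries or silently merges forms whose
data are not interchangeable. chemreg resolves this with a four-level
hierarchy computed per record:

| level | meaning | produced by |
|---|---|---|
| SC  | Standard Compound: checked, rule-standardized, salt form preserved | checker + standardizer |
| CR  | Canonical Representative: one deterministic tautomer per compound | canonicalizer |
| UCR | Unsalted CR: free base/acid, single fragment | salt strip + neutralization |
| AC  | Abstract Compound: stereo- and isotope-agnostic family key | abstractor |

Records sharing an AC-level key form a compound family; within a family
the per-level keys tell the user exactly *how* two entries differ
(tautomer only, salt only, stereochemistry, ...). Data are never merged
by the pipeline — the hierarchy exists to alert, not to aggregate.

## Identity

Uniqueness at every level is the InChIKey of the non-standard InChI
generated with the `/FixedH` option. The fixed-hydrogen layer pins
mobile hydrogens to their drawn positions, so tautomers that Standard
InChI collapses into one string receive distinct keys; for molecules
without mobile hydrogens the FixedH core layers coincide with the
standard ones. Equality of the FixedH key is the only deduplication
relation in the package; canonical SMILES and Standard InChI/Key are
written to outputs as metadata.

One deliberate invariant: identifiers are computed from the molecular
graph and its assigned stereo tags only — conformers are stripped from
the working copy first. The InChI engine otherwise re-perceives stereo
from raw coordinates, which would make a structure's key depend on
whether it happens to carry a drawing (observed concretely: freshly
generated 2D coordinates resurrected double-bond geometry the
abstractor had just cleared). Stereo a record legitimately has is
perceived into tags (from wedges or from 3D geometry) before any
identifier is generated.

## Stage behaviour and defaults

**Checker.** Kekulization is attempted before sanitization
(`Kekulize(clearAromaticFlags=True)` then full sanitization); if that
path fails, plain sanitization is tried, and only a structure failing
both is rejected. This rescues molblocks whose aromatic bond flags
would otherwise trip aromaticity perception, and guarantees that adding
the kekulization step never loses a structure plain sanitization would
accept. Valence checking follows RDKit's default valence model; the
parser's built-in cleanup already fixes hypervalent nitro groups, so
those are corrected rather than rejected, while genuinely wrong
valences (e.g. a neutral pentavalent non-nitro nitrogen) and
unkekulizable aromatic systems are expelled with stage SANITIZATION.
Wedge marks on non-stereocenters are dropped
(`AssignStereochemistry(cleanIt=True)`), keeping the record. Empty
molblocks go to `No_structures/`.

**Standardizer.** `rdMolStandardize.Cleanup` supplies the normalization
rule set (the established cleanup rule collection; writing new
transforms is explicitly out of scope), charge recombination, metal
disconnection and re-ionization. Two safety nets follow. (1)
*extra neutralization*: structures whose net formal charge is non-zero
after cleanup are passed through the Uncharger; net-zero structures —
neutral molecules, zwitterions and balanced ion pairs — are left alone,
so a carboxylate·Na⁺ pair survives to the salt-strip stage and the free
acid only appears at UCR level. Permanent charges (quaternary N)
survive, flagged. (2) *residual metal-bond breaking*: any remaining
covalent single bond between a metal (alkali, alkaline-earth,
transition rows, and Al/Ga/In/Tl/Sn/Pb/Bi) and O/N/S becomes an ion
pair with +1 on the metal and −1 on the heteroatom per broken bond, so
total formal charge is conserved; metal–carbon bonds (true
organometallics) are out of scope for this pass. Stereochemistry is
assigned from 3D geometry when the input record carries 3D coordinates,
overriding wedge-derived marks; degenerate neighborhoods are left
unassigned. Validation (round-trippable molblock + successful
identifier generation) gates the SC output; failures reject with stage
STANDARDIZATION.

**Canonicalizer.** Defaults: heavy-atom limit 100, at most 30
tautomers, 250 ms per-record budget. Enumeration uses RDKit's tautomer
enumerator with "remove sp3 stereo" and "remove bond stereo" disabled;
because the enumerator can nonetheless tautomerize *through* a
stereocenter or emit chemically invalid states, enumerants are filtered:
any candidate that changes net formal charge, the assigned-stereocenter
count, or the assigned double-bond-stereo count, or that fails a
canonical-SMILES round trip, is discarded. If nothing but the input
survives, the input tautomer passes through (protection beats
canonicalization — a conservative choice that favours fidelity to the
registered stereochemistry). The representative is the maximum-scoring
survivor under the established aromaticity-favouring tautomer score,
with ties broken by lexicographically smallest canonical SMILES, making
the pick deterministic and independent of enumeration order. The chosen
tautomer is round-tripped through canonical SMILES before identifier
generation (enumerant objects can carry stale internal state).
Structures above the heavy-atom limit skip the stage unchanged
(`skipped_large`); the time budget is checked after enumeration and
between enumerant evaluations — the underlying enumeration call itself
is not preemptible — and on expiry the SC passes through flagged
(`timed_out`), never rejected. A multi-fragment (salted) record whose
organic-fragment net charge differs between SC and CR is rejected with
stage CHARGED_AFTER_CANONICALIZATION: such charge shifts are
registration artifacts, not chemistry.

**Salt strip.** Only organic (any C–C or C–H bond), multi-fragment
structures are processed; inorganics and single fragments pass through.
Order of operations: (1) remove every fragment whose canonical SMILES
is in the salt/solvent dictionaries — dictionary membership beats
relative size, which is what rescues parents smaller than their
counterion (ethylamine tosylate); (2) among survivors, drop fragments
with strictly fewer heavy atoms than the largest; (3) identical
duplicates collapse to the first; distinct equal-sized survivors have
no principled winner, so the lexicographically smallest canonical
SMILES is kept and the entry flagged `ambiguous_parent`; (4) the
survivor is neutralized (no counterions remain to balance it).
Stripping never deletes everything: if every fragment is a dictionary
entry, the first original fragment is kept and flagged. The shipped
dictionaries (`data/salts.smi`, `data/solvents.smi`) are editable
plain-text SMILES lists (~100 common counterions and solvents, charged
and neutral forms listed separately); salt entries are routed to the
inorganic or organic set by the same carbon-skeleton rule. "Smaller" is
measured in heavy atoms, not SMILES string length, which is
dialect-dependent. The same operation applied to an SC yields the
ad-hoc "unsalted Standard Compound" used by the enrichment statistic.

**Abstractor.** Isotope mass numbers are zeroed, tetrahedral parities
and double-bond stereo (cis/trans flags and E/Z specifications) are
removed, residual directional-bond slashes are stripped from the
canonical SMILES as a belt-and-braces pass, and 2D coordinates are
regenerated so no wedge artifacts survive in written molblocks. The AC
inherits the CR's tautomer; stage 5 does not re-canonicalize. In
written output, stereogenic double bonds without defined stereo are
marked "crossed" (explicitly undefined) by the writer, which is what
preserves FixedH keys through write/read round trips.

## Batch contract

Inputs are processed in chunks (default 3000 records per iteration —
large enough to amortize per-chunk overhead, small enough to bound
worker memory). Each chunk is independent: no operation may read
cross-record state, so chunks can be dispatched to parallel workers
(`jobs`) with outputs — level files, registry, families — byte-identical
regardless of worker count. Per input file and iteration, exactly four
result files are written (`<base>_CH_{SC,CR,UCR,AC}_<iteration>.sdf.gz`,
so a 7000-record file yields 12); error files
(`_SDF_Parsing_Errors`, `_Sanitisation_Errors`, `_Standardization_Errors`,
`_Canonicalization_Errors`, and `_No_Structures` for empty molblocks)
are written once per input file and only when non-empty. `registry.tsv`
(per-record keys + flags), `families.tsv` and `stage_report.json` go to
the output root so the Results directory holds only structure files.
SD tags are written in a fixed order to keep outputs byte-comparable.
The stage report reconciles exactly: parsed = standardized +
sanitization + empty + standardization errors, and registered =
standardized − charged-after-canonicalization.

## Enrichment statistic

To compare canonicalization sensitivity between two groups (e.g.
approved drugs vs all other compounds), each group is reduced to unique
structures at the unsalted-SC level (so salt forms of one compound count
once), "modified" means the unsalted-SC key differs from the
unsalted-CR key, and the 2×2 modified/unmodified table is tested with
Pearson's χ² (df = 1). No continuity correction is applied: the
statistic targets the large-count regime this analysis is used in, and
the implementation refuses tables with a zero margin. Chirality counts
(entries with ≥1 assigned tetrahedral center in the SC) are reported
alongside, untested.

## Synthetic data

The fixtures module generates SDF corpora as a pure function of
(seed, category counts); the gzip stream is written with a zeroed
timestamp so identical inputs give byte-identical files. Categories are
built from small hand-written SMILES templates: tautomer pairs chosen
to be merged by Standard InChI (2-/4-pyridone, pyridinethione, amidine
drawings) so they witness both CR convergence and FixedH sensitivity;
salt forms (hydrochloride, sodium benzoate, a tosylate larger than its
ethylamine-like parent); enantiomer/racemate, E/Z and isotopologue
pairs; charge-separated sulfones; covalent Na/Bi metal bonds;
hypervalent nitro; and checker-rejection categories (empty molblock,
bad valence, unkekulizable aromatic ring, a 102-carbon chain above the
heavy-atom gate, duplicate-fragment records). Clean records are
decorated aromatics/aliphatics drawn from a seeded generator;
category-defining templates are never decorated. Each file ships with a
manifest stating every record's category, expected fate and expected
key relations, and the test suite asserts the pipeline satisfies every
manifest line.

What the generator does *not* emulate: the error modes of real
depositor files (mangled counts lines beyond the one synthesized in
tests, nonstandard valence conventions, V3000 blocks), realistic
chemical-space property distributions, and very large/complex
structures where tautomer enumeration strains the time budget. Passing
tests therefore demonstrate the contracts of the pipeline's logic, not
corpus-level rejection or modification *rates* on any real database.

## Known limitations

- Tautomer canonicalization inherits RDKit's enumerator limitations;
  the protection filter favours fidelity over canonicalization, so some
  genuinely equivalent forms with drawn double-bond geometry will not
  converge (they still meet at the AC level).
- The 250 ms budget cannot interrupt a single long enumeration call;
  pathological structures may overrun it before being flagged.
- Sulfur valence handling follows RDKit's defaults, which accept some
  unusual valences other pipelines reject.
- The salt dictionaries are seed lists, not exhaustive; records whose
  counterion is missing fall back to the size rule, which keeps the
  counterion whenever it is the largest fragment and not listed.
- Multi-API mixtures are out of scope: a record with two distinct
  equal-sized actives yields a flagged, deterministic but arbitrary
  parent.
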