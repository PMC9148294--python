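# chemreg

A chemical registration and standardization pipeline for small-molecule
batches. It converts heterogeneous SDF inputs — the same compound often
arrives from different databases as different tautomers, salt forms,
stereoisomers or isotopologues — into a four-level compound hierarchy so
that all registered forms of one compound can be linked and their
bioactivity data explored together.

## Who it is for

Maintainers of compound registries and integrative bioactivity
databases, and anyone who needs deterministic, traceable structure
standardization with tautomer-aware deduplication: the same molecule
deposited twice in different drawings must map to the same key, and
related forms (salts, stereoisomers) must land in the same family
without being silently merged.

## The model

Five sequential stages process each record:

1. **Checker** — parse V2000 molblocks, drop records with empty
   molblocks, kekulize ahead of sanitization (rescuing many
   aromatic-flag artifacts), reject unfixable valence/aromaticity
   errors, clean impossible wedge marks, generate 2D coordinates where
   absent.
2. **Standardizer** → *Standard Compound (SC)* — rule-based cleanup
   (functional-group normalization such as N(=O)=O → [N+](=O)[O−] and
   O⁻–S²⁺–O⁻ → O=S=O, charge recombination, metal-bond disconnection,
   re-ionization with the strongest acid first, neutralization), a
   second neutralization pass for unbalanced residual charges, breaking
   of residual covalent metal–O/N/S bonds into charge-balanced ion
   pairs, and stereo assignment preferring 3D geometry when the input
   provides it. Balanced ion pairs (e.g. carboxylate·Na⁺) are kept: the
   SC stays faithful to the registered salt form.
3. **Canonicalizer** → *Canonical Representative (CR)* — deterministic
   canonical tautomer selection (at most 30 enumerated tautomers,
   aromaticity-favouring score, lexicographic SMILES tie-break)
   protecting net charge, aromaticity, assigned tetrahedral
   stereocenters and assigned double-bond stereo. Structures with more
   than 100 heavy atoms skip this stage; a 250 ms per-record budget caps
   enumeration time; salted records whose organic fragment changes net
   charge during canonicalization are rejected as artifacts.
4. **Salt strip** → *Unsalted Canonical Representative (UCR)* —
   dictionary-based removal of counterions/solvents (which handles
   counterions larger than the parent), a largest-fragment fallback,
   collapse of identical duplicate fragments, then neutralization of the
   surviving parent. Inorganic records are never stripped.
5. **Abstractor** → *Abstract Compound (AC)* — clear tetrahedral
   stereo, cis/trans and E/Z double-bond stereo, and isotope labels.
   Compound **families** are the partition of the registry by
   AC-level key.

Identity at every level is the **FixedH non-standard InChIKey**: the
InChI generated with the `/FixedH` option adds a fixed-hydrogen layer
that distinguishes tautomers the Standard InChI merges, so the key is
tautomer-sensitive. SMILES and Standard InChI are carried as metadata,
never as identity.

The package also computes a canonicalization-enrichment statistic
between two compound groups: per group, the unique structures (at the
unsalted-SC level) whose unsalted standard form differs from their
unsalted canonical form, compared with a Pearson χ² test (df = 1, no
continuity correction) on the resulting 2×2 table.

## Worked example

```bash
python examples/tautomer_identity.py
```

```
Oc1ccccn1        Standard: UBQKCCHYAOITMY-UHFFFAOYSA-N   FixedH: UBQKCCHYAOITMY-QDQILVOLNA-N
O=c1cccc[nH]1    Standard: UBQKCCHYAOITMY-UHFFFAOYSA-N   FixedH: UBQKCCHYAOITMY-BRMMOCHJNA-N

Oc1ccccn1        -> canonical representative O=c1cccc[nH]1    UBQKCCHYAOITMY-BRMMOCHJNA-N   (modified)
O=c1cccc[nH]1    -> canonical representative O=c1cccc[nH]1    UBQKCCHYAOITMY-BRMMOCHJNA-N
```

2-hydroxypyridine and 2-pyridone share one Standard InChIKey (the
standard identifier cannot tell the deposited forms apart) but carry
distinct FixedH keys; canonicalization then maps both onto the single
representative key `UBQKCCHYAOITMY-BRMMOCHJNA-N`, which is what links
the two registered forms — and any data attached to them — into one
hierarchy. The other examples show the full batch pipeline
(`standardize_batch.py`), the four-level hierarchy of a salt form
(`salt_strip_hierarchy.py`, sodium benzoate → benzoic acid parent) and
the enrichment statistic (`enrichment_stats.py`).

## Command line

```bash
chemreg fixtures --seed 3 --out demo            # synthetic test corpus
chemreg run --input "demo/*.sdf.gz" --out out \
    [--chunk-size 3000 --jobs 4 --heavy-atom-limit 100 \
     --max-tautomers 30 --timeout-ms 250 --id-tag ID \
     --salts FILE --solvents FILE --config cfg.yaml]
chemreg report --registry out/registry.tsv
chemreg enrich --registry A/registry.tsv --registry-b B/registry.tsv
```

`run` processes inputs in chunks of 3000 records per iteration and
writes, per input file and iteration, four gzipped SDF result files
(`<base>_CH_SC_<i>.sdf.gz`, `_CH_CR_`, `_CH_UCR_`, `_CH_AC_`) into
`Results/`, plus `registry.tsv` (one row per accepted record with all
four level keys and the family key) and `families.tsv` at the output
root. Rejected records go verbatim to `Errors/` (parsing,
sanitisation, standardization, canonicalization) or `No_structures/`
(empty molblocks), only when non-empty. Outputs are deterministic and
independent of `--jobs`.

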