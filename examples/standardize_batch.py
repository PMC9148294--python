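"""Run the full five-stage pipeline over a small synthetic SDF batch.

Builds a mixed corpus (clean molecules, tautomer pairs, salt forms,
stereo variants, deliberately broken records), processes it, and prints
the stage report and the resulting compound families.
"""

import tempfile
from pathlib import Path

from chemreg import (
    PipelineConfig,
    build_families,
    default_mixed_spec,
    generate_fixtures,
    run_pipeline,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    sdf, manifest = generate_fixtures(default_mixed_spec(), tmp / "in",
                                      seed=7)
    registry, report = run_pipeline(
        PipelineConfig(input_glob=str(sdf), output_root=tmp / "out"))

    print(f"input records:        {report.input_records}")
    print(f"registered:           {report.registered}")
    print(f"rejected (sanitization/empty/standardization): "
          f"{report.sanitization_errors}/{report.empty_molblock}/"
          f"{report.standardization_errors}")
    print(f"modified by canonicalization: {report.canonicalization_modified}")
    print(f"salt-stripped:        {report.salt_stripped}")
    print(f"unique keys SC/CR/UCR/AC: "
          f"{registry.unique_count('SC')}/{registry.unique_count('CR')}/"
          f"{registry.unique_count('UCR')}/{registry.unique_count('AC')}")

    families = build_families(registry)
    multi = [f for f in families if len(f) > 1]
    print(f"families: {len(families)} ({len(multi)} with >1 member)")
    for fam in multi[:5]:
        print(f"  {fam.family_key}: "
              f"{[m.source_id for m in fam.members]}")

# Every record lands in the registry or a rejection log; families group
# records whose abstract (salt/stereo/isotope-agnostic) structure is the
# same, so tautomers and salt forms of one compound share a family.
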