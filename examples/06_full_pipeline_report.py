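"""The full three-phase pipeline, from event CSV to report bundle.

Simulates a cohort to CSV files, runs the pipeline exactly as the command
line would, and prints the headline rows of the report tables.
"""

import tempfile
from pathlib import Path

import inactigraphy as ig

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = ig.scenario("taxonomy_mixture", n_participants=40, n_days=7, seed=3)
    ig.write_cohort(ig.simulate_cohort(cfg), tmp / "cohort")

    tables = ig.run_pipeline(ig.PipelineConfig(
        events_path=tmp / "cohort" / "events.csv",
        demographics_path=tmp / "cohort" / "demographics.csv",
        out_dir=tmp / "report"))

    print("cohort composition (gender block):")
    ct = tables["cohort_table"]
    print(ct[ct["grouping"] == "gender"].to_string(index=False))

    print("\nnocturnal inactivity by stratum (overall row):")
    it = tables["inactivity_table"]
    print(it[it["grouping"] == "all"].round(2).to_string(index=False))

    print("\nfiles written:")
    for p in sorted((tmp / "report").iterdir()):
        print(" ", p.name)

print(
    "\nPhase 1 describes the cohort and its usage, phase 2 compares usage\n"
    "and night-gap indicators across demographic strata, phase 3 reports\n"
    "usage-gap associations; every exclusion is counted in run.log."
)
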