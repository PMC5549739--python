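#!/usr/bin/env python
"""Run the full catalog -> prune -> score -> sign-test pipeline on both
simulated cohorts from 01_simulate_cohorts.py and print the reports.

Under neutrality the sign test should usually accept (p > 0.05); under the
selection regime the focal group's mean GRS exceeds the reference's and the
sign test rejects decisively.
"""

from pathlib import Path

from signburden.pipeline import RunConfig, report_render, run

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

for name in ("neutral", "selected"):
    sim = SCRATCH / "sim" / name
    if not sim.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    report = run(RunConfig(
        catalog=str(sim / "catalog.tsv"),
        vcf=str(sim / "genotypes.vcf"),
        panel=str(sim / "panel.txt"),
        outdir=str(BASE / f"run_{name}"),
        focal_group="GRPA",
        reference_group="GRPB",
    ))
    print(f"\n=== {name} cohort ===")
    print(report_render(report))
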