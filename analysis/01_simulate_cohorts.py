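#!/usr/bin/env python
"""Emit the two study datasets: a neutral-drift cohort pair and a
selection-regime pair (logit shift delta = 1 in the focal population).

Both use 147 unlinked risk variants, 300 individuals per population and
F_ST = 0.15; the (large) raw datasets land under scratch/sim/{neutral,selected}/.
"""

from pathlib import Path

from signburden.simulate import SimConfig, emit_dataset

RESULTS = Path(__file__).resolve().parent.parent / "scratch" / "sim"

for name, delta, seed in [("neutral", 0.0, 101), ("selected", 1.0, 102)]:
    cfg = SimConfig(n_variants=147, n_per_pop=300, fst=0.15, delta=delta, seed=seed)
    out = emit_dataset(cfg, RESULTS / name)
    print(f"{name}: wrote {out.vcf_path}")
    print(f"  truth mean f_focal - f_ref = "
          f"{(out.truth['f_focal'] - out.truth['f_ref']).mean():+.4f}")
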