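#!/usr/bin/env python
"""Generate one example synthetic session per stimulation condition.

Writes raw stimulated + blank TIFF stacks with ground truth under
scratch/demo/data/<condition>/ so the later stages can be run file-to-file
(large binary stacks go under scratch/, not results/).
The full-study tables (six sessions per condition) are produced by
03_run_study.py directly through the library.
"""
from pathlib import Path

from vsdpop import io
from vsdpop.pipeline import simulate_condition

OUT = Path("scratch/demo/data")

for group, pulse in [("short_exp", 10.0), ("long_exp", 10.0), ("icms", 20.0)]:
    stim_stack, blank_stack, truth = simulate_condition(
        group, pulse, seed=1, n_stim_trials=8, n_blank_trials=6,
        session_id=f"{group}_demo")
    d = io.save_session(OUT / group, stim_stack, blank_stack, truth)
    print(f"{group}: wrote {stim_stack.n_trials} stimulated + "
          f"{blank_stack.n_trials} blank trials "
          f"(peak dF/f {truth.resp.amplitude:.2e}) -> {d}")
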