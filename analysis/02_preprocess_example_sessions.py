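#!/usr/bin/env python
"""Preprocess the example sessions of 01 into clean dF/f movies.

Frame-zero division, blank subtraction, trial averaging, then removal of
the laser-artifact frames (t = 0, 10 ms; opto only) and bleached pixels
near the fiber tip.  Writes scratch/demo/dff/<condition>/ and reports how much
data each masking step removed.
"""
from pathlib import Path

from vsdpop import io
from vsdpop.preprocess import preprocess_session

IN, OUT = Path("scratch/demo/data"), Path("scratch/demo/dff")

for d in sorted(IN.iterdir()):
    stim_stack, blank_stack, _ = io.load_session(d)
    movie = preprocess_session(stim_stack, blank_stack)
    io.save_dff(OUT / d.name, movie)
    print(f"{d.name}: {int((~movie.valid_frames).sum())} frames and "
          f"{int((~movie.valid_pixels).sum())} pixels masked; "
          f"wrote {OUT / d.name}")
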