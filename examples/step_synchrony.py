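"""Polarity invariance with step stimuli.

Runs all four polarity pairings of the step design (intensity
increments/decrements in each modality) through the detector with
transient and with sustained front-ends.
"""

import numpy as np

from mcd import MCDParams, StepStimSpec, gen_step_pair, mcd_respond

transient = MCDParams()                      # band-pass + squaring front-end
sustained = MCDParams(variant="sustained")   # low-pass front-end

print("condition   transient corr   sustained corr")
for cond in ("on-on", "off-off", "on-off", "off-on"):
    v, a = gen_step_pair(StepStimSpec(condition=cond, lag=0.0), 1000.0)
    ct = mcd_respond(v, a, transient).corr_mean
    cs = mcd_respond(v, a, sustained).corr_mean
    print(f"{cond:10s}  {ct:14.6e}  {cs:14.6e}")

# Through transient channels the four conditions are indistinguishable
# (identical correlation output): unsigned transients erase step
# polarity. Through sustained channels the conditions separate - the
# output tracks intensity itself, so it depends on step polarity and
# level. Behavioural data follow the transient pattern.
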