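"""Frequency doubling in the model's synchrony curve.

Scans the periodic design (windowed 0.5 Hz square waves, 40 crossmodal
phase shifts over one full cycle) through the transient-channel
detector, then Fourier-analyzes the resulting synchrony curve.
"""

import numpy as np

from mcd import psychometric_spectrum
from mcd.experiments import curve_peaks_deg, synchrony_phase_curve

phases, curve = synchrony_phase_curve()
spec = psychometric_spectrum(curve)
primary, secondary = curve_peaks_deg(phases, curve)

print(f"dominant non-DC frequency: {spec.dominant_nondc()} cpp")
print(f"amplitude ratio 1 cpp / 2 cpp: {spec.amplitudes[1] / spec.amplitudes[2]:.4f}")
print(f"synchrony maxima at {primary:.0f} deg and {secondary:.0f} deg "
      f"({(secondary - primary) % 360:.0f} deg apart)")

# A 2 cycles-per-period dominant component means the detector reports
# high synchrony twice per cycle of crossmodal phase shift - the
# frequency-doubling signature of unsigned transient input channels
# (a sustained front-end would peak only once, at 1 cpp). The maxima
# sit ~sqrt(6)*(tau_v - tau_a) ~ 37 ms from 0/180 deg because the
# slower visual filter is compensated by a small auditory delay.
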