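"""Analyze simulated atrial activation-time series (the tissue-model side).

Per-point activation times are converted to instantaneous-frequency series
at 10 Hz; points without a sufficiently peaked spectrum are discarded; the
retained series are averaged and summarized as Ffs (median frequency) and
dFfs (modulation linearly related to a 0.14 Hz respiratory sinusoid).
"""

import numpy as np

from fwavetilt.activation import analyze_activation_set
from fwavetilt.synthetic import generate_activation_series

rng = np.random.default_rng(1)
aset = generate_activation_series(
    n_points=223, duration=120.0, base_freq=8.25, mod_amplitude=0.13,
    resp_rate=0.14, jitter_sd=0.001, frac_unpeaked=0.3, rng=rng)

result = analyze_activation_set(aset)
n_kept = sum(result.retained.values())
print(f"points: {len(result.fcs)}, retained by peak-conditioned "
      f"selection: {n_kept} ({n_kept / len(result.fcs):.0%})")
print(f"Ffs  = {result.ffs:.3f} Hz   (injected base rate 8.25 Hz)")
print(f"dFfs = {result.delta_ffs:.3f} Hz  (injected modulation 0.13 Hz)")

# 30 % of points were generated with broadband random rates; the selection
# should discard almost exactly those, and the summaries recover the
# injected activation rate and its respiratory-type modulation.
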