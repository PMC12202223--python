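"""Quantify respiration-linked f-wave frequency modulation (dFf, Pr).

Derives an ECG respiration surrogate from QRS slope ranges combined across
leads by periodic component analysis, then projects the detrended frequency
trend onto delayed copies of it (orthogonal subspace projection).
"""

from fwavetilt import run_ecg_pipeline
from fwavetilt.synthetic import generate_tilt_recording, table2_scenario

record, truth = generate_tilt_recording(table2_scenario(seed=1))
table = run_ecg_pipeline(record, record_id="example")

print(f"{'phase':>6} {'FRR est':>8} {'FRR true':>9} {'dFf est':>8} "
      f"{'dFf true':>9} {'Pr (%)':>7}")
for _, row in table.iterrows():
    t = truth.per_phase[row.phase]
    print(f"{row.phase:>6} {row.frr:8.3f} {t['frr']:9.3f} "
          f"{row.delta_ff:8.3f} {t['delta_ff']:9.3f} {row.pr:7.1f}")

# FRR is the respiration-rate estimate from periodic component analysis;
# dFf the average peak amplitude of respiration-linked frequency variation
# (the parasympathetic-modulation marker); Pr the percentage of trend
# variance the respiratory subspace explains.
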