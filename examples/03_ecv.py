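"""Compute an extracellular volume fraction from peak T1 values.

Uses representative values: native muscle peak 1900 ms shortening to
600 ms after contrast, blood 1700 -> 400 ms, hematocrit 40%.  ECV is the
contrast-induced change in muscle R1 (=1/T1) relative to blood R1, scaled
by the plasma fraction (1 - hematocrit); healthy skeletal muscle sits
around 10-20%, fibrotic or inflamed muscle higher.
"""

from calfmolli import EcvInputs, compute_ecv

inputs = EcvInputs(t1m_pre_ms=1900.0, t1m_post_ms=600.0,
                   t1b_pre_ms=1700.0, t1b_post_ms=400.0, hematocrit=0.40)
res = compute_ecv(inputs)
print(f"ECV = {res.percent:.2f}%  (plausible: {res.plausible})")

# hematocrit given in percent is auto-detected
res_pct = compute_ecv(EcvInputs(1900.0, 600.0, 1700.0, 400.0, 40.0))
print(f"same inputs with hematocrit as percent: {res_pct.percent:.2f}%")
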