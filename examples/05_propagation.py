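"""Seizure propagation: staged cross-correlation and PLV networks.

The seizure span is split into three equal stages. Pathway propagation
recruits leads one by one; volume conduction mixes a common waveform into
every lead with rising gain, so late-stage cross-lead correlation approaches
1 and the HF phase-locking network tightens.
"""

import svdc
from svdc.network import stage_summaries

for mode in ("pathway", "volume"):
    cfg = svdc.SimConfig(seed=42)
    cfg.seizure.propagation = mode
    rec, truth = svdc.generate_ictal(cfg)
    span = (truth.seizure_onset_s, truth.seizure_onset_s + cfg.seizure.duration_s)

    band = svdc.extract_band(rec, 0.5, 300.0)
    cc = svdc.staged_cross_correlation(band[0], band[-1], rec.fs, span)
    hf = svdc.extract_band(rec, 40.0, 300.0)
    plv_series = svdc.staged_plv(hf, rec.labels, rec.fs, span, band="hf")

    print(f"{mode} propagation:")
    print("  staged rho(A1, B4):", [f"{v:.3f}" for v in cc.values])
    print("  staged mean off-diagonal HF PLV:",
          [f"{v:.3f}" for v in stage_summaries(plv_series)])
# Volume mode shows the signature rise toward rho ~ 1 and strong phase
# locking in the final stage; pathway mode stays lead-specific.
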