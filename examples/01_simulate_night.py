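"""Simulate one night of polysomnography and inspect its architecture.

Builds a 9-h ground-truth hypnogram from the semi-Markov bout model and the
matching stage-conditioned EEG, then prints the night's sleep metrics.
"""

import numpy as np

from somnostage import (ArchitectureParams, simulate_hypnogram, sleep_metrics,
                        synthesize_eeg)

params = ArchitectureParams()  # 9-h night, adapted-sleeper calibration
hyp = simulate_hypnogram(params, seed=7)

m = sleep_metrics(hyp, tsc_h=9.0)
print(f"epochs: {len(hyp)} (30 s each)")
print(f"TST   {m.tst_h:5.2f} h   sleep actually obtained")
print(f"SE    {m.se_pct:5.2f} %   TST as a share of the 9-h collection")
print(f"SOL   {m.sol_min:5.1f} min lights-off to the first N2 epoch")
print(f"N1/N2/N3/REM % of TST: {m.n1_pct:.1f} / {m.n2_pct:.1f} / "
      f"{m.n3_pct:.1f} / {m.rem_pct:.1f}")
print(f"awakenings (interior wake bouts): {m.wn}")

# a short EEG excerpt: synthesize only the first 10 epochs
short = simulate_hypnogram(ArchitectureParams.scaled_to(1.0), seed=7)
rec = synthesize_eeg(short, seed=7)
print(f"\nEEG: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.rate:g} Hz, amplitude sd = {np.std(rec.data):.1f} uV")
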