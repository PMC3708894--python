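"""Depth-weighted minimum-norm source reconstruction.

Builds the inverse operator (lambda^2 = 0.33, depth-weighting exponent
0.5), reconstructs ROI current time courses for one subject, and runs a
quick single-dipole localization check.
"""

import numpy as np

from dmnrest import inverse as inv
from dmnrest import preprocess as pre
from dmnrest import studies, synth
from dmnrest.montage import ROI_ORDER

space = synth.make_source_space(2, seed=0)
lf = synth.make_lead_field(space)
op = inv.build_inverse(lf, lambda2=0.33, gamma=0.5)
print(f"inverse kernel: {op.kernel.shape} (vertices x sensors), "
      f"lambda^2 = {op.lambda2}")

spec = synth.mci_like_spec(n_subjects=2, duration_s=64.0)
rec, _ = synth.simulate_subject(spec, space, lf, 0)
eset, _ = pre.preprocess_recording(rec, ica=False)
rts = inv.extract_roi(inv.apply_inverse(op, eset), space, fs=eset.fs)
act = inv.mean_activation(rts)
print("\nmean |current| per ROI (pAm):")
for roi, a in zip(ROI_ORDER, act):
    print(f"  {roi:>6}: {a:10.0f}")
print("posterior regions carry the strongest currents (the generator's")
print("posterior alpha dominates); magnitudes are minimum-norm estimates,")
print("so they understate the true source moments.")

rate = studies.localization_study(n_fixtures=50, snr=10.0, seed=0)
print(f"\nsingle-dipole localization, 50 fixtures at SNR 10: "
      f"{100 * rate:.0f}% land in the true ROI")
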