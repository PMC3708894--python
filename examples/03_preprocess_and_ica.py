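"""Preprocessing with ICA-based artifact rejection.

Simulates one clean subject, injects ocular and muscle artifacts, then
runs the fixed chain (mastoid re-reference, 1-40 Hz zero-phase band-pass,
2-s epochs, seeded FastICA, two-criteria component rejection, random
selection of 30 epochs) and shows that frontal delta power returns to its
artifact-free level.
"""

import numpy as np
from scipy import signal as sg

from dmnrest import preprocess as pre
from dmnrest import synth

space = synth.make_source_space(1, seed=0)
lf = synth.make_lead_field(space)
spec = synth.mci_like_spec(n_subjects=2, duration_s=64.0)
rec, _ = synth.simulate_subject(spec, space, lf, 0)
dirty = synth.inject_artifacts(rec, {"ocular", "muscle"}, seed=1)
print(f"injected {len(dirty.artifacts)} artifact events "
      f"({sum(e['kind'] == 'ocular' for e in dirty.artifacts)} ocular, "
      f"{sum(e['kind'] == 'muscle' for e in dirty.artifacts)} muscle)")


def fp1_delta(eset):
    f, p = sg.welch(eset.epochs[:, 0, :].ravel(), fs=200.0, nperseg=512)
    return p[(f >= 1) & (f < 4)].sum()


clean_epochs = pre.segment(pre.bandpass(pre.rereference(rec)))
eset = pre.segment(pre.bandpass(pre.rereference(dirty)))
dec = pre.decompose(eset, seed=0)
cleaned, rejected = pre.score_and_reject(dec)
selected = pre.select_epochs(cleaned, n=30, seed=0)

print(f"rejected components: {rejected}")
print(f"Fp1 delta power  clean {fp1_delta(clean_epochs):8.1f}  "
      f"with artifacts {fp1_delta(eset):8.1f}  "
      f"after rejection {fp1_delta(cleaned):8.1f}  (uV^2/Hz sums)")
print(f"selected {selected.n_epochs} epochs for analysis")
print("after rejection the frontal delta power is back near the clean value,")
print("so the ocular component was removed without distorting the rest.")
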