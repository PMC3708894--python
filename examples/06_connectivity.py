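"""Imaginary-coherence functional connectivity.

First an analytic check: two sinusoids a quarter-cycle apart at an exact
FFT bin have |IC| = 1 at that bin, while identical signals give IC = 0
everywhere (volume-conduction immunity).  Then the PCC--PCu coupling
injected by the generator is recovered from a simulated subject.
"""

import numpy as np

from dmnrest import connectivity as con
from dmnrest import inverse as inv
from dmnrest import preprocess as pre
from dmnrest import spectral as spe
from dmnrest import synth
from dmnrest.inverse import ROITimeSeries

# analytic: quarter-cycle lag at 12.5 Hz (an exact bin, rectangular window)
t = np.arange(8 * 400) / 200.0
data = np.zeros((8, 12, 400))
data[:, 0] = np.cos(2 * np.pi * 12.5 * t).reshape(8, 400)
data[:, 1] = np.cos(2 * np.pi * 12.5 * t - np.pi / 2).reshape(8, 400)
coef, freqs = spe.epoch_fft(ROITimeSeries(data=data, fs=200.0), window="rect")
ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
k = int(round(12.5 / (freqs[1] - freqs[0])))
print(f"quarter-cycle-lagged sinusoids: IC at 12.5 Hz = {ic[0, k]:+.6f}")

data[:, 1] = data[:, 0]
coef, freqs = spe.epoch_fft(ROITimeSeries(data=data, fs=200.0), window="rect")
ic0 = con.imaginary_coherence(con.cross_spectra(coef, freqs))
print(f"identical signals (zero lag):   max |IC| = {np.abs(ic0[0]).max():.2e}")

# generator coupling recovered from a full simulated subject
space = synth.make_source_space(1, seed=0)
lf = synth.make_lead_field(space)
op = inv.build_inverse(lf)
spec = synth.mci_like_spec(n_subjects=2, duration_s=64.0)
rec, _ = synth.simulate_subject(spec, space, lf, 0)
eset, _ = pre.preprocess_recording(rec, ica=False)
rts = inv.extract_roi(inv.apply_inverse(op, eset), space, fs=eset.fs)
spectrum = spe.epoch_spectrum(rts)
scheme = spe.BandScheme(iaf=spe.detect_iaf(spectrum))
band_ic, z = con.subject_connectivity(rts, scheme)
p = con.PAIR_LABELS.index("PCC_L--PCu_L")
print("\nPCC_L--PCu_L Fisher-z IC per band "
      "(the generator couples this pair at 10 Hz with a pi/2 lag):")
for band, v in zip(spe.BAND_ORDER, z[p]):
    print(f"  {band:>6}: {v:+.3f}")
print("the alpha bands stand out; instantaneous field spread contributes")
print("nothing because only the imaginary cross-spectrum is used.")
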