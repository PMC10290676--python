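"""Noise immunity: adaptive constraints vs a static support at 15 dB SNR.

White Gaussian noise inside a static aperture cannot be rejected and
accumulates over iterations, so the static-support error grows; the
adaptive mask re-segments the object every iteration and keeps the error
bounded.  The printed MSE-vs-iteration traces show the two behaviours.
"""

import numpy as np

import holomorph as hm

geo = hm.paper_geometry()
obj, truth = hm.make_object(hm.standard_scene("flat", seed=0))
holo = hm.add_gaussian_noise(hm.forward_hologram(obj, geo["z"]), snr_db=15.0, seed=1)

fp = truth.amp_footprint | truth.phase_footprint
rr, cc = np.nonzero(fp)
support = hm.static_support_mask(
    holo.shape, "rect",
    bounds=(max(rr.min() - 20, 0), min(rr.max() + 20, holo.shape[0]),
            max(cc.min() - 20, 0), min(cc.max() + 20, holo.shape[1])),
)

base = dict(z=geo["z"], iterations=100, record_every=20, seed=0)
ra = hm.retrieve(holo, hm.RetrievalConfig(constraint="adaptive", **base), truth)
rs = hm.retrieve(holo, hm.RetrievalConfig(constraint="support", support=support, **base), truth)

print("iteration  adaptive mse_amp  static-support mse_amp")
for i, it in enumerate(ra.iterations):
    print(f"{it:>9}  {ra.mse_amp_trace[i]:<16.5f}  {rs.mse_amp_trace[i]:.5f}")
print("\nThe static-support trace rises (noise accumulates inside the "
      "aperture); the adaptive trace stays flat or falls.")
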