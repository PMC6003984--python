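"""Classify arteries by their heartbeat-band pulsation.

A synthetic scene holds two vessels; one pulsates at 1.2 Hz (an artery),
the other is static (a vein). 100 frames at 10 Hz are motion-screened,
rigidly registered in 16 overlapping subdomains, and Fourier-analysed per
pixel; spectral power inside the 1.0-1.6 Hz heart band separates the two.
"""

import numpy as np

import ringpact as rp

rng = np.random.default_rng(0)
img = 0.05 * rng.random((96, 96))
artery = np.zeros((96, 96), bool)
vein = np.zeros((96, 96), bool)
artery[30:35, 8:88] = True
vein[60:65, 8:88] = True
img[artery] = img[vein] = 1.0

seq = rp.generate_dynamic_frames(
    img, "pulsation", target_mask=artery, frequency=1.2, amplitude=0.15,
    n_frames=100, frame_rate=10.0, noise_sd=0.015, seed=4,
)
registered, log = rp.register_subdomains(seq)
result = rp.spectral_artery_map(registered, vessel_mask=artery | vein)

print(f"frames kept after motion screening : {len(log['kept'])}/100")
print(f"estimated heart rate               : {result.heart_rate_hz:.2f} Hz"
      "  (planted 1.20 Hz)")
print(f"artery pixels classified artery    : {result.artery_mask[artery].mean():.1%}")
print(f"vein pixels misclassified artery   : {result.artery_mask[vein].mean():.1%}")
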