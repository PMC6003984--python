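"""Density-ratio ROC over affected vs contralateral breasts.

Each breast contributes one density ratio (mean density of its
high-density region over its normal region, at the mean+k*SD cutoff);
sweeping a decision threshold over the ratios from 1 to 6 yields the ROC
curve. Synthetic density maps stand in for the per-breast inputs here.
"""

import numpy as np

from ringpact.tumor import DensityMap, density_ratio_and_roc


def synthetic_breast(ratio, seed):
    rng = np.random.default_rng(seed)
    d = np.abs(rng.normal(1.0, 0.08, (120, 120)))
    d[40:80, 40:80] = ratio  # high-density (tumor-like) plateau
    return DensityMap(
        density=d, window_mm=2.0, pixel_size=0.1,
        support_mask=np.ones_like(d, bool),
        mean=float(d.mean()), sd=float(d.std()),
    )


# affected breasts carry stronger high-density regions than contralaterals
affected = [synthetic_breast(r, i) for i, r in enumerate((3.4, 2.9, 4.1, 2.4))]
contralateral = [synthetic_breast(r, 10 + i) for i, r in enumerate((1.9, 2.2, 1.7, 2.6))]
maps = affected + contralateral
labels = [1] * 4 + [0] * 4

res = density_ratio_and_roc(maps, labels)
for k in (1.5, 2.0, 2.5):
    r = ", ".join(f"{v:.2f}" for v in res.ratios[k])
    print(f"k = {k}: ratios [{r}]  AUC = {res.auc[k]:.3f}  "
          f"best threshold in [{res.optimal_threshold[k][0]:.2f}, "
          f"{res.optimal_threshold[k][1]:.2f}]")
print("\nAUC < 1 reflects the overlapping affected/contralateral ratios;"
      "\nthe optimal-threshold interval maximizes sensitivity+specificity.")
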