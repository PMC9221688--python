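"""Tortuosity, bifurcation and fractal-dimension biomarkers on closed-form
test curves, compared with their analytic values.

A straight segment has arc/chord ratio 1 and zero curvature everywhere; a
semicircle has arc/chord π/2 ≈ 1.571 and total curvature π; a uniformly
sampled line segment has box-counting dimension 1.
"""

import numpy as np

from retinograph import morphometry as mm

straight = mm.resample_and_curvature(np.array([[0.0, 0.0], [150.0, 0.0]]))
tv = mm.tortuosity_metrics(straight)
print(f"straight segment:  tau1={tv.tau1:.6f} (expect 1), total curvature tau3={tv.tau3:.2e} (expect 0)")

t = np.linspace(0, np.pi, 300)
semi = mm.resample_and_curvature(np.column_stack([50 * np.cos(t), 50 * np.sin(t)]))
tv = mm.tortuosity_metrics(semi)
print(f"semicircle r=50:   tau1={tv.tau1:.4f} (expect {np.pi/2:.4f}), tau3={tv.tau3:.4f} (expect {np.pi:.4f})")

d0 = 10.0
d1 = d0 * 2 ** (-1 / 3)
bm = mm.bifurcation_metrics(d0, d1, d1, np.array([1.0, 0.0]),
                            np.array([1.0, 0.4]), np.array([1.0, -0.4]))
print(f"Murray junction:   alpha={bm.alpha:.3f} lam={bm.lam:.3f} "
      f"beta={bm.beta:.4f} (expect 2^(1/3)={2**(1/3):.4f}), theta={bm.theta:.1f}°")

rng = np.random.default_rng(0)
line = np.column_stack([rng.uniform(0, 1000, 10000), np.full(10000, 200.0)])
fd = mm.fractal_dimensions(line, (1024, 1024))
print(f"line point set:    D_B={fd.D_B:.3f} D_I={fd.D_I:.3f} D_C={fd.D_C:.3f} (expect 1.0)")
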