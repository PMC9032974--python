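"""Two-dimensional interference: an elliptical ring focuses activity.

On an isotropic 2D lattice every ring element radiates an intrinsic wave;
for a ring whose focal distance is half the intrinsic period the
contributions from the near and far vertices arrive in phase at the
geometric foci, producing two islands of positive activation there.
"""

import numpy as np

from neuralwave import (
    DEFAULT_RING, Stimulus2D, detect_foci, get_config, simulate_lattice2d,
    threshold_region,
)

c = get_config("reference_low_damping")
s = Stimulus2D(kind="elliptical_ring", j0=0.02, **DEFAULT_RING)
L = DEFAULT_RING["a"] + 16.0
f = simulate_lattice2d(c, s, domain=(-L, L, -L, L), nx=256, ny=256,
                      method="spectral")
foci = detect_foci(f, s)
print(f"ring semi-axes a={s.a}, b={s.b} -> geometric foci at "
      f"(+-{np.sqrt(s.a**2 - s.b**2):.2f}, 0)")
print(f"detected interference peaks: {np.round(foci.peaks, 2).tolist()}")
print(f"mean displacement from geometric foci: {foci.displacement:.3f}")
for frac in (0.1, 0.9):
    out = threshold_region(f, frac * f.r_E.max())
    print(f"threshold {frac:.1f} x max -> {out['n_components']} "
          f"supra-threshold component(s)")
print("-> raising the detection threshold splits activation into two islands")
print("   at the foci, where contrast thresholds are predicted lowest.")
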