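"""The circuit's intrinsic wave: point stimulation of the distributed circuit.

Builds the packaged weakly damped configuration, extracts the analytic
standing-wave solution, and verifies it against direct numerical integration
of the field equations (using the moderately damped configuration, whose
transients decay quickly).
"""

import numpy as np

from neuralwave import (
    Stimulus1D, get_config, greens_function, simulate_pde, wave_params,
)

c = get_config("reference_low_damping")
w = wave_params(c)
print(f"intrinsic spatial frequency k_n = {w.k_n:.4f} rad/unit "
      f"(period {w.period:.2f} motif spacings)")
print(f"spatial decay rate lambda = {w.lam:.4f}  (damping ratio "
      f"lambda/k_n = {w.lam / w.k_n:.3f})")
print(f"amplitude coefficients: Gamma_E={w.Gamma_E:.3f} Delta_E={w.Delta_E:.3f} "
      f"Gamma_I={w.Gamma_I:.3f} Delta_I={w.Delta_I:.3f}")

x = np.array([0.0, w.period / 2, w.period])
GE, _ = greens_function(w, x)
print("\nexcitatory response at 0, half period, full period:", np.round(GE, 3))
print("-> the response alternates sign with distance: a damped standing wave.")

cm = get_config("reference_moderate")
wm = wave_params(cm)
r = simulate_pde(cm, Stimulus1D(kind="point", j0=1e-3),
                 domain=(-60, 60), nx=512, t_end=300, tol=1e-10)
GE_m, _ = greens_function(wm, r.grid)
sel = np.abs(r.grid) < 48
err = np.abs(r.r_E[sel] / 1e-3 - GE_m[sel]).max() / np.abs(GE_m).max()
print(f"\nnumerical steady state vs analytic wave (moderate damping): "
      f"max relative error {err:.4f} over the central 80% of the domain")
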