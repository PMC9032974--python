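"""Direct (zone 1) vs lateral (zone 2) activation for bounded gratings.

Inside the stimulated region the response follows the stimulus spatial
frequency; outside it, the response always oscillates at the circuit's own
intrinsic frequency, with a decaying envelope.
"""

import numpy as np

from neuralwave import (
    Stimulus1D, get_config, linear_response, wave_params, zone2_spectrum,
)

w = wave_params(get_config("reference_low_damping"))
T = w.period
grid = np.arange(-40 * T, 12 * T, T / 64)

print(f"intrinsic SF k_n = {w.k_n:.3f}")
for mult in (0.5, 1.0, 2.0):
    stim = Stimulus1D(kind="bounded_grating", j0=1.0, k=mult * w.k_n,
                      region=(grid[0], 0.0))
    r = linear_response(stim, w, grid)
    interior = (grid > -35 * T) & (grid < -6 * T)
    amp = np.abs(r.r_E[interior]).max()
    spec = zone2_spectrum(r, (grid[0], 0.0), k_hint=w.k_n)
    print(f"stimulus SF = {mult:3.1f} x k_n : zone-1 amplitude {amp:8.2f}   "
          f"zone-2 dominant SF {spec['k_spectral']:.3f} +- {spec['uncertainty']:.3f}")
print("-> zone-1 amplitude peaks at the intrinsic SF (spatial resonance);")
print("   zone-2 frequency equals k_n for every stimulus (lateral activation")
print("   reflects the intrinsic wave, not the stimulus).")
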