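"""Temporal interference in a single motif and duration thresholds.

A brief pulse rings at the motif's natural period.  Pulse pairs interfere
across time like waves across space.  Detection ("just visible") thresholds
on stimulus duration behave very differently depending on how the input
splits between excitation and inhibition.
"""

import numpy as np

from neuralwave import (
    PulseTrain, duration_threshold_curve, get_config, node_frequency,
    node_oscillation,
)

m = get_config("node_excitatory")
freq = node_frequency(m)
print(f"natural period {freq['period']:.2f}, decay rate {freq['decay_rate']:.2f}")

t = np.arange(0, 40, 0.02)
single = node_oscillation(m, PulseTrain(times=(0.0,), amplitudes=(0.05,), width=0.2), t)
P = single["period"]
sync = node_oscillation(m, PulseTrain(times=(0.0, P), amplitudes=(0.05, 0.05), width=0.2), t)
anti = node_oscillation(m, PulseTrain(times=(0.0, P / 2), amplitudes=(0.05, 0.05), width=0.2), t)
print(f"single-pulse peak {single['r_E'].max():.4f}; "
      f"pair at full period {sync['r_E'].max():.4f} (constructive); "
      f"pair at half period {anti['r_E'][t > P / 2 + 0.2].max():.4f} (destructive)")

contrasts = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
for name in ("node_excitatory", "node_inhibitory"):
    cur = duration_threshold_curve(contrasts, get_config(name), theta_det=0.2)
    th = ["never" if not np.isfinite(v) else f"{v:.2f}" for v in cur.thresholds]
    print(f"{name} (alpha={cur.alpha}): duration thresholds {th} "
          f"{'(monotone decline)' if cur.monotone_decreasing else '(non-monotonic)'}")
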