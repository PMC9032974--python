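"""Synthetic-data generators with known ground truth.

Every dataset consumed by the analysis pipeline can be generated here with
its generating parameters recorded, so downstream estimates are scorable
against truth without any external data.  The tuning generator emulates the
design of awake-primate frequency-tuning experiments (log-spaced SF/TF
grids, a handful of contrasts, 10 trials per condition); the sensitivity
generator emulates lateral contrast-sensitivity profiles with
damped-harmonic structure; the observer generator provides a seeded 2AFC
trial oracle for staircase simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lateral import SensitivityProfile
from .tuning import TuningDataset

__all__ = [
    "GeneratorConfig",
    "gen_tuning_dataset",
    "gen_sensitivity_profiles",
    "gen_observer",
    "Observer2AFC",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded scenario description for the synthetic generators.

    Tuning scenario fields
    ----------------------
    ``sf_grid``/``tf_grid``/``contrasts``: stimulus values (cycles/deg, Hz, %).
    ``n_trials``: trials per condition (10, matching common practice).
    ``peak_sf_by_contrast``: planted peak SF per contrast; by default the
    peak SF rises with contrast (the qualitative pattern of
    contrast-dependent spatial tuning in area MT).
    ``peak_tf``: planted peak TF (shared across contrasts).
    ``rate_scale``: peak firing rate (spikes/s); ``dispersion``: variance /
    mean of the truncated-normal rate noise (count-like overdispersion).

    Sensitivity scenario fields
    ---------------------------
    ``probe_distances`` (deg), damped-harmonic truth (``lateral_f``
    cycles/deg shared across conditions, envelope ``lateral_O``,
    ``lateral_c``, phase ``lateral_phi``), ``baseline`` sensitivity,
    ``threshold_noise_sd``, and the flanker-SF ``conditions`` labels.

    Observer fields
    ---------------
    ``observer_threshold`` (%): contrast of 75%-correct performance;
    ``observer_slope``: Weibull slope; ``lapse``: lapse rate.
    """

    seed: int = 0
    scenario: str = "default"
    # --- tuning ---
    sf_grid: tuple = (0.03, 0.06, 0.12, 0.25, 0.5)
    tf_grid: tuple = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    contrasts: tuple = (2.0, 7.0, 14.0, 52.0, 100.0)
    n_trials: int = 10
    peak_sf_by_contrast: tuple | None = None
    peak_tf: float = 4.0
    tuning_width: float = 0.8          # SD of log-Gaussian tuning (log units)
    rate_scale: float = 40.0
    base_rate: float = 4.0
    dispersion: float = 2.0
    # --- sensitivity profiles ---
    probe_distances: tuple = (0.0, 0.0625, 0.125, 0.1875, 0.25, 0.3125, 0.375, 0.4375, 0.5)
    conditions: tuple = ("sf1", "sf2", "sf4")
    lateral_f: float = 4.0
    lateral_O: float = 12.0
    lateral_c: float = 0.35
    lateral_phi: float = 0.0
    baseline: float = 30.0
    threshold_noise_sd: float = 0.8
    decay_only: bool = False           # null scenario: no oscillation
    # --- observer ---
    observer_threshold: float = 10.0
    observer_slope: float = 3.0
    lapse: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _planted_peaks(g: GeneratorConfig) -> np.ndarray:
    if g.peak_sf_by_contrast is not None:
        peaks = np.asarray(g.peak_sf_by_contrast, dtype=float)
        if peaks.size != len(g.contrasts):
            raise ValueError("peak_sf_by_contrast length must match contrasts")
        return peaks
    # default: peak SF rises with contrast across the central grid range
    lo, hi = g.sf_grid[1], g.sf_grid[-2]
    t = np.linspace(0.0, 1.0, len(g.contrasts))
    return lo * (hi / lo) ** t


def gen_tuning_dataset(g: GeneratorConfig) -> tuple[TuningDataset, dict]:
    """Trial-wise firing rates with log-Gaussian SF x TF tuning surfaces.

    The tuning surface at contrast c_i peaks at ``peak_sf_by_contrast[i]``
    (SF) and ``peak_tf`` (TF); response gain grows saturating with contrast.
    Rates are drawn from a truncated normal with variance = dispersion *
    mean (overdispersed, count-like) and clipped at zero.  Returns the
    dataset and its ground truth.
    """
    rng = g.rng()
    peaks = _planted_peaks(g)
    rows = []
    for ci, contrast in enumerate(g.contrasts):
        gain = contrast / (contrast + 10.0)  # saturating contrast response
        for sf in g.sf_grid:
            for tf in g.tf_grid:
                mean = g.base_rate + g.rate_scale * gain * math.exp(
                    -((math.log(sf / peaks[ci])) ** 2) / (2 * g.tuning_width**2)
                    - ((math.log(tf / g.peak_tf)) ** 2) / (2 * g.tuning_width**2)
                )
                sd = math.sqrt(g.dispersion * mean)
                rates = np.clip(rng.normal(mean, sd, size=g.n_trials), 0.0, None)
                for trial, rate in enumerate(rates):
                    rows.append((sf, tf, contrast, trial, rate))
    data = pd.DataFrame(rows, columns=["sf", "tf", "contrast", "trial", "rate"])
    truth = {
        "seed": g.seed,
        "scenario": g.scenario,
        "peak_sf_by_contrast": dict(zip(map(float, g.contrasts), map(float, peaks))),
        "peak_tf": g.peak_tf,
        "tuning_width": g.tuning_width,
        "dispersion": g.dispersion,
    }
    return TuningDataset(data, meta=truth), truth


def gen_sensitivity_profiles(g: GeneratorConfig) -> tuple[list[SensitivityProfile], dict]:
    """Lateral sensitivity profiles sharing one modulation frequency.

    Each condition (flanker SF) gets its own envelope amplitude but the same
    spatial frequency ``lateral_f`` -- the wave account predicts the lateral
    modulation period is a property of the circuit, not of the stimulus.
    The ``decay_only`` scenario instead uses the degenerate f = 0 member
    (pure Gaussian decay), the null against which modulation is tested.
    """
    rng = g.rng()
    d = np.asarray(g.probe_distances, dtype=float)
    profiles = []
    amps = {}
    for i, cond in enumerate(g.conditions):
        O = g.lateral_O * (0.8 + 0.4 * rng.random())
        amps[cond] = float(O)
        f = 0.0 if g.decay_only else g.lateral_f
        mod = O * np.exp(-(d**2) / (2 * g.lateral_c**2)) * np.cos(
            2 * math.pi * f * d + g.lateral_phi
        )
        sens = np.clip(g.baseline + mod + rng.normal(0.0, g.threshold_noise_sd, d.size),
                       1e-3, None)
        profiles.append(SensitivityProfile(distances=d, sensitivities=sens, condition=cond))
    truth = {
        "seed": g.seed,
        "scenario": g.scenario,
        "f": 0.0 if g.decay_only else g.lateral_f,
        "c": g.lateral_c,
        "phi": g.lateral_phi,
        "amplitudes": amps,
        "baseline": g.baseline,
        "noise_sd": g.threshold_noise_sd,
    }
    return profiles, truth


@dataclass
class Observer2AFC:
    """Simulated two-alternative forced-choice observer.

    Probability correct follows a Weibull psychometric function between the
    guessing rate 0.5 and 1 - lapse:

        P(c) = 0.5 + (0.5 - lapse) * (1 - exp(-(c / threshold)^slope))

    ``threshold`` is then roughly the 75%-correct contrast (exactly, the
    63%-of-range point); the 3-down/1-up convergence point solves
    P(c) = 0.794.
    """

    threshold: float
    slope: float = 3.0
    lapse: float = 0.0

    def prob_correct(self, contrast: float) -> float:
        return 0.5 + (0.5 - self.lapse) * (
            1.0 - math.exp(-((max(contrast, 0.0) / self.threshold) ** self.slope))
        )

    def __call__(self, contrast: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.prob_correct(contrast))

    def contrast_at(self, p: float) -> float:
        """Contrast at which P(correct) = p (inverse psychometric function)."""
        frac = (p - 0.5) / (0.5 - self.lapse)
        if not 0.0 < frac < 1.0:
            raise ValueError("requested performance outside the attainable range")
        return self.threshold * (-math.log(1.0 - frac)) ** (1.0 / self.slope)


def gen_observer(g: GeneratorConfig) -> tuple[Observer2AFC, dict]:
    obs = Observer2AFC(threshold=g.observer_threshold, slope=g.observer_slope, lapse=g.lapse)
    truth = {
        "seed": g.seed,
        "threshold": g.observer_threshold,
        "slope": g.observer_slope,
        "lapse": g.lapse,
        "p794_contrast": obs.contrast_at(0.794),
    }
    return obs, truth
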