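"""Packaged parameter sets and YAML/JSON config handling.

Weight values for circuits of this kind are rarely published, so the
package ships named reference configurations chosen by construction:

``reference_low_damping``
    Oscillatory Green's function with lam/k_n ~ 0.04 (k_n ~ 1, intrinsic
    period ~ 2*pi) and a homogeneous state that is linearly stable at every
    wavenumber; the default for time-domain simulation, interference and
    zone analyses.
``regime_1`` / ``regime_2``
    Weight sets on either side of the resonance separatrix
    k_n^2 - lam^2 = kappa_asymp: spatial resonance rises (regime 1) or falls
    (regime 2) with temporal frequency.  These serve the algebraic resonance
    analysis; in regime 1 the continuum's homogeneous state is unstable to
    very short wavelengths (the chain itself is fine), so they are not meant
    for PDE time stepping.
``contrast_up`` / ``contrast_down``
    The low-damping weights with cubic nonlinearity split so that the
    contrast-dependent resonance shift xi_E - xi_I is positive (peak spatial
    frequency rises with contrast) or negative (falls).
``node_excitatory`` / ``node_inhibitory``
    Single-motif weight sets in the damped-oscillatory temporal regime with
    high / low excitatory input fraction alpha, for duration-threshold
    studies.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .params import ContinuumParams, MotifWeights, SigmoidParams

__all__ = [
    "get_config",
    "list_configs",
    "load_config",
    "dump_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """A parameter file failed validation."""


_CONTINUUM = {
    "reference_low_damping": dict(
        W_EE=1.2, W_EI=0.2445, W_IE=2.0895, W_II=0.3,
        D_EE=0.6, D_EI=0.5568, D_IE=0.5568, D_II=0.1,
        tau_E=0.5, alpha=0.5,
    ),
    "reference_moderate": dict(
        W_EE=1.326, W_EI=0.913, W_IE=1.4494, W_II=0.5368,
        D_EE=0.3647, D_EI=0.7632, D_IE=1.1724, D_II=0.2516,
        tau_E=0.3082, alpha=0.5,
    ),
    "regime_1": dict(
        W_EE=1.1, W_EI=0.494, W_IE=0.494, W_II=0.2,
        D_EE=0.1, D_EI=0.45, D_IE=0.45, D_II=0.8,
        tau_E=1.0, alpha=0.5,
    ),
    "regime_2": dict(
        W_EE=1.2583, W_EI=1.097, W_IE=0.5138, W_II=0.0055,
        D_EE=0.118, D_EI=0.7747, D_IE=0.5325, D_II=1.0499,
        tau_E=1.4049, alpha=0.5,
    ),
    "contrast_up": dict(
        W_EE=1.2, W_EI=0.2445, W_IE=2.0895, W_II=0.3,
        D_EE=0.6, D_EI=0.5568, D_IE=0.5568, D_II=0.1,
        tau_E=0.5, alpha=0.5, gamma_E=0.5, gamma_I=0.02,
    ),
    "contrast_down": dict(
        W_EE=1.2, W_EI=0.2445, W_IE=2.0895, W_II=0.3,
        D_EE=0.6, D_EI=0.5568, D_IE=0.5568, D_II=0.1,
        tau_E=0.5, alpha=0.5, gamma_E=0.02, gamma_I=0.5,
    ),
}

_MOTIF = {
    # chain equivalents (w = W - 2*wt, wt = D) used for cross-validation
    "reference_low_damping_chain": dict(
        w_EE=0.0, w_EI=-0.8691, w_IE=0.9759, w_II=0.1,
        wt_EE=0.6, wt_EI=0.5568, wt_IE=0.5568, wt_II=0.1,
        tau_E=0.5, alpha=0.5,
    ),
    "reference_moderate_chain": dict(
        w_EE=0.5966, w_EI=-0.6134, w_IE=-0.8954, w_II=0.0336,
        wt_EE=0.3647, wt_EI=0.7632, wt_IE=1.1724, wt_II=0.2516,
        tau_E=0.3082, alpha=0.5,
    ),
    # single-node sets: wt = 0; damped temporal oscillation of one motif.
    # Excitation saturates early (S_E = 1) while inhibition is recruited
    # supralinearly above its threshold, which makes the low-alpha duration
    # threshold non-monotonic in contrast.
    "node_excitatory": dict(
        w_EE=1.5, w_EI=2.0, w_IE=2.0, w_II=0.5,
        wt_EE=0.0, wt_EI=0.0, wt_IE=0.0, wt_II=0.0,
        tau_E=0.5, alpha=0.9,
        sigmoid_E={"saturation": 1.0, "gain": 4.0},
        sigmoid_I={"saturation": 10.0, "gain": 1.0, "threshold": 1.0},
    ),
    "node_inhibitory": dict(
        w_EE=1.5, w_EI=2.0, w_IE=2.0, w_II=0.5,
        wt_EE=0.0, wt_EI=0.0, wt_IE=0.0, wt_II=0.0,
        tau_E=0.5, alpha=0.2,
        sigmoid_E={"saturation": 1.0, "gain": 4.0},
        sigmoid_I={"saturation": 10.0, "gain": 1.0, "threshold": 1.0},
    ),
}


def list_configs() -> list[str]:
    return sorted(list(_CONTINUUM) + list(_MOTIF))


def _build(payload: dict) -> ContinuumParams | MotifWeights:
    payload = dict(payload)
    kind = payload.pop("kind", None)
    if kind is None:
        kind = "motif" if any(k.startswith("w_") for k in payload) else "continuum"
    if kind == "continuum":
        cls = ContinuumParams
    elif kind == "motif":
        cls = MotifWeights
        for key in ("sigmoid_E", "sigmoid_I"):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = SigmoidParams(**payload[key])
    else:
        raise ConfigError(f"unknown config kind {kind!r}")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def get_config(name: str) -> ContinuumParams | MotifWeights:
    """Return a packaged parameter set by name."""
    if name in _CONTINUUM:
        return _build({**_CONTINUUM[name], "kind": "continuum"})
    if name in _MOTIF:
        return _build({**_MOTIF[name], "kind": "motif"})
    raise ConfigError(f"unknown config {name!r}; available: {list_configs()}")


def load_config(path: str | Path) -> ContinuumParams | MotifWeights:
    """Load and validate a YAML or JSON parameter file.

    Keys mirror the :class:`ContinuumParams` / :class:`MotifWeights` field
    names; an optional ``kind: continuum|motif`` key disambiguates.  Unknown
    keys are rejected with the offending key named.
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return _build(payload)


def dump_config(params: ContinuumParams | MotifWeights, path: str | Path) -> Path:
    """Serialize a parameter set to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    d = dataclasses.asdict(params)
    d["kind"] = "continuum" if isinstance(params, ContinuumParams) else "motif"
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path
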