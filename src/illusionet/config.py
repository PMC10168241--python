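"""Configuration resolution, validation, manifests, and result serialization.

Run configuration is a nested key/value mapping (YAML on disk) with four
sections: ``model`` (network absolutes and scaled parameters), ``cc`` and
``am`` (stimulus geometry), and ``sd_grid`` (the stimulus-duration grid
for apparent motion).  Every key has a committed default; loading a
config resolves it against the defaults, rejects unknown keys, and
validates the domain invariants.  A run manifest records the fully
resolved configuration plus convergence flags so that any output can be
regenerated bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import KernelSpec, make_subfields
from .dynamics import LayerParams, NetworkConfig

__all__ = [
    "DEFAULT_CONFIG",
    "resolve_config",
    "load_config",
    "dump_config",
    "build_network",
    "RunManifest",
    "write_results",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration file is malformed or violates an invariant."""


# ---------------------------------------------------------------------------
# Committed defaults.  The scaled parameters (sigma_*_scale, h_*_scale,
# alpha) follow the figure-axis conventions; the absolutes (sigma_unit,
# h_inh, A, B, C, spatial_period) were fixed once by the calibration
# procedure in `experiments.calibrate_baseline` and are recorded here.
# ---------------------------------------------------------------------------
DEFAULT_CONFIG: dict = {
    "model": {
        # shunting dynamics
        "A": 0.1,             # decay rate, 1/time-step (one step = 4.44 ms)
        "B": 1.0,             # upper activation bound
        "C": 1.0,             # lower activation bound (activity >= -C)
        # receptive subfields (scaled axes: sigma = scale * sigma_unit)
        "sigma_unit": 30.0,   # position units per unit of scaled width
        "sigma_inh_scale": 2.0,
        "sigma_ex_scale": 1.0,
        # baseline inhibitory peak amplitude; together with the baseline
        # width (60) this puts the kernel mass h*sigma*sqrt(2*pi) at 0.1
        "h_inh": 0.0006649038006690545,
        "h_ratio": 2.0,       # hEx / hInh at baseline
        "h_inh_scale": 1.0,
        "h_ex_scale": 1.0,
        "radius_sigmas": 4.0,
        "normalize_subfields": True,
        # feedforward-feedback loop
        "alpha": 0.3,
        "n_loops": 2,
        "dt_integ": 0.1,
        "settle_tol": 1e-7,
        "max_settle_steps": 200_000,
        "boundary": "replicate",
        "rectify_transmission": False,
    },
    "cc": {
        "center_contrast": 0.40,
        "surround_contrast": 0.95,
        "mean_luminance": 0.5,
        "spatial_period": 118.0,
        "patch_start": 3200,
        "patch_width": 200,
        "display_start": 2900,
        "display_stop": 3700,
        "pad": 300,
        "center_window": (3200, 3300),
    },
    "am": {
        "zeta": 46,
        "separation": 340,
        "bar_width": 40,
        "amplitude": 5.0,
        "t_on": 20,
        "n_cycles": 3,
        "n_positions": 512,
        "dt_ms": 4.44,
    },
    "sd_grid": (75, 54, 41, 33, 24, 18, 15, 12, 9, 6),
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {where} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def _validate(cfg: dict) -> None:
    m = cfg["model"]
    positives = ("A", "B", "sigma_unit", "sigma_inh_scale", "sigma_ex_scale",
                 "h_inh", "h_ratio", "h_inh_scale", "h_ex_scale", "dt_integ")
    for key in positives:
        if not m[key] > 0:
            raise ConfigError(f"invariant violated: model.{key} must be > 0, got {m[key]}")
    if not m["C"] >= 0:
        raise ConfigError(f"invariant violated: model.C must be >= 0, got {m['C']}")
    if not m["alpha"] >= 0:
        raise ConfigError(f"invariant violated: model.alpha must be >= 0 (feedback gain), got {m['alpha']}")
    if not m["n_loops"] >= 1:
        raise ConfigError(f"invariant violated: model.n_loops must be >= 1, got {m['n_loops']}")
    if not m["radius_sigmas"] >= 3:
        raise ConfigError(f"invariant violated: model.radius_sigmas must be >= 3, got {m['radius_sigmas']}")
    cc = cfg["cc"]
    if cc["center_contrast"] > cc["surround_contrast"]:
        raise ConfigError("invariant violated: cc.center_contrast must not exceed cc.surround_contrast")
    if any(sd < 1 for sd in cfg["sd_grid"]):
        raise ConfigError("invariant violated: sd_grid entries must be >= 1")


def resolve_config(config: dict | None = None, overrides: dict | None = None) -> dict:
    """Merge a (possibly partial) config over the defaults and validate it."""
    cfg = _merge(DEFAULT_CONFIG, config) if config is not None else copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        cfg = _merge(cfg, overrides)
    cfg = _canonical(cfg)
    _validate(cfg)
    return cfg


def _canonical(obj):
    """Normalize sequences to lists so resolved configs round-trip."""
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> dict:
    """Read a YAML config file and resolve it against the defaults.

    An empty file yields the committed calibrated defaults.  Unknown keys
    and invariant violations raise :class:`ConfigError` naming the key or
    invariant.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return resolve_config(data)


def dump_config(cfg: dict, path=None) -> str:
    """Serialize a resolved config to YAML (round-trips through load)."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    text = yaml.safe_dump(clean(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def build_network(cfg: dict) -> NetworkConfig:
    """Construct the two-layer network from a resolved configuration.

    Layer 1 always uses the baseline subfields (inhibitory scale 2.0,
    excitatory scale 1.0, amplitude scales 1.0); the scaled parameters in
    the config apply to layer 2 only.
    """
    m = cfg["model"]
    unit = m["sigma_unit"]
    h_inh = m["h_inh"]
    h_ex = h_inh * m["h_ratio"]
    radius = m["radius_sigmas"]
    norm = m["normalize_subfields"]

    def layer(sig_inh_scale, sig_ex_scale, h_inh_scale, h_ex_scale) -> LayerParams:
        exc = KernelSpec(h=h_ex * h_ex_scale, sigma=unit * sig_ex_scale,
                         radius_sigmas=radius)
        inh = KernelSpec(h=h_inh * h_inh_scale, sigma=unit * sig_inh_scale,
                         radius_sigmas=radius)
        g_ex, g_inh = make_subfields(exc, inh, m["B"], m["C"], normalize=norm)
        return LayerParams(A=m["A"], B=m["B"], C=m["C"], g_ex=g_ex, g_inh=g_inh)

    layer1 = layer(2.0, 1.0, 1.0, 1.0)
    layer2 = layer(m["sigma_inh_scale"], m["sigma_ex_scale"],
                   m["h_inh_scale"], m["h_ex_scale"])
    return NetworkConfig(
        layer1=layer1,
        layer2=layer2,
        alpha=m["alpha"],
        dt_integ=m["dt_integ"],
        n_loops=m["n_loops"],
        settle_tol=m["settle_tol"],
        max_settle_steps=m["max_settle_steps"],
        boundary=m["boundary"],
        rectify_transmission=m["rectify_transmission"],
    )


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit-identically."""

    config: dict
    converged: bool = True
    extras: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.config), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "config": _jsonable(self.config),
            "config_hash": self.config_hash,
            "converged": self.converged,
            "extras": _jsonable(self.extras),
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return repr(obj)


def write_results(table: pd.DataFrame, manifest: RunManifest, out_dir,
                  stem: str = "results") -> tuple[Path, Path]:
    """Write a result table as CSV plus its JSON manifest.

    The CSV has a stable column order (as held by the table) and full
    float precision, so identical manifests reproduce identical bytes;
    the timestamp lives only in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.manifest.json"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    json_path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return csv_path, json_path
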