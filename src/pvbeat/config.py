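"""Run configuration: one structured YAML file, flat keys internally.

The file mirrors the analysis knobs::

    sampling:
      target_hz: 500
    smoothing:
      window: 31          # samples at 500 Hz (scaled with rate)
      polyorder: 5
      cutoff_hz: 15.0     # Gaussian pre-smoother, -3 dB
    segmentation:
      mode: auto          # auto | pressure_minima | ecg
    analysis:
      pisomax_ceiling: 500.0
      veed_prior_ml: 140.0

Command-line flags override file values; all keys are optional.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

__all__ = ["load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "target_hz": 500.0,
    "segmentation_mode": "auto",
}


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Load the YAML config file and flatten it to analysis keys.

    Returns a dict accepted by :func:`pvbeat.mechanics.analyze_trace`;
    ``overrides`` (flat keys) win over file values, which win over
    defaults.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        sampling = raw.get("sampling", {}) or {}
        if "target_hz" in sampling:
            cfg["target_hz"] = float(sampling["target_hz"])
        smoothing = raw.get("smoothing", {}) or {}
        if smoothing:
            cfg["smoothing"] = {
                k: smoothing[k]
                for k in ("window", "polyorder", "cutoff_hz")
                if k in smoothing
            }
        segmentation = raw.get("segmentation", {}) or {}
        if "mode" in segmentation:
            cfg["segmentation_mode"] = str(segmentation["mode"])
        analysis = raw.get("analysis", {}) or {}
        for key in ("pisomax_ceiling", "veed_prior_ml"):
            if key in analysis:
                cfg[key] = float(analysis[key])
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
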