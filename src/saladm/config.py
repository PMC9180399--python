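"""Scenario configuration files.

A scenario file is YAML with three blocks: the preset name, flat parameter
overrides named by their tabulated symbols (``km_pro``, ``KS_su``,
``KI_pp``, ``n`` ...), and the operating schedule::

    scenario: NaCl
    params:
      km_pro: 0.039
    schedule:
      srt: 40
      feed_cod: 158
      sulfate_feed: 0.0
      segments:
        - [0, 330, 0.8]
        - [330, 480, 0.75]

Omitted blocks fall back to the preset defaults; a missing schedule yields
``None`` so callers can supply their own.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .model_core import build_model, build_processes
from .reactor import OperatingSchedule

__all__ = ["load_scenario", "scenario_from_dict", "config_hash"]


def scenario_from_dict(cfg: dict):
    """Build ``(model, schedule_or_None)`` from a parsed scenario dict."""
    name = cfg.get("scenario", "default")
    registry, processes, params = build_model(name)
    overrides = cfg.get("params") or {}
    for key, value in overrides.items():
        params.set_flat(key, float(value))
    params.validate()
    if overrides:
        processes = build_processes(params)

    schedule = None
    sched_cfg = cfg.get("schedule")
    if sched_cfg:
        kw = {k: float(sched_cfg[k])
              for k in ("volume", "srt", "feed_cod", "sulfate_feed")
              if k in sched_cfg}
        segments = [tuple(map(float, s)) for s in sched_cfg["segments"]]
        schedule = OperatingSchedule(segments=segments, **kw)
    return (registry, processes, params), schedule


def load_scenario(path) -> Tuple[tuple, Optional[OperatingSchedule]]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return scenario_from_dict(cfg)


def config_hash(path) -> str:
    """Short stable digest of a config file, for run metadata."""
    data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()[:12]
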