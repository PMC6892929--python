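"""Structured run configuration: defaults, YAML loading, and hashing.

A single YAML file can override any of the defaults. Sections map onto the
library's dataclasses:

.. code-block:: yaml

    assay:
      serum_fraction: 0.25
      reaction_volume_uL: 200
      serum_volume_uL: 50
      serum_thresholds: [10.0, 13.0]
    roi:
      window_side: 20
      zoom_side: 200
    thresholds:
      purple_red: 1.5
      red_orange: 2.5
      violacein_purple: 0.2
    palette:
      residual_gate: 60.0
      anchors:
        - [0.0, [105, 33, 82]]
        # ...
    circuit:       # simulation only; placeholder dose-response parameters
      v_max: 0.5
      k_vio: 1.5
    optics:        # simulation only
      noise_sigma: 3.0
    simulate:
      standards_zinc: [0, 1, 2, 3.5, 5]
      test_zinc: 2.5
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .color_model import ClassThresholds, Palette
from .errors import ConfigError
from .forward_model import DEFAULT_STANDARDS_ZINC, CircuitParams, OpticalModel
from .pellet_extraction import DEFAULT_WINDOW_SIDE, DEFAULT_ZOOM_SIDE
from .quantify import AssayConfig

__all__ = ["RoiConfig", "SimulateConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class RoiConfig:
    """Region-of-interest geometry for pellet selection."""

    window_side: int = DEFAULT_WINDOW_SIDE
    zoom_side: int = DEFAULT_ZOOM_SIDE

    def __post_init__(self) -> None:
        if not (0 < self.window_side <= self.zoom_side):
            raise ConfigError("need 0 < window_side <= zoom_side")


@dataclass(frozen=True)
class SimulateConfig:
    """Scenario for synthetic assay images."""

    standards_zinc: tuple[float, ...] = DEFAULT_STANDARDS_ZINC
    test_zinc: float = 2.5
    pellet_radius: float = 16.0
    spacing: int = 56
    margin: int = 40
    height: int = 80


@dataclass(frozen=True)
class RunConfig:
    """All tunables for one run, with field defaults throughout."""

    assay: AssayConfig = field(default_factory=AssayConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    palette: Palette = field(default_factory=Palette)
    circuit: CircuitParams = field(default_factory=CircuitParams)
    optics: OpticalModel = field(default_factory=OpticalModel)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0

    def config_hash(self) -> str:
        """Short stable digest of the full configuration, for run logs."""
        def default(o):
            try:
                return o.tolist()
            except AttributeError:
                return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, section: dict, **coerced):
    try:
        return cls(**{**section, **coerced})
    except TypeError as exc:
        raise ConfigError(f"bad keys for {cls.__name__}: {exc}") from exc


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults plus an optional YAML file."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")

    assay_sec = dict(raw.get("assay", {}))
    if "serum_thresholds" in assay_sec:
        assay_sec["serum_thresholds"] = tuple(assay_sec["serum_thresholds"])
    palette_sec = dict(raw.get("palette", {}))
    if "anchors" in palette_sec:
        palette_sec["anchors"] = tuple(
            (float(s), tuple(map(float, rgb))) for s, rgb in palette_sec["anchors"]
        )
    optics_sec = dict(raw.get("optics", {}))
    for key in ("background_rgb", "illumination_gain"):
        if key in optics_sec:
            optics_sec[key] = tuple(map(float, optics_sec[key]))
    sim_sec = dict(raw.get("simulate", {}))
    if "standards_zinc" in sim_sec:
        sim_sec["standards_zinc"] = tuple(map(float, sim_sec["standards_zinc"]))

    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    if cfg_seed < 0:
        raise ConfigError("seed must be a nonnegative integer")
    return RunConfig(
        assay=_build(AssayConfig, assay_sec),
        roi=_build(RoiConfig, dict(raw.get("roi", {}))),
        thresholds=_build(ClassThresholds, dict(raw.get("thresholds", {}))),
        palette=_build(Palette, palette_sec),
        circuit=_build(CircuitParams, dict(raw.get("circuit", {}))),
        optics=_build(OpticalModel, optics_sec),
        simulate=_build(SimulateConfig, sim_sec),
        seed=cfg_seed,
    )
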