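"""YAML configuration loading.

One YAML file configures a whole analysis run; top-level keys map to the
component configs (``laser``, ``occlusion``, ``trajectory``,
``detection``, ``pipeline``).  The full key schema ships with the
package as ``config_schema.yaml``.
"""

from __future__ import annotations

from dataclasses import fields
from importlib import resources
from pathlib import Path

import yaml

from .calibration import LaserDetectionConfig
from .footwear import OcclusionSearchConfig
from .pipeline import PipelineConfig
from .trajectory import StrideSegmentationConfig


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (defaults if None)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        laser=_build(LaserDetectionConfig, doc.get("laser", {})),
        occlusion=_build(OcclusionSearchConfig, doc.get("occlusion", {})),
        strides=_build(StrideSegmentationConfig, doc.get("trajectory", {})),
    )
    pipe = doc.get("pipeline", {})
    for key in ("laser_distance_mm", "mfc_method", "laser_min_hits",
                "laser_miss_patience"):
        if key in pipe:
            setattr(cfg, key, pipe[key])
    # `detection:` keys configure the classical backend and are consumed
    # by the caller constructing it.
    cfg.detection = doc.get("detection", {})  # type: ignore[attr-defined]
    return cfg


def config_schema() -> str:
    """The documented YAML schema shipped with the package."""
    return resources.files("footclear").joinpath("config_schema.yaml").read_text()
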