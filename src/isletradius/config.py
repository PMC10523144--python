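"""Detection and analysis configuration.

Thresholds live in a single TOML file with an ``[ihc]`` and an ``[if]``
section (plus an optional ``[geometry]`` section); CLI flags override file
values. Hue is configured in degrees [0, 360) regardless of any internal
library scaling; saturation, value and intensity are fractions in [0, 1].

The shipped IHC defaults describe an "earthy red-brown" DAB chromogen box
(hue 0-50 deg, saturation >= 0.2, value 0.1-0.95). They are a documented
heuristic starting point, not measured constants, and users are expected to
override them per staining batch.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "DetectionConfig",
    "default_config",
    "load_config",
]


class ConfigError(ValueError):
    """Malformed or inconsistent configuration."""


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for one staining mode.

    mode
        ``"ihc"`` (RGB, HSV box) or ``"if"`` (grayscale, intensity threshold).
    hsv_lower, hsv_upper
        (hue deg, saturation, value) box corners; the hue interval may wrap
        (lower > upper means the interval passes through 0 deg).
    if_threshold
        intensity in [0, 1], or ``"otsu"`` for a per-image Otsu threshold.
    min_blob_size
        optional minimum connected-component size in pixels (0 disables;
        default off — detection is pure thresholding).
    """

    mode: str
    hsv_lower: tuple[float, float, float] = (0.0, 0.2, 0.1)
    hsv_upper: tuple[float, float, float] = (50.0, 1.0, 0.95)
    if_threshold: float | str = "otsu"
    min_blob_size: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ihc", "if"):
            raise ConfigError(f"mode must be 'ihc' or 'if', got {self.mode!r}")
        lo, hi = self.hsv_lower, self.hsv_upper
        if len(lo) != 3 or len(hi) != 3:
            raise ConfigError("hsv_lower/hsv_upper must be (hue, sat, value) triples")
        if not (0.0 <= lo[0] < 360.0 and 0.0 <= hi[0] < 360.0):
            raise ConfigError("hue bounds must lie in [0, 360)")
        for name, (a, b) in (("saturation", (lo[1], hi[1])), ("value", (lo[2], hi[2]))):
            if not (0.0 <= a <= b <= 1.0):
                raise ConfigError(f"{name} bounds must satisfy 0 <= lower <= upper <= 1")
        if isinstance(self.if_threshold, str):
            if self.if_threshold != "otsu":
                raise ConfigError("if_threshold must be a number in [0,1] or 'otsu'")
        elif not (0.0 <= float(self.if_threshold) <= 1.0):
            raise ConfigError("if_threshold must lie in [0, 1]")
        if self.min_blob_size < 0:
            raise ConfigError("min_blob_size must be >= 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """Full run configuration: one detection config per mode + geometry options."""

    ihc: DetectionConfig = field(default_factory=lambda: DetectionConfig(mode="ihc"))
    if_: DetectionConfig = field(default_factory=lambda: DetectionConfig(mode="if"))
    centroid_method: str = "vertex_mean"

    def __post_init__(self) -> None:
        if self.centroid_method not in ("vertex_mean", "area"):
            raise ConfigError("centroid_method must be 'vertex_mean' or 'area'")

    def detection_for(self, mode: str) -> DetectionConfig:
        if mode == "ihc":
            return self.ihc
        if mode == "if":
            return self.if_
        raise ConfigError(f"unknown stain mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "ihc": {
                "hsv_lower": list(self.ihc.hsv_lower),
                "hsv_upper": list(self.ihc.hsv_upper),
                "min_blob_size": self.ihc.min_blob_size,
            },
            "if": {
                "threshold": self.if_.if_threshold,
                "min_blob_size": self.if_.min_blob_size,
            },
            "geometry": {"centroid": self.centroid_method},
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_config() -> AnalysisConfig:
    return AnalysisConfig()


def _pair(section: dict, key: str, fallback: tuple[float, float]) -> tuple[float, float]:
    raw = section.get(key, list(fallback))
    if not isinstance(raw, (list, tuple)) or len(raw) != 2:
        raise ConfigError(f"'{key}' must be a [lower, upper] pair")
    return float(raw[0]), float(raw[1])


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML file; defaults if ``path`` is None."""
    if path is None:
        return default_config()
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid TOML: {exc}") from exc

    base = default_config()
    ihc_sec = data.get("ihc", {})
    h = _pair(ihc_sec, "hue", (base.ihc.hsv_lower[0], base.ihc.hsv_upper[0]))
    s = _pair(ihc_sec, "saturation", (base.ihc.hsv_lower[1], base.ihc.hsv_upper[1]))
    v = _pair(ihc_sec, "value", (base.ihc.hsv_lower[2], base.ihc.hsv_upper[2]))
    ihc = DetectionConfig(
        mode="ihc",
        hsv_lower=(h[0], s[0], v[0]),
        hsv_upper=(h[1], s[1], v[1]),
        min_blob_size=int(ihc_sec.get("min_blob_size", 0)),
    )
    if_sec = data.get("if", {})
    thr = if_sec.get("threshold", base.if_.if_threshold)
    if not isinstance(thr, str):
        thr = float(thr)
    if_ = DetectionConfig(
        mode="if",
        if_threshold=thr,
        min_blob_size=int(if_sec.get("min_blob_size", 0)),
    )
    geo = data.get("geometry", {})
    return AnalysisConfig(
        ihc=ihc, if_=if_, centroid_method=geo.get("centroid", base.centroid_method)
    )
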