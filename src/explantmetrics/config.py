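"""Run-wide configuration shared by every pipeline stage.

The defaults reproduce the analysis parameters of the dataset's original
quantification code: 2.58 µm per pixel, 360 angular samples, a boundary
moving-average window of 150 samples, and a reconstruction order of 2
(i.e. the five coefficients a0, a1, b1, a2, b2).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("explantmetrics")

#: Physical scale of the dataset, micrometres per pixel.
DEFAULT_SCALE_UM_PER_PX = 2.58
#: Number of discrete polar angles for the radial outgrowth function.
DEFAULT_ANGLE_COUNT = 360
#: Width (in boundary samples) of the circular moving-average smoother.
DEFAULT_SMOOTHING_WIDTH = 150
#: Maximum harmonic kept when reconstructing shapes for display.
DEFAULT_RECONSTRUCTION_ORDER = 2


@dataclass
class RunConfig:
    """Resolved parameters for one quantification run.

    Attributes
    ----------
    scale_um_per_px:
        Micrometres per image pixel; converts radial quantities to µm.
    angle_count:
        Number of discrete angles θ_n = 2πn/N. Must be even.
    smoothing_width:
        Window (boundary samples) of the circular moving average applied to
        boundary curves before polar parameterisation.
    reconstruction_order:
        Highest harmonic drawn in overlays; 2 keeps the five coefficients
        a0, a1, b1, a2, b2.
    correction_factors:
        Optional mapping steepness level -> concentration multiplier, applied
        only to the concentration axis of condition summaries (never to
        per-explant metrics). The published multipliers are distributed with
        the original dataset and are not bundled here; the default identity
        mapping leaves nominal concentrations untouched.
    seed:
        Seed for any stochastic step (synthetic generation only; the
        measurement pipeline itself is deterministic).
    log_level:
        Logging level name for the package logger.
    """

    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    angle_count: int = DEFAULT_ANGLE_COUNT
    smoothing_width: int = DEFAULT_SMOOTHING_WIDTH
    reconstruction_order: int = DEFAULT_RECONSTRUCTION_ORDER
    correction_factors: dict[float, float] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.angle_count < 4 or self.angle_count % 2:
            raise ValueError("angle_count must be even and >= 4")
        if self.smoothing_width < 1:
            raise ValueError("smoothing_width must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["correction_factors"] is not None:
            d["correction_factors"] = {str(k): v for k, v in d["correction_factors"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cf = d.get("correction_factors")
        if cf is not None:
            d["correction_factors"] = {float(k): float(v) for k, v in cf.items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key=value`` configuration file.

        Lines are ``name=value``; blank lines and ``#`` comments are ignored.
        ``correction_factors`` is given as ``steepness:mult`` pairs separated
        by commas, e.g. ``correction_factors=0.1:0.9,0.2:0.85``.
        """
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "correction_factors":
                pairs = [p for p in value.split(",") if p.strip()]
                kwargs[key] = {
                    float(p.split(":")[0]): float(p.split(":")[1]) for p in pairs
                }
            elif key in ("angle_count", "smoothing_width", "reconstruction_order", "seed"):
                kwargs[key] = int(value)
            elif key == "scale_um_per_px":
                kwargs[key] = float(value)
            elif key == "log_level":
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)


def configure_logging(level: str = "INFO") -> None:
    """Send package logs to stderr; machine-readable output goes to files only."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
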