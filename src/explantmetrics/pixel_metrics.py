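"""Area-based outgrowth/guidance statistics and the per-explant pipeline.

Two pixel-count measures summarise each explant:

* outgrowth ratio ``OG`` — foreground pixels in the neurite mask divided by
  foreground pixels in the explant-body mask;
* guidance ratio ``GR = (H − L)/(H + L)`` — where H and L count neurite
  pixels on the high- (toward row 0, up-gradient) and low-concentration
  sides of the horizontal line through the body centroid. Pixels exactly on
  the (rounded) centroid row belong to neither side, which keeps GR exactly
  antisymmetric under a vertical mirror.

:func:`quantify_explant` chains the whole measurement — contiguity filter,
boundary tracing, smoothing, polar parameterisation, Fourier decomposition —
into one record per explant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import boundary_geometry as bg
from . import fourier_shape as fs
from .config import DEFAULT_SCALE_UM_PER_PX, RunConfig, log
from .dataset_io import BinaryMask, ExplantRecord


class UndefinedGuidanceError(ValueError):
    """GR undefined: no neurite pixels off the centroid row."""


def outgrowth_ratio(neurite_mask: BinaryMask, explant_mask: BinaryMask) -> float:
    """OG: neurite foreground pixel count over explant foreground count."""
    if explant_mask.is_empty:
        raise bg.EmptyMaskError("outgrowth ratio undefined: empty explant mask")
    return neurite_mask.count / explant_mask.count


def guidance_ratio(neurite_mask: BinaryMask, explant_mask: BinaryMask) -> float:
    """GR = (H − L)/(H + L) about the explant-body centroid row.

    H counts neurite pixels strictly above the centroid row (up-gradient),
    L strictly below; the centroid row itself is excluded from both.
    """
    if neurite_mask.is_empty:
        raise bg.EmptyMaskError("guidance ratio undefined: empty neurite mask")
    split_row = round(bg.centroid(explant_mask)[0])
    rows = np.nonzero(neurite_mask.pixels)[0]
    h = int((rows < split_row).sum())
    low = int((rows > split_row).sum())
    if h + low == 0:
        raise UndefinedGuidanceError("all neurite pixels lie on the centroid row")
    return (h - low) / (h + low)


def to_micrometres(value_px: float, scale: float = DEFAULT_SCALE_UM_PER_PX) -> float:
    """Convert a pixel length to micrometres."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return value_px * scale


@dataclass
class ExplantResult:
    """Full quantification record for one explant (the S.mat row analogue)."""

    name: str
    steepness: float | None
    concentration: float | None
    centroid: tuple[float, float]
    soma_curve: bg.BoundaryCurve
    outgrowth_curve: bg.BoundaryCurve | None
    outgrowth_coeffs: fs.FourierCoefficients
    somata_coeffs: fs.FourierCoefficients
    averageOutgrowth_px: float
    averageOutgrowth_um: float
    directionalBias: float | None
    orthogonalBias: float | None
    OG: float
    GR: float | None
    empty_outgrowth: bool
    config: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat scalar summary for one CSV row."""
        return {
            "name": self.name,
            "steepness": self.steepness,
            "concentration": self.concentration,
            "centroid_row": self.centroid[0],
            "centroid_col": self.centroid[1],
            "averageOutgrowth_px": self.averageOutgrowth_px,
            "averageOutgrowth_um": self.averageOutgrowth_um,
            "directionalBias": self.directionalBias,
            "orthogonalBias": self.orthogonalBias,
            "OG": self.OG,
            "GR": self.GR,
            "empty_outgrowth": self.empty_outgrowth,
        }

    def to_json_dict(self) -> dict:
        """Boundary curves and coefficient tables (the JSON sidecar)."""
        return {
            "name": self.name,
            "steepness": self.steepness,
            "concentration": self.concentration,
            "centroid": list(self.centroid),
            "somataBoundary_xy": self.soma_curve.to_xy().tolist(),
            "outgrowthBoundary_xy": (
                self.outgrowth_curve.to_xy().tolist() if self.outgrowth_curve else None
            ),
            "outgrowthCoeffs": self.outgrowth_coeffs.to_table().to_dict(orient="list"),
            "somataCoeffs": self.somata_coeffs.to_table().to_dict(orient="list"),
            "metrics": self.to_row(),
            "config": self.config,
        }


def _zero_coeffs(n_angles: int) -> fs.FourierCoefficients:
    k = n_angles // 2
    return fs.FourierCoefficients(a=np.zeros(k + 1), b=np.zeros(k), n_angles=n_angles)


def quantify_explant(
    neurite_mask: BinaryMask,
    explant_mask: BinaryMask,
    config: RunConfig | None = None,
    record: ExplantRecord | None = None,
    name: str = "",
) -> ExplantResult:
    """Run the complete measurement chain on one explant.

    Debris (neurite components not contiguous with the body) is removed
    before any measurement, so all reported quantities refer to the
    contiguous outgrowth only. A zero-outgrowth explant yields OG = 0, an
    all-zero coefficient table and undefined (None) bias and GR.
    """
    cfg = config or RunConfig()
    if neurite_mask.shape != explant_mask.shape:
        raise ValueError("neurite and explant masks must share dimensions")
    name = name or (record.stem if record is not None else "")

    retained = bg.retain_contiguous(neurite_mask, explant_mask)
    origin = bg.centroid(explant_mask)
    soma_traced = bg.trace_outer_boundary(explant_mask)
    # Clamp the window for tiny regions so batch runs never abort on them.
    soma_curve = bg.smooth_boundary(soma_traced, min(cfg.smoothing_width, len(soma_traced)))
    n = cfg.angle_count
    soma_radius = bg.curve_radius_profile(soma_curve, origin, n)
    somata_coeffs = fs.decompose(soma_radius)

    og = outgrowth_ratio(retained, explant_mask)
    if retained.is_empty:
        log.info("%s: no contiguous outgrowth", name or "<unnamed>")
        return ExplantResult(
            name=name,
            steepness=record.steepness if record else None,
            concentration=record.concentration if record else None,
            centroid=origin,
            soma_curve=soma_curve,
            outgrowth_curve=None,
            outgrowth_coeffs=_zero_coeffs(n),
            somata_coeffs=somata_coeffs,
            averageOutgrowth_px=0.0,
            averageOutgrowth_um=0.0,
            directionalBias=None,
            orthogonalBias=None,
            OG=og,
            GR=None,
            empty_outgrowth=True,
            config=cfg.to_dict(),
        )

    # The outgrowth region's outer boundary: trace the union of body and
    # contiguous outgrowth so interior holes along the body interface cannot
    # split the outer contour.
    combined = BinaryMask(retained.pixels | explant_mask.pixels, scale=retained.scale)
    out_traced = bg.trace_outer_boundary(combined)
    out_curve = bg.smooth_boundary(out_traced, min(cfg.smoothing_width, len(out_traced)))
    profile = bg.radial_profile(soma_curve, out_curve, origin, n, scale=cfg.scale_um_per_px)
    coeffs = fs.decompose(profile)

    try:
        metrics = fs.bias_metrics(coeffs, scale=1.0)
        directional = metrics["directionalBias"]
        orthogonal = metrics["orthogonalBias"]
    except fs.DegenerateProfileError:
        directional = orthogonal = None
    try:
        gr = guidance_ratio(retained, explant_mask)
    except UndefinedGuidanceError:
        gr = None

    a0_px = float(coeffs.a[0])
    return ExplantResult(
        name=name,
        steepness=record.steepness if record else None,
        concentration=record.concentration if record else None,
        centroid=origin,
        soma_curve=soma_curve,
        outgrowth_curve=out_curve,
        outgrowth_coeffs=coeffs,
        somata_coeffs=somata_coeffs,
        averageOutgrowth_px=a0_px,
        averageOutgrowth_um=to_micrometres(a0_px, cfg.scale_um_per_px),
        directionalBias=directional,
        orthogonalBias=orthogonal,
        OG=og,
        GR=gr,
        empty_outgrowth=False,
        config=cfg.to_dict(),
    )
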