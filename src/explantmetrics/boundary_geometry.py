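"""Boundary extraction and polar parameterisation of explant masks.

The measurement chain implemented here turns a pair of binary masks (explant
body, neurite outgrowth) into the radial outgrowth function R(θ_n):

1. keep only outgrowth components contiguous with the explant body;
2. trace the outer boundary of each region as a closed pixel chain
   (Moore-neighbour tracing, 8-connectivity);
3. smooth each boundary with a circular moving average;
4. sample each curve's radius at N discrete angles about the body centroid
   and subtract, clamping at zero.

Angle convention, shared package-wide: θ is measured in the Cartesian frame
x = column, y = −row, so θ = 0 points right and θ = π/2 points to the top of
the image — the up-gradient direction. A positive first sine coefficient of
R(θ) therefore means outgrowth biased up the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DEFAULT_ANGLE_COUNT, log
from .dataset_io import BinaryMask

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order starting west, as (drow, dcol).
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


class EmptyMaskError(ValueError):
    """Geometric operation attempted on a mask with no foreground pixels."""


@dataclass
class BoundaryCurve:
    """Ordered closed polyline of (row, col) coordinates.

    The first point is not repeated at the end; closure is implicit.
    Consecutive points of a freshly traced curve are 8-connected; smoothing
    yields sub-pixel coordinates but preserves order and closure.
    """

    points: np.ndarray  # (M, 2) float or int, rows then cols
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (M, 2)")

    def __len__(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area in the (x=col, y=−row) frame; positive = CCW."""
        x = self.points[:, 1]
        y = -self.points[:, 0]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def to_xy(self) -> np.ndarray:
        """(M, 2) array of (x, y) in the flipped-y Cartesian frame."""
        return np.column_stack([self.points[:, 1], -self.points[:, 0]])


@dataclass
class RadialProfile:
    """R(θ_n) sampled at N angles θ_n = 2πn/N about a fixed origin."""

    values: np.ndarray  # length N, >= 0, pixels
    origin: tuple[float, float]  # (row, col)
    scale: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def n_angles(self) -> int:
        return len(self.values)

    @property
    def thetas(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_angles) / self.n_angles


def retain_contiguous(neurite_mask: BinaryMask, explant_mask: BinaryMask) -> BinaryMask:
    """Keep only neurite components contiguous with the explant body.

    A component is retained iff one of its pixels coincides with, or
    8-neighbours, an explant-body pixel; disconnected debris is removed.
    An empty result is valid (an explant with no outgrowth) and is returned
    as an empty mask for the caller to flag. Idempotent.
    """
    if neurite_mask.shape != explant_mask.shape:
        raise ValueError("neurite and explant masks must share dimensions")
    if explant_mask.is_empty:
        raise EmptyMaskError("explant mask has no foreground pixels")
    labels, n = ndimage.label(neurite_mask.pixels, structure=_EIGHT)
    if n == 0:
        return BinaryMask(np.zeros(neurite_mask.shape, bool), scale=neurite_mask.scale)
    reach = ndimage.binary_dilation(explant_mask.pixels, structure=_EIGHT)
    touching = np.unique(labels[reach & (labels > 0)])
    if touching.size == 0:
        log.info("no neurite component touches the explant body: empty outgrowth")
        kept = np.zeros(neurite_mask.shape, bool)
    else:
        kept = np.isin(labels, touching)
    return BinaryMask(kept, scale=neurite_mask.scale)


def _largest_component(pixels: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(pixels, structure=_EIGHT)
    if n <= 1:
        return pixels
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def trace_outer_boundary(mask: BinaryMask) -> BoundaryCurve:
    """Trace the closed outer boundary of the mask's largest component.

    Moore-neighbour tracing with 8-connectivity and Jacob's stopping
    criterion, visiting each outer-boundary pixel in order. The returned
    curve is normalised counter-clockwise in the (x=col, y=−row) frame.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot trace boundary of an empty mask")
    pix = _largest_component(mask.pixels)
    # Pad so neighbour lookups never leave the array.
    padded = np.zeros((pix.shape[0] + 2, pix.shape[1] + 2), bool)
    padded[1:-1, 1:-1] = pix
    rows, cols = np.nonzero(padded)  # row-major: first entry is uppermost-leftmost
    start = (int(rows[0]), int(cols[0]))
    # Row-major scan: the W..NE neighbours of the start pixel are background,
    # so W is a valid initial backtrack direction.
    p, back_dir = start, 0
    first_state = (p, back_dir)
    points: list[tuple[int, int]] = []
    while True:
        points.append(p)
        for i in range(1, 9):
            d = (back_dir + i) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if padded[q]:
                prev = (back_dir + i - 1) % 8
                back_pixel = (p[0] + _MOORE[prev][0], p[1] + _MOORE[prev][1])
                p = q
                back_dir = _MOORE_INDEX[(back_pixel[0] - q[0], back_pixel[1] - q[1])]
                break
        else:  # isolated single pixel
            break
        if (p, back_dir) == first_state:
            break
    pts = np.array(points, dtype=float) - 1.0  # undo padding offset
    curve = BoundaryCurve(pts)
    if len(curve) > 2 and curve.signed_area() < 0:
        curve = BoundaryCurve(pts[::-1])
    return curve


def centroid(mask: BinaryMask) -> tuple[float, float]:
    """Sub-pixel centroid (mean row, mean col) of the foreground pixels."""
    if mask.is_empty:
        raise EmptyMaskError("cannot compute centroid of an empty mask")
    rows, cols = np.nonzero(mask.pixels)
    return float(rows.mean()), float(cols.mean())


def smooth_boundary(curve: BoundaryCurve, width: int = 150) -> BoundaryCurve:
    """Circular moving average of the boundary points.

    Each output point is the unweighted mean of ``width`` consecutive input
    points, with wrap-around so curve closure is preserved; the point count
    is unchanged. ``width`` is measured in boundary samples, which for an
    8-connected pixel chain corresponds to the original method's
    width-in-pixels. Width 1 is the identity.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    m = len(curve)
    if width > m:
        raise ValueError(
            f"smoothing width {width} exceeds curve length {m}; use width <= {m}"
        )
    if width == 1:
        return BoundaryCurve(curve.points.copy())
    offsets = np.arange(width) - (width - 1) // 2
    idx = (np.arange(m)[:, None] + offsets[None, :]) % m
    return BoundaryCurve(curve.points[idx].mean(axis=1))


def curve_radius_profile(
    curve: BoundaryCurve, origin: tuple[float, float], n_angles: int = DEFAULT_ANGLE_COUNT
) -> np.ndarray:
    """Radius of a closed curve at each θ_n, as seen from ``origin``.

    Each ray θ_n is intersected with the closed polyline: every segment whose
    endpoint angles straddle θ_n contributes a crossing radius (linear
    interpolation in angle), and where a ray crosses the curve more than once
    the crossing *closest to the origin* wins. Angles with no crossing (only
    possible for degenerate curves that do not enclose the origin) are filled
    by linear interpolation between their nearest sampled neighbours in
    circular order.
    """
    delta = 2.0 * np.pi / n_angles
    d_row = curve.points[:, 0] - origin[0]
    d_col = curve.points[:, 1] - origin[1]
    theta = np.arctan2(-d_row, d_col) % (2.0 * np.pi)
    radius = np.hypot(d_row, d_col)
    prof = np.full(n_angles, np.nan)

    if len(curve) > 1:
        theta_next = np.roll(theta, -1)
        radius_next = np.roll(radius, -1)
        # signed shortest angular step of each segment
        step = (theta_next - theta + np.pi) % (2.0 * np.pi) - np.pi
        end = theta + step
        lo = np.minimum(theta, end)
        hi = np.maximum(theta, end)
        n_lo = np.ceil(lo / delta - 1e-9).astype(int)
        n_hi = np.floor(hi / delta + 1e-9).astype(int)
        counts = n_hi - n_lo + 1
        valid = counts > 0
        if valid.any():
            c = counts[valid]
            seg = np.repeat(np.nonzero(valid)[0], c)
            intra = np.arange(c.sum()) - np.repeat(np.cumsum(c) - c, c)
            grid = (n_lo[valid].repeat(c) + intra) * delta
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(
                    np.abs(step[seg]) > 1e-12, (grid - theta[seg]) / step[seg], 0.0
                )
            crossing = radius[seg] + (radius_next[seg] - radius[seg]) * np.clip(frac, 0.0, 1.0)
            bins = np.rint(grid / delta).astype(int) % n_angles
            np.fmin.at(prof, bins, crossing)
    else:
        prof[int(np.rint(theta[0] / delta)) % n_angles] = radius[0]

    empty = np.isnan(prof)
    if empty.any():
        if empty.all():
            # curve so small it crosses no grid angle: constant radius
            return np.full(n_angles, float(radius.min()))
        log.debug("interpolating %d empty angular samples", int(empty.sum()))
        idx = np.arange(n_angles)
        prof = np.interp(idx, idx[~empty], prof[~empty], period=n_angles)
    return prof


def radial_profile(
    soma_curve: BoundaryCurve,
    outgrowth_curve: BoundaryCurve,
    origin: tuple[float, float],
    n_angles: int = DEFAULT_ANGLE_COUNT,
    scale: float = 1.0,
) -> RadialProfile:
    """Radial outgrowth function R(θ_n) between two closed boundaries.

    R(θ_n) is the distance from the cell-body boundary to the outgrowth
    boundary along direction θ_n from ``origin`` (the body centroid),
    clamped at zero where smoothing pushes the outer curve inside the body.
    """
    if n_angles < 4 or n_angles % 2:
        raise ValueError("n_angles must be even and >= 4")
    r_soma = curve_radius_profile(soma_curve, origin, n_angles)
    r_out = curve_radius_profile(outgrowth_curve, origin, n_angles)
    values = np.clip(r_out - r_soma, 0.0, None)
    return RadialProfile(values=values, origin=origin, scale=scale)
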