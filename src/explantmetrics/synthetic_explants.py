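"""Synthetic explant masks with known ground truth.

Real DRG explants in collagen show a roughly elliptical cell-body region
surrounded by a halo of neurite outgrowth whose outer contour is dominated
by low-order angular harmonics, plus occasional disconnected debris from
segmentation. This module rasterises exactly that structure from explicit
ground-truth parameters so that every stage of the measurement pipeline can
be validated without the original ~3500-image dataset.

Rasterisation is a per-pixel polar test (is the pixel centre inside the
curve?), deliberately sharing no code with the boundary-tracing/Fourier
measurement path: recovered coefficients are therefore an independent check,
not a tautology.

The angle convention matches the measurement modules (x = col, y = −row), so
a positive true b1 places extra outgrowth toward the top of the image — the
up-gradient direction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .config import log
from .dataset_io import BinaryMask, ExplantRecord, format_filename
from .dataset_io import write_mask as _write_mask

#: Default image size (rows, cols); holds a body of ~250 px semi-axis plus
#: outgrowth of ~120–160 px with margin.
DEFAULT_SHAPE = (1024, 1024)
#: Pixel intensity threshold that recovers the masks from rendered images.
INTENSITY_THRESHOLD = 10000

#: Steepness levels (%/10 µm) of the emulated condition grid.
DEFAULT_STEEPNESS_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4)
#: Background concentrations (nM) of the emulated condition grid.
DEFAULT_CONCENTRATION_LEVELS = (0.001, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


class GenerationError(ValueError):
    """Truth parameters describe a non-physical (self-intersecting) shape."""


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for one synthetic explant.

    The outgrowth profile is R(θ) = a0 + a1·cosθ + b1·sinθ + a2·cos2θ +
    b2·sin2θ plus band-limited noise harmonics with random phases. The
    positivity invariant a0 > |a1|+|b1|+|a2|+|b2| + noise amplitude
    guarantees a star-shaped (non-self-intersecting) outer contour.
    """

    centre: tuple[float, float] = (512.0, 512.0)  # (row, col)
    soma_radii: tuple[float, float] = (250.0, 225.0)  # semi-axes, px
    soma_orientation: float = 0.0  # radians, flipped-y frame
    a0: float = 120.0
    a1: float = 0.0
    b1: float = 0.0
    a2: float = 0.0
    b2: float = 0.0
    noise_harmonics: tuple[int, int] = (3, 8)  # inclusive harmonic range
    noise_amplitude: float = 8.0  # total |coefficient| budget, px
    debris_count: int = 0
    debris_radius_range: tuple[float, float] = (3.0, 10.0)
    debris_min_distance: float = 30.0  # px clearance from the outgrowth
    seed: int = 0

    def __post_init__(self) -> None:
        higher = abs(self.a1) + abs(self.b1) + abs(self.a2) + abs(self.b2)
        if self.a0 <= higher + self.noise_amplitude:
            raise GenerationError(
                "a0 must exceed the sum of higher-order amplitudes plus noise "
                f"(a0={self.a0}, sum={higher + self.noise_amplitude})"
            )
        if min(self.soma_radii) <= 0:
            raise GenerationError("soma radii must be positive")

    @property
    def true_bias(self) -> float:
        """The dimensionless up-gradient bias b1/a0 this explant encodes."""
        return self.b1 / self.a0

    def to_dict(self) -> dict:
        return {
            "centre": list(self.centre),
            "soma_radii": list(self.soma_radii),
            "soma_orientation": self.soma_orientation,
            "a0": self.a0, "a1": self.a1, "b1": self.b1,
            "a2": self.a2, "b2": self.b2,
            "noise_harmonics": list(self.noise_harmonics),
            "noise_amplitude": self.noise_amplitude,
            "debris_count": self.debris_count,
            "debris_radius_range": list(self.debris_radius_range),
            "debris_min_distance": self.debris_min_distance,
            "seed": self.seed,
            "true_bias": self.true_bias,
        }


def _soma_radius(truth: SyntheticTruth, theta: np.ndarray) -> np.ndarray:
    p, q = truth.soma_radii
    t = theta - truth.soma_orientation
    return p * q / np.sqrt((q * np.cos(t)) ** 2 + (p * np.sin(t)) ** 2)


def _noise_series(truth: SyntheticTruth, rng: np.random.Generator) -> list[tuple[int, float, float]]:
    """Random (k, amplitude, phase) noise harmonics within the budget."""
    lo, hi = truth.noise_harmonics
    ks = list(range(lo, hi + 1))
    if not ks or truth.noise_amplitude == 0:
        return []
    per = truth.noise_amplitude / len(ks)
    return [
        (k, rng.uniform(0.0, per), rng.uniform(0.0, 2.0 * np.pi)) for k in ks
    ]


def true_outgrowth_profile(truth: SyntheticTruth, theta: np.ndarray,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Evaluate the ground-truth R(θ), including this explant's noise draw.

    The noise draw is a pure function of ``truth.seed``, so repeated calls
    (and the rasteriser) see the same realisation.
    """
    rng = rng or np.random.default_rng(truth.seed)
    r = (
        truth.a0
        + truth.a1 * np.cos(theta) + truth.b1 * np.sin(theta)
        + truth.a2 * np.cos(2 * theta) + truth.b2 * np.sin(2 * theta)
    )
    for k, amp, phase in _noise_series(truth, rng):
        r = r + amp * np.cos(k * theta + phase)
    return r


def generate_explant(
    truth: SyntheticTruth, shape: tuple[int, int] = DEFAULT_SHAPE
) -> tuple[BinaryMask, BinaryMask, SyntheticTruth]:
    """Rasterise one explant: (explant-body mask, neurite mask, truth).

    The body is a filled ellipse; the neurite mask is the annular region
    between the body boundary r_soma(θ) and r_soma(θ) + R_true(θ), plus any
    debris blobs placed clear of the outgrowth. Deterministic given the
    truth (including its seed).
    """
    rng = np.random.default_rng(truth.seed)
    # Dense lookup tables keep the 10^6-pixel polar test cheap.
    theta_table = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    r_soma_tab = _soma_radius(truth, theta_table)
    r_true_tab = true_outgrowth_profile(truth, theta_table, rng)
    if np.min(r_true_tab) <= 0:
        raise GenerationError("outgrowth profile non-positive: outer curve self-intersects")
    r_out_tab = r_soma_tab + r_true_tab

    rows = np.arange(shape[0])[:, None] - truth.centre[0]
    cols = np.arange(shape[1])[None, :] - truth.centre[1]
    theta = np.arctan2(-rows, cols) % (2 * np.pi)  # broadcasts to (rows, cols)
    radius = np.hypot(rows, cols)
    idx = np.rint(theta / (2 * np.pi / len(theta_table))).astype(int) % len(theta_table)
    r_soma_px = r_soma_tab[idx]
    r_out_px = r_out_tab[idx]

    explant = radius <= r_soma_px
    neurite = (radius > r_soma_px) & (radius <= r_out_px)

    for _ in range(truth.debris_count):
        neurite |= _place_debris(truth, rng, shape, r_out_tab, theta_table)

    return (
        BinaryMask(explant),
        BinaryMask(neurite),
        truth,
    )


def _place_debris(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    shape: tuple[int, int],
    r_out_tab: np.ndarray,
    theta_table: np.ndarray,
) -> np.ndarray:
    """One debris disc, rejection-sampled clear of the outgrowth region."""
    radius = rng.uniform(*truth.debris_radius_range)
    for _ in range(200):
        row = rng.uniform(radius + 1, shape[0] - radius - 1)
        col = rng.uniform(radius + 1, shape[1] - radius - 1)
        d_row, d_col = row - truth.centre[0], col - truth.centre[1]
        theta = np.arctan2(-d_row, d_col) % (2 * np.pi)
        r = np.hypot(d_row, d_col)
        k = int(np.rint(theta / (2 * np.pi / len(theta_table)))) % len(theta_table)
        if r >= r_out_tab[k] + truth.debris_min_distance + radius:
            rr = np.arange(shape[0])[:, None] - row
            cc = np.arange(shape[1])[None, :] - col
            return rr**2 + cc**2 <= radius**2
    log.warning("could not place debris blob after 200 attempts; skipping")
    return np.zeros(shape, bool)


@dataclass
class ResponseModel:
    """Phenomenological concentration/steepness response for simulation.

    Mean outgrowth follows a bell curve on log10 concentration (chemotropic
    factors act over a narrow concentration window around their receptor's
    effective range, here centred at 1 nM); mean up-gradient bias scales
    linearly with gradient steepness and shares a bell-shaped concentration
    window. Between-explant variability is Gaussian. These parameter values
    are test-fixture choices, not measurements.
    """

    outgrowth_baseline_px: float = 50.0
    outgrowth_peak_px: float = 80.0
    outgrowth_log10_centre: float = 0.0  # log10 nM; peak at 1 nM
    outgrowth_log10_width: float = 0.8
    bias_per_steepness: float = 0.75  # bias units per (%/10 µm) at peak
    bias_log10_centre: float = 0.0
    bias_log10_width: float = 0.7
    sd_outgrowth_px: float = 12.0
    sd_bias: float = 0.05

    def mean_outgrowth(self, concentration: float) -> float:
        z = (np.log10(concentration) - self.outgrowth_log10_centre) / self.outgrowth_log10_width
        return self.outgrowth_baseline_px + self.outgrowth_peak_px * float(np.exp(-0.5 * z * z))

    def mean_bias(self, steepness: float, concentration: float) -> float:
        if steepness == 0:
            return 0.0
        z = (np.log10(concentration) - self.bias_log10_centre) / self.bias_log10_width
        return self.bias_per_steepness * steepness * float(np.exp(-0.5 * z * z))

    def sample_truth(
        self,
        steepness: float,
        concentration: float,
        seed: int,
        debris_count: int = 2,
        shape: tuple[int, int] = DEFAULT_SHAPE,
    ) -> SyntheticTruth:
        """Draw one explant's ground truth for a condition cell."""
        rng = np.random.default_rng(seed)
        a0 = max(40.0, rng.normal(self.mean_outgrowth(concentration), self.sd_outgrowth_px))
        bias = float(np.clip(rng.normal(self.mean_bias(steepness, concentration), self.sd_bias), -0.4, 0.4))
        a1 = rng.normal(0.0, 0.03) * a0
        a2 = rng.normal(0.0, 0.05) * a0
        b2 = rng.normal(0.0, 0.05) * a0
        soma = (rng.uniform(230.0, 260.0), rng.uniform(210.0, 240.0))
        return SyntheticTruth(
            centre=(shape[0] / 2 + rng.uniform(-20, 20), shape[1] / 2 + rng.uniform(-20, 20)),
            soma_radii=soma,
            soma_orientation=rng.uniform(0, np.pi),
            a0=a0,
            a1=a1,
            b1=bias * a0,
            a2=a2,
            b2=b2,
            noise_amplitude=min(8.0, 0.9 * (a0 - abs(a1) - abs(bias * a0) - abs(a2) - abs(b2))),
            debris_count=debris_count,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary labelled parts (< 2^31).

    Hash-derived so per-file reproducibility survives reordering of the
    generation loop.
    """
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def generate_dataset(
    out_dir: str | Path,
    model: ResponseModel | None = None,
    n_per_condition: int = 2,
    seed: int = 0,
    steepness_levels: tuple[float, ...] = DEFAULT_STEEPNESS_LEVELS,
    concentration_levels: tuple[float, ...] = DEFAULT_CONCENTRATION_LEVELS,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    write_raw: bool = True,
    debris_count: int = 2,
) -> list[Path]:
    """Emit a full synthetic dataset directory following the filename grammar.

    For every (steepness, concentration) cell, ``n_per_condition`` explants
    are generated; each explant yields an explant-body mask (``x``), a
    neurite mask (``n``), optionally a rendered raw-style image, and a
    ``*_truth.json`` sidecar with the generating parameters. Returns the
    list of written files. Byte-identical across runs for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or ResponseModel()
    written: list[Path] = []
    for i_s, s in enumerate(steepness_levels):
        for i_c, c in enumerate(concentration_levels):
            for rep in range(n_per_condition):
                child = derive_seed(seed, s, c, rep)
                truth = model.sample_truth(s, c, child, debris_count=debris_count, shape=shape)
                explant, neurite, _ = generate_explant(truth, shape=shape)
                rec = ExplantRecord(
                    experiment=i_s + 1,
                    plate=i_c + 1,
                    explant=rep + 1,
                    orientation="u" if rep % 2 == 0 else "d",
                    steepness=s,
                    concentration=c,
                )
                stem = rec.stem
                x_path = out_dir / format_filename(rec.with_role("explant_mask"))
                n_path = out_dir / format_filename(rec.with_role("neurite_mask"))
                _write_mask(x_path, explant)
                _write_mask(n_path, neurite)
                written += [x_path, n_path]
                if write_raw:
                    raw_path = out_dir / format_filename(rec)
                    tifffile.imwrite(
                        str(raw_path),
                        render_intensity(explant, neurite, truth, seed=child),
                    )
                    written.append(raw_path)
                sidecar = out_dir / f"{stem}_truth.json"
                sidecar.write_text(json.dumps(truth.to_dict(), indent=1))
                written.append(sidecar)
    return written


def render_intensity(
    explant_mask: BinaryMask,
    neurite_mask: BinaryMask,
    truth: SyntheticTruth,
    seed: int = 0,
    background_level: float = 200.0,
    background_noise: float = 30.0,
    soma_level: float = 40000.0,
    neurite_level: float = 20000.0,
    speckle_sigma: float = 0.25,
) -> np.ndarray:
    """Render a fluorescence-like 16-bit image from the masks.

    Bright soma, multiplicative log-normal speckle over the neurite halo and
    additive Gaussian background. Thresholding at
    :data:`INTENSITY_THRESHOLD` and removing the body region recovers the
    neurite mask (exactly when both noise terms are zero, to within a small
    pixel fraction at the defaults).
    """
    rng = np.random.default_rng(seed)
    shape = explant_mask.shape
    img = np.zeros(shape, dtype=float)
    if background_noise > 0:
        img += np.abs(rng.normal(background_level, background_noise, shape))
    img[explant_mask.pixels] = soma_level
    speckle = (
        np.exp(rng.normal(0.0, speckle_sigma, shape)) if speckle_sigma > 0 else np.ones(shape)
    )
    img[neurite_mask.pixels] = neurite_level * speckle[neurite_mask.pixels]
    return np.clip(img, 0, 65535).astype(np.uint16)


def recover_mask_from_intensity(image: np.ndarray, explant_mask: BinaryMask,
                                threshold: float = INTENSITY_THRESHOLD) -> BinaryMask:
    """Threshold a rendered image and strip the body region (neurite recovery)."""
    return BinaryMask((image >= threshold) & ~explant_mask.pixels, scale=explant_mask.scale)
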