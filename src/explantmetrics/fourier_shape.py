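"""Folded real Fourier decomposition of the radial outgrowth function.

With the analysis convention R̂_k = (1/N) Σ_n R(θ_n) e^{−2πikn/N}, the real
series coefficients are obtained by folding the spectrum of the real signal
about the Nyquist frequency:

    a_0 = Re(R̂_0),  a_k = 2·Re(R̂_k),  b_k = −2·Im(R̂_k),  1 ≤ k ≤ N/2,

so that a_0 is the mean radial outgrowth and, for k < N/2,

    R(θ) = a_0 + Σ_k [a_k cos(kθ) + b_k sin(kθ)].

The stored Nyquist coefficient a_{N/2} follows the same ×2 folding rule
(keeping the published 181-row table shape for N = 360); because the Nyquist
bin of a real signal must not be double-counted, :func:`reconstruct` weights
that one term by ½ so that full-order reconstruction inverts the transform
exactly.

Low orders carry the biologically meaningful shape summary: a_0 is the
average radial outgrowth, b_1/a_0 the dimensionless bias up the gradient,
a_1/a_0 the bias orthogonal to it, and the k = 2 pair captures polarised
(bipolar) outgrowth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary_geometry import RadialProfile


class DegenerateProfileError(ValueError):
    """Bias is undefined because the mean outgrowth a0 is not positive."""


@dataclass
class FourierCoefficients:
    """Folded real-series coefficients of an N-point radial profile.

    ``a`` holds a_0..a_K and ``b`` holds b_1..b_K with K = N/2 (181 and 180
    values for N = 360). Units are those of the source profile (pixels
    unless converted).
    """

    a: np.ndarray
    b: np.ndarray
    n_angles: int

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        k = self.n_angles // 2
        if self.a.shape != (k + 1,) or self.b.shape != (k,):
            raise ValueError(
                f"expected {k + 1} cosine and {k} sine coefficients for N={self.n_angles}"
            )

    @property
    def order(self) -> int:
        return self.n_angles // 2

    def to_table(self) -> pd.DataFrame:
        """Coefficient table with columns (k, a_k, b_k), K+1 rows.

        Row 0 stores a placeholder 0 in the b column (b_0 does not exist),
        matching the published (N/2+1)×2 matrix layout.
        """
        return pd.DataFrame(
            {
                "k": np.arange(self.order + 1),
                "a_k": self.a,
                "b_k": np.concatenate([[0.0], self.b]),
            }
        )


def decompose(profile: RadialProfile | np.ndarray) -> FourierCoefficients:
    """Fourier-analyse a radial profile into folded real coefficients.

    Accepts a :class:`RadialProfile` or a bare 1-D array of samples; the
    sample count N must be even and at least 4.
    """
    values = profile.values if isinstance(profile, RadialProfile) else np.asarray(profile, float)
    n = len(values)
    if n < 4 or n % 2:
        raise ValueError("profile length must be even and >= 4")
    spectrum = np.fft.rfft(values) / n  # R̂_0 .. R̂_{N/2}
    a = np.empty(n // 2 + 1)
    a[0] = spectrum[0].real
    a[1:] = 2.0 * spectrum[1:].real
    b = -2.0 * spectrum[1:].imag
    return FourierCoefficients(a=a, b=b, n_angles=n)


def reconstruct(coeffs: FourierCoefficients, order: int | None = None) -> np.ndarray:
    """Evaluate the truncated series at the source angles θ_n.

    R(θ) = a_0 + Σ_{k=1}^{order} [a_k cos(kθ) + b_k sin(kθ)], with the
    Nyquist term (k = N/2, only when included) weighted by ½ so that
    ``reconstruct(decompose(R), N/2)`` returns R exactly. The default order
    2 keeps the five coefficients a_0, a_1, b_1, a_2, b_2.
    """
    if order is None:
        order = 2
    k_max = coeffs.order
    if not 0 <= order <= k_max:
        raise ValueError(f"order must be in [0, {k_max}]")
    n = coeffs.n_angles
    theta = 2.0 * np.pi * np.arange(n) / n
    values = np.full(n, coeffs.a[0])
    for k in range(1, order + 1):
        weight = 0.5 if k == k_max else 1.0
        values += weight * (coeffs.a[k] * np.cos(k * theta) + coeffs.b[k - 1] * np.sin(k * theta))
    return values


def evaluate_series(coeffs: FourierCoefficients, theta: np.ndarray, order: int = 2) -> np.ndarray:
    """Evaluate the truncated series at arbitrary angles (for overlays)."""
    k_max = coeffs.order
    if not 0 <= order <= k_max:
        raise ValueError(f"order must be in [0, {k_max}]")
    theta = np.asarray(theta, float)
    values = np.full(theta.shape, coeffs.a[0])
    for k in range(1, order + 1):
        weight = 0.5 if k == k_max else 1.0
        values += weight * (coeffs.a[k] * np.cos(k * theta) + coeffs.b[k - 1] * np.sin(k * theta))
    return values


def bias_metrics(coeffs: FourierCoefficients, scale: float = 1.0) -> dict[str, float]:
    """Outgrowth and guidance summary measures from the low-order terms.

    Returns ``averageOutgrowth`` (a_0, multiplied by ``scale`` to convert to
    µm), ``directionalBias`` (b_1/a_0, dimensionless bias up the gradient)
    and ``orthogonalBias`` (a_1/a_0, bias orthogonal to the gradient).
    """
    a0 = coeffs.a[0]
    if a0 <= 0:
        raise DegenerateProfileError("bias undefined: average outgrowth a0 <= 0")
    return {
        "averageOutgrowth": float(a0 * scale),
        "directionalBias": float(coeffs.b[0] / a0),
        "orthogonalBias": float(coeffs.a[1] / a0),
    }
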