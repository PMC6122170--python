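import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import explantmetrics as em

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def disc_mask(shape, centre, radius, scale=2.58):
    """Rasterised filled disc as a BinaryMask."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return em.BinaryMask((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2, scale=scale)


def ellipse_mask(shape, centre, semi_row, semi_col, scale=2.58):
    """Axis-aligned filled ellipse (semi-axes along rows/cols)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    inside = ((yy - centre[0]) / semi_row) ** 2 + ((xx - centre[1]) / semi_col) ** 2 <= 1.0
    return em.BinaryMask(inside, scale=scale)


@pytest.fixture(scope="session")
def default_explant():
    """One mid-sized synthetic explant with known truth, shared read-only."""
    truth = em.SyntheticTruth(a0=100.0, b1=25.0, a2=5.0, noise_amplitude=6.0, seed=42)
    explant, neurite, _ = em.generate_explant(truth)
    return explant, neurite, truth


@pytest.fixture(scope="session")
def bias_ladder_results():
    """Measured vs true bias over a ladder of 200 synthetic explants.

    Ground truth spans bias in [-0.3, 0.3] with varied body geometry, mean
    outgrowth and band-limited shape noise; measurements run the full
    pipeline at its default parameters. Shared (read-only) by the
    recovery, concordance and regression tests.
    """
    rng = np.random.default_rng(20240917)
    rows = []
    for i in range(200):
        bias = -0.3 + 0.6 * i / 199
        a0 = rng.uniform(100.0, 150.0)
        truth = em.SyntheticTruth(
            centre=(512 + rng.uniform(-15, 15), 512 + rng.uniform(-15, 15)),
            soma_radii=(rng.uniform(240, 260), rng.uniform(215, 235)),
            soma_orientation=rng.uniform(0, np.pi),
            a0=a0,
            a1=rng.uniform(-0.03, 0.03) * a0,
            b1=bias * a0,
            a2=rng.uniform(-0.03, 0.03) * a0,
            b2=rng.uniform(-0.03, 0.03) * a0,
            noise_amplitude=6.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        explant, neurite, _ = em.generate_explant(truth)
        res = em.quantify_explant(neurite, explant)
        rows.append(
            {
                "true_a0": truth.a0,
                "true_bias": truth.true_bias,
                "meas_a0": res.averageOutgrowth_px,
                "meas_bias": res.directionalBias,
                "GR": res.GR,
            }
        )
    return rows
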