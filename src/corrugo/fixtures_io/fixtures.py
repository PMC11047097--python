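"""Synthetic fixture generators: sector transects and two-channel intensities."""

from __future__ import annotations

import numpy as np

from ..clonal_stats import SectorProfile

__all__ = ["make_sector_fixture", "make_intensity_fixture"]


def make_sector_fixture(
    n_sectors: int,
    width: float = 100.0,
    noise: float = 0.0,
    seed: int = 0,
    spacing: float = 0.5,
):
    """Equal-width sectors of distinct labels with Bernoulli label noise.

    Returns ``(profile, true_boundaries)`` where the boundaries are the
    planted sector edges (excluding the well walls).
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    positions = np.arange(0.0, width + 0.5 * spacing, spacing)
    positions[-1] = min(positions[-1], width)
    if n_sectors > positions.size:
        raise ValueError("n_sectors exceeds the number of samples")
    labels = np.minimum((positions / width * n_sectors).astype(np.int64), n_sectors - 1)
    rng = np.random.default_rng(seed)
    if noise > 0:
        flip = rng.random(positions.size) < noise
        labels = labels.copy()
        labels[flip] = rng.integers(0, n_sectors, int(flip.sum()))
    true_boundaries = width * np.arange(1, n_sectors) / n_sectors
    return SectorProfile(positions=positions, labels=labels, width=width), true_boundaries


def make_intensity_fixture(
    f1_profile,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two-channel intensity transect ``I1 = total f1 + eps`` (clipped at 0)."""
    f1 = np.asarray(f1_profile, dtype=float)
    if np.any((f1 < 0) | (f1 > 1)):
        raise ValueError("f1 profile must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    I1 = total_intensity * f1
    I2 = total_intensity * (1.0 - f1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        I1 = I1 + rng.normal(0.0, noise_sd, f1.shape)
        I2 = I2 + rng.normal(0.0, noise_sd, f1.shape)
    return np.clip(I1, 0.0, None), np.clip(I2, 0.0, None)
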