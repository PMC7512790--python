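"""Synthetic phantom images and noise models for desk-scale benchmarking.

Two phantoms are provided: a 50x50 two-value image (intensities 0 and 1 in
two compact halves) and a 64x64 four-region image at four equally spaced
intensity levels. Noise levels are expressed as a percentage of the clean
image's intensity range: "r% noise" means the Gaussian component standard
deviation is sigma = (r/100) * (max - min). Rician corruption is the
magnitude-MRI model sqrt((I + e1)^2 + e2^2) with independent Gaussian e1,
e2, which reduces to a Rayleigh distribution where the clean signal is
zero. Noisy intensities are not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "Phantom",
    "NoiseSpec",
    "make_two_value_phantom",
    "make_trin_phantom",
    "add_gaussian_noise",
    "add_rician_noise",
    "add_noise",
]


@dataclass
class Phantom:
    """Clean benchmark image with its ground-truth label map."""

    image: np.ndarray
    labels: np.ndarray
    n_regions: int
    intensity_levels: tuple


@dataclass
class NoiseSpec:
    """Noise kind ('gaussian' | 'rician'), level as % of intensity range, seed."""

    kind: str
    level_percent: float
    seed: int = 0


def make_two_value_phantom(size: int = 50) -> Phantom:
    """Two-region binary image: left half 0, right half 1."""
    if size < 2:
        raise ValueError("size must be >= 2")
    image = np.zeros((size, size), dtype=float)
    image[:, size // 2:] = 1.0
    labels = image.astype(int)
    return Phantom(image=image, labels=labels, n_regions=2, intensity_levels=(0.0, 1.0))


def make_trin_phantom(size: int = 64) -> Phantom:
    """Four-region image: quadrants at equally spaced levels 0, 1/3, 2/3, 1."""
    if size < 2 or size % 2:
        raise ValueError("size must be an even integer >= 2")
    levels = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
    half = size // 2
    labels = np.zeros((size, size), dtype=int)
    labels[:half, half:] = 1
    labels[half:, :half] = 2
    labels[half:, half:] = 3
    image = np.asarray(levels)[labels]
    return Phantom(image=image, labels=labels, n_regions=4, intensity_levels=levels)


def _sigma(phantom: Phantom, level_percent: float) -> float:
    lo, hi = float(phantom.image.min()), float(phantom.image.max())
    rng = hi - lo
    if rng == 0.0:
        raise DegenerateInputError("constant clean image: intensity range is zero")
    if level_percent < 0:
        raise ValueError("noise level must be non-negative")
    return (level_percent / 100.0) * rng


def add_gaussian_noise(phantom: Phantom, spec: NoiseSpec) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise at the given percentage level."""
    if spec.kind != "gaussian":
        raise ValueError(f"expected gaussian spec, got {spec.kind!r}")
    sigma = _sigma(phantom, spec.level_percent)
    rng = np.random.default_rng(spec.seed)
    return phantom.image + rng.normal(0.0, sigma, size=phantom.image.shape)


def add_rician_noise(phantom: Phantom, spec: NoiseSpec) -> np.ndarray:
    """Apply magnitude-MRI Rician corruption at the given percentage level."""
    if spec.kind != "rician":
        raise ValueError(f"expected rician spec, got {spec.kind!r}")
    sigma = _sigma(phantom, spec.level_percent)
    rng = np.random.default_rng(spec.seed)
    e1 = rng.normal(0.0, sigma, size=phantom.image.shape)
    e2 = rng.normal(0.0, sigma, size=phantom.image.shape)
    return np.sqrt((phantom.image + e1) ** 2 + e2**2)


def add_noise(phantom: Phantom, spec: NoiseSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "gaussian":
        return add_gaussian_noise(phantom, spec)
    if spec.kind == "rician":
        return add_rician_noise(phantom, spec)
    raise ValueError(f"unknown noise kind {spec.kind!r}")
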