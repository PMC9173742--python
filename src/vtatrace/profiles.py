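"""Axonal innervation profiles along the medial--lateral axis of the VTA.

A band (a line with thickness, as drawn with an interactive line tool) is
sampled across a grayscale projection image from the midline to the lateral
end of the medial lemniscus.  The band-averaged gray value is resampled into
100 bins, normalized to the per-image maximum, and then averaged up a
hierarchy: images -> brain, brains -> input region, regions -> cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ProfileLine",
    "InnervationProfile",
    "extract_band_profile",
    "bin_profile",
    "normalize_profile",
    "average_profiles",
    "profile_from_image",
]

N_BINS_DEFAULT = 100
LEVELS = ("image", "brain", "region", "cluster")


@dataclass(frozen=True)
class ProfileLine:
    """Band geometry in pixel coordinates (row, col), 0-based.

    ``start`` is the midline point and ``end`` the lateral terminus;
    ``thickness`` is the band width in pixels perpendicular to the line.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    thickness: int = 100

    def __post_init__(self):
        if tuple(self.start) == tuple(self.end):
            raise ValueError("line start and end must differ")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")


@dataclass
class InnervationProfile:
    """Fixed-length normalized intensity profile, midline -> lateral."""

    values: np.ndarray
    level: str = "image"
    n_averaged: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if (self.values < 0).any():
            raise ValueError("profile values must be nonnegative")


def _as_float_image(image: np.ndarray) -> np.ndarray:
    """Convert to float in [0, 1] regardless of integer bit depth."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    return img.astype(float)


def extract_band_profile(image: np.ndarray, line: ProfileLine) -> np.ndarray:
    """Band-averaged intensity sampled along the line at unit arc length.

    At each of ``floor(length)+1`` positions along the line, ``thickness``
    bilinear samples are taken at unit spacing perpendicular to the line and
    averaged.  Raises if any sample falls outside the image.
    """
    img = _as_float_image(image)
    p0 = np.asarray(line.start, dtype=float)
    p1 = np.asarray(line.end, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n_samples = int(np.floor(length)) + 1
    t = (
        np.linspace(0.0, 1.0, n_samples)
        if n_samples > 1
        else np.array([0.0])
    )
    centers = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(line.thickness, dtype=float) - (line.thickness - 1) / 2.0
    # samples: (n_samples, thickness, 2)
    samples = centers[:, None, :] + offsets[None, :, None] * normal[None, None, :]
    rows = samples[..., 0]
    cols = samples[..., 1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > img.shape[0] - 1
        or cols.max() > img.shape[1] - 1
    ):
        raise ValueError("band extends outside the image bounds")
    values = map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    return values.mean(axis=1)


def bin_profile(raw: Sequence[float], n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Resample a raw intensity vector to exactly ``n_bins`` values.

    When the raw vector is at least ``n_bins`` long, samples are partitioned
    uniformly by position and averaged within each bin; shorter vectors are
    linearly interpolated up to ``n_bins``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty profile")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if raw.size >= n_bins:
        idx = (np.arange(raw.size) * n_bins) // raw.size
        sums = np.bincount(idx, weights=raw, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        return sums / counts
    positions = np.linspace(0, raw.size - 1, n_bins)
    return np.interp(positions, np.arange(raw.size), raw)


def normalize_profile(binned: Sequence[float]) -> InnervationProfile:
    """Divide by the maximum so the image-level profile peaks at exactly 1."""
    values = np.asarray(binned, dtype=float)
    peak = values.max() if values.size else 0.0
    if values.size == 0 or peak <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return InnervationProfile(values=values / peak, level="image", n_averaged=1)


def average_profiles(profiles: Sequence[InnervationProfile],
                     level_out: str) -> InnervationProfile:
    """Element-wise mean of equal-length profiles, one hierarchy level up."""
    if not profiles:
        raise ValueError("no profiles to average")
    lengths = {len(p.values) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles must share length")
    stacked = np.stack([p.values for p in profiles])
    return InnervationProfile(
        values=stacked.mean(axis=0),
        level=level_out,
        n_averaged=sum(p.n_averaged for p in profiles),
    )


def profile_from_image(image: np.ndarray, line: ProfileLine,
                       n_bins: int = N_BINS_DEFAULT) -> InnervationProfile:
    """Full image-level pipeline: band average -> bin -> max-normalize."""
    raw = extract_band_profile(image, line)
    return normalize_profile(bin_profile(raw, n_bins))
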