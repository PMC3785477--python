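"""Conversion of single-nucleotide occupancy into expected ChIP-seq-like profiles.

The start-position occupancy is first expanded over the bound footprint
(each bound molecule protects ``footprint`` bp), then convolved with a
fragment-size kernel (uniform or triangular) of width ``fragment_length``
mimicking the fragment-averaged enrichment a ChIP experiment reports.
Edges use truncated-kernel renormalization; the profile is finally
normalized to max 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import OccupancyTrack


@dataclass(frozen=True)
class ProfileConfig:
    fragment_length: int = 150
    kernel: str = "uniform"

    def __post_init__(self):
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.kernel not in ("uniform", "triangular"):
            raise ValueError("kernel must be 'uniform' or 'triangular'")

    def weights(self) -> np.ndarray:
        n = self.fragment_length
        if self.kernel == "uniform":
            w = np.ones(n)
        else:
            half = (n - 1) / 2.0
            w = 1.0 - np.abs(np.arange(n) - half) / (half + 1.0)
        return w / w.sum()


def expand_footprint(values: np.ndarray, footprint: int) -> np.ndarray:
    """Per-bp coverage from per-start occupancy (length grows by fp - 1)."""
    return np.convolve(np.asarray(values, dtype=float), np.ones(footprint))


def smooth_profile(track: OccupancyTrack, profile_config: ProfileConfig,
                   footprint: int = 1, max_normalize: bool = True) -> np.ndarray:
    """Expected ChIP-seq profile of an occupancy track.

    Returns one value per bp of the covered DNA (track length +
    footprint - 1).  Convolution mass is preserved in the interior;
    edges are renormalized by the truncated kernel weight.
    """
    values = track.values
    if values.size == 0:
        raise ValueError("empty track")
    coverage = expand_footprint(values, footprint)
    if profile_config.fragment_length > coverage.size:
        raise ValueError("fragment_length exceeds track length")
    w = profile_config.weights()
    num = np.convolve(coverage, w, mode="same")
    den = np.convolve(np.ones_like(coverage), w, mode="same")
    profile = num / den
    if max_normalize:
        pmax = profile.max()
        if pmax <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        profile = profile / pmax
    return profile


def write_wig(values, path, chrom: str = "seq", start: int = 1, step: int = 1) -> None:
    """fixedStep wiggle writer (1-based starts per wig convention)."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start={start} step={step}\n")
        for v in np.asarray(values):
            fh.write(f"{v:.6g}\n")
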