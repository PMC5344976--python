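"""Microscopy-derived geometry: rotational cell volumes and locus distances.

Small utilities mirroring how cell volume is reconstructed from tilted
electron-microscopy outlines (a stack of cylinders and cones around the
rotational symmetry axis) and how imaging-derived locus separations are
compared with model-derived ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RadialProfile:
    """Radii (nm) of axial slices of a rotationally symmetric body."""

    slice_height: float
    radii: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if self.slice_height <= 0:
            raise ValueError("slice_height must be positive")
        if self.radii.size < 1:
            raise ValueError("need at least one slice")
        if np.any(self.radii < 0):
            raise ValueError("radii must be nonnegative")


def rotational_volume(profile: RadialProfile) -> float:
    """Volume (um^3) of the solid of revolution described by a radial profile.

    Consecutive radii (r_a, r_b) over one slice height h contribute a
    cylinder of the smaller radius plus the cone completing the radius
    change: ``pi*min^2*h + (1/3)*pi*(max^2 - min^2)*h``.  Equal radii give
    a pure cylinder; a profile tapering to zero ends in a pure cone.
    Additive over profile concatenation and cubic under uniform rescaling.
    A single-slice profile has zero height and zero volume.
    """
    r = profile.radii
    h = profile.slice_height
    vol = 0.0
    for a, b in zip(r[:-1], r[1:]):
        lo, hi = min(a, b), max(a, b)
        vol += np.pi * lo**2 * h + (np.pi / 3.0) * (hi**2 - lo**2) * h
    return float(vol * 1e-9)  # nm^3 -> um^3


def mean_rotational_volume(profiles) -> float:
    """Average rotational volume (um^3) over per-tilt-image profiles.

    Averaging over the outlines extracted from individual tilt images
    damps manual-segmentation error and residual asymmetry.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    return float(np.mean([rotational_volume(p) for p in profiles]))


def fish_relative_distance(median_locus_ao: float, median_midpoint_ao: float) -> float:
    """Locus-midpoint separation inferred from distances to a fixed pole marker.

    The reference marker sits at one cell pole near the chromosome
    midpoint; subtracting the midpoint-marker median from a locus-marker
    median approximates the locus-midpoint distance.  May be negative and
    is reported as-is.
    """
    if median_locus_ao < 0 or median_midpoint_ao < 0:
        raise ValueError("median distances must be nonnegative")
    return float(median_locus_ao - median_midpoint_ao)


def model_imaging_correlation(model_medians, imaging_medians) -> float:
    """Pearson correlation between model and imaging median locus distances."""
    a = np.asarray(model_medians, dtype=float)
    b = np.asarray(imaging_medians, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length lists of at least 3 paired medians")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(a, b)[0])
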