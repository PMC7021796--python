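"""Construction of the reserved "free" pixel set.

A small fraction (≈5% by default) of the measured pixels is withheld from
the Fourier-magnitude constraint and used only to score solutions — the
CDI analogue of crystallography's R_free cross-validation set.  Because
oversampled diffraction data correlates neighbouring pixels, free pixels
are grouped in islands (disks in 2D, balls in 3D) of a few pixels radius
so the withheld set stays statistically independent of the working set.
The low-q centre of the pattern, which concentrates most of the photons,
is excluded so that withholding it cannot hinder the initial object
estimate.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .datamodel_io import DiffractionPattern, radius_grid
from .errors import NoCandidatesError, ValidationError

__all__ = ["FreeMaskSpec", "generate_free_mask", "free_mask_islands", "split_sets"]


@dataclasses.dataclass
class FreeMaskSpec:
    """Parameters of the free-set generator.

    fraction
        Target fraction of *valid* pixels to reserve (default 0.05).
    island_radius
        Euclidean radius in pixels of each island (default 3; a discrete
        disk of radius 3 spans 7 pixels).  Radius 0 gives isolated pixels.
    exclusion_radius_fraction
        Central exclusion zone, as a fraction of the largest
        center-to-pixel distance on the grid (default 0.05).
    seed
        Seed of the island-placement RNG; identical seeds give identical
        masks.
    """

    fraction: float = 0.05
    island_radius: int = 3
    exclusion_radius_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fraction < 0.5):
            raise ValidationError("fraction must be in [0, 0.5)")
        if self.island_radius < 0:
            raise ValidationError("island_radius must be >= 0")
        if not (0 <= self.exclusion_radius_fraction < 1):
            raise ValidationError("exclusion_radius_fraction must be in [0, 1)")


def _ball_offsets(radius: int, ndim: int) -> np.ndarray:
    """Integer index offsets inside a Euclidean ball of the given radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    grids = np.meshgrid(*([ax] * ndim), indexing="ij")
    d2 = sum(g ** 2 for g in grids)
    keep = d2 <= r ** 2
    return np.stack([g[keep] for g in grids], axis=-1)  # (n_offsets, ndim)


def free_mask_islands(
    pattern: DiffractionPattern, spec: FreeMaskSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the free mask and return the island centres used.

    Island centres are drawn uniformly without replacement from valid
    pixels outside the exclusion zone; each island is the Euclidean ball
    of ``spec.island_radius`` around its centre, clipped to the valid
    region and the exclusion zone.  Drawing stops when the marked fraction
    of valid pixels first reaches or exceeds ``spec.fraction`` (overlap
    between islands is not double-counted).
    """
    shape = pattern.shape
    r = radius_grid(shape, pattern.center)
    max_radius = float(r.max())
    exclusion = r <= spec.exclusion_radius_fraction * max_radius
    eligible = pattern.valid_mask & ~exclusion

    mask = np.zeros(shape, dtype=bool)
    if spec.fraction == 0:
        return mask, np.empty((0, pattern.ndim), dtype=np.intp)
    if not eligible.any():
        raise NoCandidatesError("exclusion zone covers all valid pixels")

    n_valid = int(pattern.valid_mask.sum())
    target = spec.fraction * n_valid
    rng = np.random.default_rng(spec.seed)
    cand_flat = np.flatnonzero(eligible)
    rng.shuffle(cand_flat)
    offsets = _ball_offsets(spec.island_radius, pattern.ndim)

    centers = []
    count = 0
    dims = np.array(shape)
    for flat in cand_flat:
        if count >= target:
            break
        center = np.array(np.unravel_index(flat, shape))
        # wrap-around stamping: the FFT-layout seam is the physical border,
        # clipping at the detector edge happens through `eligible`
        pts = (center + offsets) % dims
        idx = tuple(pts.T)
        island = np.zeros(shape, dtype=bool)
        island[idx] = True
        island &= eligible
        mask |= island
        centers.append(center)
        count = int(mask.sum())
    return mask, np.array(centers, dtype=np.intp).reshape(-1, pattern.ndim)


def generate_free_mask(pattern: DiffractionPattern, spec: FreeMaskSpec) -> np.ndarray:
    """Random island-structured free mask (see :func:`free_mask_islands`)."""
    mask, _ = free_mask_islands(pattern, spec)
    return mask


def split_sets(
    pattern: DiffractionPattern, free: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the valid pixels into working and free sets.

    Returns ``(working, free)`` with working = valid ∧ ¬free.  Warns when
    the working set comes out empty (free = valid), a degenerate split
    that leaves nothing to phase against.
    """
    free = np.asarray(free, dtype=bool)
    if np.any(free & ~pattern.valid_mask):
        raise ValidationError("free pixels must be a subset of valid pixels")
    working = pattern.valid_mask & ~free
    if not working.any():
        warnings.warn("free set covers all valid pixels; working set is empty")
    return working, free
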