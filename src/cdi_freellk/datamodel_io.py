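"""Core data containers and file I/O for oversampled diffraction data.

Conventions
-----------
Fourier-space arrays (intensities, validity masks) are kept in the FFT
layout internally: the zero-frequency pixel sits at index ``(0, 0[, 0])``
and frequencies wrap around at ``n/2``.  Files, in contrast, store the
human-readable *centered* layout (beamstop in the middle of the image);
:func:`read_pattern` / :func:`write_pattern` apply ``ifftshift`` /
``fftshift`` so that round trips are bit-exact.

Real-space objects use the natural array layout with the specimen placed
near the array center; its absolute position only contributes a linear
phase ramp in Fourier space and is irrelevant for intensities.

Distances "from the center" in Fourier space (beamstop radii, the free-set
exclusion zone, resolution rings) are computed with wrap-around index
offsets, which is the metric the FFT layout induces.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "DiffractionPattern",
    "Support",
    "ObjectEstimate",
    "FourierEstimate",
    "SolutionSet",
    "read_pattern",
    "write_pattern",
    "read_solutions",
    "write_solutions",
    "centro_symmetrize",
    "wrapped_offsets",
    "radius_grid",
    "frequency_radius",
    "disk_mask",
]


# ---------------------------------------------------------------------------
# grid helpers

def wrapped_offsets(shape: Sequence[int], center: Sequence[int] | None = None):
    """Per-axis signed index offsets from ``center`` with wrap-around.

    Offsets lie in ``[-n//2, (n-1)//2]`` along an axis of length ``n``; for
    ``center = 0`` this reproduces ``np.fft.fftfreq(n) * n``.  Returns an
    open (broadcastable) grid, one array per axis.
    """
    if center is None:
        center = [0] * len(shape)
    offs = []
    for ax, (n, c) in enumerate(zip(shape, center)):
        idx = np.arange(n)
        d = (idx - int(c) + n // 2) % n - n // 2
        sh = [1] * len(shape)
        sh[ax] = n
        offs.append(d.reshape(sh))
    return offs


def radius_grid(shape: Sequence[int], center: Sequence[int] | None = None) -> np.ndarray:
    """Euclidean distance (in pixels, wrap-around metric) from ``center``."""
    offs = wrapped_offsets(shape, center)
    r2 = sum(np.asarray(d, dtype=float) ** 2 for d in offs)
    return np.sqrt(r2)


def frequency_radius(shape: Sequence[int]) -> np.ndarray:
    """Radial spatial frequency as a fraction of the sampling frequency.

    Zero at the (0,...,0) pixel, 0.5 at the Nyquist edge along an axis.
    """
    grids = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij", sparse=True)
    return np.sqrt(sum(g ** 2 for g in grids))


def disk_mask(shape: Sequence[int], center: Sequence[float], radius: float) -> np.ndarray:
    """Plain (non wrapping) Euclidean disk/ball in real space."""
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij", sparse=True)
    r2 = sum((g - c) ** 2 for g, c in zip(idx, center))
    return r2 <= radius ** 2


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class DiffractionPattern:
    """Observed photon counts plus validity and free-set masks.

    Parameters
    ----------
    intensity
        Nonnegative real array of photon counts, shape (H, W) or (D, H, W).
        Non-integer values are permitted (post-processed data) but Poisson
        counting semantics are assumed by the log-likelihood metrics.
    valid_mask
        True where the pixel was measured.  Defaults to all-true.
    free_mask
        True for pixels reserved for cross-validation; must be a subset of
        ``valid_mask``.  Defaults to all-false.
    center
        Index of the zero-frequency pixel; ``(0, ..., 0)`` in the internal
        FFT layout.
    wavelength, pixel_size, detector_distance
        Optional physical metadata (SI units), used only to label
        resolution axes.
    """

    intensity: np.ndarray
    valid_mask: np.ndarray | None = None
    free_mask: np.ndarray | None = None
    center: tuple[int, ...] | None = None
    wavelength: float | None = None
    pixel_size: float | None = None
    detector_distance: float | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim not in (2, 3):
            raise ValidationError("intensity must be 2D or 3D")
        if np.any(self.intensity < 0):
            raise ValidationError("intensity must be nonnegative")
        shape = self.intensity.shape
        if self.valid_mask is None:
            self.valid_mask = np.ones(shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.free_mask is None:
            self.free_mask = np.zeros(shape, dtype=bool)
        else:
            self.free_mask = np.asarray(self.free_mask, dtype=bool)
        if self.valid_mask.shape != shape or self.free_mask.shape != shape:
            raise ValidationError("mask shapes must match intensity shape")
        if np.any(self.free_mask & ~self.valid_mask):
            raise ValidationError("free_mask must be a subset of valid_mask")
        if self.center is None:
            self.center = (0,) * self.intensity.ndim
        else:
            self.center = tuple(int(c) for c in self.center)
            if len(self.center) != self.intensity.ndim:
                raise ValidationError("center dimensionality mismatch")
            for c, n in zip(self.center, shape):
                if not (0 <= c < n):
                    raise ValidationError("center outside grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape

    @property
    def ndim(self) -> int:
        return self.intensity.ndim

    @property
    def working_mask(self) -> np.ndarray:
        """Measured pixels actually enforced during phasing (valid ∧ ¬free)."""
        return self.valid_mask & ~self.free_mask

    def with_free_mask(self, free_mask: np.ndarray) -> "DiffractionPattern":
        return dataclasses.replace(self, free_mask=np.asarray(free_mask, dtype=bool))


@dataclasses.dataclass
class Support:
    """Boolean region Ω where the object is allowed to be nonzero."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def nb_support(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclasses.dataclass
class ObjectEstimate:
    """Complex-valued real-space object density ρ."""

    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=complex)
        if not np.all(np.isfinite(self.rho)):
            raise ValidationError("object density contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rho.shape


@dataclasses.dataclass
class FourierEstimate:
    """Calculated structure factors and their intensities."""

    f_calc: np.ndarray

    def __post_init__(self):
        self.f_calc = np.asarray(self.f_calc, dtype=complex)

    @property
    def i_calc(self) -> np.ndarray:
        return np.abs(self.f_calc) ** 2


@dataclasses.dataclass
class SolutionSet:
    """A stack of reconstructions with per-solution metadata.

    ``rho`` has shape ``(n_solutions, *grid)``; ``supports`` the matching
    boolean stack (or None); ``meta`` maps names (seed, threshold, llk,
    llk_free, e_o2, e_f2, nb_support, ...) to 1-D arrays of length
    ``n_solutions``.  ``free_mask`` records the cross-validation mask the
    metrics were computed against.
    """

    rho: np.ndarray
    supports: np.ndarray | None = None
    meta: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    free_mask: np.ndarray | None = None

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=complex)
        if self.rho.ndim < 3:
            raise ValidationError("solution stack must be (n, H, W[, D])")
        if len(self) == 0:
            raise ValidationError("empty solution stack")
        if self.supports is not None:
            self.supports = np.asarray(self.supports, dtype=bool)
            if self.supports.shape != self.rho.shape:
                raise ValidationError("supports shape mismatch within stack")
        for k, v in self.meta.items():
            v = np.asarray(v)
            if v.shape[0] != len(self):
                raise ValidationError(f"metadata '{k}' length mismatch")
            self.meta[k] = v

    def __len__(self) -> int:
        return self.rho.shape[0]

    def objects(self) -> list[ObjectEstimate]:
        return [ObjectEstimate(r) for r in self.rho]


# ---------------------------------------------------------------------------
# pattern I/O

_CXI_DATA = "/entry_1/data_1/data"
_CXI_MASK = "/entry_1/data_1/mask"
_CXI_PRIVATE = "/cdi_freellk"  # private group: free mask + center


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    s = str(path)
    if s.endswith(".npz"):
        return "npz"
    return "cxi"


def write_pattern(pattern: DiffractionPattern, path: str | Path, format: str | None = None) -> None:
    """Write a pattern to CXI/HDF5 or NPZ.

    Arrays are stored in the centered (fftshifted) layout with the stored
    center at ``shape // 2``; read_pattern undoes the shift so the round
    trip is bit-exact.
    """
    fmt = _infer_format(path, format)
    if np.any(pattern.free_mask & ~pattern.valid_mask):  # re-check on write
        raise ValidationError("free_mask must be a subset of valid_mask")
    # shift to centered layout relative to the pattern's own center
    shift = [n // 2 - c for n, c in zip(pattern.shape, pattern.center)]
    inten = np.roll(pattern.intensity, shift, axis=tuple(range(pattern.ndim)))
    valid = np.roll(pattern.valid_mask, shift, axis=tuple(range(pattern.ndim)))
    free = np.roll(pattern.free_mask, shift, axis=tuple(range(pattern.ndim)))
    center = np.array([n // 2 for n in pattern.shape], dtype=np.int64)
    if fmt == "npz":
        np.savez(
            path,
            intensity=inten,
            valid_mask=valid,
            free_mask=free,
            center=center,
        )
    elif fmt == "cxi":
        with h5py.File(path, "w") as f:
            f.create_dataset(_CXI_DATA, data=inten)
            # CXI convention: 0 = valid pixel, nonzero = bad
            f.create_dataset(_CXI_MASK, data=(~valid).astype(np.uint8))
            g = f.require_group(_CXI_PRIVATE)
            g.create_dataset("free_mask", data=free.astype(np.uint8))
            g.create_dataset("center", data=center)
            for name in ("wavelength", "pixel_size", "detector_distance"):
                val = getattr(pattern, name)
                if val is not None:
                    g.attrs[name] = float(val)
    else:
        raise FormatError(f"unknown format '{fmt}'")


def read_pattern(path: str | Path, format: str | None = None) -> DiffractionPattern:
    """Read a diffraction pattern from CXI/HDF5 or NPZ.

    Missing valid mask defaults to all-true, missing free mask to
    all-false; a missing center is taken as the grid center (files use the
    centered layout).  The returned pattern is in FFT layout with
    ``center = (0, ..., 0)``.
    """
    fmt = _infer_format(path, format)
    meta: dict[str, float] = {}
    if fmt == "npz":
        with np.load(path) as d:
            if "intensity" not in d:
                raise FormatError("NPZ file lacks an 'intensity' array")
            inten = d["intensity"]
            valid = d["valid_mask"].astype(bool) if "valid_mask" in d else None
            free = d["free_mask"].astype(bool) if "free_mask" in d else None
            center = d["center"] if "center" in d else None
    elif fmt == "cxi":
        with h5py.File(path, "r") as f:
            if _CXI_DATA not in f:
                raise FormatError(f"CXI file lacks {_CXI_DATA}")
            inten = f[_CXI_DATA][()]
            valid = None
            if _CXI_MASK in f:
                valid = f[_CXI_MASK][()] == 0
            free = None
            center = None
            if _CXI_PRIVATE in f:
                g = f[_CXI_PRIVATE]
                if "free_mask" in g:
                    free = g["free_mask"][()].astype(bool)
                if "center" in g:
                    center = g["center"][()]
                for name in ("wavelength", "pixel_size", "detector_distance"):
                    if name in g.attrs:
                        meta[name] = float(g.attrs[name])
    else:
        raise FormatError(f"unknown format '{fmt}'")

    if np.any(np.asarray(inten) < 0):
        raise ValidationError("file contains negative intensities")
    shape = inten.shape
    if center is None:
        center = [n // 2 for n in shape]
    # shift from the file's centered layout back to FFT layout
    shift = [-int(c) for c in center]
    axes = tuple(range(inten.ndim))
    inten = np.roll(inten, shift, axis=axes)
    if valid is not None:
        valid = np.roll(valid, shift, axis=axes)
    if free is not None:
        free = np.roll(free, shift, axis=axes)
    return DiffractionPattern(inten, valid, free, center=(0,) * inten.ndim, **meta)


# ---------------------------------------------------------------------------
# solution-stack I/O

def write_solutions(solutions: SolutionSet, path: str | Path) -> None:
    """Write a reconstruction stack (complex arrays + metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("solutions/rho", data=solutions.rho)
        if solutions.supports is not None:
            f.create_dataset("solutions/supports", data=solutions.supports.astype(np.uint8))
        if solutions.free_mask is not None:
            f.create_dataset("solutions/free_mask", data=np.asarray(solutions.free_mask, dtype=np.uint8))
        g = f.require_group("solutions/meta")
        for k, v in solutions.meta.items():
            v = np.asarray(v)
            if v.dtype.kind == "U":  # h5py cannot store numpy unicode
                v = v.astype("S")
            g.create_dataset(k, data=v)


def read_solutions(path: str | Path) -> SolutionSet:
    with h5py.File(path, "r") as f:
        if "solutions/rho" not in f:
            raise FormatError("file lacks a solutions/rho stack")
        rho = f["solutions/rho"][()]
        supports = None
        if "solutions/supports" in f:
            supports = f["solutions/supports"][()].astype(bool)
        free_mask = None
        if "solutions/free_mask" in f:
            free_mask = f["solutions/free_mask"][()].astype(bool)
        meta = {}
        if "solutions/meta" in f:
            g = f["solutions/meta"]
            for k in g:
                v = g[k][()]
                if isinstance(v, np.ndarray) and v.dtype.kind == "S":
                    v = v.astype("U")
                meta[k] = v
    return SolutionSet(rho, supports, meta, free_mask)


# ---------------------------------------------------------------------------
# preprocessing

def centro_symmetrize(pattern: DiffractionPattern) -> DiffractionPattern:
    """Fill unmeasured pixels from their centro-symmetric partners.

    For a real-valued object (up to a constant phase factor) the
    diffracted intensity is centro-symmetric, so pixels hidden behind a
    beamstop can be recovered from their Friedel partners at −q.  Pixels
    that were measured keep their measured value (no averaging); pixels
    whose partner is also unmeasured stay invalid.  Idempotent.
    """
    shape = pattern.shape
    c = pattern.center
    # partner of index k along an axis of length n with center c: (2c−k) mod n
    partner_idx = np.ix_(*[(2 * c[ax] - np.arange(n)) % n for ax, n in enumerate(shape)])
    part_int = pattern.intensity[partner_idx]
    part_valid = pattern.valid_mask[partner_idx]
    fill = ~pattern.valid_mask & part_valid
    intensity = pattern.intensity.copy()
    intensity[fill] = part_int[fill]
    valid = pattern.valid_mask | fill
    return dataclasses.replace(pattern, intensity=intensity, valid_mask=valid)
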