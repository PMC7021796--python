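"""Phantoms and simulated oversampled diffraction patterns.

The forward model is the plain far-field one: the detector records
photon counts drawn from a Poisson law whose mean is the squared modulus
of the (orthonormal) Fourier transform of the object, scaled to a total
photon budget.  A central beamstop can mark low-q pixels as unmeasured,
and the pattern can optionally be centro-symmetrized, mimicking the
standard treatment of homogeneous (real-valued) specimens.

Three phantom families cover the use cases: flat binary glyph-like
shapes (block letters drawn procedurally, no font dependency), random
non-overlapping binary disks, and a smooth "cell" with internal
substructure and an optional smooth phase of at most π/2 span.  Every
phantom comes with its exact tight support, so recovery can be scored
against ground truth.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .combine import match_phase_and_twin, register_subpixel, twin_image
from .datamodel_io import (
    DiffractionPattern,
    ObjectEstimate,
    Support,
    centro_symmetrize,
    radius_grid,
)
from .errors import RegistrationError, ValidationError

__all__ = [
    "PhantomSpec",
    "SimulationSpec",
    "make_phantom",
    "simulate_pattern",
    "oracle_compare",
]


@dataclasses.dataclass
class PhantomSpec:
    """Ground-truth object description.

    ``oversampling`` is the ratio of grid extent to object extent; the
    object is confined to a central box of side grid_size/oversampling.
    Values ≥ 2 satisfy the Nyquist condition that makes phase retrieval
    well-posed; ≥ 3 is typical experimentally.
    """

    kind: str  # "binary_text" | "disks" | "cell"
    grid_size: int = 128
    oversampling: float = 4.0
    complex_phase: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("binary_text", "disks", "cell"):
            raise ValidationError(f"unknown phantom kind '{self.kind}'")
        if self.oversampling < 2:
            raise ValidationError("oversampling must be >= 2 (Nyquist)")
        if self.grid_size / self.oversampling < 4:
            raise ValidationError("object box too small at this oversampling")


@dataclasses.dataclass
class SimulationSpec:
    """Measurement conditions.

    ``total_photons`` is the expected count over the whole detector
    (default 1e8, comparable to a high-quality 2D dataset); ``None`` or
    ``inf`` switches off noise and scaling (intensity = |FT ρ|² exactly).
    ``beamstop_radius`` is in pixels around the zero-frequency pixel
    (0 = none).
    """

    total_photons: float | None = 1e8
    beamstop_radius: float = 0.0
    symmetrize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.total_photons is not None and not (self.total_photons > 0):
            raise ValidationError("total_photons must be positive")


# ---------------------------------------------------------------------------
# phantoms

# 5x3 block glyphs; enough letters for procedurally drawn test objects
_GLYPHS = {
    "C": ["111", "100", "100", "100", "111"],
    "D": ["110", "101", "101", "101", "110"],
    "I": ["111", "010", "010", "010", "111"],
    "E": ["111", "100", "110", "100", "111"],
    "S": ["111", "100", "111", "001", "111"],
    "F": ["111", "100", "110", "100", "100"],
    "R": ["110", "101", "110", "101", "101"],
    "L": ["100", "100", "100", "100", "111"],
}


def _glyph_canvas(text: str) -> np.ndarray:
    rows = 5
    cols = 4 * len(text) - 1
    canvas = np.zeros((rows, cols))
    for i, ch in enumerate(text):
        bm = np.array([[int(b) for b in row] for row in _GLYPHS[ch.upper()]])
        canvas[:, 4 * i : 4 * i + 3] = bm
    return canvas


def _binary_text(box: int, rng: np.random.Generator) -> np.ndarray:
    text = "CDI"
    canvas = _glyph_canvas(text)
    scale = max(1, box // max(canvas.shape[1], canvas.shape[0] * 2))
    img = np.kron(canvas, np.ones((scale, scale)))
    out = np.zeros((box, box))
    h, w = img.shape
    h, w = min(h, box), min(w, box)
    r0, c0 = (box - h) // 2, (box - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = img[:h, :w]
    return out


def _disks(box: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((box, box))
    yy, xx = np.mgrid[0:box, 0:box]
    placed: list[tuple[float, float, float]] = []
    n_disks = 5
    attempts = 0
    while len(placed) < n_disks and attempts < 500:
        attempts += 1
        r = rng.uniform(box / 16, box / 6)
        cy = rng.uniform(r, box - r)
        cx = rng.uniform(r, box - r)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr) ** 2 for y, x, rr in placed):
            placed.append((cy, cx, r))
            out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = 1.0
    return out


def _cell(box: int, rng: np.random.Generator, complex_phase: bool) -> np.ndarray:
    yy, xx = np.mgrid[0:box, 0:box].astype(float)
    cy = cx = (box - 1) / 2
    theta = rng.uniform(0, np.pi)
    a_ax = box * rng.uniform(0.30, 0.42)
    b_ax = box * rng.uniform(0.20, 0.30)
    u = (yy - cy) * math.cos(theta) + (xx - cx) * math.sin(theta)
    v = -(yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)
    r_ell = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)
    amp = np.where(r_ell <= 1, np.cos(0.5 * np.pi * np.clip(r_ell, 0, 1)) ** 2, 0.0)
    # internal substructure: a few Gaussian granules
    for _ in range(4):
        gy = cy + rng.uniform(-0.4, 0.4) * a_ax
        gx = cx + rng.uniform(-0.4, 0.4) * b_ax
        gs = box * rng.uniform(0.03, 0.08)
        amp *= 1 + 0.5 * np.exp(-(((yy - gy) ** 2 + (xx - gx) ** 2) / (2 * gs ** 2)))
    amp /= max(amp.max(), 1e-12)
    if complex_phase:
        gy = cy + rng.uniform(-0.3, 0.3) * a_ax
        gx = cx + rng.uniform(-0.3, 0.3) * b_ax
        gs = box * rng.uniform(0.2, 0.4)
        field = np.exp(-(((yy - gy) ** 2 + (xx - gx) ** 2) / (2 * gs ** 2)))
        span = field.max() - field.min()
        phase = (field - field.min()) / max(span, 1e-12) * (np.pi / 2)
        return amp * np.exp(1j * phase) * (amp > 0)
    return amp


def make_phantom(spec: PhantomSpec) -> tuple[ObjectEstimate, Support]:
    """Ground-truth object and its exact tight support."""
    n = spec.grid_size
    box = int(round(n / spec.oversampling))
    if box < 4:
        raise ValidationError("object cannot fit at requested oversampling")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "binary_text":
        small = _binary_text(box, rng).astype(complex)
    elif spec.kind == "disks":
        small = _disks(box, rng).astype(complex)
    else:
        small = np.asarray(_cell(box, rng, spec.complex_phase), dtype=complex)
    rho = np.zeros((n, n), dtype=complex)
    r0 = (n - box) // 2
    rho[r0 : r0 + box, r0 : r0 + box] = small
    support = Support(np.abs(rho) > 0)
    return ObjectEstimate(rho), support


# ---------------------------------------------------------------------------
# forward simulation

def simulate_pattern(obj: ObjectEstimate, sim: SimulationSpec) -> DiffractionPattern:
    """Far-field pattern of an object under Poisson counting statistics."""
    f = np.fft.fftn(obj.rho, norm="ortho")
    i_ideal = np.abs(f) ** 2
    noiseless = sim.total_photons is None or not np.isfinite(sim.total_photons)
    if noiseless:
        intensity = i_ideal
    else:
        i_ideal = i_ideal * (sim.total_photons / i_ideal.sum())
        rng = np.random.default_rng(sim.seed)
        intensity = rng.poisson(i_ideal).astype(float)
    valid = np.ones(intensity.shape, dtype=bool)
    if sim.beamstop_radius > 0:
        r = radius_grid(intensity.shape)
        blocked = r < sim.beamstop_radius
        valid &= ~blocked
        intensity = np.where(blocked, 0.0, intensity)
    pattern = DiffractionPattern(intensity, valid)
    if sim.symmetrize:
        pattern = centro_symmetrize(pattern)
    return pattern


def oracle_compare(
    reconstruction: ObjectEstimate,
    truth: ObjectEstimate,
    support_truth: Support | None = None,
    upsample: int = 20,
) -> float:
    """Normalized correlation with ground truth, in [0, 1].

    Invariant to translation (sub-pixel registration), global phase and
    the twin ambiguity: both candidates are registered to the truth and
    the better normalized inner product |⟨ρ, ρ_truth⟩|/(‖ρ‖·‖ρ_truth‖)
    is returned.
    """
    if reconstruction.shape != truth.shape:
        raise ValidationError("shape mismatch")
    nt = np.linalg.norm(truth.rho)
    nr = np.linalg.norm(reconstruction.rho)
    if nt <= 0 or nr <= 0:
        raise RegistrationError("zero-power input")
    best = 0.0
    for cand in (reconstruction, twin_image(reconstruction)):
        _, reg = register_subpixel(cand, truth, upsample=upsample)
        c = abs(np.vdot(truth.rho, reg.rho))
        best = max(best, c / (np.linalg.norm(reg.rho) * nt + 1e-300))
    return float(best)
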