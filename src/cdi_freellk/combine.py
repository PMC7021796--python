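"""Alignment, combination and consensus analysis of solution stacks.

Independent phase-retrieval runs converge to objects that differ by an
arbitrary translation, a global phase factor and possibly the twin
(conjugate centro-inverted) image — all exact symmetries of the
modulus-only problem.  Before any combination the stack is therefore
registered to sub-pixel precision, twin-resolved and phase-matched
against a reference (by default the solution with the lowest free
log-likelihood).

Two combinations are provided: the plain complex average, and the SVD
eigen-decomposition, where each solution becomes a row of a matrix and
the singular-value-scaled right singular vectors ("eigen-solutions")
carry relative weights σ²/Σσ².  A first-mode weight close to 100% means
the selected solutions agree; outliers are shunted into secondary modes
instead of contaminating the consensus, which is what makes the first
eigen-mode more robust than the average.

The phase retrieval transfer function (PRTF) — the ring-wise ratio of
the modulus of the solution-averaged structure factors to the observed
amplitudes — quantifies reproducibility per resolution shell; its first
drop below 50% is the conventional resolution estimate.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from .datamodel_io import (
    DiffractionPattern,
    ObjectEstimate,
    SolutionSet,
    frequency_radius,
)
from .errors import ConsistencyError, RegistrationError, ValidationError

__all__ = [
    "EigenDecomposition",
    "PRTFCurve",
    "register_subpixel",
    "twin_image",
    "match_phase_and_twin",
    "align_solutions",
    "eigen_solutions",
    "average_solution",
    "prtf",
    "select_best",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EigenDecomposition:
    """SVD modes of an aligned solution stack.

    ``modes[m]`` is the m-th singular-value-scaled right singular vector
    reshaped to the grid (so Σ_m ‖mode_m‖² equals the total squared
    amplitude of the stack); ``weights[m]`` = σ_m²/Σσ² × 100.
    """

    modes: np.ndarray  # (n_modes, *grid), complex
    weights: np.ndarray  # percentages, sum to 100
    alignment_log: list[dict] | None = None


@dataclasses.dataclass
class PRTFCurve:
    """PRTF sampled on rings of spatial frequency (fractions of the
    sampling frequency, in (0, 0.5])."""

    ring_frequencies: np.ndarray
    prtf: np.ndarray
    cutoff_frequency: float | None = None


# ---------------------------------------------------------------------------
# alignment

def register_subpixel(
    moving: ObjectEstimate, reference: ObjectEstimate, upsample: int = 20
) -> tuple[np.ndarray, ObjectEstimate]:
    """Register ``moving`` onto ``reference`` by upsampled cross-correlation.

    The shift is estimated on the amplitudes |ρ| to 1/upsample pixel and
    applied to the complex object by Fourier-shifting.  Deterministic.
    """
    if moving.shape != reference.shape:
        raise ValidationError("shape mismatch")
    a, b = np.abs(moving.rho), np.abs(reference.rho)
    if a.max() <= 0 or b.max() <= 0:
        raise RegistrationError("zero-power input")
    shift, _, _ = phase_cross_correlation(
        b, a, upsample_factor=upsample, normalization=None
    )
    registered = np.fft.ifftn(fourier_shift(np.fft.fftn(moving.rho), shift))
    return np.asarray(shift, dtype=float), ObjectEstimate(registered)


def twin_image(obj: ObjectEstimate) -> ObjectEstimate:
    """Conjugate centro-inverted object: ρ*(−r), the twin solution."""
    rho = obj.rho
    flipped = np.flip(rho)
    # index 0 maps to itself under r -> -r on a periodic grid
    twin = np.conj(np.roll(flipped, 1, axis=tuple(range(rho.ndim))))
    return ObjectEstimate(twin)


def _inner(a: np.ndarray, b: np.ndarray) -> complex:
    return complex(np.vdot(b, a))  # Σ a·conj(b)


def match_phase_and_twin(
    moving: ObjectEstimate, reference: ObjectEstimate
) -> ObjectEstimate:
    """Resolve the global-phase and twin ambiguities against a reference.

    Both candidates (the object and its twin) have the global phase
    θ = arg Σ ρ·conj(ρ_ref) removed; the candidate with the larger
    |Σ ρ·conj(ρ_ref)| is returned.
    """
    if moving.shape != reference.shape:
        raise ValidationError("shape mismatch")
    best, best_c = None, -1.0
    for cand in (moving, twin_image(moving)):
        c = _inner(cand.rho, reference.rho)
        if abs(c) > best_c:
            best_c = abs(c)
            best = ObjectEstimate(cand.rho * np.exp(-1j * np.angle(c)) if c != 0 else cand.rho)
    return best


def align_solutions(
    solutions: SolutionSet | np.ndarray,
    reference_index: int | None = None,
    upsample: int = 20,
    low_correlation: float = 0.3,
) -> tuple[np.ndarray, list[dict]]:
    """Register, twin-resolve and phase-match a stack to a reference.

    The reference defaults to the solution with the lowest free
    log-likelihood (when metadata is available, else index 0).  For every
    solution both the original and the twin candidate are registered and
    phase-matched; the candidate with the higher normalized correlation
    to the reference wins.  Returns the aligned complex stack and a log
    with per-solution shift, global phase, twin flag and correlation
    (correlations below ``low_correlation`` are flagged).
    """
    if isinstance(solutions, SolutionSet):
        stack = solutions.rho
        if reference_index is None and "llk_free" in solutions.meta:
            lf = np.asarray(solutions.meta["llk_free"], dtype=float)
            reference_index = int(np.nanargmin(lf))
    else:
        stack = np.asarray(solutions, dtype=complex)
    if reference_index is None:
        reference_index = 0
    ref = ObjectEstimate(stack[reference_index])
    ref_norm = np.linalg.norm(ref.rho)
    if ref_norm <= 0:
        raise RegistrationError("reference solution has zero power")

    aligned = np.empty_like(stack)
    log: list[dict] = []
    for k in range(stack.shape[0]):
        entry: dict = {"index": k}
        if k == reference_index:
            aligned[k] = ref.rho
            entry.update(shift=np.zeros(ref.rho.ndim), phase=0.0, twin=False, correlation=1.0)
            log.append(entry)
            continue
        best = None
        for is_twin, cand in ((False, ObjectEstimate(stack[k])), (True, twin_image(ObjectEstimate(stack[k])))):
            shift, reg = register_subpixel(cand, ref, upsample=upsample)
            c = _inner(reg.rho, ref.rho)
            corr = abs(c) / (np.linalg.norm(reg.rho) * ref_norm + 1e-300)
            if best is None or corr > best[0]:
                best = (corr, shift, reg, c, is_twin)
        corr, shift, reg, c, is_twin = best
        phase = float(np.angle(c))
        aligned[k] = reg.rho * np.exp(-1j * phase)
        entry.update(shift=shift, phase=phase, twin=is_twin, correlation=float(corr))
        if corr < low_correlation:
            entry["low_correlation"] = True
            logger.warning("solution %d correlates poorly with reference (%.3f)", k, corr)
        log.append(entry)
    return aligned, log


# ---------------------------------------------------------------------------
# combination

def eigen_solutions(solutions: np.ndarray | SolutionSet) -> EigenDecomposition:
    """SVD eigen-decomposition of an aligned stack.

    Each solution is flattened into a row of a matrix A; the
    decomposition is computed from the n×n Gram matrix A·Aᴴ (identical to
    the full SVD, cheaper for n_solutions ≪ n_pixels).  Modes are the
    σ-scaled right singular vectors, so the total squared amplitude of
    the stack is conserved: Σ_m ‖mode_m‖² = Σ_k ‖solution_k‖².
    """
    stack = solutions.rho if isinstance(solutions, SolutionSet) else np.asarray(solutions, dtype=complex)
    n = stack.shape[0]
    if n < 2:
        raise ValidationError("eigen-decomposition needs at least 2 solutions")
    grid_shape = stack.shape[1:]
    a = stack.reshape(n, -1)
    gram = a @ a.conj().T
    w, u = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0, None)
    u = u[:, order]
    modes = (a.conj().T @ u).T.conj().reshape(n, *grid_shape)
    # A = UΣVᴴ  ⇒  Aᴴu_m = σ_m v_m, so row m of (Aᴴ U)ᴴ* is σ_m v_m
    total = w.sum()
    if total <= 0:
        raise ValidationError("solutions have zero total power")
    weights = 100.0 * w / total
    return EigenDecomposition(modes=modes, weights=weights)


def average_solution(solutions: np.ndarray | SolutionSet) -> ObjectEstimate:
    """Pixel-wise complex mean of an aligned stack."""
    stack = solutions.rho if isinstance(solutions, SolutionSet) else np.asarray(solutions, dtype=complex)
    if stack.shape[0] < 1:
        raise ValidationError("empty stack")
    return ObjectEstimate(stack.mean(axis=0))


def prtf(
    solutions: np.ndarray | SolutionSet,
    pattern: DiffractionPattern,
    n_rings: int = 50,
) -> PRTFCurve:
    """Phase retrieval transfer function of an aligned stack.

    Per ring r (linear bins of spatial frequency up to Nyquist):
    PRTF(r) = Σ_{i∈ring∩working} |⟨F_i⟩_solutions| / Σ sqrt(I_i^obs),
    with the average taken over the complex structure factors of the
    solutions.  Free and invalid pixels are excluded.  The cutoff is the
    centre of the first ring where the PRTF falls below 0.5 (None if it
    never does).  Empty rings are skipped with a log notice.
    """
    stack = solutions.rho if isinstance(solutions, SolutionSet) else np.asarray(solutions, dtype=complex)
    if stack.shape[0] < 1:
        raise ValidationError("empty stack")
    if stack.shape[1:] != pattern.shape:
        raise ValidationError("stack/pattern shape mismatch")
    f_mean = np.mean(
        [np.fft.fftn(s, norm="ortho") for s in stack], axis=0
    )
    fr = frequency_radius(pattern.shape)
    working = pattern.working_mask
    edges = np.linspace(0.0, 0.5, n_rings + 1)
    freqs, vals = [], []
    num_map = np.abs(f_mean)
    den_map = np.sqrt(pattern.intensity)
    for i in range(n_rings):
        ring = (fr > edges[i]) & (fr <= edges[i + 1]) & working
        den = den_map[ring].sum()
        if not ring.any() or den <= 0:
            logger.info("PRTF ring %d empty; skipped", i)
            continue
        freqs.append(0.5 * (edges[i] + edges[i + 1]))
        vals.append(float(num_map[ring].sum() / den))
    freqs = np.asarray(freqs)
    vals = np.asarray(vals)
    below = np.nonzero(vals < 0.5)[0]
    cutoff = float(freqs[below[0]]) if below.size else None
    return PRTFCurve(ring_frequencies=freqs, prtf=vals, cutoff_frequency=cutoff)


def select_best(
    solutions: SolutionSet, k: int, metric: str = "llk_free"
) -> np.ndarray:
    """Indices of the k best (lowest-metric) solutions.

    Ranking by the free log-likelihood is only meaningful when every
    solution was scored against the same free mask; a stack recording
    mixed masks raises :class:`ConsistencyError`.  Ties are broken by
    smaller support size, then by lower index.
    """
    if metric not in solutions.meta:
        raise ValidationError(f"metric '{metric}' not in solution metadata")
    if "free_mask_hash" in solutions.meta:
        hashes = solutions.meta["free_mask_hash"]
        if len(set(map(str, hashes))) > 1:
            raise ConsistencyError("solutions were scored against different free masks")
    vals = np.asarray(solutions.meta[metric], dtype=float)
    if k > len(solutions):
        raise ValidationError("k exceeds the number of solutions")
    nb = np.asarray(
        solutions.meta.get("nb_support", np.zeros(len(solutions))), dtype=float
    )
    order = sorted(range(len(solutions)), key=lambda i: (vals[i], nb[i], i))
    return np.asarray(order[:k], dtype=np.intp)
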