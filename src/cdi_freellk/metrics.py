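"""Figures of merit for phase-retrieval solutions.

Four quantities are computed per solution:

* ``E_o²`` — object-domain error: the fraction of object power lying
  outside the support, Σ_{i∉Ω}|ρ_i|² / Σ_i|ρ_i|².
* ``E_F²`` — Fourier-domain error: Σ(|F_calc| − |F_obs|)² / Σ|F_obs|²
  over a pixel subset, comparing amplitude moduli since the observed
  phases are unknown (an intensity-based variant is available).
* ``LLK`` — mean per-pixel negative Poisson log-likelihood of the
  calculated intensities given the observed counts, over the working set:
  (1/N) Σ [I_calc − I_obs·log I_calc + log(I_obs!)].
* ``LLK_free`` — the same likelihood evaluated only on the withheld free
  set.  Because free pixels never enter the Fourier update, LLK_free is
  an unbiased, cross-validated score: enlarging the support lets the fit
  chase noise in the working set (LLK keeps dropping) but degrades
  LLK_free, which is what makes it a usable model-selection metric.

All Fourier transforms use the orthonormal convention, matching the
phasing engine, so a converged solution has |F_calc| ≈ √I_obs without any
global rescaling.
"""
from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
from scipy.special import gammaln

from .datamodel_io import DiffractionPattern, ObjectEstimate, Support
from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "MetricReport",
    "object_domain_error",
    "fourier_error",
    "poisson_llk",
    "report",
    "free_mask_hash",
]

_EPS = 1e-20  # floor for I_calc where I_obs > 0 (log would diverge)


@dataclasses.dataclass
class MetricReport:
    """Per-solution figures of merit."""

    e_o2: float
    e_f2: float
    llk: float
    llk_free: float
    nb_support: int
    n_working: int
    n_free: int
    free_mask_hash: str | None = None


def free_mask_hash(free_mask: np.ndarray) -> str:
    """Stable digest of a free mask, used to assert ranking consistency."""
    m = np.ascontiguousarray(np.asarray(free_mask, dtype=bool))
    return hashlib.sha1(m.tobytes() + str(m.shape).encode()).hexdigest()


def object_domain_error(obj: ObjectEstimate, support: Support) -> float:
    """Fraction of the object's power outside the support Ω."""
    p = np.abs(obj.rho) ** 2
    total = p.sum()
    if total <= 0:
        raise UndefinedMetricError("object has zero total power")
    return float(p[~support.mask].sum() / total)


def fourier_error(
    f_calc: np.ndarray,
    pattern: DiffractionPattern,
    subset: np.ndarray,
    use_intensity: bool = False,
) -> float:
    """Normalised Fourier-domain residual over a pixel subset.

    Amplitude form (default): Σ(|F_calc| − √I_obs)² / Σ I_obs.
    Intensity form: Σ(|F_calc|² − I_obs)² / Σ I_obs².
    """
    subset = np.asarray(subset, dtype=bool)
    if not subset.any():
        raise UndefinedMetricError("empty subset")
    i_obs = pattern.intensity[subset]
    if use_intensity:
        denom = (i_obs ** 2).sum()
        if denom <= 0:
            raise UndefinedMetricError("zero observed intensity over subset")
        num = ((np.abs(np.asarray(f_calc)[subset]) ** 2 - i_obs) ** 2).sum()
        return float(num / denom)
    denom = i_obs.sum()
    if denom <= 0:
        raise UndefinedMetricError("zero observed intensity over subset")
    num = ((np.abs(np.asarray(f_calc)[subset]) - np.sqrt(i_obs)) ** 2).sum()
    return float(num / denom)


def poisson_llk(
    i_calc: np.ndarray,
    pattern: DiffractionPattern,
    subset: np.ndarray,
    scale: str = "none",
) -> float:
    """Mean negative Poisson log-likelihood over a pixel subset.

    (1/N) Σ [I_calc − I_obs·log(I_calc) + log(I_obs!)], N = |subset|, with
    log(I_obs!) evaluated through the log-gamma function.  The term for
    I_obs = I_calc = 0 is zero (0⁰ = 1 convention); I_calc = 0 with
    I_obs > 0 is floored at a tiny epsilon.  ``scale='working_flux'``
    first rescales I_calc by Σ_working I_obs / Σ_working I_calc, for
    evaluating models whose global flux is not already pinned by the
    Fourier projection.
    """
    i_calc = np.asarray(i_calc, dtype=float)
    if np.any(i_calc < 0):
        raise ValidationError("I_calc must be nonnegative")
    subset = np.asarray(subset, dtype=bool)
    if not subset.any():
        raise UndefinedMetricError("empty subset")
    if scale == "working_flux":
        w = pattern.working_mask
        denom = i_calc[w].sum()
        if denom <= 0:
            raise UndefinedMetricError("zero calculated flux on working set")
        i_calc = i_calc * (pattern.intensity[w].sum() / denom)
    elif scale != "none":
        raise ValidationError(f"unknown scale '{scale}'")

    ic = i_calc[subset]
    io = pattern.intensity[subset]
    terms = ic + gammaln(io + 1.0)
    pos = io > 0
    terms[pos] -= io[pos] * np.log(np.maximum(ic[pos], _EPS))
    return float(terms.sum() / io.size)


def report(
    obj: ObjectEstimate,
    support: Support,
    pattern: DiffractionPattern,
) -> MetricReport:
    """Compute all figures of merit for one solution.

    F_calc is the orthonormal FT of the support-projected object, so LLK,
    LLK_free and E_F² refer to the density the support actually allows;
    E_o² is computed on the raw object against that same support, since a
    projected object trivially has zero out-of-support power.  LLK_free is
    NaN when the pattern carries no free set.
    """
    # plain support projection (no positivity); kept inline to avoid a
    # metrics -> engine dependency
    proj = obj.rho * support.mask
    f_calc = np.fft.fftn(proj, norm="ortho")
    i_calc = np.abs(f_calc) ** 2
    working = pattern.working_mask
    e_o2 = object_domain_error(obj, support)
    e_f2 = fourier_error(f_calc, pattern, working)
    llk = poisson_llk(i_calc, pattern, working)
    n_free = int(pattern.free_mask.sum())
    if n_free > 0:
        llk_free = poisson_llk(i_calc, pattern, pattern.free_mask)
        fmh = free_mask_hash(pattern.free_mask)
    else:
        llk_free = float("nan")
        fmh = None
    return MetricReport(
        e_o2=e_o2,
        e_f2=e_f2,
        llk=llk,
        llk_free=llk_free,
        nb_support=support.nb_support,
        n_working=int(working.sum()),
        n_free=n_free,
        free_mask_hash=fmh,
    )
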