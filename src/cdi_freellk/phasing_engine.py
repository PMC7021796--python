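"""Iterative projection phase retrieval.

Implements the classic alternating-projection family — Error Reduction
(ER), Hybrid Input-Output (HIO) and Relaxed Averaged Alternating
Reflectors (RAAR) — with a free-set-aware Fourier update, shrinkwrap
support estimation, an optional positivity constraint, a half-space
detwinning step, and a seeded multi-start runner that attaches all
figures of merit to every solution.

The Fourier update replaces calculated amplitudes with observed ones on
the *working* pixels only: pixels in the free set (and unmeasured pixels)
keep their calculated complex value, which is what keeps the free
log-likelihood unbiased — the algorithm never sees the withheld data.

All FFTs use the orthonormal convention so Parseval holds without
bookkeeping factors.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .datamodel_io import (
    DiffractionPattern,
    ObjectEstimate,
    SolutionSet,
    Support,
    disk_mask,
)
from .errors import NumericalDivergenceError, ValidationError
from .metrics import free_mask_hash, report

__all__ = [
    "AlgorithmStep",
    "ShrinkwrapSpec",
    "RunRecipe",
    "apply_fourier_magnitudes",
    "fourier_project",
    "support_project",
    "er_cycle",
    "hio_cycle",
    "raar_cycle",
    "shrinkwrap_update",
    "detwin",
    "random_start",
    "run_recipe",
    "multi_start",
    "preset_recipe",
]

HIO_BETA_DEFAULT = 0.9
RAAR_BETA_DEFAULT = 0.75


@dataclasses.dataclass
class AlgorithmStep:
    """One homogeneous block of phasing cycles."""

    kind: str  # "ER" | "HIO" | "RAAR"
    cycles: int
    beta: float | None = None
    positivity: bool = False

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in ("ER", "HIO", "RAAR"):
            raise ValidationError(f"unknown algorithm kind '{self.kind}'")
        if self.cycles < 1:
            raise ValidationError("cycles must be >= 1")
        if self.kind in ("HIO", "RAAR"):
            if self.beta is None:
                self.beta = HIO_BETA_DEFAULT if self.kind == "HIO" else RAAR_BETA_DEFAULT
            if not (0 < self.beta < 1):
                raise ValidationError("beta must lie in (0, 1)")


@dataclasses.dataclass
class ShrinkwrapSpec:
    """Periodic support re-estimation by thresholding the blurred object.

    Every ``update_every`` cycles the support becomes the set of pixels
    where a Gaussian blur (width ``sigma`` pixels) of |ρ| exceeds
    ``threshold`` × its maximum.
    """

    threshold: float
    update_every: int = 20
    sigma: float = 2.0
    sigma_final: float | None = None  # optional linear decay target

    def __post_init__(self):
        if not (0 < self.threshold < 1):
            raise ValidationError("threshold must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.update_every < 1:
            raise ValidationError("update_every must be >= 1")


@dataclasses.dataclass
class RunRecipe:
    """A full reconstruction schedule.

    ``initial_support`` is either a :class:`Support` or a disk diameter in
    pixels (disk centred on the grid).  ``detwin_after``, if set, applies
    the detwinning cut right after that (1-based, global) cycle.
    """

    steps: list[AlgorithmStep]
    shrinkwrap: ShrinkwrapSpec | None = None
    detwin_after: int | None = None
    initial_support: Support | int | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.steps:
            raise ValidationError("recipe needs at least one step")
        total = sum(s.cycles for s in self.steps)
        if self.detwin_after is not None and not (1 <= self.detwin_after <= total):
            raise ValidationError("detwin_after falls outside the step schedule")

    @property
    def total_cycles(self) -> int:
        return sum(s.cycles for s in self.steps)


# ---------------------------------------------------------------------------
# elementary projections

def apply_fourier_magnitudes(f: np.ndarray, pattern: DiffractionPattern) -> np.ndarray:
    """Fourier-magnitude constraint on the working set.

    On working pixels the calculated amplitude is replaced by √I_obs with
    the calculated phase kept (zero-amplitude pixels get zero phase);
    free and invalid pixels are returned bit-unchanged.
    """
    if f.shape != pattern.shape:
        raise ValidationError("shape mismatch between F and pattern")
    out = f.copy()
    w = pattern.working_mask
    fw = f[w]
    amp = np.abs(fw)
    target = np.sqrt(pattern.intensity[w])
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(amp > 0, fw / amp, 1.0 + 0.0j)
    out[w] = target * phase
    return out


def fourier_project(obj: ObjectEstimate, pattern: DiffractionPattern) -> ObjectEstimate:
    """P_F: enforce observed Fourier amplitudes on the working set."""
    if obj.shape != pattern.shape:
        raise ValidationError("object and pattern shapes differ")
    f = np.fft.fftn(obj.rho, norm="ortho")
    f = apply_fourier_magnitudes(f, pattern)
    return ObjectEstimate(np.fft.ifftn(f, norm="ortho"))


def support_project(
    obj: ObjectEstimate, support: Support, positivity: bool = False
) -> ObjectEstimate:
    """P_S: zero the density outside Ω; optionally enforce positivity.

    With positivity on, pixels inside Ω whose real part is negative are
    zeroed entirely and imaginary parts are dropped (real-part
    convention).
    """
    if obj.shape != support.shape:
        raise ValidationError("object and support shapes differ")
    if support.nb_support < 1:
        raise ValidationError("support is empty")
    rho = obj.rho * support.mask
    if positivity:
        rho = np.where(rho.real < 0, 0, rho.real).astype(complex)
        rho *= support.mask
    return ObjectEstimate(rho)


def _constraint_region(
    pf_rho: np.ndarray, support: Support, positivity: bool
) -> np.ndarray:
    """Pixels where the Fourier-projected estimate satisfies the
    real-space constraints (inside Ω, and nonnegative real part when
    positivity is on)."""
    inside = support.mask
    if positivity:
        inside = inside & (pf_rho.real >= 0)
    return inside


def _er(rho, pf_rho, support, positivity, beta):
    new = pf_rho * support.mask
    if positivity:
        new = np.where(new.real < 0, 0, new.real).astype(complex) * support.mask
    return new


def _hio(rho, pf_rho, support, positivity, beta):
    inside = _constraint_region(pf_rho, support, positivity)
    return np.where(inside, pf_rho, rho - beta * pf_rho)


def _raar(rho, pf_rho, support, positivity, beta):
    # elementwise form of ½β(ρ + R_S R_F ρ) + (1−β) P_F ρ with R = 2P − I:
    # constraint-satisfying pixels take P_F ρ, violating pixels
    # βρ + (1 − 2β) P_F ρ.
    inside = _constraint_region(pf_rho, support, positivity)
    return np.where(inside, pf_rho, beta * rho + (1 - 2 * beta) * pf_rho)


_CYCLE_FUN = {"ER": _er, "HIO": _hio, "RAAR": _raar}


def _one_cycle(kind, rho, pattern, support, beta, positivity):
    pf = np.fft.ifftn(
        apply_fourier_magnitudes(np.fft.fftn(rho, norm="ortho"), pattern),
        norm="ortho",
    )
    new = _CYCLE_FUN[kind](rho, pf, support, positivity, beta)
    return new, pf


def er_cycle(
    obj: ObjectEstimate,
    pattern: DiffractionPattern,
    support: Support,
    positivity: bool = False,
) -> ObjectEstimate:
    """One Error-Reduction cycle: ρ' = P_S P_F ρ."""
    if support.nb_support < 1:
        raise ValidationError("support is empty")
    new, _ = _one_cycle("ER", obj.rho, pattern, support, None, positivity)
    return ObjectEstimate(new)


def hio_cycle(
    obj: ObjectEstimate,
    pattern: DiffractionPattern,
    support: Support,
    beta: float = HIO_BETA_DEFAULT,
    positivity: bool = False,
) -> ObjectEstimate:
    """One Hybrid Input-Output cycle: feedback −β·P_Fρ outside the
    constraint region, P_Fρ inside."""
    if support.nb_support < 1:
        raise ValidationError("support is empty")
    new, _ = _one_cycle("HIO", obj.rho, pattern, support, beta, positivity)
    return ObjectEstimate(new)


def raar_cycle(
    obj: ObjectEstimate,
    pattern: DiffractionPattern,
    support: Support,
    beta: float = RAAR_BETA_DEFAULT,
    positivity: bool = False,
) -> ObjectEstimate:
    """One Relaxed Averaged Alternating Reflectors cycle."""
    if support.nb_support < 1:
        raise ValidationError("support is empty")
    new, _ = _one_cycle("RAAR", obj.rho, pattern, support, beta, positivity)
    return ObjectEstimate(new)


# ---------------------------------------------------------------------------
# support estimation and detwinning

def shrinkwrap_update(obj: ObjectEstimate, spec: ShrinkwrapSpec, sigma: float | None = None) -> Support:
    """Re-estimate the support from the blurred object amplitude."""
    amp = np.abs(obj.rho)
    m = amp.max()
    if m <= 0:
        raise ValidationError("object amplitude is identically zero")
    blurred = gaussian_filter(amp, sigma if sigma is not None else spec.sigma)
    mask = blurred > spec.threshold * blurred.max()
    if not mask.any():
        raise ValidationError("shrinkwrap threshold too high: empty support")
    return Support(mask)


def detwin(obj: ObjectEstimate, support: Support) -> tuple[ObjectEstimate, Support]:
    """Break the twin-image ambiguity by a half-space support cut.

    The support is cut by the hyperplane through its centroid,
    perpendicular to the axis of greatest support extent; the half
    carrying the larger share of |ρ|² mass is kept (ties go to the
    lower-index half) and the object is masked accordingly.
    """
    if support.nb_support < 1:
        raise ValidationError("support is empty")
    idx = np.nonzero(support.mask)
    extents = [int(i.max() - i.min()) for i in idx]
    axis = int(np.argmax(extents))
    centroid = float(idx[axis].mean())
    coords = np.arange(support.shape[axis])
    shape = [1] * support.mask.ndim
    shape[axis] = support.shape[axis]
    lower = (coords <= np.floor(centroid)).reshape(shape)
    power = np.abs(obj.rho) ** 2 * support.mask
    m_lower = float((power * lower).sum())
    m_upper = float((power * ~lower).sum())
    half = lower if m_lower >= m_upper else ~lower
    new_mask = support.mask & np.broadcast_to(half, support.mask.shape)
    new_support = Support(new_mask)
    return ObjectEstimate(obj.rho * new_mask), new_support


def random_start(support: Support, rng: np.random.Generator) -> ObjectEstimate:
    """Random object: amplitude U[0,1), phase U[0,2π) inside the support."""
    amp = rng.uniform(0, 1, size=support.shape)
    phase = rng.uniform(0, 2 * np.pi, size=support.shape)
    return ObjectEstimate(amp * np.exp(1j * phase) * support.mask)


# ---------------------------------------------------------------------------
# runners

def _resolve_initial_support(recipe: RunRecipe, shape) -> Support:
    init = recipe.initial_support
    if isinstance(init, Support):
        return init
    if isinstance(init, (int, float)):
        center = [n / 2 for n in shape]
        return Support(disk_mask(shape, center, float(init) / 2))
    raise ValidationError("recipe.initial_support must be a Support or a diameter")


def run_recipe(
    pattern: DiffractionPattern,
    recipe: RunRecipe,
    record_every: int | None = 20,
) -> tuple[ObjectEstimate, Support, list[dict]]:
    """Execute a full phasing schedule.

    Starts from a random object inside the initial support (seeded by
    ``recipe.seed``), runs the steps in order, re-estimates the support
    every ``shrinkwrap.update_every`` cycles from the support-projected
    Fourier estimate, applies detwinning after ``detwin_after`` cycles,
    and records LLK / LLK_free / E_F² every ``record_every`` cycles.

    Returns the final free-running iterate (not support-projected, so the
    object-domain error stays informative), the final support, and the
    metric trace.  Fully reproducible per seed.
    """
    support = _resolve_initial_support(recipe, pattern.shape)
    rng = np.random.default_rng(recipe.seed)
    obj = random_start(support, rng)
    rho = obj.rho
    trace: list[dict] = []
    cycle = 0
    sw = recipe.shrinkwrap
    total = recipe.total_cycles
    for step in recipe.steps:
        for _ in range(step.cycles):
            cycle += 1
            rho, pf = _one_cycle(step.kind, rho, pattern, support, step.beta, step.positivity)
            if not np.all(np.isfinite(rho)):
                raise NumericalDivergenceError(
                    f"non-finite values at cycle {cycle} ({step.kind})", cycle=cycle
                )
            if sw is not None and cycle % sw.update_every == 0:
                if sw.sigma_final is not None:
                    sigma = sw.sigma + (sw.sigma_final - sw.sigma) * cycle / total
                else:
                    sigma = sw.sigma
                support = shrinkwrap_update(
                    ObjectEstimate(pf * support.mask), sw, sigma=sigma
                )
            if recipe.detwin_after is not None and cycle == recipe.detwin_after:
                o, support = detwin(ObjectEstimate(rho), support)
                rho = o.rho
            if record_every is not None and (cycle % record_every == 0 or cycle == total):
                rep = report(ObjectEstimate(rho), support, pattern)
                trace.append(
                    {
                        "cycle": cycle,
                        "llk": rep.llk,
                        "llk_free": rep.llk_free,
                        "e_f2": rep.e_f2,
                        "nb_support": rep.nb_support,
                    }
                )
    return ObjectEstimate(rho), support, trace


def multi_start(
    pattern: DiffractionPattern,
    recipe: RunRecipe,
    n_runs: int,
    threshold_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> SolutionSet:
    """Run ``n_runs`` independent reconstructions from random starts.

    Each run gets its own RNG stream (spawned from ``seed``) and, when
    ``threshold_range`` is given, its own shrinkwrap threshold drawn
    uniformly from that range.  The free mask is the one carried by the
    pattern and stays fixed across runs, which keeps the free
    log-likelihoods mutually comparable.  All figures of merit are
    attached per solution.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    if threshold_range is not None and recipe.shrinkwrap is None:
        raise ValidationError("threshold_range given but recipe has no shrinkwrap")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_runs + 1)
    thr_rng = np.random.default_rng(children[0])
    thresholds = (
        thr_rng.uniform(threshold_range[0], threshold_range[1], size=n_runs)
        if threshold_range is not None
        else np.full(n_runs, recipe.shrinkwrap.threshold if recipe.shrinkwrap else np.nan)
    )
    run_seeds = np.array(
        [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children[1:]], dtype=np.int64
    )

    rhos, supports = [], []
    meta: dict[str, list] = {
        k: [] for k in ("seed", "threshold", "llk", "llk_free", "e_o2", "e_f2", "nb_support")
    }
    failures: list[Exception] = []
    for i in range(n_runs):
        r = dataclasses.replace(recipe, seed=int(run_seeds[i]))
        if threshold_range is not None:
            r.shrinkwrap = dataclasses.replace(recipe.shrinkwrap, threshold=float(thresholds[i]))
        try:
            obj, support, _ = run_recipe(pattern, r, record_every=None)
        except NumericalDivergenceError as exc:
            failures.append(exc)
            continue
        rep = report(obj, support, pattern)
        rhos.append(obj.rho)
        supports.append(support.mask)
        meta["seed"].append(run_seeds[i])
        meta["threshold"].append(thresholds[i])
        meta["llk"].append(rep.llk)
        meta["llk_free"].append(rep.llk_free)
        meta["e_o2"].append(rep.e_o2)
        meta["e_f2"].append(rep.e_f2)
        meta["nb_support"].append(rep.nb_support)
    if not rhos:
        raise NumericalDivergenceError(
            f"all {n_runs} runs diverged (first: {failures[0]})"
        )
    return SolutionSet(
        rho=np.stack(rhos),
        supports=np.stack(supports),
        meta={k: np.asarray(v) for k, v in meta.items()},
        free_mask=pattern.free_mask.copy(),
    )


# ---------------------------------------------------------------------------
# presets

def preset_recipe(
    name: str,
    initial_support: Support | int,
    seed: int = 0,
    shrinkwrap: ShrinkwrapSpec | None = None,
) -> RunRecipe:
    """Named reconstruction protocols.

    ``logo``: 400 HIO + 200 ER, no positivity — the short protocol suited
    to compact binary objects; shrinkwrap (threshold 0.25–0.4 typical)
    every 20 cycles unless overridden.

    ``cell``: 2000 HIO with positivity and detwinning after cycle 1000,
    then 2000 HIO and 2000 RAAR without positivity, finishing with 200
    ER; shrinkwrap every 20 cycles (threshold 0.1–0.4 typical) — the
    long unsupervised protocol for low-contrast biological specimens.
    """
    if name == "logo":
        steps = [AlgorithmStep("HIO", 400), AlgorithmStep("ER", 200)]
        sw = shrinkwrap if shrinkwrap is not None else ShrinkwrapSpec(threshold=0.3)
        return RunRecipe(steps=steps, shrinkwrap=sw, initial_support=initial_support, seed=seed)
    if name == "cell":
        steps = [
            AlgorithmStep("HIO", 2000, positivity=True),
            AlgorithmStep("HIO", 2000),
            AlgorithmStep("RAAR", 2000),
            AlgorithmStep("ER", 200),
        ]
        sw = shrinkwrap if shrinkwrap is not None else ShrinkwrapSpec(threshold=0.25)
        return RunRecipe(
            steps=steps,
            shrinkwrap=sw,
            detwin_after=1000,
            initial_support=initial_support,
            seed=seed,
        )
    raise ValidationError(f"unknown preset '{name}'")
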