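"""Projections, cycles, shrinkwrap, detwinning and runners."""
import numpy as np
import pytest

from cdi_freellk import (
    AlgorithmStep,
    DiffractionPattern,
    ObjectEstimate,
    RunRecipe,
    ShrinkwrapSpec,
    Support,
    detwin,
    er_cycle,
    fourier_error,
    fourier_project,
    hio_cycle,
    multi_start,
    preset_recipe,
    raar_cycle,
    run_recipe,
    shrinkwrap_update,
    support_project,
)
from cdi_freellk.errors import ValidationError
from cdi_freellk.phasing_engine import apply_fourier_magnitudes


class TestFourierProjection:
    def test_working_pixel_amplitude_rescaled_phase_kept(self):
        # F = 3+4i with I_obs = 100: amplitude 5 -> 10, so F' = 6+8i
        f = np.full((2, 2), 3.0 + 4.0j)
        p = DiffractionPattern(np.full((2, 2), 100.0))
        out = apply_fourier_magnitudes(f, p)
        np.testing.assert_allclose(out, np.full((2, 2), 6.0 + 8.0j), rtol=1e-14)

    def test_free_and_invalid_pixels_bit_unchanged(self, rng):
        f = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        valid = rng.random((12, 12)) > 0.2
        free = (rng.random((12, 12)) > 0.7) & valid
        p = DiffractionPattern(rng.poisson(4.0, (12, 12)).astype(float) * valid, valid, free)
        out = apply_fourier_magnitudes(f, p)
        untouched = free | ~valid
        assert (out[untouched] == f[untouched]).all()  # bit-level

    def test_working_amplitudes_match_observed(self, rng):
        f = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        p = DiffractionPattern(rng.poisson(10.0, (12, 12)).astype(float) + 1.0)
        out = apply_fourier_magnitudes(f, p)
        np.testing.assert_allclose(np.abs(out) ** 2, p.intensity, rtol=1e-10)

    def test_zero_amplitude_gets_zero_phase(self):
        f = np.zeros((2, 2), complex)
        p = DiffractionPattern(np.full((2, 2), 9.0))
        out = apply_fourier_magnitudes(f, p)
        np.testing.assert_allclose(out, np.full((2, 2), 3.0 + 0j))

    def test_fixed_point(self, disks_truth_64, noiseless_pattern_64):
        obj, _ = disks_truth_64
        out = fourier_project(obj, noiseless_pattern_64)
        np.testing.assert_allclose(out.rho, obj.rho, atol=1e-10)

    def test_shape_mismatch(self, noiseless_pattern_64):
        with pytest.raises(ValidationError):
            fourier_project(ObjectEstimate(np.zeros((4, 4), complex)), noiseless_pattern_64)


class TestSupportProjection:
    def test_all_true_identity(self, rng):
        rho = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        out = support_project(ObjectEstimate(rho), Support(np.ones((6, 6), bool)))
        np.testing.assert_array_equal(out.rho, rho)

    def test_outside_zeroed(self):
        rho = np.full((4, 4), 5.0 + 1.0j)
        sup = np.zeros((4, 4), bool)
        sup[0, 0] = True
        out = support_project(ObjectEstimate(rho), Support(sup))
        assert out.rho[1, 1] == 0
        assert out.rho[0, 0] == 5.0 + 1.0j

    def test_positivity_zeroes_negative_real(self):
        rho = np.full((4, 4), -2.0 + 0j)
        out = support_project(ObjectEstimate(rho), Support(np.ones((4, 4), bool)), positivity=True)
        assert (out.rho == 0).all()

    def test_positivity_drops_imaginary(self):
        rho = np.full((4, 4), 2.0 + 3.0j)
        out = support_project(ObjectEstimate(rho), Support(np.ones((4, 4), bool)), positivity=True)
        np.testing.assert_array_equal(out.rho, np.full((4, 4), 2.0 + 0j))

    def test_empty_support_rejected(self):
        with pytest.raises(ValidationError):
            support_project(ObjectEstimate(np.ones((4, 4), complex)),
                            Support(np.zeros((4, 4), bool)))


class TestCycles:
    def test_truth_is_fixed_point_of_every_cycle(self, disks_truth_64, noiseless_pattern_64):
        obj, sup = disks_truth_64
        for fn in (er_cycle, hio_cycle, raar_cycle):
            out = fn(obj, noiseless_pattern_64, sup)
            np.testing.assert_allclose(out.rho, obj.rho, atol=1e-10)

    def test_er_monotone_noiseless(self, disks_truth_64, noiseless_pattern_64):
        obj, sup = disks_truth_64
        r = np.random.default_rng(0)
        cur = ObjectEstimate(
            r.uniform(0, 1, sup.shape) * np.exp(1j * r.uniform(0, 2 * np.pi, sup.shape)) * sup.mask
        )
        prev = np.inf
        for _ in range(20):
            cur = er_cycle(cur, noiseless_pattern_64, sup)
            f = np.fft.fftn(cur.rho, norm="ortho")
            e = fourier_error(f, noiseless_pattern_64, noiseless_pattern_64.working_mask)
            assert e <= prev + 1e-12
            prev = e

    def test_hio_beta_zero_is_fourier_projection(self, noisy_pattern_64, rng):
        rho = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
        obj = ObjectEstimate(rho)
        sup = Support(np.ones((64, 64), bool))
        out = hio_cycle(obj, noisy_pattern_64, sup, beta=0.0)
        pf = fourier_project(obj, noisy_pattern_64)
        np.testing.assert_allclose(out.rho, pf.rho, atol=1e-12)

    def test_step_validation(self):
        with pytest.raises(ValidationError):
            AlgorithmStep("HIO", 10, beta=1.5)
        with pytest.raises(ValidationError):
            AlgorithmStep("XYZ", 10)
        with pytest.raises(ValidationError):
            AlgorithmStep("ER", 0)


class TestShrinkwrap:
    def test_bright_pixel_disk(self):
        rho = np.zeros((32, 32), complex)
        rho[16, 16] = 1.0
        sup = shrinkwrap_update(ObjectEstimate(rho), ShrinkwrapSpec(threshold=0.3, sigma=2.0))
        assert sup.mask[16, 16]
        assert 1 <= sup.nb_support <= 200

    def test_threshold_near_one_keeps_argmax(self):
        r = np.random.default_rng(1)
        rho = r.uniform(0.1, 0.5, (16, 16)).astype(complex)
        rho[4, 9] = 5.0
        sup = shrinkwrap_update(ObjectEstimate(rho), ShrinkwrapSpec(threshold=0.999, sigma=0.5))
        assert sup.mask[4, 9]
        assert sup.nb_support <= 5

    def test_uniform_amplitude_all_true(self):
        rho = np.ones((16, 16), complex)
        sup = shrinkwrap_update(ObjectEstimate(rho), ShrinkwrapSpec(threshold=0.9, sigma=2.0))
        assert sup.mask.all()

    def test_zero_object_rejected(self):
        with pytest.raises(ValidationError):
            shrinkwrap_update(ObjectEstimate(np.zeros((8, 8), complex)),
                              ShrinkwrapSpec(threshold=0.3))


class TestDetwin:
    def test_twin_suppression_improves_overlap(self):
        # object + its mirrored copy inside a symmetric support
        n = 64
        single = np.zeros((n, n), complex)
        single[20:30, 24:40] = 1.0
        single[22:26, 28:32] = 2.0
        twin = np.conj(single[::-1, ::-1])
        both = single + 0.8 * twin
        sup = (np.abs(both) > 0)
        obj2, sup2 = detwin(ObjectEstimate(both), Support(sup))

        def corr(a, b):
            return abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))

        assert corr(obj2.rho, single) > corr(both, single)

    def test_confined_object_kept(self):
        rho = np.zeros((32, 32), complex)
        rho[4:10, 4:10] = 1.0
        sup = np.abs(rho) > 0
        obj2, sup2 = detwin(ObjectEstimate(rho), Support(sup))
        assert sup2.nb_support >= 0.5 * sup.sum()
        assert np.abs(obj2.rho).sum() > 0

    def test_exact_tie_keeps_lower_half(self):
        rho = np.zeros((32, 32), complex)
        rho[10, 10] = 1.0
        rho[20, 10] = 1.0  # symmetric 50/50 split along axis 0
        sup = np.abs(rho) > 0
        obj2, sup2 = detwin(ObjectEstimate(rho), Support(sup))
        assert sup2.mask[10, 10] and not sup2.mask[20, 10]


class TestRunners:
    @pytest.fixture
    def pattern_with_free(self, noisy_pattern_64):
        from cdi_freellk import FreeMaskSpec, generate_free_mask

        fm = generate_free_mask(noisy_pattern_64, FreeMaskSpec(seed=2))
        return noisy_pattern_64.with_free_mask(fm)

    @pytest.fixture
    def short_recipe(self, disks_truth_64):
        _, sup = disks_truth_64
        from scipy.ndimage import binary_dilation

        init = Support(binary_dilation(sup.mask, iterations=4))
        return RunRecipe(
            steps=[AlgorithmStep("HIO", 40), AlgorithmStep("ER", 20)],
            shrinkwrap=ShrinkwrapSpec(threshold=0.3),
            initial_support=init,
            seed=9,
        )

    def test_same_seed_bit_identical(self, pattern_with_free, short_recipe):
        o1, s1, t1 = run_recipe(pattern_with_free, short_recipe)
        o2, s2, t2 = run_recipe(pattern_with_free, short_recipe)
        assert (o1.rho == o2.rho).all()
        assert (s1.mask == s2.mask).all()
        assert t1 == t2

    def test_trace_records_metrics(self, noisy_pattern_64, short_recipe):
        _, _, trace = run_recipe(noisy_pattern_64, short_recipe)
        assert trace[-1]["cycle"] == 60
        assert all(np.isfinite(e["llk"]) for e in trace)

    def test_detwin_schedule_validated(self):
        with pytest.raises(ValidationError):
            RunRecipe(steps=[AlgorithmStep("ER", 10)], detwin_after=50, initial_support=8)

    def test_multi_start_bookkeeping(self, noisy_pattern_64, short_recipe, disks_truth_64):
        from cdi_freellk import FreeMaskSpec, generate_free_mask

        fm = generate_free_mask(noisy_pattern_64, FreeMaskSpec(seed=2))
        pat = noisy_pattern_64.with_free_mask(fm)
        sols = multi_start(pat, short_recipe, n_runs=3, threshold_range=(0.25, 0.4), seed=1)
        assert len(sols) == 3
        for key in ("nb_support", "llk", "llk_free", "threshold", "seed"):
            assert key in sols.meta and len(sols.meta[key]) == 3
        assert ((0.25 <= sols.meta["threshold"]) & (sols.meta["threshold"] <= 0.4)).all()
        np.testing.assert_array_equal(sols.free_mask, fm)

    def test_multi_start_single_run_equals_run_recipe(self, noisy_pattern_64, short_recipe):
        import dataclasses

        sols = multi_start(noisy_pattern_64, short_recipe, n_runs=1,
                           threshold_range=(0.25, 0.4), seed=3)
        r = dataclasses.replace(
            short_recipe,
            seed=int(sols.meta["seed"][0]),
            shrinkwrap=dataclasses.replace(short_recipe.shrinkwrap,
                                           threshold=float(sols.meta["threshold"][0])),
        )
        obj, sup, _ = run_recipe(noisy_pattern_64, r, record_every=None)
        np.testing.assert_array_equal(sols.rho[0], obj.rho)
        np.testing.assert_array_equal(sols.supports[0], sup.mask)

    def test_presets_match_protocols(self):
        logo = preset_recipe("logo", initial_support=64)
        assert [(s.kind, s.cycles) for s in logo.steps] == [("HIO", 400), ("ER", 200)]
        cell = preset_recipe("cell", initial_support=200)
        assert [(s.kind, s.cycles) for s in cell.steps] == [
            ("HIO", 2000), ("HIO", 2000), ("RAAR", 2000), ("ER", 200)]
        assert cell.steps[0].positivity and not cell.steps[1].positivity
        assert cell.detwin_after == 1000
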