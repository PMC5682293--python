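import math

import numpy as np
import pytest

from mirrorspim.forward_model import (
    AcquisitionPlan,
    AxisSwappedOperator,
    CameraStack,
    ImagingOperator,
    ObjectBelowMirrorError,
    ReflectedOperator,
    dense_operator,
    extended_object,
    illumination_pattern,
    simulate_acquisition,
)
from mirrorspim.geometry import MirrorGeometry, reflect_array, reflect_volume
from mirrorspim.optics import LightSheetSpec, ObjectiveSpec, make_detection_psf
from mirrorspim.volume import GridSpec, Volume


class TestExtendedObject:
    def test_reflectivity_one_doubles_total(self, mirror45, rng):
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        arr = np.zeros(grid.shape)
        arr[12:15, :, 12:15] = rng.random((3, 4, 3))  # well above the mirror
        f = Volume(arr, grid.pitch)
        ft = extended_object(f, mirror45)
        assert ft.total() == pytest.approx(2 * f.total())

    def test_zero_reflectivity_is_identity(self, rng):
        mirror = MirrorGeometry(45.0, reflectivity=1e-12)
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        arr = np.zeros(grid.shape)
        arr[12, 2, 12] = 1.0
        f = Volume(arr, grid.pitch)
        ft = extended_object(f, mirror)
        assert np.allclose(ft.data, arr, atol=1e-12)

    def test_matches_per_voxel_branch_evaluation(self, mirror45, rng):
        # brute-force oracle: evaluate the two half-space branches voxel by
        # voxel (above: f itself; below: f at the reflected coordinates)
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        arr = np.zeros(grid.shape)
        for _ in range(20):
            iz, iy, ix = rng.integers(0, 16), rng.integers(0, 4), rng.integers(0, 16)
            z = (iz - grid.origin[0]) * 0.1
            x = (ix - grid.origin[2]) * 0.1
            if z >= -x + 1e-9:
                arr[iz, iy, ix] = rng.random() + 0.1
        f = Volume(arr, grid.pitch)
        got = extended_object(f, mirror45).data

        expected = np.zeros_like(arr)
        tan = 1.0
        for iz in range(16):
            for iy in range(4):
                for ix in range(16):
                    z = (iz - grid.origin[0]) * 0.1
                    x = (ix - grid.origin[2]) * 0.1
                    if z >= -x * tan:
                        expected[iz, iy, ix] = arr[iz, iy, ix]
                    else:
                        # reflected coords: x' = -z, z' = -x (theta = 45)
                        jx = int(round(-z / 0.1 + grid.origin[2]))
                        jz = int(round(-x / 0.1 + grid.origin[0]))
                        if 0 <= jz < 16 and 0 <= jx < 16:
                            expected[iz, iy, ix] = arr[jz, iy, jx]
        assert np.allclose(got, expected, atol=1e-12)

    def test_unphysical_object_rejected(self, mirror45):
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        arr = np.zeros(grid.shape)
        arr[1, 0, 1] = 1.0  # z<0, x<0: below the mirror
        with pytest.raises(ObjectBelowMirrorError):
            extended_object(Volume(arr, grid.pitch), mirror45)


class TestIllumination:
    def test_mirror_symmetric_by_construction(self, mirror45, thin_sheet):
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        I = illumination_pattern(thin_sheet, mirror45, grid)
        refl = reflect_volume(I, mirror45)
        assert np.abs(refl.data - I.data).max() <= 1e-6

    def test_reflected_sheet_is_orthogonal_at_45(self, mirror45, thin_sheet):
        grid = GridSpec((33, 1, 33), (0.05, 0.05, 0.05))
        I = illumination_pattern(thin_sheet, mirror45, grid).data[:, 0, :]
        # incident sheet: ridge along z=0 row; reflected: ridge along x=0 col
        assert I[16, :].min() >= 1.0 - 1e-9   # z = 0 plane fully lit
        assert I[:, 16].min() >= 1.0 - 1e-9   # x = 0 plane fully lit

    def test_crossing_point_sums_both_peaks(self, mirror45, thin_sheet):
        grid = GridSpec((33, 1, 33), (0.05, 0.05, 0.05))
        I = illumination_pattern(thin_sheet, mirror45, grid)
        # the sheets cross at the origin on the mirror: intensity = 1 + 1
        assert I.data[16, 0, 16] == pytest.approx(2.0, rel=1e-9)


class TestForwardOperator:
    def test_delta_psf_uniform_illumination_reads_object_voxel(self, small_grid):
        psf_grid = GridSpec((3, 3, 3), small_grid.pitch)
        delta = make_detection_psf(ObjectiveSpec(na=0.8), 0.525, psf_grid, "delta")
        op = ImagingOperator(delta, None, MirrorGeometry(45.0), small_grid)
        F = np.zeros(small_grid.shape)
        F[7, 3, 5] = 2.5
        plane = op.forward_plane(F, 7)
        assert plane[3, 5] == pytest.approx(2.5, abs=1e-12)
        assert np.abs(plane).sum() == pytest.approx(2.5, abs=1e-9)

    def test_linearity(self, operator, rng):
        F1 = rng.random(operator.grid.shape)
        F2 = rng.random(operator.grid.shape)
        a, b = 1.7, -0.6
        lhs = operator.forward(a * F1 + b * F2)
        rhs = a * operator.forward(F1) + b * operator.forward(F2)
        assert np.abs(lhs - rhs).max() <= 1e-9 * np.abs(lhs).max()

    def test_forward_matches_dense_matrix_oracle(self, operator, rng):
        M = dense_operator(operator)
        F = rng.random(operator.grid.shape)
        assert np.abs(M @ F.ravel() - operator.forward(F).ravel()).max() <= 1e-9

    def test_adjoint_identity_against_dense_oracle(self, operator, rng):
        F = rng.random(operator.grid.shape)
        u = rng.random((len(operator.focal_indices),) + operator.grid.shape[1:])
        lhs = np.vdot(operator.forward(F), u)
        rhs = np.vdot(F, operator.transpose(u))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)
        M = dense_operator(operator)
        dense_t = (M.T @ u.ravel()).reshape(operator.grid.shape)
        assert np.abs(dense_t - operator.transpose(u)).max() <= 1e-9

    def test_normalization_is_transpose_of_ones(self, operator):
        ones = np.ones((len(operator.focal_indices),) + operator.grid.shape[1:])
        V = operator.normalization.data
        assert np.allclose(V, operator.transpose(ones), atol=1e-12)
        M = dense_operator(operator)
        assert np.abs(M.sum(axis=0) - V.ravel()).max() <= 1e-9
        assert V.min() > 0  # illuminated support covers this small grid

    def test_transpose_linearity(self, operator, rng):
        shape = (len(operator.focal_indices),) + operator.grid.shape[1:]
        r1, r2 = rng.random(shape), rng.random(shape)
        lhs = operator.transpose(2.0 * r1 + 0.5 * r2)
        rhs = 2.0 * operator.transpose(r1) + 0.5 * operator.transpose(r2)
        assert np.abs(lhs - rhs).max() <= 1e-9 * np.abs(lhs).max()

    def test_dense_operator_shape_and_guard(self, operator):
        M = dense_operator(operator)
        K = int(np.prod(operator.grid.shape))
        assert M.shape == (len(operator.focal_indices) * 8 * 12, K)
        big = GridSpec((20, 20, 20), (0.1, 0.1, 0.1))
        op_big = ImagingOperator(operator.psf, None, operator.mirror, big)
        with pytest.raises(ValueError, match="16"):
            dense_operator(op_big)


class TestShiftVariance:
    def test_mirror_term_breaks_shift_invariance(self, gaussian_psf, thin_sheet):
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        mirror = MirrorGeometry(45.0)
        op = ImagingOperator(gaussian_psf, thin_sheet, mirror, grid)
        f1 = np.zeros(grid.shape); f1[9, 2, 9] = 1.0
        f2 = np.zeros(grid.shape); f2[9, 2, 12] = 1.0   # shifted 3 voxels in x
        u1 = op.forward(f1)
        u2 = op.forward(f2)
        shifted = np.roll(u1, 3, axis=2)
        # outputs differ by more than the translation
        assert np.abs(u2 - shifted).max() > 0.05 * u1.max()

    def test_uniform_illumination_reduces_to_convolution(self, gaussian_psf, rng):
        from scipy.signal import fftconvolve
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        op = ImagingOperator(gaussian_psf, None, MirrorGeometry(45.0), grid)
        F = rng.random(grid.shape)
        conv = fftconvolve(F, gaussian_psf.kernel, mode="same")
        assert np.abs(op.forward(F) - conv).max() <= 1e-6 * conv.max()


class TestSimulateAcquisition:
    @pytest.fixture()
    def bead_setup(self, gaussian_psf, thin_sheet, mirror45):
        grid = GridSpec((24, 8, 24), (0.1, 0.1, 0.1))
        op = ImagingOperator(gaussian_psf, thin_sheet, mirror45, grid)
        arr = np.zeros(grid.shape)
        # bead ~1 um above the mirror along its normal: (z, x) = (0.7, 0.7)
        arr[int(round(11.5 + 7)), 4, int(round(11.5 + 7))] = 1.0
        return Volume(arr, grid.pitch), op

    def test_noiseless_output_scales_linearly(self, bead_setup):
        f, op = bead_setup
        (s1,) = simulate_acquisition(f, op)
        (s2,) = simulate_acquisition(f.with_data(2 * f.data), op)
        assert np.allclose(s2.planes, 2 * s1.planes, rtol=1e-9, atol=1e-12)

    def test_zero_object_gives_zero_stacks(self, bead_setup):
        f, op = bead_setup
        (s,) = simulate_acquisition(f.with_data(np.zeros_like(f.data)), op)
        assert not np.any(s.planes)

    def test_bead_images_symmetric_about_mirror(self, bead_setup):
        # direct + mirror image: two blobs whose midpoint lies on the mirror
        f, op = bead_setup
        (s,) = simulate_acquisition(f, op)
        vol = s.planes
        p1 = np.unravel_index(np.argmax(vol), vol.shape)
        masked = vol.copy()
        sl = tuple(slice(max(i - 4, 0), i + 5) for i in p1)
        masked[sl] = 0
        p2 = np.unravel_index(np.argmax(masked), masked.shape)
        mid = [(a + b) / 2 for a, b in zip(p1, p2)]
        # mirror plane: z + x = 2 * origin -> mid[0] + mid[2] == 23
        assert abs((mid[0] + mid[2]) - 23.0) <= 1.0
        assert abs(mid[1] - p1[1]) <= 1.0

    def test_poisson_noise_is_seed_reproducible(self, bead_setup):
        f, op = bead_setup
        f1k = f.with_data(f.data * 1e4)
        (a,) = simulate_acquisition(f1k, op, noise="poisson", seed=7)
        (b,) = simulate_acquisition(f1k, op, noise="poisson", seed=7)
        (c,) = simulate_acquisition(f1k, op, noise="poisson", seed=8)
        assert np.array_equal(a.planes, b.planes)
        assert not np.array_equal(a.planes, c.planes)


class TestFluxConservation:
    def test_total_signal_matches_sensitivity_weighted_object(
        self, gaussian_psf, thin_sheet, mirror45, rng
    ):
        grid = GridSpec((20, 8, 20), (0.1, 0.1, 0.1))
        op = ImagingOperator(gaussian_psf, thin_sheet, mirror45, grid)
        F = np.zeros(grid.shape)
        F[8:12, 3:5, 8:12] = rng.random((4, 2, 4))  # interior object
        u = op.forward(F)
        # <MF, 1> = <F, V> exactly (adjoint identity)
        assert u.sum() == pytest.approx(float((F * op.normalization.data).sum()), rel=1e-9)
        # and V itself matches the ideal (untruncated-in-x/y) sensitivity to 1%
        ideal = np.zeros(grid.shape)
        slice_sums = gaussian_psf.kernel.sum(axis=(1, 2))
        kz = gaussian_psf.kernel.shape[0]
        for k in op.focal_indices:
            w = op.illumination_weight(k)
            for m, sm in enumerate(slice_sums):
                zsrc = k + (m - kz // 2)
                if 0 <= zsrc < grid.shape[0]:
                    ideal[zsrc] += (w * np.ones(grid.shape))[zsrc] * sm
        ratio = (F * op.normalization.data).sum() / (F * ideal).sum()
        assert 0.99 <= ratio <= 1.0 + 1e-9


class TestConjugatedOperators:
    def test_reflected_operator_predicts_virtual_view(
        self, gaussian_psf, thin_sheet, mirror45
    ):
        grid = GridSpec((16, 4, 16), (0.1, 0.1, 0.1))
        op = ImagingOperator(gaussian_psf, thin_sheet, mirror45, grid)
        op2 = ReflectedOperator(op)
        arr = np.zeros(grid.shape)
        arr[11, 2, 11] = 1.0
        ft = extended_object(Volume(arr, grid.pitch), mirror45)
        U1 = op.forward(ft.data)
        U2 = op2.forward(ft.data)
        assert np.allclose(
            U2, reflect_array(U1, grid.pitch, grid.origin, 45.0), atol=1e-12
        )

    def test_axis_swapped_operator_is_self_adjoint_conjugation(
        self, gaussian_psf, thin_sheet, mirror45, rng
    ):
        grid = GridSpec((12, 6, 12), (0.1, 0.1, 0.1))
        op = ImagingOperator(gaussian_psf, thin_sheet, mirror45, grid)
        op3 = AxisSwappedOperator(op)
        F = rng.random(grid.shape)
        u = rng.random((12, 6, 12))
        lhs = np.vdot(op3.forward(F), u)
        rhs = np.vdot(F, op3.transpose(u))
        assert abs(lhs - rhs) <= 1e-9 * abs(lhs)


class TestPlanAndStack:
    def test_plan_validation(self):
        with pytest.raises(ValueError):
            AcquisitionPlan(step_um=0.0, n_steps=4)
        with pytest.raises(ValueError):
            AcquisitionPlan(step_um=0.1, n_steps=4, noise="poisson")  # no seed
        plan = AcquisitionPlan(step_um=0.1, n_steps=4, noise="poisson", seed=3)
        assert plan.seed == 3

    def test_stack_rejects_negative_data(self):
        with pytest.raises(ValueError):
            CameraStack(-np.ones((2, 3, 3)), (0.1, 0.1), (0, 1), 0.1)
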