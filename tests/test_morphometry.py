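import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pipn.errors import ValidationError
from pipn.morphometry import (
    FiberGeometry,
    FiberMorphometry,
    circularity,
    equivalent_diameter,
    fibers_from_frame,
    fibers_to_frame,
    measure_fiber,
    measure_from_labelmask,
    summarize_nerve,
)
from pipn.synthetic_data import (
    NerveSynthParams,
    generate_nerve_cross_section,
    rasterize_fibers,
)


def regular_ngon(n, radius=1.0, center=(0.0, 0.0)):
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


class TestCircularity:
    def test_square_closed_form(self):
        sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        assert circularity(sq) == pytest.approx(math.pi / 4, abs=1e-9)

    def test_hexagon_closed_form(self):
        assert circularity(regular_ngon(6)) == pytest.approx(math.pi * math.sqrt(3) / 6, abs=1e-9)

    @pytest.mark.parametrize("n", [3, 5, 8, 16, 64, 256])
    def test_regular_ngon_closed_form(self, n):
        expected = (math.pi / n) / math.tan(math.pi / n)
        assert circularity(regular_ngon(n)) == pytest.approx(expected, abs=1e-9)

    def test_ngon_circularity_increases_to_one(self):
        vals = [circularity(regular_ngon(n)) for n in (4, 8, 16, 32, 64, 128)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0 + 1e-6

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError):
            circularity(np.array([[0, 0], [1, 0]], float))
        with pytest.raises(ValidationError):
            circularity(np.array([[0, 0], [1, 0], [2, 0]], float))

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 2**31 - 1))
    def test_isoperimetric_bound_random_polygons(self, seed):
        rng = np.random.default_rng(seed)
        # star-shaped polygon: random radii on sorted angles (always simple)
        n = int(rng.integers(3, 40))
        theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
        theta = theta + rng.uniform(-0.4, 0.4, n) * (2 * math.pi / n)
        r = rng.uniform(0.2, 2.0, n)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert circularity(poly) <= 1 + 1e-6

    def test_scale_invariance(self):
        poly = regular_ngon(17, radius=0.7)
        assert circularity(poly * 123.4) == pytest.approx(circularity(poly), rel=1e-12)


class TestEquivalentDiameter:
    def test_closed_forms(self):
        assert equivalent_diameter(math.pi) == pytest.approx(2.0)
        assert equivalent_diameter(78.53981633974483) == pytest.approx(10.0)

    def test_scaling_law(self):
        assert equivalent_diameter(4 * 3.3) == pytest.approx(2 * equivalent_diameter(3.3))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValidationError):
            equivalent_diameter(0.0)


class TestMeasureFiber:
    def concentric(self, d_axon=6.0, d_fiber=10.0, n=4096):
        return FiberGeometry(
            "f", regular_ngon(n, d_fiber / 2), regular_ngon(n, d_axon / 2)
        )

    def test_concentric_circle_closed_form(self):
        m = measure_fiber(self.concentric())
        assert m.g_ratio == pytest.approx(0.6, abs=1e-9)  # exact for similar polygons
        assert m.myelin_thickness_um == pytest.approx(2.0, abs=1e-4)

    def test_demyelinated_limit(self):
        f = FiberGeometry("f", regular_ngon(64, 5.0), regular_ngon(64, 5.0))
        with pytest.warns(UserWarning, match="no measurable myelin"):
            m = measure_fiber(f)
        assert m.g_ratio == pytest.approx(1.0)
        assert m.myelin_thickness_um == pytest.approx(0.0, abs=1e-12)

    def test_axon_not_contained_rejected(self):
        with pytest.raises(ValidationError):
            FiberGeometry("f", regular_ngon(64, 2.0), regular_ngon(64, 1.0, center=(3.0, 0.0)))

    def test_radial_noise_lowers_circularity(self):
        rng = np.random.default_rng(3)
        theta = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        noise = 1 + 0.2 * np.sin(5 * theta)
        noisy = np.column_stack([3 * noise * np.cos(theta), 3 * noise * np.sin(theta)])
        assert circularity(noisy) < circularity(regular_ngon(64, 3.0))

    def test_circularity_contour_flag(self):
        f = FiberGeometry("f", regular_ngon(64, 5.0), regular_ngon(4, 2.0))
        assert measure_fiber(f, "fiber").circularity > measure_fiber(f, "axon").circularity

    def test_uniform_scaling(self):
        f = self.concentric(n=256)
        m1 = measure_fiber(f)
        f2 = FiberGeometry("f", f.outer * 3, f.inner * 3)
        m2 = measure_fiber(f2)
        assert m2.circularity == pytest.approx(m1.circularity, rel=1e-12)
        assert m2.g_ratio == pytest.approx(m1.g_ratio, rel=1e-12)
        assert m2.myelin_thickness_um == pytest.approx(3 * m1.myelin_thickness_um, rel=1e-12)


class TestLabelMaskPathway:
    def test_rasterized_circle_near_unit_circularity(self):
        from skimage.draw import disk

        mask = np.zeros((128, 128), dtype=np.int32)
        rr, cc = disk((64, 64), 50)
        mask[rr, cc] = 3  # myelin of fiber 1
        rr, cc = disk((64, 64), 30)
        mask[rr, cc] = 2  # axon of fiber 1
        m = measure_from_labelmask(mask, pixel_size_um=1.0, circularity_contour="fiber")
        assert len(m) == 1
        assert m[0].circularity == pytest.approx(1.0, abs=0.02)

    def test_mask_agrees_with_polygon_oracle(self):
        params = NerveSynthParams(
            n_fibers=10, fiber_diameter_mean_um=10, fiber_diameter_sd_um=1.5,
            field_size_um=60, degeneration_level=0.4, seed=2,
        )
        fibers = generate_nerve_cross_section(params)
        mask = rasterize_fibers(fibers, 0.1, params.field_size_um)  # d >= 20 px
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask_m = {m.fiber_id: m for m in measure_from_labelmask(mask, 0.1)}
        assert len(mask_m) == len(fibers)
        for f in fibers:
            p = measure_fiber(f)
            m = mask_m[f.fiber_id]
            for attr in ("circularity", "g_ratio", "myelin_thickness_um"):
                assert getattr(m, attr) == pytest.approx(getattr(p, attr), rel=0.03)

    def test_empty_mask(self):
        assert measure_from_labelmask(np.zeros((16, 16), dtype=np.int32), 1.0) == []

    def test_orphan_axon_skipped_with_warning(self):
        from skimage.draw import disk

        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 10)
        mask[rr, cc] = 2  # axon without myelin
        with pytest.warns(UserWarning, match="missing myelin"):
            assert measure_from_labelmask(mask, 1.0) == []

    def test_float_mask_rejected(self):
        with pytest.raises(ValidationError):
            measure_from_labelmask(np.zeros((8, 8)), 1.0)


class TestSummarizeNerve:
    def fibers(self, g_ratios):
        return [
            FiberMorphometry(f"f{i}", 0.9, g, 1.0, 10.0, 30.0)
            for i, g in enumerate(g_ratios)
        ]

    def test_hand_arithmetic(self):
        out = summarize_nerve(self.fibers([0.5, 0.6, 0.7]))
        row = out[out["index"] == "g_ratio"].iloc[0]
        assert row["mean"] == pytest.approx(0.6)
        assert row["sem"] == pytest.approx(0.1 / math.sqrt(3), abs=1e-4)

    def test_single_fiber_sem_missing(self):
        with pytest.warns(UserWarning, match="single fiber"):
            out = summarize_nerve(self.fibers([0.6]))
        assert out["sem"].isna().all()

    def test_permutation_invariant(self):
        a = summarize_nerve(self.fibers([0.5, 0.6, 0.7]))
        b = summarize_nerve(self.fibers([0.7, 0.5, 0.6]))
        assert np.allclose(a["mean"], b["mean"]) and np.allclose(a["sem"], b["sem"])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_nerve([])


class TestPolygonIO:
    def test_frame_round_trip(self):
        fibers = generate_nerve_cross_section(NerveSynthParams(n_fibers=5, seed=1))
        back = fibers_from_frame(fibers_to_frame(fibers))
        assert len(back) == len(fibers)
        for a, b in zip(sorted(fibers, key=lambda f: f.fiber_id), back):
            assert np.allclose(a.outer, b.outer) and np.allclose(a.inner, b.inner)


class TestEndToEndPattern:
    def test_degeneration_shifts_all_three_indices(self):
        def group_means(level, seed):
            fibers = generate_nerve_cross_section(
                NerveSynthParams(n_fibers=60, degeneration_level=level, seed=seed,
                                 field_size_um=160)
            )
            m = [measure_fiber(f) for f in fibers]
            return (
                np.mean([x.circularity for x in m]),
                np.mean([x.g_ratio for x in m]),
                np.mean([x.myelin_thickness_um for x in m]),
            )

        circ0, g0, th0 = group_means(0.0, seed=31)
        circ6, g6, th6 = group_means(0.6, seed=32)
        assert circ6 < circ0
        assert g6 > g0
        assert th6 < th0
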