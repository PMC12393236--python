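"""Atlas construction: normalization, templates, longitudinal maps, residual
means, and the iterative fixed point."""

import numpy as np
import pytest

from svfatlas.atlas import (
    build_atlas,
    build_template,
    normalize_global,
    residual_deformation,
    update_longitudinal_maps,
)
from svfatlas.diffeo import exp_svf
from svfatlas.fields import Image3D, InvalidInputError
from svfatlas.kernel import KernelWeights, compute_weights
from svfatlas.phantom import Subject, make_phantom

from conftest import constant_svf


class TestNormalizeGlobal:
    def test_image_in_unit_range_with_matching_percentiles_unchanged(self, rng):
        vals = rng.random((20, 20, 20))
        p1, p99 = np.percentile(vals, [1, 99])
        vals = (vals - p1) / (p99 - p1)  # robust range exactly [0, 1]
        out = normalize_global(Image3D(vals))
        assert np.allclose(out.values, vals, atol=1e-12)

    def test_affine_invariance(self, rng):
        vals = rng.random((16, 16, 16))
        a = normalize_global(Image3D(vals))
        b = normalize_global(Image3D(vals * 10.0 + 3.0))
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_two_tissue_phantom_percentiles_map_to_unit_range(self):
        subj, _ = make_phantom(28.0, seed=1)
        out = normalize_global(subj.image)
        p1, p99 = np.percentile(out.values, [1, 99])
        assert abs(p1) < 1e-9 and abs(p99 - 1.0) < 1e-9

    def test_reference_matching_aligns_median_and_iqr(self, rng):
        img = Image3D(rng.random((16, 16, 16)) * 5)
        ref = Image3D(rng.random((16, 16, 16)))
        out = normalize_global(img, reference=ref)
        assert np.percentile(out.values, 50) == pytest.approx(np.percentile(ref.values, 50))
        iqr = np.subtract(*np.percentile(out.values, [75, 25]))
        ref_iqr = np.subtract(*np.percentile(ref.values, [75, 25]))
        assert iqr == pytest.approx(ref_iqr)

    def test_constant_image_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_global(Image3D(np.full((8, 8, 8), 3.0)))


def _identity_maps(n, shape):
    return [exp_svf(constant_svf(shape, [0, 0, 0])) for _ in range(n)]


class TestBuildTemplate:
    def test_identical_images_any_weights_reproduce_image(self, rng):
        shape = (12, 12, 12)
        img = Image3D(rng.random(shape))
        subjects = [Subject(f"s{i}", img.copy(), 28.0) for i in range(3)]
        kw = KernelWeights(np.array([0.2, 0.5, 0.3]), 28.0, 0.5)
        out = build_template(subjects, _identity_maps(3, shape), kw)
        assert np.allclose(out.values, img.values, atol=1e-12)

    def test_degenerate_weight_selects_single_subject(self, rng):
        shape = (10, 10, 10)
        a = Image3D(rng.random(shape))
        b = Image3D(rng.random(shape))
        subjects = [Subject("a", a, 28.0), Subject("b", b, 28.0)]
        kw = KernelWeights(np.array([1.0, 0.0]), 28.0, 0.5)
        out = build_template(subjects, _identity_maps(2, shape), kw)
        assert np.array_equal(out.values, a.values)

    def test_constant_images_weighted_mean(self):
        shape = (8, 8, 8)
        subjects = [Subject("a", Image3D(np.full(shape, 0.2)), 28.0),
                    Subject("b", Image3D(np.full(shape, 0.8)), 28.0)]
        kw = KernelWeights(np.array([0.25, 0.75]), 28.0, 0.5)
        out = build_template(subjects, _identity_maps(2, shape), kw)
        assert np.allclose(out.values, 0.65, atol=1e-12)

    def test_misaligned_weights_rejected(self, rng):
        shape = (8, 8, 8)
        subjects = [Subject("a", Image3D(rng.random(shape)), 28.0)]
        kw = KernelWeights(np.array([0.5, 0.5]), 28.0, 0.5)
        with pytest.raises(InvalidInputError):
            build_template(subjects, _identity_maps(1, shape), kw)


class TestLongitudinalMaps:
    SHAPE = (10, 10, 10)

    def test_empty_history_means_identity(self):
        out = update_longitudinal_maps([], 28.0, [27.0, 28.0])
        assert out == {}

    def test_own_age_gives_identity_at_any_depth(self):
        hist = [{27.0: constant_svf(self.SHAPE, [1, 0, 0]),
                 28.0: constant_svf(self.SHAPE, [0, 1, 0])},
                {27.0: constant_svf(self.SHAPE, [0, 0, 2]),
                 28.0: constant_svf(self.SHAPE, [0.5, 0, 0])}]
        out = update_longitudinal_maps(hist, 28.0, [28.0])
        assert np.abs(out[28.0].vectors).max() < 1e-12

    def test_constant_field_history_sums_differences(self):
        hist = [{27.0: constant_svf(self.SHAPE, [1.0, 0, 0]),
                 28.0: constant_svf(self.SHAPE, [0.2, 0, 0])},
                {27.0: constant_svf(self.SHAPE, [0, 0.5, 0]),
                 28.0: constant_svf(self.SHAPE, [0, 0.1, 0])}]
        out = update_longitudinal_maps(hist, 28.0, [27.0])
        expected = np.array([1.0 - 0.2, 0.5 - 0.1, 0.0])
        assert np.allclose(out[27.0].vectors[3, 3, 3], expected, atol=1e-12)

    def test_missing_svf_rejected(self):
        with pytest.raises(InvalidInputError):
            update_longitudinal_maps([{27.0: "not a field"}], 28.0, [27.0])


class TestResidualDeformation:
    SHAPE = (10, 10, 10)

    def test_shared_deformation_returns_its_inverse_exp(self):
        v = constant_svf(self.SHAPE, [0.5, -0.2, 0.0])
        kw = KernelWeights(np.array([0.4, 0.6]), 28.0, 0.5)
        out = residual_deformation([v, v], kw)
        assert np.allclose(out.displacement, [-0.5, 0.2, 0.0], atol=1e-12)

    def test_antisymmetric_pair_equal_weights_identity(self):
        v = constant_svf(self.SHAPE, [1.0, 0, 0])
        kw = KernelWeights(np.array([0.5, 0.5]), 28.0, 0.5)
        out = residual_deformation([v, -v], kw)
        assert np.abs(out.displacement).max() < 1e-12

    def test_kernel_weighted_constant_fields(self):
        ages = [27.6, 28.0, 28.4]
        kw = compute_weights(ages, 28.0)
        fields = [constant_svf(self.SHAPE, [1, 0, 0]),
                  constant_svf(self.SHAPE, [0, 1, 0]),
                  constant_svf(self.SHAPE, [0, 0, 1])]
        out = residual_deformation(fields, kw)
        assert np.allclose(out.displacement[5, 5, 5], -kw.weights, atol=1e-12)


class TestBuildAtlas:
    def test_identical_cohort_is_fixed_point(self, fast_ssd_config):
        from svfatlas.phantom import scaled_params

        subj, _ = make_phantom(28.0, scaled_params((24, 24, 24)), seed=7)
        cohort = [Subject(f"s{i}", subj.image.copy(), 28.0) for i in range(5)]
        res = build_atlas(cohort, [28.0], n_iter=2, reg_config=fast_ssd_config)
        tp = res.timepoints[0]
        assert np.abs(tp.template.values - subj.image.values).mean() <= 1e-6
        for tr in res.transforms.values():
            assert tr.phi.max_displacement() <= 1e-6

    def test_mirror_symmetric_pair_yields_symmetric_template(self, fast_ssd_config):
        from dataclasses import replace
        from svfatlas.phantom import scaled_params

        params = replace(scaled_params((24, 24, 24)), noise_sd=0.0)
        subj, _ = make_phantom(28.0, params, seed=0)
        mirrored = Image3D(subj.image.values[::-1].copy())
        cohort = [Subject("a", subj.image, 28.0), Subject("b", mirrored, 28.0)]
        res = build_atlas(cohort, [28.0], n_iter=2, reg_config=fast_ssd_config)
        tmpl = res.timepoints[0].template.values
        asym = np.abs(tmpl - tmpl[::-1]).mean()
        assert asym < 0.02  # resampling tolerance

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidInputError):
            build_atlas([], [28.0])

    def test_unsupported_target_age_raises_early(self):
        subj, _ = make_phantom(28.0, seed=1)
        from svfatlas.kernel import NoSupportError

        with pytest.raises(NoSupportError):
            build_atlas([Subject("a", subj.image, 28.0)], [35.0], n_iter=1)
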