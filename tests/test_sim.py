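"""Forward physics, noise family and spheroid-map generator."""

import math

import numpy as np
import pytest
from scipy import stats

from mechspheroid.io import ConfigurationError, SizingError
from mechspheroid.sim import (AcousticMaterial, CohortSpec, OpticsConfig,
                              PhenotypeParams, brillouin_shift_from_modulus,
                              default_phenotype_table, generate_cohort,
                              generate_spheroid_map, modulus_from_shift,
                              skewnorm_from_moments, spheroid_seed)

WATER = AcousticMaterial(longitudinal_modulus=2.2e9, refractive_index=1.33,
                         mass_density=1000.0)


class TestBrillouinShift:
    def test_water_reference_value(self):
        # independent hand evaluation of (2n/lambda)*sqrt(M'/rho) in GHz
        expected = (2 * 1.33 / 660e-9) * math.sqrt(2.2e9 / 1000.0) / 1e9
        shift = brillouin_shift_from_modulus(WATER, OpticsConfig(660e-9, 180))
        assert shift == pytest.approx(expected, rel=1e-12)
        assert shift == pytest.approx(5.98, abs=0.01)

    def test_square_root_homogeneity_in_modulus(self):
        m4 = AcousticMaterial(4 * 2.2e9, 1.33, 1000.0)
        assert brillouin_shift_from_modulus(m4) == pytest.approx(
            2 * brillouin_shift_from_modulus(WATER), rel=1e-12)

    def test_shift_vanishes_as_angle_closes(self):
        # theta=0 itself is outside the valid optics domain
        with pytest.raises(ValueError):
            OpticsConfig(scattering_angle=0.0)
        tiny = brillouin_shift_from_modulus(WATER, OpticsConfig(660e-9, 1e-6))
        assert tiny < 1e-7

    @pytest.mark.parametrize("field,values,increasing", [
        ("longitudinal_modulus", np.logspace(8, 11, 7), True),
        ("refractive_index", np.linspace(1.0, 1.6, 7), True),
        ("mass_density", np.linspace(800, 1400, 7), False),
    ])
    def test_monotonicity_in_material(self, field, values, increasing):
        shifts = []
        for v in values:
            kwargs = dict(longitudinal_modulus=2.2e9, refractive_index=1.33,
                          mass_density=1000.0)
            kwargs[field] = v
            shifts.append(brillouin_shift_from_modulus(
                AcousticMaterial(**kwargs)))
        diffs = np.diff(shifts)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_monotone_decreasing_in_wavelength(self):
        shifts = [brillouin_shift_from_modulus(WATER, OpticsConfig(lam, 180))
                  for lam in np.linspace(400e-9, 800e-9, 7)]
        assert np.all(np.diff(shifts) < 0)

    def test_forward_inverse_round_trip_log_grid(self):
        for modulus in np.logspace(np.log10(0.1e9), np.log10(100e9), 25):
            mat = AcousticMaterial(modulus, 1.37, 1050.0)
            shift = brillouin_shift_from_modulus(mat)
            recovered = modulus_from_shift(shift, 1.37, 1050.0)
            assert recovered == pytest.approx(modulus, rel=1e-12)

    def test_quadratic_relation_of_inverse(self):
        m1 = modulus_from_shift(3.0, 1.33, 1000.0)
        m2 = modulus_from_shift(6.0, 1.33, 1000.0)
        assert m2 == pytest.approx(4 * m1, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(longitudinal_modulus=-1.0, refractive_index=1.33,
             mass_density=1000.0),
        dict(longitudinal_modulus=2.2e9, refractive_index=0.9,
             mass_density=1000.0),
        dict(longitudinal_modulus=2.2e9, refractive_index=1.33,
             mass_density=0.0),
    ])
    def test_invalid_material_rejected(self, bad):
        with pytest.raises(ValueError):
            AcousticMaterial(**bad)

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            modulus_from_shift(0.0, 1.33, 1000.0)


class TestSkewNormalMoments:
    @pytest.mark.parametrize("mean,sd,skew", [
        (5.2, 0.06, -0.5), (0.0, 1.0, -0.9), (10.0, 2.0, 0.0),
        (5.0, 0.1, -0.2),
    ])
    def test_sample_moments_match_targets(self, mean, sd, skew):
        alpha, loc, scale = skewnorm_from_moments(mean, sd, skew)
        rng = np.random.default_rng(42)
        x = stats.skewnorm.rvs(alpha, loc=loc, scale=scale, size=200_000,
                               random_state=rng)
        assert x.mean() == pytest.approx(mean, abs=4 * sd / np.sqrt(2e5) + 1e-3)
        assert x.std() == pytest.approx(sd, rel=0.02)
        assert stats.skew(x) == pytest.approx(skew, abs=0.05)

    def test_unrepresentable_skew_rejected(self):
        with pytest.raises(ValueError):
            skewnorm_from_moments(0.0, 1.0, -1.2)


def _symmetric_params(**overrides):
    base = dict(cell_line="normal", day=8, core_mean_shift=5.3,
                periphery_mean_shift=5.3, core_sd=0.05, periphery_sd=0.05,
                periphery_skew=0.0, radius_mean=44.0, radius_sd=0.0,
                boundary_roughness=0.0, protrusion_count=0,
                protrusion_length=0.0, mean_jitter_sd=0.0,
                sd_scale_jitter=0.0, skew_jitter_sd=0.0)
    base.update(overrides)
    return PhenotypeParams(**base)


class TestGenerateSpheroidMap:
    def test_symmetric_generator_has_zero_skewness(self):
        params = _symmetric_params(radius_mean=60.0)
        bmap, mask, _ = generate_spheroid_map(params, 1.0,
                                              extent=160, seed=3)
        values = bmap.shifts[mask]
        assert values.size >= 10_000
        assert abs(stats.skew(values)) < 0.1

    def test_core_stiffer_than_periphery_on_default_map(self):
        params = default_phenotype_table()[("normal", 8)]
        bmap, mask, core = generate_spheroid_map(params, 1.0, seed=11)
        core_vals = bmap.shifts[core]
        peri_vals = bmap.shifts[mask & ~core]
        res = stats.ttest_ind(core_vals, peri_vals, equal_var=False)
        assert core_vals.mean() > peri_vals.mean()
        assert res.pvalue < 0.05

    def test_same_seed_bit_identical(self):
        params = default_phenotype_table()[("cancer", 5)]
        a = generate_spheroid_map(params, 1.0, seed=99)
        b = generate_spheroid_map(params, 1.0, seed=99)
        assert np.array_equal(a[0].shifts, b[0].shifts)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2], b[2])

    def test_extent_too_small_raises(self):
        params = default_phenotype_table()[("normal", 8)]
        with pytest.raises(SizingError):
            generate_spheroid_map(params, 1.0, extent=40, seed=0)

    def test_protrusions_extend_reach(self):
        base = _symmetric_params(boundary_roughness=0.0)
        spiky = _symmetric_params(protrusion_count=4, protrusion_length=10.0)
        _, mask_base, _ = generate_spheroid_map(base, 1.0, extent=160, seed=5)
        _, mask_spiky, _ = generate_spheroid_map(spiky, 1.0, extent=160,
                                                 seed=5)
        assert mask_spiky.sum() > mask_base.sum()

    def test_phenotype_invariants_enforced(self):
        with pytest.raises(ValueError):
            _symmetric_params(core_mean_shift=5.0, periphery_mean_shift=5.3)
        with pytest.raises(ValueError):
            _symmetric_params(periphery_skew=0.5)
        with pytest.raises(ValueError):
            _symmetric_params(core_sd=0.1, periphery_sd=0.05)


class TestGenerateCohort:
    def test_counts_and_manifest(self):
        spec = CohortSpec(n_normal=2, n_cancer=2, days=(2,), seed=1)
        ds = generate_cohort(spec)
        assert len(ds) == 4
        assert len(ds.manifest) == 4
        assert set(ds.manifest["line"]) == {"normal", "cancer"}

    def test_deterministic_across_runs(self):
        spec = CohortSpec(n_normal=2, n_cancer=1, days=(2, 5), seed=7)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert a.manifest.equals(b.manifest)
        for sa, sb in zip(a.spheroids, b.spheroids):
            assert np.array_equal(sa.map.shifts, sb.map.shifts)

    def test_missing_phenotype_entry_raises(self):
        table = default_phenotype_table()
        del table[("cancer", 5)]
        spec = CohortSpec(n_normal=1, n_cancer=1, days=(5,), seed=0)
        with pytest.raises(ConfigurationError):
            generate_cohort(spec, table)

    def test_per_spheroid_seeds_stable_and_distinct(self):
        s1 = spheroid_seed(0, "normal", 2, 0)
        assert s1 == spheroid_seed(0, "normal", 2, 0)
        seeds = {spheroid_seed(0, line, day, i)
                 for line in ("normal", "cancer")
                 for day in (2, 5, 8) for i in range(10)}
        assert len(seeds) == 60
        assert all(0 <= s < 2 ** 31 for s in seeds)
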