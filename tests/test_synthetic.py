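"""Claw generator, stress simulator and benchmark cohorts."""

import numpy as np
import pytest

import clawfsa as c
from clawfsa.synthetic import GenerationError


def test_straight_cone_volume_closed_form():
    params = c.ClawParams(
        length_mm=50.0,
        centerline_arc_deg=0.0,
        base_depth_mm=10.0,
        base_width_mm=10.0,
        taper_exponent=1.0,
        axial_segments=32,
        circumferential_segments=16,
    )
    mesh = c.generate_claw_mesh(params)
    exact = np.pi * 5.0**2 * 50.0 / 3.0
    assert abs(mesh.tet_volumes().sum() - exact) / exact < 0.02


def test_same_seed_bit_identical():
    p = c.ClawParams(noise_amplitude_mm=0.3, seed=17)
    a, b = c.generate_claw_mesh(p), c.generate_claw_mesh(p)
    np.testing.assert_array_equal(a.node_coords, b.node_coords)
    np.testing.assert_array_equal(a.tets, b.tets)


def test_dw_parameter_recovered():
    params = c.ClawParams(
        base_depth_mm=16.0, base_width_mm=8.0, centerline_arc_deg=60.0,
        axial_segments=16, circumferential_segments=8,
    )
    m = c.measure_claw(c.generate_claw_mesh(params))
    assert abs(m.ratio_DW - 2.0) / 2.0 < 0.05


def test_region_sets_and_node_u():
    mesh = c.generate_claw_mesh(c.ClawParams(axial_segments=8, circumferential_segments=4))
    assert len(mesh.node_sets["articular"]) > 0
    assert len(mesh.facet_sets["ventral"]) > 0
    assert mesh.node_u is not None
    assert np.all(mesh.node_u[mesh.node_sets["articular"]] == 0.0)
    assert np.all(mesh.node_u[mesh.node_sets["tip"]] >= 0.95)


def test_too_tight_arc_rejected():
    with pytest.raises(GenerationError, match="radius"):
        c.generate_claw_mesh(
            c.ClawParams(length_mm=20.0, centerline_arc_deg=170.0, base_depth_mm=30.0)
        )


def test_invalid_params_rejected():
    with pytest.raises(GenerationError):
        c.ClawParams(axial_segments=2).validate()
    with pytest.raises(GenerationError):
        c.ClawParams(taper_exponent=0.0).validate()
    with pytest.raises(GenerationError):
        c.ClawParams(centerline_arc_deg=180.0).validate()


def test_random_parameter_sweep_valid_meshes():
    """Generated meshes satisfy all structural invariants across a sweep."""
    g = np.random.default_rng(123)
    for draw in range(200):
        params = c.ClawParams(
            length_mm=float(g.uniform(20, 80)),
            centerline_arc_deg=float(g.uniform(0, 100)),
            base_depth_mm=float(g.uniform(4, 16)),
            base_width_mm=float(g.uniform(4, 16)),
            taper_exponent=float(g.uniform(0.5, 2.0)),
            axial_segments=int(g.integers(4, 10)),
            circumferential_segments=4,
            noise_amplitude_mm=float(g.uniform(0, 0.3)),
            seed=int(g.integers(2**31)),
        )
        try:
            mesh = c.generate_claw_mesh(params)
        except GenerationError:
            continue  # over-tight arcs are allowed to refuse
        mesh.validate(require_articular=True)
        assert mesh.is_closed()


def test_volume_and_area_converge_with_axial_refinement():
    """Axial refinement of a curved claw converges monotonically toward a
    fine-resolution reference (a straight cone is axially exact, so the
    curved centerline is the interesting case)."""

    def make(na):
        return c.generate_claw_mesh(
            c.ClawParams(
                length_mm=50.0, centerline_arc_deg=75.0, base_depth_mm=12.0,
                base_width_mm=8.0, axial_segments=na, circumferential_segments=8,
            )
        )

    ref = make(256)
    ref_vol = ref.tet_volumes().sum()
    ref_area = ref.surface_area()
    vol_errs, area_errs = [], []
    for na in (8, 16, 32, 64):
        m = make(na)
        vol_errs.append(abs(m.tet_volumes().sum() - ref_vol))
        area_errs.append(abs(m.surface_area() - ref_area))
    assert all(b < a for a, b in zip(vol_errs, vol_errs[1:]))
    assert all(b < a for a, b in zip(area_errs, area_errs[1:]))


class TestStressSim:
    def test_constant_family(self, small_claw):
        sp = c.StressSimParams(
            family="constant", scenario_params={s: (7.0, 0.0) for s in c.SCENARIOS}
        )
        f = c.generate_stress_field(small_claw, sp, "piercing")
        assert np.all(f.element_vm_mpa == 7.0)
        np.testing.assert_array_equal(f.element_volume_mm3, small_claw.tet_volumes())

    def test_seeded_reproducibility(self, small_claw):
        sp = c.StressSimParams(seed=5)
        a = c.generate_stress_field(small_claw, sp, "scratch_digging")
        b = c.generate_stress_field(small_claw, sp, "scratch_digging")
        np.testing.assert_array_equal(a.element_vm_mpa, b.element_vm_mpa)
        other = c.generate_stress_field(small_claw, sp, "piercing")
        assert not np.array_equal(a.element_vm_mpa, other.element_vm_mpa)

    def test_lognormal_moment_oracle(self):
        mesh = c.generate_claw_mesh(
            c.ClawParams(axial_segments=28, circumferential_segments=8)
        )
        assert mesh.n_tets >= 10_000
        mu, sigma = 1.0, 0.5
        sp = c.StressSimParams(
            scenario_params={s: (mu, sigma) for s in c.SCENARIOS}, seed=0
        )
        f = c.generate_stress_field(mesh, sp, "hook_and_pull")
        expected = np.exp(mu + sigma**2 / 2)
        sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2))
        # exact standard error of the volume-weighted mean of i.i.d. draws
        w = f.element_volume_mm3
        se = sd * np.sqrt((w**2).sum()) / w.sum()
        from clawfsa.intervals import mean_stress_summary

        assert abs(mean_stress_summary(f) - expected) < 4 * se

    def test_unknown_family(self, small_claw):
        with pytest.raises(ValueError, match="family"):
            c.StressSimParams(family="weibull").validate()


class TestCohort:
    def test_identical_gradient_identical_records(self):
        grad = c.GradientSpec(
            dw_range=(1.5, 1.5), arc_range_deg=(45.0, 45.0),
            base_stress_range_mpa=(8.0, 8.0),
        )
        cohort = c.make_benchmark_cohort(6, grad, seed=1)
        specs = cohort.manifest["specimens"]
        dws = {round(v["dw"], 12) for v in specs.values()}
        assert dws == {1.5}
        means = {
            tuple(sorted(v["scenario_mean_stress_mpa"].items())) for v in specs.values()
        }
        assert len(means) == 1

    def test_manifest_truth_matches_sampled_means(self):
        cohort = c.make_benchmark_cohort(4, seed=2)
        from clawfsa.intervals import mean_stress_summary

        for sid in cohort.specimen_ids:
            truth = cohort.manifest["specimens"][sid]["scenario_mean_stress_mpa"]
            for s in c.SCENARIOS:
                f = cohort.fields[(sid, s)]
                got = mean_stress_summary(f)
                # lognormal sigma=0.5: sd/mean = sqrt(e^0.25 - 1) ~ 0.53
                se = truth[s] * 0.54 / np.sqrt(len(f))
                assert abs(got - truth[s]) < 5 * se

    def test_sign_recovery_under_digging_multiplier(self):
        """dig = 3x pierce: the pipeline recovers the rule-implied sign
        (initial scenario higher => negative side) for every specimen."""
        from clawfsa.pipeline import analyze_fields

        grad = c.GradientSpec(
            scenario_multipliers={
                "scratch_digging": 3.0, "hook_and_pull": 2.0, "piercing": 1.0
            }
        )
        cohort = c.make_benchmark_cohort(5, grad, seed=3)
        ok = 0
        reps = 20
        for r in range(reps):
            fields = list(cohort.resample_fields(seed=r).values())
            rep = analyze_fields(fields).report
            if (rep["side_digpierce"] < 0).all():
                ok += 1
        assert ok / reps >= 0.95

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            c.make_benchmark_cohort(2)
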