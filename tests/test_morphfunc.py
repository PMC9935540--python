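"""Regressions, morphospace projection and divergence metrics."""

import numpy as np
import pandas as pd
import pytest

import clawfsa as c
from clawfsa.morphfunc import divergence_metrics, morphospace_project, regress_ols


class TestRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = regress_ols(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        # hand oracle: beta = (X'X)^-1 X'y with intercept column
        xm = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        res = regress_ols(x, y)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(1.99, abs=1e-10)  # = Sxy/Sxx by hand
        resid = y - xm @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert res.r_squared == pytest.approx(1 - (resid**2).sum() / ss_tot, abs=1e-10)

    def test_independent_noise_r2_small(self):
        g = np.random.default_rng(2024)
        res = regress_ols(g.standard_normal(10_000), g.standard_normal(10_000))
        assert res.r_squared < 0.01

    def test_affine_invariance_of_fit_quality(self):
        g = np.random.default_rng(5)
        x = g.uniform(1, 10, 30)
        y = 0.7 * x + g.standard_normal(30)
        r1 = regress_ols(x, y)
        r2 = regress_ols(3.2 * x - 7.0, y)
        assert r2.r_squared == pytest.approx(r1.r_squared, rel=1e-12)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)

    def test_statsmodels_crosscheck(self):
        import statsmodels.api as sm

        g = np.random.default_rng(9)
        x = g.uniform(0, 5, 40)
        y = 1.3 * x + g.standard_normal(40)
        res = regress_ols(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert res.r_squared == pytest.approx(fit.rsquared, rel=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_log_flags_and_errors(self):
        x = np.array([1.0, 10.0, 100.0])
        res = regress_ols(x, np.array([1.0, 2.0, 3.0]), log_x=True)
        assert res.slope == pytest.approx(1.0)
        with pytest.raises(ValueError, match="positive"):
            regress_ols(np.array([-1.0, 1, 2]), x, log_x=True)
        with pytest.raises(ValueError, match="variance"):
            regress_ols(np.ones(5), np.arange(5.0))

    def test_n2_perfect_fit_undefined_p(self):
        res = regress_ols([0.0, 1.0], [3.0, 5.0])
        assert res.r_squared == pytest.approx(1.0)
        assert np.isnan(res.p_value)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        res = regress_ols(x, y)
        assert res.n == 3


def toy_reference(n=6, seed=0):
    g = np.random.default_rng(seed)
    ld = g.uniform(2, 6, n)
    dw = g.uniform(0.8, 2.5, n)
    return pd.DataFrame(
        {
            "species": [f"ref{i}" for i in range(n)],
            "L/W": ld * dw,
            "L/D": ld,
            "D/W": dw,
        }
    )


class TestMorphospace:
    def test_reference_row_projects_to_own_score(self):
        ref = toy_reference()
        model = morphospace_project(ref.iloc[[2]], ref)
        np.testing.assert_allclose(
            model.record_scores[["mp1", "mp2"]].to_numpy()[0],
            model.reference_scores[["mp1", "mp2"]].to_numpy()[2],
            atol=1e-10,
        )

    def test_matches_center_scale_rotate_oracle(self):
        ref = toy_reference(5, seed=3)
        recs = toy_reference(4, seed=9)
        model = morphospace_project(recs, ref)
        # by-hand oracle: log10 -> center on reference mean -> eigvecs of cov
        xr = np.log10(ref[["L/W", "L/D", "D/W"]].to_numpy())
        mean = xr.mean(axis=0)
        cov = np.cov(xr - mean, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:2]
        axes = evecs[:, order].T
        for k in range(2):
            j = np.argmax(np.abs(axes[k]))
            if axes[k, j] < 0:
                axes[k] = -axes[k]
        xq = np.log10(recs[["L/W", "L/D", "D/W"]].to_numpy())
        oracle = (xq - mean) @ axes.T
        np.testing.assert_allclose(
            model.record_scores[["mp1", "mp2"]].to_numpy(), oracle, atol=1e-10
        )

    def test_nonpositive_ratio_rejected(self):
        ref = toy_reference()
        bad = ref.copy()
        bad.loc[0, "D/W"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            morphospace_project(bad, ref)

    def test_missing_ratio_column_rejected(self):
        ref = toy_reference()
        with pytest.raises(ValueError, match="missing"):
            morphospace_project(ref.drop(columns=["L/D"]), ref.drop(columns=["L/D"]))

    def test_log_dependence_kills_third_axis(self):
        model = morphospace_project(toy_reference(8), toy_reference(8), n_components=3)
        assert model.explained_variance_ratio[2] < 1e-12


class TestDivergence:
    def records(self):
        return pd.DataFrame(
            {
                "specimen_id": ["base", "p", "q"],
                "mp1": [0.0, 1.0, -1.0],
                "mp2": [0.0, 1.0, -1.0],
                "area": [2.0, 3.0, 4.0],
                "side_digpierce": [-1.0, -2.0, 0.5],
            }
        )

    def test_baseline_distance_zero(self):
        out = divergence_metrics(self.records(), "base")
        assert out.loc[out.specimen_id == "base", "morphological_divergence"].iloc[0] == 0.0

    def test_symmetric_records_equal_divergence(self):
        out = divergence_metrics(self.records(), "base")
        d = out.set_index("specimen_id")["morphological_divergence"]
        assert d["p"] == pytest.approx(d["q"])
        assert d["p"] == pytest.approx(np.sqrt(2))

    def test_functional_columns_passthrough(self):
        out = divergence_metrics(self.records(), "base")
        np.testing.assert_allclose(out["functional_divergence_area"], [2, 3, 4])
        np.testing.assert_allclose(out["functional_divergence_side"], [-1, -2, 0.5])

    def test_unknown_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            divergence_metrics(self.records(), "nope")


def test_stress_shape_coupling_recovered_end_to_end():
    """Cohorts built with stress scale rising along the D/W gradient show a
    significant positive regression of mean stress on D/W (n = 12)."""
    from clawfsa.pipeline import analyze_fields

    grad = c.GradientSpec(base_stress_range_mpa=(5.0, 15.0))
    cohort = c.make_benchmark_cohort(12, grad, seed=4)
    fields = [cohort.fields[k] for k in sorted(cohort.fields)]
    result = analyze_fields(fields)
    rows = []
    for sid in cohort.specimen_ids:
        meas = c.measure_claw(cohort.meshes[sid])
        stress = result.report.set_index("specimen_id").loc[sid, "mean_vertex_stress_mpa"]
        rows.append({"dw": meas.ratio_DW, "stress": stress})
    frame = pd.DataFrame(rows)
    res = regress_ols(frame["dw"], frame["stress"])
    assert res.slope > 0
    assert res.p_value < 0.05
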