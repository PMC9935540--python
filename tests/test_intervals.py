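"""Intervals method: trimming, binning, ordination."""

import numpy as np
import pytest

import clawfsa as c
from clawfsa.intervals import (
    IntervalConfig,
    batch_interval_vectors,
    compute_interval_vector,
    mean_stress_summary,
    ordinate,
    trim_upper_tail,
    vectors_to_frame,
    frame_to_vectors,
)
from conftest import random_field


def field_of(vm, vols, **kw):
    return c.StressField(np.asarray(vm, float), np.asarray(vols, float), **kw)


class TestTrim:
    def test_fraction_zero_is_identity(self):
        f = field_of([1, 2, 3], [1, 1, 1])
        t = trim_upper_tail(f, 0.0)
        np.testing.assert_array_equal(t.element_vm_mpa, f.element_vm_mpa)
        assert t.trimmed_volume_mm3 == 0.0

    def test_equal_volumes_removes_top_element(self):
        f = field_of(np.arange(10, dtype=float), np.ones(10))
        t = trim_upper_tail(f, 0.1)
        assert len(t) == 9
        assert t.element_vm_mpa.max() == 8.0
        assert t.trimmed_volume_mm3 == pytest.approx(1.0)

    def test_greedy_never_exceeds_budget(self):
        # 5 equal volumes, fraction 0.25: one element is 20% <= 25%,
        # a second would reach 40% > 25% -> exactly 1 removed
        f = field_of([5.0, 4, 3, 2, 1], np.ones(5))
        t = trim_upper_tail(f, 0.25)
        assert len(t) == 4
        assert 5.0 not in t.element_vm_mpa


class TestBinning:
    def test_four_equal_elements(self):
        f = field_of([1, 3, 5, 7], np.ones(4))
        v = compute_interval_vector(
            f, IntervalConfig(n_intervals=4, upper_bound_mpa=8.0)
        )
        np.testing.assert_allclose(v.percentages, [25, 25, 25, 25])
        np.testing.assert_allclose(v.edges, [0, 2, 4, 6, 8])

    def test_all_zero_stress(self):
        f = field_of(np.zeros(5), np.ones(5))
        v = compute_interval_vector(
            f, IntervalConfig(n_intervals=10, upper_bound_mpa=1.0)
        )
        assert v.percentages[0] == pytest.approx(100.0)
        assert v.percentages[1:].sum() == 0.0

    def test_value_at_upper_bound_in_last_interval(self):
        f = field_of([8.0], [1.0])
        v = compute_interval_vector(
            f, IntervalConfig(n_intervals=4, upper_bound_mpa=8.0)
        )
        assert v.percentages[-1] == pytest.approx(100.0)

    def test_above_bound_warns_and_clips(self):
        f = field_of([1.0, 9.0], [1.0, 1.0])
        with pytest.warns(UserWarning, match="exceed"):
            v = compute_interval_vector(
                f, IntervalConfig(n_intervals=4, upper_bound_mpa=8.0)
            )
        assert v.percentages[-1] == pytest.approx(50.0)

    def test_matches_bruteforce_histogram_oracle(self):
        f = random_field(42, n=1000)
        cfg = IntervalConfig(n_intervals=50, upper_bound_mpa=float(f.element_vm_mpa.max()))
        v = compute_interval_vector(f, cfg)
        # element-by-element accumulation oracle
        edges = v.edges
        acc = np.zeros(50)
        for vm, vol in zip(f.element_vm_mpa, f.element_volume_mm3):
            i = min(int((vm - edges[0]) / (edges[1] - edges[0])), 49)
            acc[i] += vol
        oracle = 100.0 * acc / f.element_volume_mm3.sum()
        np.testing.assert_allclose(v.percentages, oracle, rtol=1e-12, atol=1e-12)

    def test_conservation_with_trim(self):
        f = random_field(7, n=400)
        for frac in (0.0, 0.02, 0.05):
            t = trim_upper_tail(f, frac)
            v = compute_interval_vector(t, IntervalConfig())
            assert v.percentages.sum() + v.trimmed_volume_pct == pytest.approx(
                100.0, abs=1e-9
            )

    def test_refinement_nests(self):
        f = random_field(3, n=300)
        coarse = compute_interval_vector(
            f, IntervalConfig(n_intervals=25, upper_bound_mpa=30.0)
        )
        fine = compute_interval_vector(
            f, IntervalConfig(n_intervals=50, upper_bound_mpa=30.0)
        )
        np.testing.assert_allclose(
            fine.percentages.reshape(25, 2).sum(axis=1),
            coarse.percentages,
            rtol=1e-12,
            atol=1e-12,
        )


class TestMeanStress:
    def test_equal_volumes(self):
        assert mean_stress_summary(field_of([2, 4], [1, 1])) == pytest.approx(3.0)

    def test_weighted(self):
        assert mean_stress_summary(field_of([4, 0], [1, 3])) == pytest.approx(1.0)

    def test_matches_direct_sum(self):
        f = random_field(11)
        direct = (f.element_vm_mpa * f.element_volume_mm3).sum() / f.element_volume_mm3.sum()
        assert mean_stress_summary(f) == pytest.approx(direct, rel=1e-12)


class TestOrdinate:
    def make_batch(self, n=10, seed=0):
        fields = [
            random_field(
                [seed, i], n=600, mean=5.0 + i, specimen_id=f"s{i}", scenario="piercing"
            )
            for i in range(n)
        ]
        return batch_interval_vectors(fields, IntervalConfig())

    def test_identical_vectors_identical_scores(self):
        vecs = self.make_batch(4)
        twin = vecs + [vecs[0]]
        model = ordinate(twin)
        s = model.score_matrix()
        np.testing.assert_allclose(s[0], s[-1], atol=1e-9)

    def test_needs_three_vectors(self):
        vecs = self.make_batch(4)
        with pytest.raises(ValueError, match="at least 3"):
            ordinate(vecs[:2])

    def test_mismatched_edges_rejected(self):
        vecs = self.make_batch(4)
        other = vecs[0]
        other = type(other)(
            other.percentages, other.edges * 2.0, mean_stress_mpa=1.0
        )
        with pytest.raises(ValueError, match="shared"):
            ordinate(vecs[:3] + [other])

    def test_constant_column_dropped_without_failure(self):
        vecs = self.make_batch(6)
        # top intervals are empty in all batches by construction sometimes;
        # force one constant column to be sure
        for v in vecs:
            v.percentages[-1] = 0.0
        model = ordinate(vecs)
        assert len(model.kept_columns) < len(vecs[0].percentages)
        assert np.isfinite(model.score_matrix()).all()

    def test_scores_match_svd_oracle(self):
        vecs = self.make_batch(10)
        model = ordinate(vecs)
        # independent oracle: log -> standardize -> SVD scores
        p = np.vstack([v.percentages for v in vecs])
        x = np.log(p + 0.01)
        x = x[:, np.ptp(x, axis=0) > 0]
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = u * s
        k = model.n_components
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(model.score_matrix()), pdist(oracle[:, :k]), rtol=1e-8, atol=1e-8
        )

    def test_scores_centered_and_variance_sorted(self):
        vecs = self.make_batch(8)
        model = ordinate(vecs)
        s = model.score_matrix()
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-9)
        ev = model.explained_variance_ratio
        assert np.all(np.diff(ev) <= 1e-12)

    def test_pc1_oriented_with_mean_stress(self):
        model = ordinate(self.make_batch(10))
        r = np.corrcoef(
            model.score_matrix()[:, 0], model.scores["mean_stress_mpa"]
        )[0, 1]
        assert r >= 0

    def test_frame_roundtrip(self):
        vecs = self.make_batch(5)
        frame = vectors_to_frame(vecs)
        back = frame_to_vectors(frame)
        for a, b in zip(vecs, back):
            np.testing.assert_allclose(a.percentages, b.percentages, rtol=1e-12)
            assert a.specimen_id == b.specimen_id
            assert a.mean_stress_mpa == pytest.approx(b.mean_stress_mpa)


def test_config_validation():
    with pytest.raises(ValueError):
        IntervalConfig(n_intervals=1)
    with pytest.raises(ValueError):
        IntervalConfig(trim_fraction=0.06)
    with pytest.raises(ValueError):
        IntervalConfig(upper_bound_mpa=0.0, lower_bound_mpa=0.0)
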