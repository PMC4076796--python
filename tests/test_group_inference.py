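"""Random-effects group statistics, overlap erosion, and map similarity."""

import numpy as np
import pytest
from scipy import stats

from fmripitfalls import (
    Blob,
    CohortSpec,
    heterogeneity_grid,
    make_cohort,
    map_similarity,
    one_sample_t,
    overlap_map,
    subject_count_map,
)
from fmripitfalls.group_inference import significance_category


def sphere_mask(shape, center, radius):
    idx = np.indices(shape).astype(float)
    return sum((idx[a] - center[a]) ** 2 for a in range(3)) <= radius**2


class TestOneSampleT:
    def test_symmetric_pair(self):
        t, p = one_sample_t([-1.0, 1.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_oracle(self):
        # values 1..5: mean 3, sd sqrt(2.5), t = 3 / (sqrt(2.5)/sqrt(5))
        t, p = one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0])
        expected_t = 3.0 / (np.sqrt(2.5) / np.sqrt(5.0))
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert p == pytest.approx(stats.t.sf(expected_t, 4), abs=1e-12)

    def test_null_calibration(self, rng):
        n, reps = 20, 10000
        draws = rng.standard_normal((reps, n))
        # vectorized t, spot-checked against one_sample_t below
        t = draws.mean(1) / (draws.std(1, ddof=1) / np.sqrt(n))
        p = stats.t.sf(t, n - 1)
        for i in rng.integers(0, reps, size=25):
            ti, pi = one_sample_t(draws[i])
            assert ti == pytest.approx(t[i], abs=1e-10)
            assert pi == pytest.approx(p[i], abs=1e-10)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.005)

    def test_two_sided_flag(self):
        t1, p1 = one_sample_t([1.0, 2.0, 4.0], two_sided=True)
        t2, p2 = one_sample_t([1.0, 2.0, 4.0])
        assert t1 == t2
        assert p1 == pytest.approx(2 * p2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def grid():
    return heterogeneity_grid(n_subjects=20, n_reps=2000, seed=42)


class TestHeterogeneityGrid:
    def test_full_surface_shape(self, grid):
        assert len(grid.table) == 21 * 6

    def test_null_row_calibrated_and_ns(self, grid):
        null = grid.table.query("responders == 0")
        assert (null["category"] == "n.s.").all()
        assert null["reject_rate_05"].mean() == pytest.approx(0.05, abs=0.01)

    def test_full_responder_strong_effect_is_high(self, grid):
        cell = grid.table.query("responders == 20 and delta == 3.0").iloc[0]
        assert cell["category"] == "high"

    def test_significance_monotone_in_composition_and_effect(self, grid):
        # median p decreases (weakly) along both axes of the surface
        for delta, sub in grid.table.groupby("delta"):
            med = sub.sort_values("responders")["median_p"].to_numpy()
            assert np.all(np.diff(med) <= 1e-3)  # small MC slack
        for r, sub in grid.table.query("responders >= 5").groupby("responders"):
            med = sub.sort_values("delta")["median_p"].to_numpy()
            assert np.all(np.diff(med) <= 1e-3)

    def test_half_responders_match_noncentral_t_oracle(self):
        # r = 10 of 20 at delta = 3: approximate the fixed-composition sample
        # as i.i.d. draws from the normal mixture moments (mean delta/2,
        # variance 1 + delta^2/4), giving t ~ noncentral t(19, ncp)
        n, r, delta, reps = 20, 10, 3.0, 6000
        grid = heterogeneity_grid(n_subjects=n, effect_offsets=(delta,), n_reps=reps, seed=9)
        cell = grid.table.query(f"responders == {r}").iloc[0]
        ncp = (delta * r / n) * np.sqrt(n) / np.sqrt(1 + (r / n) * (1 - r / n) * delta**2)
        oracle = stats.nct.sf(stats.t.isf(0.001, n - 1), n - 1, ncp)
        mc_se = np.sqrt(oracle * (1 - oracle) / reps)
        assert cell["reject_rate_001"] == pytest.approx(oracle, abs=3 * mc_se + 0.02)
        # ...so a 50% responder group typically reaches high significance
        assert cell["category"] == "high"

    def test_category_bins(self):
        assert significance_category(0.5) == "n.s."
        assert significance_category(0.03) == "mild"
        assert significance_category(0.005) == "moderate"
        assert significance_category(0.0005) == "high"


class TestOverlapMap:
    def test_identical_masks(self):
        m = sphere_mask((16, 16, 16), (8, 8, 8), 4)
        overlap, retention = overlap_map([m, m, m])
        assert np.array_equal(overlap, m)
        assert retention == [1.0, 1.0, 1.0]

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[:2], b[6:] = True, True
        overlap, retention = overlap_map([a, b])
        assert not overlap.any()
        assert retention == [0.0, 0.0]

    def test_jittered_spheres_match_enumeration_oracle(self):
        shape = (24, 24, 24)
        centers = [(12, 12, 12), (13, 11, 12), (11, 13, 13)]
        masks = [sphere_mask(shape, c, 5) for c in centers]
        overlap, retention = overlap_map(masks)
        # oracle: brute-force voxel enumeration of the triple intersection
        expected = 0
        for v in np.ndindex(shape):
            if all(sum((v[a] - c[a]) ** 2 for a in range(3)) <= 25 for c in centers):
                expected += 1
        assert int(overlap.sum()) == expected
        assert retention[0] == pytest.approx(expected / masks[0].sum())

    def test_overlap_shrinks_as_subjects_accumulate(self, rng):
        shape = (20, 20, 20)
        masks = [
            sphere_mask(shape, (10 + dx, 10 + dy, 10 + dz), 5)
            for dx, dy, dz in rng.integers(-3, 4, size=(8, 3))
        ]
        sizes = [overlap_map(masks[: k])[0].sum() for k in range(2, 9)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_single_mask_rejected(self):
        with pytest.raises(ValueError):
            overlap_map([np.ones((4, 4, 4), dtype=bool)])


class TestSubjectCountMap:
    def test_all_zero_maps(self):
        counts = subject_count_map([np.zeros((6, 6, 6))] * 4, threshold=0.5)
        assert not counts.any()

    def test_identical_supra_threshold_maps(self):
        m = np.where(sphere_mask((12, 12, 12), (6, 6, 6), 3), 2.0, 0.0)
        counts = subject_count_map([m] * 5, threshold=1.0)
        assert counts.max() == 5
        assert np.array_equal(counts == 5, m > 1.0)

    def test_cohort_count_equals_responder_count(self):
        spec = CohortSpec(
            n_subjects=10, responder_fraction=0.5, effect_offset=50.0,
            spatial_jitter=0.0, noise_sd=1.0, seed=3,
        )
        blobs = (Blob(center=(10, 10, 10), radius=3.0),)
        cohort = make_cohort(spec, blobs, shape=(20, 20, 20))
        counts = subject_count_map(cohort, threshold=25.0)
        assert counts[10, 10, 10] == spec.n_responders == 5

    def test_counts_bridge_overlap_and_union(self):
        # counts == n exactly on the conjunction of the thresholded masks
        rng = np.random.default_rng(8)
        maps = [rng.standard_normal((10, 10, 10)) for _ in range(4)]
        thresh = 0.2
        counts = subject_count_map(maps, thresh)
        overlap, _ = overlap_map([m > thresh for m in maps])
        assert np.array_equal(counts == 4, overlap)


class TestMapSimilarity:
    def test_self_and_negation(self, rng):
        m = rng.standard_normal((8, 8, 8))
        assert map_similarity(m, m) == pytest.approx(1.0, abs=1e-12)
        assert map_similarity(m, -m) == pytest.approx(-1.0, abs=1e-12)

    def test_within_subject_similarity_exceeds_between(self):
        # generator: map = shared + subject-specific + session noise, with
        # variance shares 0.3 / 0.4 / 0.3; the analytic correlations are
        # within = (s_shared + s_subj) / total, between = s_shared / total
        rng = np.random.default_rng(17)
        shape = (30, 30, 30)
        v_shared, v_subj, v_sess = 0.3, 0.4, 0.3
        shared = np.sqrt(v_shared) * rng.standard_normal(shape)
        within, between = [], []
        n_subjects = 6
        subj_maps = []
        for _ in range(n_subjects):
            idio = np.sqrt(v_subj) * rng.standard_normal(shape)
            sessions = [shared + idio + np.sqrt(v_sess) * rng.standard_normal(shape) for _ in range(2)]
            subj_maps.append(sessions)
            within.append(map_similarity(sessions[0], sessions[1]))
        for i in range(n_subjects):
            for j in range(i + 1, n_subjects):
                between.append(map_similarity(subj_maps[i][0], subj_maps[j][1]))
        exp_within = v_shared + v_subj
        exp_between = v_shared
        assert np.mean(within) == pytest.approx(exp_within, abs=0.03)
        assert np.mean(between) == pytest.approx(exp_between, abs=0.03)
        assert np.mean(within) > np.mean(between)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            map_similarity(np.ones((4, 4, 4)), rng.standard_normal((4, 4, 4)))
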