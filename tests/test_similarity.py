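"""ISC, RDM, Kendall-tau and FDR contracts, with independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadscan import similarity as sim
from dyadscan import synthgen as gen


def brute_kendall_tau_b(a, b):
    """O(n^2) concordant/discordant enumeration with tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx, sy = np.sign(a[i] - a[j]), np.sign(b[i] - b[j])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (c - d) / denom


def brute_bh(p, alpha):
    """Hand step-up: q_i = min over j>=rank(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPearson:
    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert sim.pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_perfect_and_inverted(self):
        x = np.array([0.1, 0.5, 0.2, 0.9])
        assert sim.pearson(x, x) == pytest.approx(1.0)
        assert sim.pearson(x, -x + 3.0) == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_zero(self):
        assert np.isnan(sim.pearson(np.ones(10), np.arange(10.0)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.pearson(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestCorrDistance:
    @pytest.mark.parametrize("r,expected", [(-1.0, 0.0), (0.0, 1.0), (1.0, 2.0)])
    def test_endpoints_and_midpoint(self, r, expected):
        assert sim.corr_distance(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sim.corr_distance(1.5)

    @given(st.floats(-1.0, 1.0))
    def test_maps_into_unit_band(self, r):
        assert 0.0 <= sim.corr_distance(r) <= 2.0


class TestRDM:
    def test_identical_series_give_max_similarity(self, small_timeline):
        cohort = gen.generate_cohort(
            gen.GeneratorConfig(n_single=3, n_dyads=0, seed=1), small_timeline
        )
        # make two subjects' signals identical
        cohort.get("ss02", "gaze").values = cohort.get("ss01", "gaze").values.copy()
        rdm = sim.build_rdm(cohort, "gaze", (0.0, 20.0))
        i, j = rdm.labels.index("ss01"), rdm.labels.index("ss02")
        assert rdm.matrix[i, j] == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_diagonal_and_bounds(self, small_cohort):
        rdm = sim.build_rdm(small_cohort, "smile", (0.0, 20.0))
        m = rdm.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(m), 2.0)
        ok = ~np.isnan(m)
        assert (m[ok] >= 0.0).all() and (m[ok] <= 2.0).all()

    def test_label_ordering_ss_then_pairs_adjacent(self, small_cohort):
        rdm = sim.build_rdm(small_cohort, "gaze", (0.0, 10.0))
        assert rdm.labels == ["ss01", "ss02", "ss03", "ss04",
                              "sp01-1", "sp01-2", "sp02-1", "sp02-2"]

    def test_zero_variance_window_yields_missing_cells(self, small_cohort):
        cohort = gen.generate_cohort(
            gen.GeneratorConfig(n_single=3, n_dyads=0, seed=2),
            small_cohort.timeline,
        )
        cohort.get("ss01", "smile").values[:600] = 0.25  # flat window
        rdm = sim.build_rdm(cohort, "smile", (0.0, 20.0))
        i = rdm.labels.index("ss01")
        off = [j for j in range(3) if j != i]
        assert np.isnan(rdm.matrix[i, off]).all()
        assert rdm.matrix[i, i] == 2.0


@pytest.fixture()
def roster():
    return gen.subject_roster(gen.GeneratorConfig(seed=0))


class TestModelRDM:
    def test_strong_marks_only_true_pairs(self, roster):
        m = sim.model_rdm(roster, "strong").matrix
        iu = np.triu_indices(36, 1)
        assert (m[iu] == 2.0).sum() == 9
        assert set(np.unique(m)) == {1.0, 2.0}

    def test_weak_marks_all_sp_pairs(self, roster):
        m = sim.model_rdm(roster, "weak").matrix
        iu = np.triu_indices(36, 1)
        assert (m[iu] == 2.0).sum() == 18 * 17 // 2 == 153

    def test_no_paired_subjects_gives_flat_models(self):
        roster = gen.subject_roster(gen.GeneratorConfig(n_single=4, n_dyads=0, seed=0))
        for kind in ("strong", "weak"):
            m = sim.model_rdm(roster, kind).matrix
            iu = np.triu_indices(4, 1)
            assert (m[iu] == 1.0).all()

    def test_sp_without_dyad_rejected_for_strong(self, roster):
        broken = roster.copy()
        broken.loc[broken.subject_id == "sp01-1", "dyad_id"] = None
        with pytest.raises(ValueError, match="dyad_id"):
            sim.model_rdm(broken, "strong")


class TestVectorize:
    def test_length_for_36_subjects(self):
        labels = [f"s{i}" for i in range(36)]
        m = np.random.default_rng(0).normal(size=(36, 36))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 2.0)
        v = sim.vectorize_rdm(sim.RDM(labels=labels, matrix=m))
        assert v.size == 36 * 35 // 2 == 630

    def test_two_subjects_single_cell(self):
        m = np.array([[2.0, 0.7], [0.7, 2.0]])
        v = sim.vectorize_rdm(sim.RDM(labels=["a", "b"], matrix=m))
        assert v.tolist() == [0.7]

    def test_round_trip_preserves_traversal_order(self):
        labels = ["a", "b", "c", "d"]
        v = np.arange(6, dtype=float)
        rdm = sim.unvectorize_rdm(v, labels)
        np.testing.assert_array_equal(sim.vectorize_rdm(rdm), v)

    def test_asymmetric_rejected(self):
        m = np.array([[2.0, 0.1, 0.2], [0.4, 2.0, 0.3], [0.2, 0.3, 2.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            sim.vectorize_rdm(sim.RDM(labels=["a", "b", "c"], matrix=m))


class TestKendall:
    def test_perfect_and_reversed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert sim.kendall_tau(a, a)[0] == pytest.approx(1.0)
        assert sim.kendall_tau(a, a[::-1])[0] == pytest.approx(-1.0)

    def test_brute_force_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        tau, _ = sim.kendall_tau(a, b)
        assert tau == pytest.approx(brute_kendall_tau_b(a, b), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 3, size=12).astype(float)
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return
        tau, _ = sim.kendall_tau(a, b)
        assert tau == pytest.approx(brute_kendall_tau_b(a, b), abs=1e-12)

    def test_nan_cells_dropped_pairwise(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 5.0, 6.0])
        b = np.array([2.0, 9.0, np.nan, 5.0, 6.0, 7.0])
        tau, _ = sim.kendall_tau(a, b)
        keep = [0, 3, 4, 5]
        assert tau == pytest.approx(brute_kendall_tau_b(a[keep], b[keep]))

    def test_too_few_complete_pairs_flagged(self):
        a = np.array([1.0, np.nan, np.nan, 4.0])
        tau, p = sim.kendall_tau(a, a)
        assert np.isnan(tau) and np.isnan(p)


class TestCompareAllRDMs:
    def _random_rdms(self, k, n=8, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(n)]
        out = []
        for i in range(k):
            m = rng.normal(size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 2.0)
            out.append((f"rdm{i}", sim.RDM(labels=labels, matrix=m)))
        return out

    def test_twelve_inputs_give_66_comparisons(self):
        rdms = self._random_rdms(12)
        tau, p, masked = sim.compare_all_rdms(rdms)
        assert tau.shape == (12, 12)
        iu = np.triu_indices(12, 1)
        assert iu[0].size == 66
        assert np.isfinite(tau.to_numpy()[iu]).all()
        np.testing.assert_array_equal(np.diag(tau), 1.0)

    def test_three_inputs_three_comparisons(self):
        tau, p, _ = sim.compare_all_rdms(self._random_rdms(3))
        assert np.triu_indices(3, 1)[0].size == 3
        np.testing.assert_allclose(tau.to_numpy(), tau.to_numpy().T)

    def test_label_mismatch_rejected(self):
        rdms = self._random_rdms(2)
        other = sim.RDM(labels=["x"] * 8, matrix=rdms[0][1].matrix)
        with pytest.raises(ValueError, match="label"):
            sim.compare_all_rdms([rdms[0], ("bad", other)])

    def test_masking_hides_nonsignificant_cells(self):
        rdms = self._random_rdms(4)
        tau, p, masked = sim.compare_all_rdms(rdms, alpha=0.05)
        off = ~np.eye(4, dtype=bool)
        hidden = np.isnan(masked.to_numpy()) & off
        assert (p.to_numpy()[hidden] >= 0.05).all()


class TestBHFDR:
    def test_three_step_hand_example(self):
        q, reject = sim.bh_fdr(np.array([0.01, 0.02, 0.03]), alpha=0.05)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert reject.all()

    def test_all_ones_no_rejections(self):
        q, reject = sim.bh_fdr(np.ones(5), alpha=0.05)
        assert not reject.any()
        np.testing.assert_allclose(q, 1.0)

    def test_single_pvalue_identity(self):
        q, reject = sim.bh_fdr(np.array([0.04]), alpha=0.05)
        assert q[0] == pytest.approx(0.04) and reject[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sim.bh_fdr(np.array([0.5, 1.2]))

    @given(st.integers(0, 10_000))
    def test_ten_element_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=10)
        q, reject = sim.bh_fdr(p, alpha=0.05)
        np.testing.assert_allclose(q, brute_bh(p, 0.05), atol=1e-12)
        assert (q >= p - 1e-12).all()
        np.testing.assert_array_equal(reject, q < 0.05)


class TestScan:
    def test_permutation_statistic_matches_scipy_tau(self, small_cohort):
        from scipy import stats

        rdm = sim.build_rdm(small_cohort, "gaze", (0.0, 20.0))
        vec = sim.vectorize_rdm(rdm)
        for kind in ("weak", "strong"):
            tester = sim._BinaryModelTau(small_cohort.labels, kind, 50, 0)
            mvec = sim.vectorize_rdm(sim.model_rdm(small_cohort.labels, kind))
            expected = stats.kendalltau(vec, mvec, variant="b").statistic
            tau, p = tester.tau_and_p(vec)
            assert tau == pytest.approx(expected, abs=1e-12)
            assert 0.0 < p <= 1.0

    def test_window_count_arithmetic(self, small_cohort):
        res = sim.rsa_scan(small_cohort, "gaze", window_len=20.0, step=1.0,
                           n_permutations=20)
        assert res.window_starts.size == int((120 - 20) / 1) + 1 == 101
        assert res.window_starts[0] == 0.0 and res.window_starts[-1] == 100.0

    def test_window_longer_than_drama_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="longer than the drama"):
            sim.rsa_scan(small_cohort, "gaze", window_len=500.0)

    def test_q_dominates_p_and_intervals_significant(self, small_cohort):
        res = sim.rsa_scan(small_cohort, "smile", step=5.0, n_permutations=50)
        ok = ~np.isnan(res.p)
        assert (res.q[ok] >= res.p[ok] - 1e-12).all()
        for start, end, _, min_q in res.intervals:
            assert min_q < res.alpha
            assert end - start >= res.min_run * res.step

    def test_localizer_rdms_one_per_clip(self, small_cohort):
        rdms = sim.localizer_rdms(small_cohort, "smile")
        assert len(rdms) == 3
        names = [n for n, _ in rdms]
        assert names[0] == "childs-laughter"
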