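"""Accuracy metrics, paired comparisons, binning and correlations."""

import numpy as np
import pytest
from scipy import stats

import vfforecast as vf
from vfforecast import evaluation


def _record(eye_id, rmse_rnn_target, rmse_olr_target, **cov):
    """Record whose per-eye RMSEs equal the requested values exactly
    (a uniform error of r dB at every point has RMSE r)."""
    true = np.zeros(52)
    return vf.EvalRecord(
        eye_id=eye_id, true_tdv=true,
        rnn_pred=true + rmse_rnn_target,
        olr_pred=true + rmse_olr_target, **cov)


class TestRmse:
    def test_identical_vectors(self):
        assert vf.rmse_eye(np.zeros(52), np.zeros(52)) == 0.0

    def test_uniform_two_db_error(self):
        assert vf.rmse_eye(np.zeros(52), np.full(52, 2.0)) == \
            pytest.approx(2.0)

    def test_matches_explicit_loop(self, rng):
        a, b = rng.normal(size=52), rng.normal(size=52)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2 / 52
        assert vf.rmse_eye(a, b) == pytest.approx(np.sqrt(acc), abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            vf.rmse_eye(np.zeros(54), np.zeros(54))

    def test_qm_am_inequality(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=52), rng.normal(size=52)
            assert vf.rmse_eye(a, b) >= np.mean(np.abs(a - b)) - 1e-12


class TestMae:
    def test_perfect_predictions(self, rng):
        t = rng.normal(size=(5, 52))
        np.testing.assert_array_equal(vf.mae_points(t, t), np.zeros(52))

    def test_single_point_error(self):
        t = np.zeros((1, 52))
        p = t.copy()
        p[0, 7] = 3.0
        mae = vf.mae_points(t, p)
        assert mae[7] == 3.0 and np.all(np.delete(mae, 7) == 0.0)

    def test_hundred_eyes_match_double_loop(self, rng):
        t = rng.normal(-8, 6, (100, 52))
        p = t + rng.normal(0, 2, (100, 52))
        mae = vf.mae_points(t, p)
        for n in range(52):
            acc = sum(abs(t[i, n] - p[i, n]) for i in range(100)) / 100
            assert mae[n] == pytest.approx(acc, abs=1e-12)

    def test_chunked_cohorts_combine_by_eye_weighted_mean(self, rng):
        t = rng.normal(size=(30, 52))
        p = t + rng.normal(size=(30, 52))
        whole = vf.mae_points(t, p)
        chunks = [(t[:10], p[:10]), (t[10:], p[10:])]
        weighted = sum(len(tc) * vf.mae_points(tc, pc)
                       for tc, pc in chunks) / 30
        np.testing.assert_allclose(whole, weighted, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vf.mae_points(np.empty((0, 52)), np.empty((0, 52)))


class TestCompareMethods:
    def test_identical_methods_not_significant(self, rng):
        recs = [_record(f"e{i}", r, r)
                for i, r in enumerate(rng.uniform(1, 5, 10))]
        out = vf.compare_methods(recs)
        assert out["delta_olr_minus_rnn"] == 0.0
        assert out["p_value"] == 1.0 and not out["significant"]

    def test_constant_offset_matches_textbook_t(self, rng):
        rnn = rng.uniform(2, 5, 25)
        jitter = rng.normal(0, 0.05, 25)
        recs = [_record(f"e{i}", r, r + 1.0 + j)
                for i, (r, j) in enumerate(zip(rnn, jitter))]
        out = vf.compare_methods(recs)
        assert out["delta_olr_minus_rnn"] == pytest.approx(
            1.0 + jitter.mean(), abs=1e-9)
        assert out["significant"]
        if out["test"] == "paired t-test":
            d = -(1.0 + jitter)
            tstat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p = 2 * stats.t.sf(abs(tstat), len(d) - 1)
            assert out["p_value"] == pytest.approx(p, rel=1e-9)

    def test_summary_mean_is_arithmetic_mean(self, rng):
        vals = rng.uniform(1, 6, 12)
        recs = [_record(f"e{i}", v, v + 0.3 + 0.01 * i)
                for i, v in enumerate(vals)]
        out = vf.compare_methods(recs)
        assert out["rmse_rnn_mean"] == pytest.approx(vals.mean())

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            vf.compare_methods([_record("a", 1, 2)])


class TestBinning:
    def test_single_populated_bin(self):
        recs = [_record(f"e{i}", 2.0, 3.0, fpr=1.0, fnr=1, flr=1, md=-5)
                for i in range(6)]
        table = vf.bin_rmse(recs, "fpr")
        assert table["n"].tolist() == [6, 0, 0, 0, 0]
        assert table["bin"].tolist()[0] == "<= 2.5"

    def test_bins_partition_cohort(self, rng):
        recs = [_record(f"e{i}", 2, 3, fpr=float(rng.uniform(0, 20)),
                        fnr=1, flr=1, md=-5) for i in range(40)]
        table = vf.bin_rmse(recs, "fpr")
        assert table["n"].sum() == 40

    def test_reliability_bin_boundaries_are_left_open(self):
        recs = [_record(f"e{i}", 1, 1, fnr=v, fpr=1, flr=1, md=-5)
                for i, v in enumerate([2.5, 2.6, 5.0, 10.0, 10.1, 25.0])]
        table = vf.bin_rmse(recs, "fnr")
        # 2.5 -> first bin (<=2.5]; 2.6 and 5.0 -> (2.5,5]; 10 -> (7.5,10]
        assert table["n"].tolist() == [1, 2, 0, 1, 2]

    def test_md_bins_follow_published_edges(self):
        recs = [_record(f"e{i}", 1, 1, md=v, fpr=1, fnr=1, flr=1)
                for i, v in enumerate([-15, -12, -9.0, -8.9, -3.0, 0.0])]
        table = vf.bin_rmse(recs, "md")
        # <-12 : one (-15); [-12,-9): -12; [-9,-6): -9, -8.9; >=-3: two
        assert table["n"].tolist() == [1, 1, 2, 0, 2]

    def test_per_bin_stats_match_group_by_oracle(self, rng):
        recs = [_record(f"e{i}", float(rng.uniform(1, 6)),
                        float(rng.uniform(1, 6)),
                        fnr=float(rng.uniform(0, 15)), fpr=1, flr=1, md=-5)
                for i in range(60)]
        table = vf.bin_rmse(recs, "fnr")
        edges = [2.5, 5.0, 7.5, 10.0]
        for _, row in table.iterrows():
            if row["n"] == 0:
                continue
            members = [r for r in recs
                       if _bin_of(r.fnr, edges) == row["bin"]]
            assert row["n"] == len(members)
            assert row["rmse_rnn_mean"] == pytest.approx(
                np.mean([r.rmse_rnn for r in members]))

    def test_error_increasing_with_fnr_is_visible_in_bins(self, rng):
        # cohort built so RMSE grows with the false-negative rate
        recs = []
        for i in range(80):
            fnr = float(rng.uniform(0, 20))
            base = 1.0 + 0.3 * fnr
            recs.append(_record(f"e{i}", base + rng.normal(0, 0.05),
                                base + 0.5, fnr=fnr, fpr=1, flr=1, md=-5))
        table = vf.bin_rmse(recs, "fnr")
        means = table.loc[table["n"] > 0, "rmse_rnn_mean"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_unpopulated_factor_rejected(self):
        recs = [_record(f"e{i}", 1, 2) for i in range(5)]
        with pytest.raises(ValueError):
            vf.bin_rmse(recs, "fnr")


def _bin_of(v, edges):
    if v <= edges[0]:
        return "<= 2.5"
    if v > edges[-1]:
        return "> 10"
    for lo, hi in zip(edges, edges[1:]):
        if lo < v <= hi:
            return f"({lo:g}, {hi:g}]"
    raise AssertionError


class TestCorrelation:
    def test_exact_linear_dependence(self):
        recs = [_record(f"e{i}", 1.0 + 0.2 * v, 2.0 + 0.1 * v,
                        fnr=float(v), fpr=1, flr=1, md=-5)
                for i, v in enumerate(range(12))]
        out = vf.correlate_error(recs, "fnr")
        assert out["rnn"]["rho"] == pytest.approx(1.0)
        assert out["rnn"]["r2"] == pytest.approx(1.0)
        assert out["rnn"]["slope"] == pytest.approx(0.2)

    def test_independent_factor_small_rho(self, rng):
        recs = [_record(f"e{i}", float(rng.uniform(1, 5)),
                        float(rng.uniform(1, 5)),
                        fnr=float(rng.uniform(0, 20)), fpr=1, flr=1, md=-5)
                for i in range(500)]
        out = vf.correlate_error(recs, "fnr")
        # permutation oracle: null spread of |rho| at n=500
        x = np.array([r.fnr for r in recs])
        y = np.array([r.rmse_rnn for r in recs])
        null = []
        perm_rng = np.random.default_rng(0)
        for _ in range(200):
            null.append(abs(stats.spearmanr(perm_rng.permutation(x),
                                            y).statistic))
        assert abs(out["rnn"]["rho"]) < np.quantile(null, 0.999)
        assert out["rnn"]["rho_p"] > 0.001

    def test_rho_invariant_under_monotone_transform(self, rng):
        recs = [_record(f"e{i}", float(rng.uniform(1, 5)),
                        float(rng.uniform(1, 5)),
                        fnr=float(rng.uniform(1, 20)), fpr=1, flr=1, md=-5)
                for i in range(30)]
        before = vf.correlate_error(recs, "fnr")["rnn"]["rho"]
        for r in recs:
            r.fnr = float(np.exp(r.fnr / 10))
        after = vf.correlate_error(recs, "fnr")["rnn"]["rho"]
        assert before == pytest.approx(after, abs=1e-12)

    def test_zero_variance_factor_rejected(self):
        recs = [_record(f"e{i}", 1, 2, fnr=5.0, fpr=1, flr=1, md=-5)
                for i in range(5)]
        with pytest.raises(ValueError):
            vf.correlate_error(recs, "fnr")


class TestCohortEvaluation:
    def test_records_align_with_direct_computation(self, small_cohort):
        m = vf.init_model(vf.ModelConfig(seed=0))
        records = vf.evaluate_cohort(m, small_cohort)
        assert len(records) == len(small_cohort)
        s = small_cohort[3]
        r = next(rec for rec in records if rec.eye_id == s.eye_id)
        target = s.exams[5]
        np.testing.assert_array_equal(r.true_tdv, target.tdv)
        np.testing.assert_allclose(
            r.olr_pred, vf.olr_predict(s.exams[:5], target.exam_date))
        assert r.rmse_olr == pytest.approx(
            vf.rmse_eye(target.tdv, r.olr_pred))
        assert r.fnr == pytest.approx(
            np.mean([e.fnr for e in s.exams[:5]]))

    def test_last_covariate_rule(self, small_cohort):
        m = vf.init_model(vf.ModelConfig(seed=0))
        records = vf.evaluate_cohort(m, small_cohort, "last")
        s = small_cohort[0]
        r = records[0]
        assert r.fpr == pytest.approx(s.exams[4].fpr)
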