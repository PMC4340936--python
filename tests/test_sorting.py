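import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fnoverlap import hrf, sorting, synthio
from tests.conftest import bh_oracle


def _design(conditions=("a", "b"), n_events=8, seed=0):
    return synthio.make_design("event", n_events, tr=1.5, n_timepoints=200,
                               seed=seed, conditions=conditions)


class TestHrfConvolve:
    def test_single_event_peaks_four_to_six_seconds_after_onset(self):
        d = synthio.DesignSpec(["a"], {"a": [(30.0, 1.0)]}, tr=0.5,
                               n_timepoints=200)
        regs = sorting.hrf_convolve(d)
        col = regs.matrix[:, 0]
        t_peak = col.argmax() * 0.5 - 30.0
        assert 4.0 <= t_peak <= 6.0

    def test_hrf_kernel_shape(self):
        t = np.arange(0, 32, 0.1)
        h = hrf.double_gamma_hrf(t)
        assert t[h.argmax()] == pytest.approx(5.0, abs=1.0)  # peak ~ 5-6 s
        assert h.min() < 0  # undershoot present
        assert abs(h.min()) < h.max() / 3  # ratio parameter keeps it small

    def test_empty_condition_raises_rank_error(self):
        d = synthio.DesignSpec(["a", "b"], {"a": [(5.0, 1.0)], "b": []},
                               tr=1.5, n_timepoints=100)
        with pytest.raises(ValueError, match="no events"):
            sorting.hrf_convolve(d)

    def test_identical_conditions_raise_collinearity_error(self):
        ev = [(5.0, 1.0), (40.0, 1.0)]
        d = synthio.DesignSpec(["a", "b"], {"a": ev, "b": list(ev)},
                               tr=1.5, n_timepoints=100)
        with pytest.raises(ValueError, match="rank deficient"):
            sorting.hrf_convolve(d)

    def test_intercept_column_present(self):
        regs = sorting.hrf_convolve(_design())
        np.testing.assert_array_equal(regs.matrix[:, -1], 1.0)


class TestSortTimecourses:
    def test_regressor_as_timecourse_is_ols_identity(self):
        """A timecourse equal to condition A's regressor: after the unit-
        variance standardization the exact OLS solution is
        beta_a = 1/sd(a), beta_b = 0."""
        d = _design()
        regs = sorting.hrf_convolve(d)
        a = regs.matrix[:, 0].copy()
        table = sorting.sort_timecourses([a[:, None]], regs)
        beta_a = table[(table.condition == "a")]["beta"].iloc[0]
        beta_b = table[(table.condition == "b")]["beta"].iloc[0]
        assert beta_b == pytest.approx(0.0, abs=1e-10)
        assert beta_a == pytest.approx(1.0 / a.std(), abs=1e-10)

    def test_negated_timecourse_negates_beta(self):
        d = _design(conditions=("a",), n_events=6)
        regs = sorting.hrf_convolve(d)
        tc = regs.matrix[:, 0:1].copy()
        t1 = sorting.sort_timecourses([tc], regs)
        t2 = sorting.sort_timecourses([-tc], regs)
        assert t2["beta"].iloc[0] == pytest.approx(-t1["beta"].iloc[0])

    def test_white_noise_betas_center_on_zero(self):
        """Monte-Carlo null: over 300 noise timecourses the mean beta is
        within 2 standard errors of zero."""
        d = _design(conditions=("a",), n_events=6)
        regs = sorting.hrf_convolve(d)
        rng = np.random.default_rng(42)
        tcs = [rng.standard_normal((200, 1)) for _ in range(300)]
        table = sorting.sort_timecourses([tcs], regs)  # one subject, 300 runs
        betas = table[table.condition == "a"]["beta"].to_numpy()
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean()) <= 2 * se + 1e-12

    def test_mismatched_timepoints_rejected(self):
        regs = sorting.hrf_convolve(_design())
        with pytest.raises(ValueError, match="timepoints"):
            sorting.sort_timecourses([np.zeros((50, 2))], regs)


class TestClassifyFns:
    def _table(self, betas_by_ic, n_subjects=5, condition="a"):
        rows = []
        for ic, vals in enumerate(betas_by_ic):
            for s in range(n_subjects):
                rows.append({"subject": s, "run": 0, "ic": ic,
                             "condition": condition, "beta": vals[s]})
        return pd.DataFrame(rows)

    def test_all_zero_betas_all_neutral(self):
        table = self._table([np.zeros(5) for _ in range(4)])
        cls = sorting.classify_fns(table)
        assert (cls["label"] == "neutral").all()

    def test_one_signal_ic_among_nulls_detected(self):
        """Nine null ICs with small noise betas plus one IC at ~2.0: the t
        and BH oracles say only that IC survives."""
        rng = np.random.default_rng(7)
        nulls = [rng.normal(0, 0.1, 5) for _ in range(9)]
        signal = np.array([2.0, 2.1, 1.9, 2.05, 1.95])
        table = self._table(nulls + [signal])
        cls = sorting.classify_fns(table, alpha=0.05)
        # oracle: one-sample t per IC then BH
        ps = [stats.ttest_1samp(v, 0.0).pvalue for v in nulls + [signal]]
        expect = bh_oracle(np.array(ps), 0.05)
        got = (cls.sort_values("ic")["label"] != "neutral").to_numpy()
        np.testing.assert_array_equal(got, expect)
        assert cls[cls.ic == 9]["label"].iloc[0] == "positive"

    def test_negating_betas_flips_label_and_t(self):
        signal = np.array([2.0, 2.1, 1.9, 2.05, 1.95])
        rng = np.random.default_rng(8)
        nulls = [rng.normal(0, 0.2, 5) for _ in range(3)]
        t1 = sorting.classify_fns(self._table(nulls + [signal]))
        t2 = sorting.classify_fns(self._table(nulls + [-signal]))
        r1 = t1[t1.ic == 3].iloc[0]
        r2 = t2[t2.ic == 3].iloc[0]
        assert r1["label"] == "positive" and r2["label"] == "negative"
        assert r2["t"] == pytest.approx(-r1["t"])

    def test_single_subject_rejected(self):
        table = self._table([np.array([1.0])], n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            sorting.classify_fns(table)

    def test_fn_labels_flip_for_negative_subnetwork(self):
        cls = pd.DataFrame([
            {"ic": 0, "condition": "a", "mean_beta": 1.0, "t": 9.0,
             "p": 1e-5, "p_fdr": 1e-5, "label": "positive"},
            {"ic": 1, "condition": "a", "mean_beta": 0.0, "t": 0.0,
             "p": 1.0, "p_fdr": 1.0, "label": "neutral"},
        ])
        fn = sorting.fn_labels(cls)
        get = lambda ic, pol: fn[(fn.ic == ic) & (fn.polarity == pol)][
            "fn_label"].iloc[0]
        assert get(0, "positive") == "positive"
        assert get(0, "negative") == "negative"
        assert get(1, "positive") == "neutral"
        assert get(1, "negative") == "neutral"


class TestCompareConditions:
    def _paired_table(self, a_by_ic, b_by_ic):
        rows = []
        for ic, (av, bv) in enumerate(zip(a_by_ic, b_by_ic)):
            for s, (x, y) in enumerate(zip(av, bv)):
                rows.append({"subject": s, "run": 0, "ic": ic,
                             "condition": "a", "beta": x})
                rows.append({"subject": s, "run": 0, "ic": ic,
                             "condition": "b", "beta": y})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_t_zero(self):
        v = np.array([0.5, 1.0, -0.2, 0.3])
        table = self._paired_table([v], [v.copy()])
        out = sorting.compare_conditions(table, "a", "b")
        assert out["t"].iloc[0] == pytest.approx(0.0)

    def test_constant_shift_flagged_degenerate(self):
        v = np.array([0.5, 1.0, -0.2, 0.3])
        table = self._paired_table([v + 1.0], [v])
        out = sorting.compare_conditions(table, "a", "b")
        assert out["degenerate"].iloc[0]
        assert out["p"].iloc[0] == 0.0

    def test_missing_condition_pairs_listed(self):
        table = self._paired_table([np.array([1.0, 2.0])],
                                   [np.array([1.0, 2.0])])
        table = table[~((table.subject == 1) & (table.condition == "b"))]
        with pytest.raises(ValueError, match="missing"):
            sorting.compare_conditions(table, "a", "b")

    def test_rejection_rate_matches_noncentral_t_power(self):
        """Paired shift d=1, sd=1, n=20: empirical rejection over 400
        replicates falls in the binomial CI of the closed-form power of the
        paired t-test (noncentral t oracle)."""
        n, d, alpha, reps = 20, 1.0, 0.05, 400
        tcrit = stats.t.isf(alpha / 2, n - 1)
        nc = d / (1.0 / np.sqrt(n))
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit,
                                                                    n - 1, nc)
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(reps):
            base = rng.standard_normal(n)
            diff = rng.normal(d, 1.0, n)
            table = self._paired_table([base + diff], [base])
            out = sorting.compare_conditions(table, "a", "b", alpha=alpha)
            hits += int(out["significant"].iloc[0])
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(hits / reps - power) <= 3 * se
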