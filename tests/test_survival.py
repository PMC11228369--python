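import numpy as np
import pandas as pd
import pytest

from scexemplar.grouping import GroupAssignment
from scexemplar.survival import (
    attach_fdr,
    fdr_adjust,
    fit_sos,
    fit_subtype_corrected_sos,
    km_summary,
    results_table,
)
from scexemplar.synthdata import simulate_survival


def _groups(labels):
    s = pd.Series(labels)
    s.index = [f"s{i}" for i in range(len(labels))]
    return GroupAssignment(list(s.index), s, "median")


def _surv(times, events, ids=None, subtype=None):
    df = pd.DataFrame(
        {
            "sample_id": ids or [f"s{i}" for i in range(len(times))],
            "time": times,
            "event": events,
        }
    )
    if subtype is not None:
        df["subtype"] = subtype
    return df


class TestFitSos:
    def test_identical_distributions_null(self):
        times = [5, 8, 12, 20, 30] * 2
        events = [1, 1, 0, 1, 1] * 2
        ga = _groups(["up"] * 5 + ["down"] * 5)
        res = fit_sos(ga, _surv(times, events))
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.05)
        assert res.p_value > 0.95

    def test_planted_hazard_ratio_recovered(self):
        ids = [f"s{i}" for i in range(1000)]
        groups = pd.Series(["up"] * 500 + ["down"] * 500, index=ids)
        surv = simulate_survival(groups, hr=3.0, censor_frac=0.2, seed=11)
        res = fit_sos(GroupAssignment(ids, groups, "median"), surv)
        assert 2.2 <= res.hazard_ratio <= 4.1
        assert res.p_value < 1e-6

    def test_up_worse_means_hr_above_one(self):
        # short times in the up group -> hazard increases -> HR > 1
        times = [1, 2, 3, 4, 5] + [20, 25, 30, 35, 40]
        res = fit_sos(_groups(["up"] * 5 + ["down"] * 5), _surv(times, [1] * 10))
        assert res.hazard_ratio > 1

    def test_relabeling_inverts_hr_and_keeps_p(self, rng):
        ids = [f"s{i}" for i in range(200)]
        groups = pd.Series(rng.choice(["up", "down"], 200), index=ids)
        surv = simulate_survival(groups, hr=2.0, censor_frac=0.1, seed=3)
        a = fit_sos(GroupAssignment(ids, groups, "median"), surv)
        flipped = groups.map({"up": "down", "down": "up"})
        b = fit_sos(GroupAssignment(ids, flipped, "median"), surv)
        assert b.hazard_ratio == pytest.approx(1 / a.hazard_ratio, rel=1e-6)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_zero_events_in_group_flagged(self):
        res = fit_sos(
            _groups(["up"] * 5 + ["down"] * 5),
            _surv([1] * 10, [0] * 5 + [1] * 5),
        )
        assert "zero_events_in_group" in res.flags


class TestSubtypeCorrected:
    def test_single_subtype_reduces_to_naive(self):
        ids = [f"s{i}" for i in range(40)]
        groups = pd.Series(["up", "down"] * 20, index=ids)
        surv = simulate_survival(groups, hr=2.5, censor_frac=0.1, seed=0)
        surv["subtype"] = "only"
        naive = fit_sos(GroupAssignment(ids, groups, "median"), surv)
        corr = fit_subtype_corrected_sos(GroupAssignment(ids, groups, "median"), surv)
        assert corr.hazard_ratio == pytest.approx(naive.hazard_ratio, rel=1e-9)
        assert "single_subtype_naive_equivalent" in corr.flags

    def test_independent_subtype_leaves_hr_unchanged(self, rng):
        ids = [f"s{i}" for i in range(1000)]
        groups = pd.Series(rng.choice(["up", "down"], 1000), index=ids)
        subtype = pd.Series(rng.choice(["A", "B"], 1000), index=ids)
        surv = simulate_survival(groups, hr=2.0, censor_frac=0.2, seed=1)
        surv["subtype"] = subtype.to_numpy()
        ga = GroupAssignment(ids, groups, "median")
        naive = fit_sos(ga, surv)
        corr = fit_subtype_corrected_sos(ga, surv)
        assert corr.hazard_ratio == pytest.approx(naive.hazard_ratio, rel=0.1)

    def test_pure_confounder_designificated(self, rng):
        """Outcome driven by subtype only; groups track subtype.  The naive
        SOS looks significant, the corrected one should not."""
        ids = [f"s{i}" for i in range(800)]
        subtype = pd.Series(np.where(rng.random(800) < 0.5, "A", "B"), index=ids)
        agree = rng.random(800) < 0.8
        groups = pd.Series(
            np.where(agree == (subtype == "A"), "up", "down"), index=ids
        )
        surv = simulate_survival(
            pd.Series("down", index=ids), hr=1.0, censor_frac=0.2,
            subtype=subtype, subtype_hrs={"A": 3.0}, seed=5,
        )
        surv["subtype"] = subtype.to_numpy()
        ga = GroupAssignment(ids, groups, "median")
        assert fit_sos(ga, surv).p_value < 0.05
        assert fit_subtype_corrected_sos(ga, surv).p_value >= 0.05

    def test_collinear_subtype_flagged(self):
        ids = [f"s{i}" for i in range(40)]
        groups = pd.Series(["up"] * 20 + ["down"] * 20, index=ids)
        surv = simulate_survival(groups, hr=2.0, censor_frac=0.0, seed=2)
        surv["subtype"] = ["A"] * 20 + ["B"] * 20  # identical to groups
        res = fit_subtype_corrected_sos(GroupAssignment(ids, groups, "median"), surv)
        assert "subtype_collinear" in res.flags
        assert np.isnan(res.p_value)


class TestFdr:
    def test_worked_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self, rng):
        p = rng.random(20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert (fdr_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_attach_fdr_per_model_family(self):
        ids = [f"s{i}" for i in range(40)]
        groups = pd.Series(["up", "down"] * 20, index=ids)
        surv = simulate_survival(groups, hr=2.0, censor_frac=0.1, seed=7)
        ga = GroupAssignment(ids, groups, "median")
        results = [fit_sos(ga, surv, cohort=c, exemplar="X1") for c in "ab"]
        attach_fdr(results)
        table = results_table(results)
        assert (table["q"] >= table["p"] - 1e-12).all()


class TestKaplanMeier:
    def test_no_censoring_steps_down_by_one_over_n(self):
        ga = _groups(["up"] * 5)
        km = km_summary(ga, _surv([1, 2, 3, 4, 5], [1] * 5))
        # leading row is the t=0 baseline at survival 1
        np.testing.assert_allclose(
            km["survival"].to_numpy(), [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
        )
        np.testing.assert_array_equal(km["at_risk"].to_numpy(), [5, 5, 4, 3, 2, 1])

    def test_all_censored_flat_at_one(self):
        ga = _groups(["down"] * 4)
        km = km_summary(ga, _surv([3, 6, 9, 12], [0] * 4))
        np.testing.assert_allclose(km["survival"].to_numpy(), 1.0)

    def test_matches_product_limit_recomputation(self, rng):
        n = 60
        times = rng.exponential(10, n).round(2) + 0.01
        events = rng.integers(0, 2, n)
        ga = _groups(["up"] * n)
        km = km_summary(ga, _surv(times, events))
        # brute-force product-limit at each distinct event time
        surv = 1.0
        expect = {}
        for t in sorted(set(times)):
            at_risk = (times >= t).sum()
            d = ((times == t) & (events == 1)).sum()
            surv *= 1 - d / at_risk
            expect[t] = surv
        for _, row in km.iterrows():
            if row["time"] == 0:
                assert row["survival"] == 1.0
                continue
            assert row["survival"] == pytest.approx(expect[row["time"]], abs=1e-10)
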