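"""Mass t-test fibre screen, top-fraction retention, Spearman and R-maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimconn.screening import (
    DegenerateInputError,
    mass_t,
    retain_top,
    rmap,
    roi_correlations,
    spearman,
)


def profile_from(change, connected, fibers, **kw):
    return mass_t(pd.Series(change), connected, fibers, **kw)


class TestMassT:
    def test_pooled_variance_hand_computation(self):
        # connected Δ {2, 4}, unconnected {1, 3}: pooled s^2 = 2, t = 1/sqrt(2)
        change = {"a": 2.0, "b": 4.0, "c": 1.0, "d": 3.0}
        prof = profile_from(change, {"a": {0}, "b": {0}, "c": set(), "d": set()}, [0])
        assert prof.loc[0, "t"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert prof.loc[0, "n_connected"] == 2
        assert prof.loc[0, "n_unconnected"] == 2

    def test_identical_groups_zero(self):
        change = {"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0}
        prof = profile_from(change, {"a": {0}, "b": {0}, "c": set(), "d": set()}, [0])
        assert prof.loc[0, "t"] == 0.0

    def test_min_group_rule_excludes_not_zeroes(self):
        change = {"a": 2.0, "b": 4.0, "c": 1.0, "d": 3.0}
        prof = profile_from(change, {"a": {0}}, [0, 1], min_group=2)
        assert 0 not in prof.index  # 1 connected subject < min_group
        assert 1 not in prof.index  # 0 connected subjects

    def test_sign_convention_connected_minus_unconnected(self):
        change = {"a": 10.0, "b": 11.0, "c": 0.0, "d": 1.0}
        prof = profile_from(change, {"a": {0}, "b": {0}}, [0])
        assert prof.loc[0, "t"] > 0  # connected subjects show larger change

    def test_matches_brute_force_on_random_fibres(self):
        # independent oracle: explicit two-sample formulas per fibre
        rng = np.random.default_rng(12)
        n_sub, n_fib = 16, 1000
        subjects = [f"s{i}" for i in range(n_sub)]
        y = pd.Series(rng.normal(size=n_sub), index=subjects)
        member = rng.random((n_sub, n_fib)) < rng.uniform(0.1, 0.9, n_fib)
        connected = {
            s: set(np.flatnonzero(member[i])) for i, s in enumerate(subjects)
        }
        prof = mass_t(y, connected, range(n_fib))
        yv = y.to_numpy()
        max_diff = 0.0
        for f in prof.index:
            g1 = yv[member[:, f]]
            g0 = yv[~member[:, f]]
            s2 = (
                ((g1 - g1.mean()) ** 2).sum() + ((g0 - g0.mean()) ** 2).sum()
            ) / (len(g1) + len(g0) - 2)
            t_ref = (g1.mean() - g0.mean()) / np.sqrt(
                s2 * (1 / len(g1) + 1 / len(g0))
            )
            max_diff = max(max_diff, abs(prof.loc[f, "t"] - t_ref))
        assert max_diff < 1e-10

    def test_welch_option_matches_scipy(self):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=12), index=range(12))
        connected = {i: {0} for i in range(5)}
        prof = mass_t(y, connected, [0], welch=True)
        ref = stats.ttest_ind(
            y.iloc[:5], y.iloc[5:], equal_var=False
        ).statistic
        assert prof.loc[0, "t"] == pytest.approx(ref, abs=1e-12)


class TestRetainTop:
    def _profile(self, ts):
        return pd.DataFrame(
            {"t": ts, "n_connected": 3, "n_unconnected": 3, "retained": False},
            index=pd.Index(range(len(ts)), name="fiber_id"),
        )

    def test_twenty_percent_of_ten(self):
        ts = [0.1, 2.5, -3.0, 0.5, 1.0, -0.2, 0.9, 1.7, -2.2, 0.3]
        out = retain_top(self._profile(ts), 0.2)
        retained = set(out.index[out["retained"]])
        assert retained == {2, 1}  # |t| = 3.0 and 2.5
        assert out.loc[2, "t"] == -3.0  # sign preserved

    def test_all_ties_first_ids_win(self):
        out = retain_top(self._profile([1.0] * 10), 0.2)
        assert list(out.index[out["retained"]]) == [0, 1]

    def test_ceil_rule(self):
        out = retain_top(self._profile([1.0, 2.0, 3.0]), 0.2)
        assert out["retained"].sum() == 1  # ceil(0.6)

    def test_matches_sort_oracle_on_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(1, 80))
            ts = rng.normal(size=n).round(2)  # rounding forces ties
            frac = float(rng.uniform(0.05, 0.9))
            out = retain_top(self._profile(ts), frac)
            k = int(np.ceil(frac * n))
            order = sorted(range(n), key=lambda i: (-abs(ts[i]), i))
            assert list(out.index[out["retained"]].sort_values()) == sorted(order[:k])

    def test_signed_ranking_option(self):
        out = retain_top(self._profile([-3.0, 2.0, 1.0]), 0.4, by_abs=False)
        assert set(out.index[out["retained"]]) == {1, 2}  # highest signed t

    def test_empty_profile(self):
        out = retain_top(self._profile([]))
        assert out.empty


class TestSpearman:
    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)
        # exact permutation: 8 of 24 orderings reach |rho| >= 0.8
        assert res.p == pytest.approx(8 / 24)

    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 5], [2, 4, 9, 11]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 5], [-1, -2, -3, -4]).rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y**3)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p == pytest.approx(base.p, abs=1e-12)

    def test_matches_scipy_rho_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.normal(size=20)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_p_in_unit_interval(self):
        res = spearman(np.arange(20.0), np.arange(20.0))
        assert 0 < res.p <= 1


class TestRoiCorrelations:
    def test_planted_effect_points_to_target_roi(self):
        # counts for one ROI carry the outcome signal; others are noise
        rng = np.random.default_rng(17)
        n = 14
        subjects = [f"s{i}" for i in range(n)]
        signal = rng.uniform(0, 40, n)
        counts = pd.DataFrame(
            {
                "acc_right": np.round(signal),
                "fef_right": rng.integers(0, 40, n),
                "sef_right": rng.integers(0, 40, n),
            },
            index=subjects,
        )
        change = pd.DataFrame(
            {"delta_error_rate": 0.01 * signal + rng.normal(0, 0.02, n)},
            index=subjects,
        )
        table = roi_correlations(change, counts)
        best = table.loc[table["rho"].abs().idxmax()]
        assert best["roi"] == "acc_right"
        assert best["p"] < 0.05

    def test_shuffled_outcomes_center_on_zero(self):
        rng = np.random.default_rng(23)
        n = 14
        counts = pd.DataFrame(
            {f"roi{j}": rng.integers(0, 50, n) for j in range(4)},
            index=range(n),
        )
        rhos = []
        base = rng.normal(size=n)
        for _ in range(100):
            change = pd.DataFrame(
                {"delta": rng.permutation(base)}, index=range(n)
            )
            rhos.extend(roi_correlations(change, counts)["rho"])
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_counts_flagged_undefined(self):
        counts = pd.DataFrame({"flat": [3] * 6, "ok": range(6)}, index=range(6))
        change = pd.DataFrame({"delta": np.arange(6.0)}, index=range(6))
        table = roi_correlations(change, counts)
        flat = table[table["roi"] == "flat"].iloc[0]
        assert not flat["defined"] and np.isnan(flat["rho"])
        assert table[table["roi"] == "ok"].iloc[0]["defined"]


class TestRMap:
    def test_matches_per_voxel_oracle(self):
        # 2-voxel, 4-subject constructed case vs direct rank correlation
        dens = np.array(
            [
                [[1.0, 5.0]],
                [[2.0, 3.0]],
                [[3.0, 9.0]],
                [[4.0, 1.0]],
            ]
        )  # shape (4 subjects, 1, 2)
        y = pd.Series([0.1, 0.4, 0.2, 0.9], index=list("abcd"))
        out = rmap(y, dens)
        for v in range(2):
            ref = stats.spearmanr(dens[:, 0, v], y.to_numpy()).statistic
            assert out.data[0, v] == pytest.approx(ref, abs=1e-12)

    def test_proportional_density_is_one(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        dens = y.to_numpy().reshape(-1, 1, 1) * 7.0
        assert rmap(y, dens).data[0, 0] == pytest.approx(1.0)

    def test_constant_density_masked_undefined(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        dens = np.ones((4, 2, 2))
        out = rmap(y, dens)
        assert np.isnan(out.data).all()
        assert not out.defined.any()

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(31)
        dens = rng.poisson(3, size=(8, 3, 3)).astype(float)
        y = pd.Series(rng.normal(size=8))
        out = rmap(y, dens)
        defined = out.data[out.defined]
        assert (np.abs(defined) <= 1 + 1e-12).all()
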