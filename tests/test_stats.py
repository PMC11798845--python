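"""Stratification, Mann-Whitney, BH adjustment, Spearman, summary tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceusflow.errors import InputError
from ceusflow.stats import (
    bh_adjust,
    mann_whitney_u,
    region_contrasts,
    spearman_rho,
    stratify,
    summarize_table1,
)


def exact_mw_pvalue(x, y):
    """Oracle: exact two-sided Mann-Whitney p by enumerating all label
    assignments of the pooled (tie-free) sample."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2.0
    dev = abs(u_obs - mu)
    total = more_extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev - 1e-12:
            more_extreme += 1
    return more_extreme / total


class TestStratify:
    @pytest.mark.parametrize(
        "day,expected",
        [(1, "early"), (4, "early"), (5, "intermediate"), (8, "intermediate"), (9, "late"), (13, "late")],
    )
    def test_boundaries(self, day, expected):
        assert stratify(day) == expected

    def test_nonpositive_day_rejected(self):
        with pytest.raises(InputError):
            stratify(0)


class TestMannWhitney:
    def test_separated_pairs_exact(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_raw == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.p_raw == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for n1, n2 in [(2, 2), (3, 3), (4, 4), (5, 5), (3, 5), (4, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            assert res.p_raw == pytest.approx(exact_mw_pvalue(x, y), abs=1e-12)

    def test_approximation_close_to_exact_small_n(self):
        # continuity-corrected normal p within 0.03 of the exact p for all
        # tie-free samples with n1 = n2 = 5 (one fixed draw, full check via
        # the asymptotic z carried on the result)
        rng = np.random.default_rng(12)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = mann_whitney_u(x, y)
        from scipy.stats import norm

        p_approx = min(1.0, 2 * norm.sf(abs(res.z_statistic)))
        assert abs(p_approx - exact_mw_pvalue(x, y)) < 0.03

    def test_u_statistics_sum_to_n1n2(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 5, size=rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 5, size=rng.integers(2, 8)).astype(float)
            u1 = mann_whitney_u(x, y).u_statistic
            u2 = mann_whitney_u(y, x).u_statistic
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])


class TestBHAdjust:
    def test_closed_form_cases(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
        np.testing.assert_allclose(bh_adjust([0.05, 0.5]), [0.10, 0.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_never_below_raw_and_order_invariant(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.RandomState(0).permutation(len(pvals))
        adj_perm = bh_adjust(np.asarray(pvals)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert spearman_rho(x, x**3).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_tied_sample_matches_midrank_oracle(self):
        from scipy.stats import rankdata

        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0])
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_flagged_undefined(self):
        res = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined
        assert np.isnan(res.rho)


class TestSummaries:
    @staticmethod
    def _records(rng, n_h=9, n_n=6, shift=0.0):
        rows = []
        for group, n, offs in (("hypoxic", n_h, shift), ("normoxic", n_n, 0.0)):
            for i in range(n):
                day = int(rng.integers(2, 14))
                for region in ("whole_brain", "central_thalamic", "peripheral_parenchyma"):
                    rows.append(
                        {
                            "animal_id": f"{group[0]}{i}",
                            "group": group,
                            "day": day,
                            "region": region,
                            "mfv": float(rng.lognormal(offs, 0.3)),
                            "transit_time": float(rng.lognormal(0.0, 0.3)),
                            "mbf": float(rng.lognormal(0.0, 0.3)),
                        }
                    )
        return pd.DataFrame(rows)

    def test_quantile_arithmetic(self):
        df = pd.DataFrame(
            {
                "group": ["hypoxic"] * 4 + ["normoxic"] * 4,
                "region": ["whole_brain"] * 8,
                "mfv": [1.0, 2.0, 3.0, 4.0] * 2,
                "transit_time": [1.0] * 8,
                "mbf": [1.0] * 8,
            }
        )
        out = summarize_table1(df)
        row = out[(out["variable"] == "mfv")].iloc[0]
        assert row["median1"] == pytest.approx(2.5)
        assert row["iqr1"] == pytest.approx(1.5)

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(0)
        base = self._records(rng)
        mirrored = base.copy()
        # make the two groups literally identical in values
        for param in ("mfv", "transit_time", "mbf"):
            vals = base.loc[base["group"] == "hypoxic", param].to_numpy()
            k = (mirrored["group"] == "normoxic").sum()
            mirrored.loc[mirrored["group"] == "normoxic", param] = np.resize(vals, k)
        out = summarize_table1(mirrored)
        assert (out["p_adjusted"] > 0.5).all()

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        out = summarize_table1(self._records(rng, shift=-0.5))
        ok = out["p_adjusted"].notna()
        assert (out.loc[ok, "p_adjusted"] >= out.loc[ok, "p_raw"] - 1e-15).all()

    def test_region_contrast_arithmetic(self):
        rng = np.random.default_rng(2)
        df = self._records(rng)
        df.loc[df["region"] == "central_thalamic", ["mfv", "transit_time", "mbf"]] = 2.0
        df.loc[df["region"] == "peripheral_parenchyma", ["mfv", "transit_time", "mbf"]] = 1.0
        contrasts, tests = region_contrasts(df)
        assert (contrasts["mfv_difference"] == 1.0).all()
        assert (contrasts["mfv_ratio"] == 2.0).all()
        assert not tests.empty

    def test_ratio_test_detects_scale_difference_better(self):
        # groups share central >> peripheral MFV; ratios differ, differences
        # noisy: the ratio comparison attains a smaller p-value
        rng = np.random.default_rng(7)
        rows = []
        for group, ratio in (("hypoxic", 4.0), ("normoxic", 2.0)):
            for i in range(12):
                scale = float(rng.lognormal(0.0, 0.6))
                peripheral = scale
                central = ratio * scale * float(rng.lognormal(0.0, 0.05))
                for region, val in (
                    ("central_thalamic", central),
                    ("peripheral_parenchyma", peripheral),
                ):
                    rows.append(
                        {
                            "animal_id": f"{group[0]}{i}",
                            "group": group,
                            "day": 5,
                            "region": region,
                            "mfv": val,
                            "transit_time": 1.0,
                            "mbf": val,
                        }
                    )
        _, tests = region_contrasts(pd.DataFrame(rows))
        p_ratio = tests.loc[tests["variable"] == "mfv_ratio", "p_raw"].iloc[0]
        p_diff = tests.loc[tests["variable"] == "mfv_difference", "p_raw"].iloc[0]
        assert p_ratio < p_diff
        assert p_ratio < 0.05

    def test_type_one_error_null_simulations(self):
        # both groups from one distribution: raw p <= 0.05 in [0.02, 0.09]
        rng = np.random.default_rng(14)
        hits = sum(
            mann_whitney_u(rng.normal(size=9), rng.normal(size=6)).p_raw <= 0.05
            for _ in range(500)
        )
        assert 0.02 <= hits / 500 <= 0.09
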