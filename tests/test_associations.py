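from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivshape.associations import (
    association_screen,
    cca_modes_vs_index,
    kendall_tau_b,
    pearson_r,
    spearman_rho,
)
from bivshape.errors import JoinError, UndefinedCorrelationError
from bivshape.synthetic import ClinicalLink, sample_clinical_indices


def brute_force_spearman(x, y):
    """Independent mid-rank oracle: Pearson formula on hand-built ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            out[i] = np.sum(v < vi) + 1 + (np.sum(v == vi) - 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))


def brute_force_tau_b(x, y):
    """Pair-enumeration oracle for tau-b with tie corrections."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx != 0 and sy != 0:
                if sx == sy:
                    c += 1
                else:
                    d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - _tie_count(x)) * (n0 - _tie_count(y)))


def _tie_count(v):
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 9.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-12

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        xc, yc = x - x.mean(), y - y.mean()
        direct = xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))
        assert pearson_r(x, y).estimate == pytest.approx(direct, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        a, b = pearson_r(x, y), pearson_r(y, x)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-14)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-14)

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        a = pearson_r(x, y)
        b = pearson_r(3.0 * x - 7.0, y)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestSpearman:
    def test_monotone_relation_is_one(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.1])
        res = spearman_rho(x, np.exp(x))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_tied_example_matches_bruteforce_and_exact_p(self):
        x = np.array([1.0, 2, 2, 3])
        y = np.array([1.0, 3, 2, 4])
        res = spearman_rho(x, y)
        assert res.estimate == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        # exhaustive permutation oracle for the exact p-value
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        obs = abs(rxc @ ryc) / denom
        hits = sum(
            abs(rxc @ ryc[list(p)]) / denom >= obs - 1e-12
            for p in permutations(range(4))
        )
        assert res.p_value == pytest.approx(hits / 24.0, abs=1e-12)

    def test_reversing_y_negates_rho_keeps_p(self, rng):
        x, y = rng.standard_normal(7), rng.standard_normal(7)
        a, b = spearman_rho(x, y), spearman_rho(x, -y)
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        a = spearman_rho(x, y)
        b = spearman_rho(np.exp(x), y)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_large_n_p_close_to_exact_small_n(self, rng):
        # the t-approximation should agree with enumeration within 0.05
        # for moderate correlations at n = 8
        for seed in range(5):
            r = np.random.default_rng(seed)
            x, y = r.standard_normal(8), r.standard_normal(8)
            exact = spearman_rho(x, y).p_value
            approx = float(stats.spearmanr(x, y)[1])
            if abs(spearman_rho(x, y).estimate) < 0.9:
                assert abs(exact - approx) < 0.05


class TestKendall:
    def test_self_correlation_is_one(self, rng):
        x = rng.permutation(9).astype(float)
        assert kendall_tau_b(x, x).estimate == pytest.approx(1.0, abs=1e-12)

    def test_small_example_pair_counts(self):
        # x=(1,2,3,4), y=(1,3,2,4): 5 concordant, 1 discordant pairs
        res = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.estimate == pytest.approx(4 / 6, abs=1e-12)

    def test_tied_example_matches_bruteforce(self):
        x = [1.0, 1, 2, 3]
        y = [1.0, 2, 2, 3]
        res = kendall_tau_b(x, y)
        assert res.estimate == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_matches_scipy_estimate(self, rng):
        x = rng.integers(0, 4, 15).astype(float)
        y = rng.integers(0, 4, 15).astype(float)
        ours = kendall_tau_b(x, y)
        ref = stats.kendalltau(x, y, variant="b")
        assert ours.estimate == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            kendall_tau_b([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCca:
    def test_exact_column_gives_r_one(self, rng):
        L = rng.standard_normal((12, 5))
        res = cca_modes_vs_index(L, L[:, 2])
        assert res.estimate == pytest.approx(1.0, abs=1e-8)

    def test_matches_least_squares_oracle(self, rng):
        L = rng.standard_normal((10, 5))
        y = L @ rng.standard_normal(5) + 0.3 * rng.standard_normal(10)
        res = cca_modes_vs_index(L, y)
        X = np.column_stack([np.ones(10), L])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.estimate == pytest.approx(np.sqrt(r2), abs=1e-10)

    def test_never_below_best_single_mode_correlation(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            L = r.standard_normal((20, 5))
            y = r.standard_normal(20)
            best_single = max(
                abs(pearson_r(L[:, k], y).estimate) for k in range(5)
            )
            assert cca_modes_vs_index(L, y).estimate >= best_single - 1e-10

    def test_null_p_values_uniform(self):
        # type-I calibration: independent index at n=48, fraction of
        # p < 0.05 should be close to nominal over 1000 simulations
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            L = rng.standard_normal((48, 5))
            y = rng.standard_normal(48)
            hits += cca_modes_vs_index(L, y).p_value < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


class TestScreen:
    def make_inputs(self, rng, n=48):
        L = rng.standard_normal((n, 5))
        clinical = pd.DataFrame(
            {
                "vt_vf": rng.integers(0, 2, n),
                "syncope": rng.integers(0, 2, n),
                "tfc_major": rng.integers(1, 6, n),
            }
        )
        return L, clinical

    def test_row_count_bookkeeping(self, rng):
        L, clinical = self.make_inputs(rng)
        out = association_screen(L, clinical)
        # 3 indices x (5 modes x 3 tests + 1 CCA row)
        assert len(out) == 3 * (5 * 3 + 1)
        assert out.attrs["multiple_testing_correction"].startswith("none")

    def test_null_flag_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        flagged = total = 0
        for _ in range(60):
            L, clinical = self.make_inputs(rng)
            out = association_screen(L, clinical, tests=("r",), include_cca=False)
            flagged += int(out["significant"].sum())
            total += len(out)
        rate = flagged / total
        assert 0.03 <= rate <= 0.07

    def test_strong_link_almost_always_flagged(self):
        # beta = 3 link from mode 4 to a binary index: the (index, mode 4)
        # pair must reach p < 0.05 in at least 95 of 100 seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            z = rng.standard_normal((200, 5))
            table = sample_clinical_indices(
                z, [ClinicalLink("vt_vf", "length", 3.0)], seed=seed
            )
            out = association_screen(
                z,
                table[["vt_vf"]],
                tests=("rho",),
                include_cca=False,
            )
            row = out[(out["target"] == "mode_4") & (out["index"] == "vt_vf")]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 95

    def test_subject_mismatch_raises(self, rng):
        L, clinical = self.make_inputs(rng)
        with pytest.raises(JoinError):
            association_screen(L[:10], clinical)

    def test_constant_index_yields_nan_not_error(self, rng):
        L, clinical = self.make_inputs(rng)
        clinical["fat"] = 0
        out = association_screen(L, clinical, indices=("fat",))
        assert out["estimate"].isna().all()
        assert not out["significant"].any()
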