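"""Balanced selection, LDA classification, day-block permutation, pDFA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gibbonsong import pdfa, songsim
from gibbonsong.pdfa import (
    LinearDiscriminant, PermutedDFA, balanced_selection, classify_heldout,
    dfa_structure, permute_day_blocks, run_pdfa,
)


class TestBalancedSelection:
    def _frame(self, males=10, calls=30):
        return pd.DataFrame({
            "male_id": np.repeat([f"m{i}" for i in range(males)], calls)})

    def test_counts(self, rng):
        tr, te = balanced_selection(self._frame(), 23, rng)
        assert len(tr) == 230 and len(te) == 70

    def test_deterministic_under_seed(self):
        f = self._frame()
        tr1, _ = balanced_selection(f, 23, np.random.default_rng(5))
        tr2, _ = balanced_selection(f, 23, np.random.default_rng(5))
        assert np.array_equal(np.sort(tr1), np.sort(tr2))

    def test_selection_uniform_per_call(self, rng):
        """Every call of a male is trained on equally often."""
        f = pd.DataFrame({"male_id": ["m"] * 12})
        counts = np.zeros(12)
        n_draws = 4000
        for _ in range(n_draws):
            tr, _ = balanced_selection(f, 5, rng)
            counts[tr] += 1
        expected = n_draws * 5 / 12.0
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 11) > 0.01

    def test_small_males_excluded(self, rng, caplog):
        f = pd.DataFrame({"male_id": ["a"] * 30 + ["b"] * 1})
        tr, te = balanced_selection(f, 23, rng)
        assert len(tr) == 23 and len(te) == 7


class TestClassifier:
    def test_separable_pair_perfect(self, rng):
        X = np.vstack([rng.standard_normal((40, 4)),
                       rng.standard_normal((40, 4)) + 10.0])
        y = np.array(["a"] * 40 + ["b"] * 40)
        rate = classify_heldout(X[:60], y[:60], X[60:], y[60:])
        assert rate == 100.0

    def test_shuffled_labels_at_chance(self, rng):
        """Shuffling labels drives accuracy to the chance level."""
        rates = []
        for _ in range(100):
            X = rng.standard_normal((90, 5))
            y = rng.permutation(np.repeat(["a", "b", "c"], 30))
            tr = rng.choice(90, 60, replace=False)
            te = np.setdiff1d(np.arange(90), tr)
            rates.append(classify_heldout(X[tr], y[tr], X[te], y[te]))
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / 10.0
        assert abs(mean - 100.0 / 3) < 3 * se + 1e-9

    def test_agrees_with_sklearn_oracle(self, rng):
        """Dual route: hand LDA vs scikit-learn on a 3-male toy set."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((60, 4))
        X[20:40] += [2, 0, 1, 0]
        X[40:] += [0, 3, 0, 1]
        y = np.repeat(["a", "b", "c"], 20)
        Xt = rng.standard_normal((30, 4)) + [1, 1, 0.5, 0.5]
        mine = LinearDiscriminant().fit(X, y).predict(Xt)
        sk = LinearDiscriminantAnalysis(solver="lsqr",
                                        priors=[1 / 3] * 3).fit(X, y)
        assert np.array_equal(mine, sk.predict(Xt))

    def test_rank_deficient_ridge(self, rng):
        X = rng.standard_normal((30, 4))
        X[:, 3] = X[:, 2]  # singular pooled covariance
        y = np.repeat(["a", "b"], 15)
        lda = LinearDiscriminant().fit(X, y)
        assert lda.ridge_eps > 0
        assert len(lda.predict(X)) == 30


class TestDayPermutation:
    def _toy(self):
        males = np.repeat(["a", "a", "b", "b", "c"], 4)
        days = np.repeat(["d1", "d2", "d3", "d4", "d5"], 4)
        return males, days

    def test_day_counts_conserved(self, rng):
        males, days = self._toy()
        for _ in range(20):
            perm = permute_day_blocks(males, days, rng)
            blocks = pd.DataFrame({"m": perm, "d": days}).drop_duplicates()
            counts = blocks.groupby("m").size().sort_index()
            assert counts.tolist() == [2, 2, 1]

    def test_within_day_comembership_preserved(self, rng):
        males, days = self._toy()
        perm = permute_day_blocks(males, days, rng)
        for d in np.unique(days):
            assert len(set(perm[days == d])) == 1

    def test_block_assignment_uniform(self, rng):
        """Each day-block visits labels per uniform permutation frequencies."""
        males = np.array(["a", "a", "b"])
        days = np.array(["d1", "d2", "d3"])
        counts = {d: {m: 0 for m in "ab"} for d in days}
        n = 3000
        for _ in range(n):
            perm = permute_day_blocks(males, days, rng)
            for d, m in zip(days, perm):
                counts[d][m] += 1
        # label multiset (a,a,b): each block is 'a' w.p. 2/3, 'b' w.p. 1/3
        for d in days:
            chi2 = sum((counts[d][m] - n * e) ** 2 / (n * e)
                       for m, e in (("a", 2 / 3), ("b", 1 / 3)))
            assert stats.chi2.sf(chi2, 1) > 0.01


@pytest.fixture(scope="module")
def separable():
    return songsim.simulate_call_features(n_males=10, calls_per_male=28,
                                          n_days=3, separation=6.0, seed=8)


class TestRunPdfa:
    def test_chance_level_ten_males(self, separable):
        res = run_pdfa(separable, n_select=23, n_selections=5,
                       n_permutations=10, day_col="recording_day", seed=0)
        assert res.chance_level == pytest.approx(10.0)

    def test_p_hits_permutation_floor(self, separable):
        res = run_pdfa(separable, n_select=23, n_selections=10,
                       n_permutations=100, day_col="recording_day", seed=1)
        assert res.p_value == pytest.approx(1.0 / 100)
        assert res.observed_rate > 95.0

    def test_p_lower_bound_invariant(self, separable):
        res = run_pdfa(separable, n_select=23, n_selections=3,
                       n_permutations=25, day_col="recording_day", seed=2)
        assert 1.0 / 25 <= res.p_value <= 1.0

    def test_type_one_error_calibrated(self):
        """Under a day-correlated null, p is uniform: ~5% at alpha 0.05.

        Day-level random effects make same-day calls similar with no true
        male signal — the case a call-level permutation overstates.
        """
        rng_seeds = range(120)
        hits = 0
        for s in rng_seeds:
            df = songsim.simulate_call_features(
                n_males=5, calls_per_male=15, n_days=3, separation=0.0,
                n_features=6, day_sd=1.0, seed=1000 + s)
            res = run_pdfa(df, n_select=10, n_selections=2,
                           n_permutations=40, day_col="recording_day",
                           seed=s)
            hits += res.p_value <= 0.05
        # Binomial(120, 0.05): 95% range about [1, 12]
        assert 1 <= hits <= 12

    def test_monotone_in_separation(self):
        rates = []
        for sep in (0.5, 2.0, 6.0):
            vals = []
            for rep in range(5):
                df = songsim.simulate_call_features(
                    n_males=4, calls_per_male=16, n_days=2, separation=sep,
                    n_features=8, seed=50 + rep)
                model = PermutedDFA(df[[c for c in df if c.startswith("f")]],
                                    df["male_id"], df["recording_day"],
                                    n_select=10, n_selections=4,
                                    n_permutations=2)
                vals.append(model.fit(seed=rep).observed_rate)
            rates.append(np.mean(vals))
        assert rates[0] <= rates[1] <= rates[2]


class TestDfaStructure:
    def test_two_classes_one_function(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.repeat(["a", "b"], 20)
        eig, load, flags = dfa_structure(X, y)
        assert len(eig) == 1
        assert load.shape == (5, 1)

    def test_loadings_match_direct_correlation(self, rng):
        X = rng.standard_normal((90, 4))
        X[:30, 0] += 2.0
        X[30:60, 1] += 2.0
        y = np.repeat(["a", "b", "c"], 30)
        eig, load, _ = dfa_structure(X, y)
        # recompute scores independently and correlate
        classes, y_idx = np.unique(y, return_inverse=True)
        grand = X.mean(axis=0)
        means = np.vstack([X[y_idx == c].mean(0) for c in range(3)])
        Xc = X - means[y_idx]
        Sw = Xc.T @ Xc / (90 - 3)
        Mb = (means - grand) * np.sqrt(np.bincount(y_idx))[:, None]
        Sb = Mb.T @ Mb / 2
        from scipy.linalg import eigh
        w, V = eigh(Sb, Sw)
        V = V[:, np.argsort(w)[::-1]][:, :2]
        S = (X - grand) @ V
        for j in range(2):
            direct = [np.corrcoef(X[:, v], S[:, j])[0, 1] for v in range(4)]
            assert np.allclose(np.abs(load.iloc[:, j]), np.abs(direct),
                               atol=1e-10)

    def test_planted_variable_has_top_loading(self, rng):
        X = rng.standard_normal((80, 6))
        y = np.repeat(["a", "b"], 40)
        X[y == "b", 3] += 3.0  # only variable 3 separates the males
        _, load, flags = dfa_structure(X, y)
        assert load.iloc[:, 0].abs().idxmax() == "x4"
        assert flags.iloc[3, 0]
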