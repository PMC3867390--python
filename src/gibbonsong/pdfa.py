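"""Permuted discriminant function analysis of vocal individuality.

A plain DFA overstates individual distinctiveness when several calls come
from the same recording day: day-level effects (weather, singing bout,
recorder position, hormone state) make same-day calls similar regardless
of identity.  The permutation test here therefore keeps whole recording
days together: under the null hypothesis, day-blocks of calls are
reassigned among males (each male keeping its original number of days),
and the cross-validated classification statistic is recomputed for each
permuted dataset.  The observed arrangement counts as one permutation, so
the smallest attainable p is 1/n_permutations.

To balance individual contributions, each DFA derives its discriminant
functions from the same number of randomly selected calls per male
(default 23, one more than the number of acoustic parameters), classifies
the held-out calls, and the statistic is the percentage correct averaged
over ``n_selections`` random selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "PermutedDFA",
    "PdfaResults",
    "run_pdfa",
    "balanced_selection",
    "classify_heldout",
    "permute_day_blocks",
    "dfa_structure",
    "LinearDiscriminant",
]


class LinearDiscriminant:
    """Minimal LDA with equal priors and ridge fallback.

    Linear discriminant scores use the pooled within-class covariance;
    with equal priors the assignment is the nearest class centroid in the
    discriminant (whitened) metric.  A rank-deficient pooled covariance is
    ridge-regularized with a logged epsilon.
    """

    def __init__(self):
        self.classes_ = None
        self.ridge_eps = 0.0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
        Xc = X - means[y_idx]
        Sw = (Xc.T @ Xc) / (n - k)
        evals = np.linalg.eigvalsh(Sw)
        if evals[0] <= 1e-10 * max(evals[-1], 1e-300):
            self.ridge_eps = 1e-6 * np.trace(Sw) / p
            logger.warning("rank-deficient within-class covariance; "
                           "ridge eps = %.3g", self.ridge_eps)
            Sw = Sw + self.ridge_eps * np.eye(p)
        cho = linalg.cho_factor(Sw, lower=True)
        SwinvM = linalg.cho_solve(cho, means.T)       # p x k
        self._w = SwinvM
        self._b = -0.5 * np.einsum("ck,kc->c", means, SwinvM)
        return self

    def predict(self, X):
        scores = np.asarray(X, dtype=float) @ self._w + self._b
        return self.classes_[np.argmax(scores, axis=1)]


def balanced_selection(dataset: pd.DataFrame, n_select: int,
                       rng: np.random.Generator, male_col: str = "male_id"):
    """Split call indices into a balanced train set and the held-out rest.

    Exactly ``n_select`` training calls per male, uniformly without
    replacement.  A male with ``<= n_select`` calls cannot contribute a
    balanced selection plus a held-out call; in the observed data such
    males are excluded (logged); in day-permuted data (where call counts
    per male fluctuate) the male trains on all but one call.
    """
    train_idx, test_idx = [], []
    for male, sub in dataset.groupby(male_col, sort=True):
        idx = sub.index.to_numpy()
        take = n_select if len(idx) > n_select else len(idx) - 1
        if take < 1:
            logger.info("excluding %s: only %d calls", male, len(idx))
            continue
        chosen = rng.choice(idx, size=take, replace=False)
        train_idx.append(chosen)
        mask = np.isin(idx, chosen, invert=True)
        test_idx.append(idx[mask])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def classify_heldout(X_train, y_train, X_test, y_test) -> float:
    """Percent of held-out calls assigned to the correct male."""
    lda = LinearDiscriminant().fit(X_train, y_train)
    pred = lda.predict(X_test)
    return 100.0 * float(np.mean(pred == np.asarray(y_test)))


def permute_day_blocks(males, days, rng: np.random.Generator):
    """Reassign whole recording-day blocks of calls among male labels.

    Each (male, day) block keeps its calls together; the multiset of
    block labels is permuted, so every male retains its original number
    of recording days.  Returns the permuted male label per call.
    """
    males = np.asarray(males)
    days = np.asarray(days)
    blocks = pd.unique(pd.Series(list(zip(males, days))))
    block_male = np.array([b[0] for b in blocks], dtype=object)
    n_days_per_male = pd.Series(block_male).value_counts()
    if (n_days_per_male == 1).any() and len(n_days_per_male) == 2:
        logger.warning("a male has a single recording day with k=2: "
                       "degenerate permutation space")
    perm = rng.permutation(block_male)
    mapping = {b: perm[i] for i, b in enumerate(blocks)}
    return np.array([mapping[(m, d)] for m, d in zip(males, days)], dtype=object)


def dfa_structure(X, y, loading_threshold: float = 0.5):
    """Discriminant-function eigenvalues and structure loadings on all calls.

    Eigenvalues are those of the between-groups vs pooled within-groups
    generalized eigenproblem (at most k-1 functions); structure loadings
    are the correlations of each variable with each discriminant score.
    Returns ``(eigenvalues, loadings_df, flags_df)`` with flags marking
    |loading| >= ``loading_threshold``.
    """
    names = list(X.columns) if hasattr(X, "columns") else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 males")
    n, p = X.shape
    grand = X.mean(axis=0)
    means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
    counts = np.bincount(y_idx)
    Xc = X - means[y_idx]
    Sw = (Xc.T @ Xc) / (n - k)
    Mb = (means - grand) * np.sqrt(counts)[:, None]
    Sb = (Mb.T @ Mb) / (k - 1)
    eigval, eigvec = linalg.eigh(Sb, Sw)
    order = np.argsort(eigval)[::-1]
    n_func = min(k - 1, p)
    eigval = eigval[order][:n_func] * (k - 1) / (n - k)  # canonical scale
    V = eigvec[:, order][:, :n_func]
    scores = (X - grand) @ V
    cols = [f"df_{j+1}" for j in range(n_func)]
    load = np.zeros((p, n_func))
    for j in range(n_func):
        s = scores[:, j]
        ssd = s.std(ddof=1)
        load[:, j] = [np.corrcoef(X[:, v], s)[0, 1] if ssd > 0 else 0.0
                      for v in range(p)]
    if names is None:
        names = [f"x{v+1}" for v in range(p)]
    loadings = pd.DataFrame(load, index=names, columns=cols)
    return eigval, loadings, loadings.abs() >= loading_threshold


@dataclass
class PdfaResults:
    observed_rate: float          # % correctly cross-classified, averaged
    chance_level: float           # 100 / k males
    p_value: float
    n_selections: int
    n_permutations: int
    per_selection_rates: np.ndarray
    permuted_rates: np.ndarray
    n_males: int
    n_calls: int
    excluded_males: list = field(default_factory=list)
    seed: int | None = None

    def summary(self) -> str:
        return (
            "Permuted DFA for vocal individuality\n"
            f"  males: {self.n_males}  calls: {self.n_calls}"
            + (f"  (excluded: {', '.join(self.excluded_males)})"
               if self.excluded_males else "") + "\n"
            f"  cross-classified correct: {self.observed_rate:.1f}% "
            f"(chance level {self.chance_level:.1f}%)\n"
            f"  selections: {self.n_selections}; day-wise permutations: "
            f"{self.n_permutations} (observed included)\n"
            f"  P = {self.p_value:.3g}"
        )


class PermutedDFA:
    """Cross-validated DFA with day-wise restricted permutation test.

    Parameters
    ----------
    features : DataFrame (calls x transformed parameters) or array.
    males, days : per-call male identity and recording-day labels.
    n_select : training calls per male (balanced selection).
    n_selections : random selections averaged for the observed statistic.
    n_permutations : permutations including the observed arrangement.
    perm_selections : selections per permuted dataset (defaults to
        ``n_selections``; lower trades Monte-Carlo noise for speed).
    """

    def __init__(self, features, males, days, n_select: int = 23,
                 n_selections: int = 100, n_permutations: int = 1000,
                 perm_selections: int | None = None):
        feat = (features.reset_index(drop=True) if isinstance(features, pd.DataFrame)
                else pd.DataFrame(np.asarray(features, dtype=float)))
        self.data = feat
        self.males = np.asarray(males)
        self.days = np.asarray(days)
        if len(self.data) != len(self.males) or len(self.males) != len(self.days):
            raise ValueError("features, males and days must align")
        self.n_select = n_select
        self.n_selections = n_selections
        self.n_permutations = n_permutations
        self.perm_selections = perm_selections or n_selections

        counts = pd.Series(self.males).value_counts()
        self.excluded = sorted(counts.index[counts <= n_select])
        if self.excluded:
            logger.info("excluding %d males with <= %d calls: %s",
                        len(self.excluded), n_select, self.excluded)
        keep = ~np.isin(self.males, self.excluded)
        self.data = self.data.loc[keep].reset_index(drop=True)
        self.males = self.males[keep]
        self.days = self.days[keep]
        self.k = len(np.unique(self.males))
        if self.k < 2:
            raise ValueError("need at least 2 males with enough calls")

    def _statistic(self, males, rng, n_selections) -> tuple:
        X = self.data.to_numpy(dtype=float)
        # per-male index arrays computed once per labelling
        order = np.argsort(males, kind="stable")
        sorted_males = males[order]
        bounds = np.flatnonzero(np.r_[True, sorted_males[1:] != sorted_males[:-1],
                                      True])
        groups = [order[bounds[i]:bounds[i + 1]]
                  for i in range(len(bounds) - 1)]
        rates = np.empty(n_selections)
        n = len(males)
        for s in range(n_selections):
            train_mask = np.zeros(n, dtype=bool)
            active = np.ones(n, dtype=bool)
            for idx in groups:
                take = self.n_select if len(idx) > self.n_select else len(idx) - 1
                if take < 1:  # single-call male under permutation: left out
                    active[idx] = False
                    continue
                train_mask[rng.choice(idx, size=take, replace=False)] = True
            te = active & ~train_mask
            rates[s] = classify_heldout(X[train_mask], males[train_mask],
                                        X[te], males[te])
        return float(rates.mean()), rates

    def fit(self, seed: int = 0) -> PdfaResults:
        rng_obs = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
        observed, per_sel = self._statistic(self.males, rng_obs, self.n_selections)

        rng_perm = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 211]))
        permuted = np.empty(self.n_permutations - 1)
        for b in range(self.n_permutations - 1):
            males_b = permute_day_blocks(self.males, self.days, rng_perm)
            permuted[b], _ = self._statistic(males_b, rng_perm,
                                             self.perm_selections)
        # observed counted as one permutation; ties count against the null
        n_ge = 1 + int(np.sum(permuted >= observed))
        p = n_ge / self.n_permutations
        return PdfaResults(
            observed_rate=observed, chance_level=100.0 / self.k, p_value=p,
            n_selections=self.n_selections, n_permutations=self.n_permutations,
            per_selection_rates=per_sel, permuted_rates=permuted,
            n_males=self.k, n_calls=len(self.males),
            excluded_males=list(self.excluded), seed=seed)


def run_pdfa(dataset: pd.DataFrame, feature_cols=None, n_select: int = 23,
             n_selections: int = 100, n_permutations: int = 1000,
             perm_selections: int | None = None, seed: int = 0,
             male_col: str = "male_id", day_col: str = "recording_day") -> PdfaResults:
    """Functional wrapper: dataset has feature columns + male/day labels."""
    if feature_cols is None:
        feature_cols = [c for c in dataset.columns if c not in (male_col, day_col)]
    model = PermutedDFA(dataset[feature_cols], dataset[male_col],
                        dataset[day_col], n_select=n_select,
                        n_selections=n_selections, n_permutations=n_permutations,
                        perm_selections=perm_selections)
    return model.fit(seed=seed)
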