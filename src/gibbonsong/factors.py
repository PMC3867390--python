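"""Factor analysis of the 22 call-level acoustic parameters.

Redundancy among the call parameters is removed by an exploratory factor
analysis on the correlation matrix of the (per-parameter transformed)
features: principal-component extraction, retention of factors with
eigenvalue > 1 (Kaiser criterion), varimax rotation with Kaiser
normalization, and regression-method factor scores (weights R^-1 Lambda).
Sampling adequacy is screened with Bartlett's test of sphericity and the
Kaiser-Meyer-Olkin statistic.

Per-parameter transforms (log, sqrt, sqrt of the min-shifted value) are
fixed per parameter to symmetrize skewed distributions; the minima used
by the shifted square root are estimated on the fitting data and frozen,
so new data are transformed consistently.  The logarithm is natural: any
base only rescales a column, leaving an analysis of the correlation
matrix unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TransformSpec",
    "DEFAULT_TRANSFORMS",
    "apply_transforms",
    "sampling_adequacy",
    "varimax",
    "CallFactorAnalysis",
    "FactorAnalysisResults",
    "fit_factor_model",
    "factor_scores",
]

#: transform assigned to each of the 22 call parameters
DEFAULT_TRANSFORMS = {
    "call_duration_s": "log",
    "mean_element_duration_s": "identity",
    "mean_interval_duration_s": "sqrt_shift",
    "mean_start_f0_hz": "identity",
    "mean_end_f0_hz": "identity",
    "mean_mean_f0_hz": "identity",
    "mean_max_f0_hz": "identity",
    "mean_loc_max_f0": "sqrt",
    "max_element_duration_s": "identity",
    "max_interval_duration_s": "log",
    "max_start_f0_hz": "identity",
    "max_end_f0_hz": "sqrt_shift",
    "max_mean_f0_hz": "sqrt_shift",
    "max_max_f0_hz": "identity",
    "max_loc_max_f0": "sqrt",
    "var_element_duration_s": "sqrt",
    "var_interval_duration_s": "log",
    "var_start_f0_hz": "sqrt",
    "var_end_f0_hz": "sqrt",
    "var_mean_f0_hz": "sqrt",
    "var_max_f0_hz": "sqrt",
    "var_loc_max_f0": "sqrt",
}

_VALID = {"identity", "log", "sqrt", "sqrt_shift"}


class DataError(ValueError):
    pass


class ModelError(RuntimeError):
    pass


@dataclass
class TransformSpec:
    """Per-parameter transform map with frozen shift minima."""

    transforms: dict
    minima: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.transforms.values()) - _VALID
        if bad:
            raise ValueError(f"unknown transforms: {bad}")

    @classmethod
    def default(cls) -> "TransformSpec":
        return cls(dict(DEFAULT_TRANSFORMS))

    def fit(self, table: pd.DataFrame) -> "TransformSpec":
        """Store the dataset minima used by sqrt_shift columns."""
        for col, tf in self.transforms.items():
            if tf == "sqrt_shift":
                self.minima[col] = float(table[col].min())
        return self

    def to_dict(self) -> dict:
        return {"transforms": self.transforms, "minima": self.minima}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(dict(d["transforms"]), dict(d.get("minima", {})))


def apply_transforms(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Apply the per-parameter transforms; missing values propagate."""
    if not spec.minima and any(t == "sqrt_shift" for t in spec.transforms.values()):
        spec.fit(table)
    out = {}
    for col, tf in spec.transforms.items():
        x = table[col].to_numpy(dtype=float)
        if tf == "identity":
            y = x
        elif tf == "log":
            bad = np.where(~np.isnan(x) & (x <= 0))[0]
            if bad.size:
                raise DataError(
                    f"log transform of non-positive value in column {col!r}, "
                    f"row(s) {bad[:5].tolist()}")
            y = np.log(x)
        elif tf == "sqrt":
            bad = np.where(~np.isnan(x) & (x < 0))[0]
            if bad.size:
                raise DataError(
                    f"sqrt of negative value in column {col!r}, row(s) {bad[:5].tolist()}")
            y = np.sqrt(x)
        else:  # sqrt_shift
            shift = spec.minima.get(col, float(np.nanmin(x)))
            z = x - shift
            z[z < 0] = 0.0  # new data below the training minimum clamps at 0
            y = np.sqrt(z)
        out[col] = y
    return pd.DataFrame(out, index=table.index)


class AdequacyResult(NamedTuple):
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo: float


def sampling_adequacy(table: pd.DataFrame) -> AdequacyResult:
    """Bartlett's sphericity test and the KMO measure.

    Bartlett: chi2 = -((n-1) - (2p+5)/6) * ln det R on p(p-1)/2 df.
    KMO: sum of squared off-diagonal correlations over that sum plus the
    squared off-diagonal partial correlations (anti-image).  A singular
    correlation matrix falls back to the pseudo-inverse with a warning.
    """
    X = table.dropna().to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise DataError("need at least 2 complete rows")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * (logdet if sign > 0 else -np.inf)
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, dof)) if np.isfinite(chi2) else 0.0

    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; KMO uses pseudo-inverse")
        Rinv = np.linalg.pinv(R)
    d = np.sqrt(np.abs(np.diag(Rinv)))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    kmo = float(r2 / (r2 + p2))
    return AdequacyResult(float(chi2), dof, pval, kmo)


def varimax(loadings: np.ndarray, kaiser: bool = True, max_iter: int = 500,
            tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation (orthogonal), optionally Kaiser-normalized."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L ** 2).sum(axis=1)) if kaiser else np.ones(p)
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return (L @ R) * h[:, None]


class FactorAnalysisResults:
    """Fitted factor model: rotated loadings, diagnostics, score weights."""

    def __init__(self, model, loadings, eigenvalues, n_factors, columns,
                 means, sds, corr, diagnostics, n_obs, n_dropped):
        self.model = model
        self.loadings = loadings          # DataFrame parameters x factors
        self.eigenvalues = eigenvalues    # all p eigenvalues, descending
        self.n_factors = n_factors
        self.columns = list(columns)
        self._means = means
        self._sds = sds
        self._corr = corr
        self.diagnostics = diagnostics
        self.n_obs = n_obs
        self.n_dropped = n_dropped
        L = loadings.to_numpy()
        ss = (L ** 2).sum(axis=0)
        self.variance_explained = 100.0 * ss / len(columns)
        self.communalities = pd.Series((L ** 2).sum(axis=1), index=columns)
        # regression-method score weights: W = R^-1 Lambda
        self.score_weights = pd.DataFrame(
            np.linalg.solve(corr, L), index=columns, columns=loadings.columns)

    def score(self, table: pd.DataFrame) -> pd.DataFrame:
        """Regression-method factor scores for (transformed) data."""
        missing = set(self.columns) - set(table.columns)
        if missing:
            raise KeyError(f"table lacks fitted parameters: {sorted(missing)}")
        X = table[self.columns].to_numpy(dtype=float)
        Z = (X - self._means) / self._sds
        S = Z @ self.score_weights.to_numpy()
        return pd.DataFrame(S, index=table.index,
                            columns=self.loadings.columns)

    def label_factors(self) -> dict:
        """Map factor columns to semantic labels by dominant loading block.

        Labels follow the acoustic meaning of the variables that load
        highest: pitch, element_duration, pitch_variation,
        location_max_f0, call_duration, start_f0.
        """
        blocks = {
            "pitch": [c for c in self.columns
                      if ("f0_hz" in c and "loc" not in c and "start" not in c)],
            "element_duration": [c for c in self.columns if "element_duration" in c],
            "pitch_variation": [c for c in self.columns
                                if c.startswith("var_") and "f0_hz" in c
                                and "start" not in c],
            "location_max_f0": [c for c in self.columns if "loc_max_f0" in c],
            "call_duration": [c for c in self.columns
                              if "call_duration" in c or "interval" in c],
            "start_f0": [c for c in self.columns if "start_f0" in c],
        }
        L = self.loadings.abs()
        labels = {}
        taken = set()
        # greedy: strongest block affinity first
        scores = []
        for fac in self.loadings.columns:
            for lab, cols in blocks.items():
                cols = [c for c in cols if c in L.index]
                if cols:
                    scores.append((L.loc[cols, fac].mean(), fac, lab))
        for s, fac, lab in sorted(scores, reverse=True):
            if fac not in labels and lab not in taken:
                labels[fac] = lab
                taken.add(lab)
        for fac in self.loadings.columns:  # leftovers keep their index name
            labels.setdefault(fac, fac)
        return labels

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Factor analysis of call acoustic parameters",
            f"  observations: {self.n_obs} (dropped incomplete: {self.n_dropped})",
            f"  Bartlett chi2 = {d.bartlett_chi2:.1f}, df = {d.bartlett_df}, "
            f"p = {d.bartlett_p:.3g};  KMO = {d.kmo:.3f}",
            f"  factors retained (eigenvalue > 1): {self.n_factors}",
            f"  variance explained: "
            + ", ".join(f"{v:.1f}%" for v in self.variance_explained)
            + f"  (total {self.variance_explained.sum():.1f}%)",
            "", self.loadings.round(2).to_string(),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        payload = {
            "columns": self.columns,
            "loadings": self.loadings.to_dict(),
            "eigenvalues": list(map(float, self.eigenvalues)),
            "n_factors": int(self.n_factors),
            "variance_explained": list(map(float, self.variance_explained)),
            "diagnostics": dict(self.diagnostics._asdict()),
            "means": list(map(float, self._means)),
            "sds": list(map(float, self._sds)),
            "transforms": (self.model.transform_spec.to_dict()
                           if self.model and self.model.transform_spec else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class CallFactorAnalysis:
    """Exploratory factor analysis model for a call-feature table.

    Parameters
    ----------
    data : DataFrame of transformed acoustic parameters (rows = calls).
    transform_spec : optional TransformSpec applied before fitting (use
        :meth:`from_features` to start from raw features with the default
        transform map).
    min_eigenvalue : retention threshold on correlation-matrix eigenvalues.
    """

    def __init__(self, data: pd.DataFrame, transform_spec: TransformSpec | None = None,
                 min_eigenvalue: float = 1.0, columns=None):
        self.transform_spec = transform_spec
        if transform_spec is not None:
            transform_spec.fit(data)
            data = apply_transforms(data, transform_spec)
        self.columns = list(columns or data.columns)
        self.data = data[self.columns]
        self.min_eigenvalue = min_eigenvalue

    @classmethod
    def from_features(cls, features: pd.DataFrame, **kw) -> "CallFactorAnalysis":
        """Build from a raw call-feature table using the default transforms."""
        spec = TransformSpec.default()
        cols = [c for c in DEFAULT_TRANSFORMS if c in features.columns]
        missing = set(DEFAULT_TRANSFORMS) - set(cols)
        if missing:
            raise KeyError(f"feature table lacks parameters: {sorted(missing)}")
        return cls(features[cols], transform_spec=spec, **kw)

    def fit(self) -> FactorAnalysisResults:
        complete = self.data.dropna()
        n_dropped = len(self.data) - len(complete)
        if n_dropped:
            logger.info("dropping %d incomplete calls before factor analysis",
                        n_dropped)
        X = complete.to_numpy(dtype=float)
        n, p = X.shape
        if n < p + 1:
            raise ModelError(f"need at least {p + 1} complete rows, got {n}")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            zero = [c for c, s in zip(self.columns, sds) if s == 0]
            raise DataError(f"constant parameters cannot be factored: {zero}")
        R = np.corrcoef(X, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        k = int((eigval > self.min_eigenvalue).sum())
        if k == 0:
            raise ModelError("no eigenvalue exceeds the retention threshold")
        L = eigvec[:, :k] * np.sqrt(eigval[:k])
        Lrot = varimax(L) if k > 1 else L
        # order rotated factors by explained variance, sign so each column's
        # largest loading is positive
        ss = (Lrot ** 2).sum(axis=0)
        order = np.argsort(ss)[::-1]
        Lrot = Lrot[:, order]
        for j in range(k):
            if Lrot[np.abs(Lrot[:, j]).argmax(), j] < 0:
                Lrot[:, j] *= -1
        loadings = pd.DataFrame(
            Lrot, index=self.columns,
            columns=[f"factor_{j+1}" for j in range(k)])
        diagnostics = sampling_adequacy(complete)
        return FactorAnalysisResults(
            self, loadings, eigval, k, self.columns, means, sds, R,
            diagnostics, n, n_dropped)


def fit_factor_model(table: pd.DataFrame, **kw) -> FactorAnalysisResults:
    """Functional wrapper around :class:`CallFactorAnalysis`."""
    return CallFactorAnalysis(table, **kw).fit()


def factor_scores(table: pd.DataFrame, model: FactorAnalysisResults) -> pd.DataFrame:
    """Regression-method factor scores of ``table`` under ``model``."""
    return model.score(table)
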