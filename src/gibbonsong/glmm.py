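"""Mixed models linking factor scores to androgens, status and age.

For each acoustic factor score a Gaussian linear mixed model is fitted
with fixed effects for male status (pair-living primary as reference),
age class (adult vs senior), the between-male and within-male androgen
terms, and a temporal-autocorrelation covariate; random intercepts for
group, male, recording date within male and song (a fully nested
hierarchy: group > male > date > song), and a random slope of the
within-centred androgen term by male (uncorrelated with the intercept by
default).

The autocorrelation covariate absorbs day-scale dependence the random
effects cannot: for each observation it is the Gaussian-kernel weighted
average of the *other* residuals of the same male (weights
exp(-(dt)^2 / (2 sigma^2)) on the continuous call-time axis), z-scored
before entering the model.  The kernel bandwidth sigma is chosen to
maximize the ML likelihood of the refitted full model: a log-spaced grid
over the observable lag range followed by golden-section refinement.

P-values for fixed effects come from a parametric bootstrap of the
likelihood-ratio statistic (default), with asymptotic LRT and Wald
alternatives for large simulation studies; p-values are adjusted across
the six factor-score models per predictor with Simes' step-up method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

__all__ = [
    "build_ac_term",
    "AcousticMixedModel",
    "AcousticMixedModelResults",
    "fit_with_ac",
    "simes_adjust",
    "test_fixed_effects",
    "loso_stability",
]

PREDICTORS = ("androgen_between", "androgen_within", "age", "status", "ac_term")


class ParameterError(ValueError):
    pass


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# autocorrelation term
# ---------------------------------------------------------------------------

def build_ac_term(residuals, times, male_ids, sigma: float,
                  exclude_blocks=None):
    """Per-observation weighted average of the same male's other residuals.

    AC_i = sum_{j != i, male(j) = male(i)} w_ij r_j / sum w_ij with
    w_ij = exp(-(t_i - t_j)^2 / (2 sigma^2)); times are continuous (days).

    ``exclude_blocks`` optionally gives a block label per observation
    (e.g. the recording date); observations sharing a block are then
    excluded from each other's average.  This is how the term enters the
    mixed models here: same-day dependence is already carried by the date
    and song random intercepts, and a same-day leave-one-out average is
    an affine function of the observation's own residual given the day
    total, which lets the likelihood grow without bound once a per-date
    intercept can absorb the remainder.

    Observations with no admissible partner (single-observation males, or
    no partner outside the block) get AC = 0 and are flagged.  Returns
    ``(values, flags)``.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    r = np.asarray(residuals, dtype=float)
    t = np.asarray(times, dtype=float)
    males = np.asarray(male_ids)
    blocks = None if exclude_blocks is None else np.asarray(exclude_blocks)
    out = np.zeros(len(r))
    flags = np.zeros(len(r), dtype=bool)
    for m in pd.unique(males):
        idx = np.where(males == m)[0]
        if len(idx) == 1:
            flags[idx] = True
            continue
        tm = t[idx]
        w = np.exp(-((tm[:, None] - tm[None, :]) ** 2) / (2.0 * sigma * sigma))
        np.fill_diagonal(w, 0.0)
        if blocks is not None:
            bm = blocks[idx]
            w[bm[:, None] == bm[None, :]] = 0.0
        sw = w.sum(axis=1)
        vals = np.zeros(len(idx))
        ok = sw > 0
        vals[ok] = (w @ r[idx])[ok] / sw[ok]
        # zero weight sum (no partner, or lags >> sigma): no information
        out[idx] = vals
        flags[idx[~ok]] = True
    return out, flags


def _ztrans(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ModelError("autocorrelation term is constant; cannot z-transform")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class AcousticMixedModelResults:
    """Estimates, uncertainties and diagnostics of one fitted model."""

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues_wald: pd.Series
    cov_params: pd.DataFrame
    vcomp: pd.Series               # named variance components + group var, scale
    llf: float                     # of the final fit (REML by default)
    ml_llf: float                  # ML log-likelihood at sigma_hat
    sigma_hat: float | None        # days; None if no AC term
    converged: bool
    ac_constrained: bool           # sigma chosen on the positive-coefficient profile
    resid: np.ndarray              # conditional residuals of the final fit
    data: pd.DataFrame = field(repr=False)       # with ac_term column
    term_columns: dict = field(repr=False)       # predictor -> design columns
    model: "AcousticMixedModel" = field(repr=False, default=None)
    ac_profile: pd.DataFrame | None = field(repr=False, default=None)
    ac_singletons: int = 0

    def wald_test_term(self, predictor: str) -> tuple:
        """(statistic, df, p) for the joint Wald test of one predictor."""
        cols = self.term_columns.get(predictor, [])
        if not cols:
            return np.nan, 0, np.nan
        theta = self.params[cols].to_numpy()
        V = self.cov_params.loc[cols, cols].to_numpy()
        stat = float(theta @ np.linalg.solve(V, theta))
        df = len(cols)
        return stat, df, float(stats.chi2.sf(stat, df))

    def summary(self) -> str:
        lines = [
            f"Mixed model for {self.response!r} "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  n = {len(self.data)}; log-likelihood = {self.llf:.2f}"
            + (f"; sigma_hat = {self.sigma_hat:.3f} days"
               if self.sigma_hat is not None else ""),
            "  fixed effects (estimate, SE, Wald p):",
        ]
        for name in self.params.index:
            lines.append(f"    {name:<45s} {self.params[name]:+9.4f} "
                         f"{self.bse[name]:8.4f}  {self.pvalues_wald[name]:.4f}")
        lines.append("  variance components:")
        for name, v in self.vcomp.items():
            lines.append(f"    {name:<30s} {v:10.5f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class AcousticMixedModel:
    """One factor-score response against androgens, status and age.

    Parameters
    ----------
    data : observation table with columns ``response``, androgen_between,
        androgen_within, status, age_class, group_id, male_id, date,
        song_id, time_days.
    response : name of the response column.
    include_ac : add the Gaussian-kernel autocorrelation term with its
        likelihood-maximizing bandwidth.
    sigma_grid_size : log-spaced candidate bandwidths between the
        smallest positive within-male lag and the study span.
    refine_tol : absolute golden-section tolerance on sigma (days).
    random_slope : include the by-male random slope of androgen_within.
    slope_corr : allow intercept-slope correlation (off by default; few
        subjects carry little information about it).
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 include_ac: bool = True, sigma_grid_size: int = 25,
                 refine_tol: float = 1e-3, random_slope: bool = True,
                 slope_corr: bool = False, exclude_subadults: bool = True,
                 status_ref: str = "pair_primary", age_ref: str = "adult"):
        d = data.copy()
        if exclude_subadults and "age_class" in d:
            d = d[d["age_class"] != "subadult"]
        d = d.dropna(subset=[response, "androgen_between", "androgen_within"])
        self.data = d.reset_index(drop=True)
        if len(self.data) < 10:
            raise ModelError("too few complete observations")
        self.response = response
        self.include_ac = include_ac
        self.sigma_grid_size = sigma_grid_size
        self.refine_tol = refine_tol
        self.random_slope = random_slope
        self.slope_corr = slope_corr
        self.status_ref = status_ref
        self.age_ref = age_ref
        self._build_terms()

    def _build_terms(self):
        d = self.data
        self.fixed_terms = {}
        if d["status"].nunique() > 1:
            self.fixed_terms["status"] = (
                f"C(status, Treatment('{self.status_ref}'))")
        else:
            logger.warning("status has a single level; predictor dropped")
        if d["age_class"].nunique() > 1:
            self.fixed_terms["age"] = (
                f"C(age_class, Treatment('{self.age_ref}'))")
        else:
            logger.warning("age_class has a single level; predictor dropped")
        self.fixed_terms["androgen_between"] = "androgen_between"
        self.fixed_terms["androgen_within"] = "androgen_within"

    def _formula(self, with_ac: bool, drop: str | None = None) -> str:
        rhs = [t for name, t in self.fixed_terms.items() if name != drop]
        if with_ac and drop != "ac_term":
            rhs.append("ac_term")
        return f"{self.response} ~ " + " + ".join(rhs)

    def _vc(self) -> dict:
        vc = {"male": "0 + C(male_id)", "date": "0 + C(date)",
              "song": "0 + C(song_id)"}
        if self.random_slope and not self.slope_corr:
            vc["slope"] = "0 + C(male_id):androgen_within"
        return vc

    DROP_LADDER = [(), ("slope",), ("slope", "song"),
                   ("slope", "song", "date"),
                   ("slope", "song", "date", "male")]

    def _fit_formula(self, formula: str, data: pd.DataFrame, reml: bool,
                     require_se: bool = True, forced_drop=None):
        re_formula = "1"
        if self.random_slope and self.slope_corr:
            re_formula = "1 + androgen_within"
        # variance components estimated on the zero boundary leave the
        # observed information singular; retry with the degenerate
        # component(s) removed (constrained fit at the boundary optimum)
        vc_full = self._vc()
        if forced_drop is not None:
            start = self.DROP_LADDER.index(tuple(forced_drop))
            drop_ladder = self.DROP_LADDER[start:]
        else:
            drop_ladder = self.DROP_LADDER
        last_err = None
        fallback = None
        for drop in drop_ladder:
            vc = {k: v for k, v in vc_full.items() if k not in drop}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = None
                for method in ("lbfgs", "powell"):
                    try:
                        model = smf.mixedlm(formula, data,
                                            groups=data["group_id"],
                                            re_formula=re_formula,
                                            vc_formula=vc or None)
                        res = model.fit(reml=reml, method=[method],
                                        maxiter=200)
                        if require_se and not res.converged:
                            # warm restart frequently repairs premature
                            # optimizer stops on the vc parameterization
                            # (profiling fits skip this: llf differences
                            # at a premature stop are immaterial there)
                            res2 = model.fit(reml=reml, method=[method],
                                             maxiter=500,
                                             start_params=res.params_object)
                            if np.isfinite(res2.llf) and res2.llf >= res.llf:
                                res = res2
                        break
                    except (np.linalg.LinAlgError, ValueError) as exc:
                        last_err = exc
                if res is None:
                    continue
                # boundary estimates can leave the information matrix
                # indefinite: fixed-effect SEs come out NaN; when SEs are
                # needed, treat as a failed fit and simplify further.
                # Likelihood-only fits (sigma profiling, LR tests) keep the
                # full structure so log-likelihoods stay comparable.
                if require_se and np.isnan(
                        np.asarray(res.bse_fe, dtype=float)).any():
                    if fallback is None:
                        model.vc_drop_used = drop
                        fallback = (model, res)
                    last_err = ModelError("indefinite information matrix")
                    continue
            if drop:
                logger.debug("dropped boundary components %s for %r",
                             drop, formula)
            model.vc_drop_used = drop
            return model, res
        if fallback is not None:
            # converged point estimates with unusable SEs beat no fit
            logger.warning("returning fit with indefinite information "
                           "matrix for %r", formula)
            return fallback
        raise ModelError(f"mixed-model fit failed: {last_err}")

    # -- sigma search -------------------------------------------------------

    def _loglike_at_sigma(self, sigma: float, resid0, cache: dict):
        key = round(float(sigma), 9)
        if key in cache:
            return cache[key]
        d = self.data
        ac, _ = build_ac_term(resid0, d["time_days"], d["male_id"], sigma,
                              exclude_blocks=d["date"])
        try:
            dat = d.assign(ac_term=_ztrans(ac))
            _, res = self._fit_formula(self._formula(True), dat, reml=False,
                                       require_se=False)
            llf = float(res.llf) if res.converged or np.isfinite(res.llf) else -np.inf
            # Guard against the degenerate wide-bandwidth solution: as the
            # kernel flattens, the average of a male's *other* centred
            # residuals tends to -r_i/(n-1), a proxy for the observation's
            # own residual.  The likelihood rewards that self-cancellation
            # with a negative coefficient although it models no temporal
            # dependence; only bandwidths where the term enters with the
            # positive sign of genuine autocorrelation are admissible.
            if (not getattr(self, "_allow_negative_ac", False)
                    and "ac_term" in res.fe_params
                    and res.fe_params["ac_term"] <= 0):
                llf = -np.inf
        except (ModelError, np.linalg.LinAlgError, ValueError):
            logger.warning("sigma = %.4g skipped (fit failed)", sigma)
            llf = -np.inf
        cache[key] = llf
        return llf

    def _sigma_bounds(self):
        # day-level lags: same-date pairs are excluded from the kernel, so
        # the smallest informative bandwidth is the smallest between-day lag
        d = self.data
        t = d["time_days"].to_numpy(dtype=float)
        lags = []
        for _, sub in d.groupby("male_id"):
            day_t = np.sort(sub.groupby("date")["time_days"].mean().to_numpy())
            dl = np.diff(day_t)
            lags.extend(dl[dl > 0])
        lo = max(min(lags) / 4.0, 1e-3) if lags else 1e-2
        hi = max(t.max() - t.min(), lo * 10)
        return lo, hi

    def _search_sigma(self, resid0):
        lo, hi = self._sigma_bounds()
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), self.sigma_grid_size))
        self._allow_negative_ac = False
        cache: dict = {}
        lls = np.array([self._loglike_at_sigma(s, resid0, cache) for s in grid])
        if not np.isfinite(lls).any():
            # no bandwidth gives a positive-signed term (e.g. independent
            # residuals); fall back to the unconstrained profile
            logger.info("no positive-coefficient bandwidth; "
                        "using unconstrained likelihood profile")
            self._allow_negative_ac = True
            cache = {}
            lls = np.array([self._loglike_at_sigma(s, resid0, cache)
                            for s in grid])
        if not np.isfinite(lls).any():
            raise ModelError("likelihood evaluation failed at every sigma")
        best = int(np.nanargmax(lls))
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, len(grid) - 1)]
        sigma_hat = _golden_max(
            lambda s: self._loglike_at_sigma(s, resid0, cache),
            a, b, tol=self.refine_tol)
        profile = pd.DataFrame({"sigma": list(cache), "llf": [cache[k] for k in cache]})
        return float(sigma_hat), profile.sort_values("sigma").reset_index(drop=True)

    # -- public fit ---------------------------------------------------------

    def fit(self, reml_final: bool = True, sigma: float | None = None
            ) -> AcousticMixedModelResults:
        """Fit the model; if ``include_ac``, first find the bandwidth.

        Stage 1 fits the model without the AC term (ML) and takes its
        conditional residuals; stage 2 profiles the ML likelihood over
        the kernel bandwidth; stage 3 refits at the best bandwidth, with
        REML for the final variance components.
        """
        d = self.data
        ac_profile = None
        sigma_hat = None
        n_singletons = 0
        if self.include_ac:
            model0, res0 = self._fit_formula(self._formula(False), d,
                                             reml=False, require_se=False)
            # residuals for the AC term: fixed-effect (marginal) residuals.
            # Conditional residuals would have the day- and song-scale
            # structure absorbed into the date/song BLUPs already, and
            # centring per male would make the average of a male's other
            # residuals a mechanical proxy for -(own residual) — both
            # destroy or fake the temporal signal the kernel is after.
            resid0 = np.asarray(model0.endog) - np.asarray(
                model0.exog @ res0.fe_params)
            if sigma is None:
                sigma_hat, ac_profile = self._search_sigma(resid0)
            else:
                sigma_hat = float(sigma)
            ac, flags = build_ac_term(resid0, d["time_days"], d["male_id"],
                                      sigma_hat, exclude_blocks=d["date"])
            n_singletons = int(flags.sum())
            d = d.assign(ac_term=_ztrans(ac))
            self.data = d
        formula = self._formula(self.include_ac)
        model_ml, res_ml = self._fit_formula(formula, d, reml=False)
        if reml_final:
            model_f, res_f = self._fit_formula(formula, d, reml=True)
        else:
            model_f, res_f = model_ml, res_ml

        fe_names = list(model_f.exog_names)
        term_columns = {name: [c for c in fe_names if _belongs(c, name, term)]
                        for name, term in self.fixed_terms.items()}
        if self.include_ac:
            term_columns["ac_term"] = [c for c in fe_names if c == "ac_term"]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bse_fe = res_f.bse_fe
            covp = np.asarray(res_f.cov_params())
        fe = res_f.fe_params
        try:  # conditional residuals; marginal if BLUPs are unavailable
            final_resid = np.asarray(res_f.resid)
        except (ValueError, np.linalg.LinAlgError):
            final_resid = np.asarray(model_f.endog) - np.asarray(
                model_f.exog @ fe)
        vnames = list(model_f.exog_vc.names) if model_f.exog_vc is not None else []
        vcomp = pd.Series(
            {**{f"var_{n}": v for n, v in zip(vnames, np.atleast_1d(res_f.vcomp))},
             "var_group": float(np.atleast_2d(res_f.cov_re)[0, 0])
             if res_f.cov_re.size else 0.0,
             "var_residual": float(res_f.scale)})
        self._last_model = model_f
        return AcousticMixedModelResults(
            response=self.response,
            params=fe,
            bse=bse_fe,
            pvalues_wald=pd.Series(
                2 * stats.norm.sf(np.abs(fe / bse_fe)), index=fe.index),
            cov_params=pd.DataFrame(covp[:len(fe), :len(fe)],
                                    index=fe.index, columns=fe.index),
            vcomp=vcomp,
            llf=float(res_f.llf),
            ml_llf=float(res_ml.llf),
            sigma_hat=sigma_hat,
            converged=bool(res_f.converged),
            ac_constrained=not getattr(self, "_allow_negative_ac", False),
            resid=final_resid,
            data=d,
            term_columns=term_columns,
            model=self,
            ac_profile=ac_profile,
            ac_singletons=n_singletons,
        )

    # -- inference ----------------------------------------------------------

    def lrt_pvalue(self, predictor: str) -> tuple:
        """Asymptotic likelihood-ratio p for dropping one predictor (ML).

        Both models must carry the same random-effects structure for the
        log-likelihoods to be comparable; if numerical fallbacks simplified
        one of them, both are refitted at the common (more reduced) level.
        """
        full_m, full = self._fit_formula(self._formula(self.include_ac),
                                         self.data, reml=False,
                                         require_se=False)
        red_m, reduced = self._fit_formula(
            self._formula(self.include_ac, drop=predictor), self.data,
            reml=False, require_se=False)
        d_full = getattr(full_m, "vc_drop_used", ())
        d_red = getattr(red_m, "vc_drop_used", ())
        if d_full != d_red:
            common = max((d_full, d_red), key=len)
            full = self._fit_formula(
                self._formula(self.include_ac), self.data, reml=False,
                require_se=False, forced_drop=common)[1]
            reduced = self._fit_formula(
                self._formula(self.include_ac, drop=predictor), self.data,
                reml=False, require_se=False, forced_drop=common)[1]
        df = len(full.fe_params) - len(reduced.fe_params)
        lr = max(0.0, 2.0 * (full.llf - reduced.llf))
        return lr, df, float(stats.chi2.sf(lr, df))

    def bootstrap_pvalue(self, predictor: str, n_boot: int = 1000,
                         seed: int = 0, max_fail: float = 0.1) -> tuple:
        """Parametric-bootstrap LR p-value for one predictor.

        Simulates responses from the reduced (null) model's estimates —
        fixed effects plus fresh draws of every random effect and the
        residual — then refits null and full models on each simulated
        response.  Ties counted conservatively; the observed statistic is
        included in the reference set.
        """
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        lr_obs, df, _ = self.lrt_pvalue(predictor)
        null_formula = self._formula(self.include_ac, drop=predictor)
        model_null, res_null = self._fit_formula(null_formula, self.data,
                                                 reml=False, require_se=False)
        mu = np.asarray(model_null.exog @ res_null.fe_params)
        d = self.data
        vnames = list(model_null.exog_vc.names) if model_null.exog_vc is not None else []
        vvar = dict(zip(vnames, np.atleast_1d(res_null.vcomp)))
        g_var = float(np.atleast_2d(res_null.cov_re)[0, 0]) if res_null.cov_re.size else 0.0
        scale = float(res_null.scale)

        group_codes = d["group_id"].astype("category").cat.codes.to_numpy()
        male_codes = d["male_id"].astype("category").cat.codes.to_numpy()
        date_codes = d["date"].astype("category").cat.codes.to_numpy()
        song_codes = d["song_id"].astype("category").cat.codes.to_numpy()
        aw = d["androgen_within"].to_numpy(dtype=float)

        n_fail = 0
        count_ge = 0
        n_done = 0
        for b in range(n_boot):
            y = mu.copy()
            y += np.sqrt(g_var) * rng.standard_normal(group_codes.max() + 1)[group_codes]
            if "male" in vvar:
                y += np.sqrt(vvar["male"]) * rng.standard_normal(male_codes.max() + 1)[male_codes]
            if "date" in vvar:
                y += np.sqrt(vvar["date"]) * rng.standard_normal(date_codes.max() + 1)[date_codes]
            if "song" in vvar:
                y += np.sqrt(vvar["song"]) * rng.standard_normal(song_codes.max() + 1)[song_codes]
            if "slope" in vvar:
                y += (np.sqrt(vvar["slope"])
                      * rng.standard_normal(male_codes.max() + 1)[male_codes]) * aw
            y += np.sqrt(scale) * rng.standard_normal(len(y))
            sim = d.assign(**{self.response: y})
            try:
                # design (incl. any ac_term column) is held fixed under the null
                sim_model = AcousticMixedModel(
                    sim, self.response, include_ac=False,
                    random_slope=self.random_slope, slope_corr=self.slope_corr,
                    exclude_subadults=False)
                lr_b = _boot_lrt(sim_model, self.include_ac, predictor)
            except (ModelError, np.linalg.LinAlgError, ValueError):
                n_fail += 1
                continue
            n_done += 1
            if lr_b >= lr_obs:
                count_ge += 1
        if n_boot and n_fail / n_boot > max_fail:
            logger.warning("bootstrap non-convergence rate %.0f%% exceeds %0.f%%",
                           100 * n_fail / n_boot, 100 * max_fail)
        p = (1 + count_ge) / (n_done + 1) if n_done else np.nan
        return lr_obs, df, float(p)


def _boot_lrt(model: "AcousticMixedModel", with_ac: bool, predictor: str) -> float:
    full = model._fit_formula(model._formula(with_ac), model.data,
                              reml=False, require_se=False)[1]
    red = model._fit_formula(model._formula(with_ac, drop=predictor),
                             model.data, reml=False, require_se=False)[1]
    return max(0.0, 2.0 * (full.llf - red.llf))


def _belongs(col: str, name: str, term: str) -> bool:
    if name == "status":
        return col.startswith("C(status")
    if name == "age":
        return col.startswith("C(age_class")
    return col == term


def _golden_max(f, a: float, b: float, tol: float = 1e-3, max_iter: int = 60) -> float:
    """Golden-section maximization of ``f`` on [a, b] to absolute ``tol``."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    it = 0
    while (b - a) > tol and it < max_iter:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        it += 1
    return (a + b) / 2.0


def fit_with_ac(data: pd.DataFrame, response: str, **kw) -> AcousticMixedModelResults:
    """Functional wrapper around :class:`AcousticMixedModel`."""
    return AcousticMixedModel(data, response, **kw).fit()


# ---------------------------------------------------------------------------
# multiple testing and reporting
# ---------------------------------------------------------------------------

def simes_adjust(pvals) -> np.ndarray:
    """Simes step-up adjusted p-values.

    For ordered p_(1) <= ... <= p_(m): adj_(i) = min_{j >= i} (m/j) p_(j),
    capped at 1; monotone non-decreasing by construction.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def test_fixed_effects(fits: dict, method: str = "boot", n_boot: int = 1000,
                       seed: int = 0,
                       predictors=("androgen_between", "androgen_within",
                                   "age", "status")) -> pd.DataFrame:
    """Per-predictor raw and Simes-adjusted p across all factor models.

    ``fits`` maps factor labels to :class:`AcousticMixedModelResults`.
    Adjustment is applied across the models (m = number of responses)
    separately for each predictor.  Direction markers come from estimate
    signs (single-df predictors) or the adult-vs-senior contrast.
    """
    rows = {}
    for label, res in fits.items():
        row = {}
        for k, pred in enumerate(predictors):
            if pred not in res.term_columns or not res.term_columns[pred]:
                row[f"p_{pred}"] = np.nan
                row[f"dir_{pred}"] = ""
                continue
            if method == "wald":
                _, _, p = res.wald_test_term(pred)
            elif method == "lrt":
                _, _, p = res.model.lrt_pvalue(pred)
            elif method == "boot":
                _, _, p = res.model.bootstrap_pvalue(
                    pred, n_boot=n_boot,
                    seed=(seed * 1009 + 97 * k + hash(label) % 1000) & 0x7FFFFFFF)
            else:
                raise ValueError(f"unknown method {method!r}")
            row[f"p_{pred}"] = p
            cols = res.term_columns[pred]
            if pred == "age":
                est = res.params[cols[0]]
                row[f"dir_{pred}"] = "A>S" if est < 0 else "S>A"
            elif len(cols) == 1:
                row[f"dir_{pred}"] = "up" if res.params[cols[0]] > 0 else "down"
            else:
                row[f"dir_{pred}"] = ""
        rows[label] = row
    table = pd.DataFrame(rows).T
    for pred in predictors:
        col = f"p_{pred}"
        raw = table[col].astype(float)
        ok = raw.notna()
        adj = raw.copy()
        if ok.any():
            adj[ok] = simes_adjust(raw[ok].to_numpy())
        table[f"p_adj_{pred}"] = adj
    return table


def loso_stability(data: pd.DataFrame, response: str, **model_kw) -> pd.DataFrame:
    """Leave-one-male-out refits: estimate range per fixed effect.

    Returns a DataFrame indexed by excluded male with one column per
    fixed effect, plus summary rows ``min``, ``max`` and ``spread``.
    Failed refits are recorded as missing, not fatal.
    """
    males = sorted(data["male_id"].unique())
    rows = {}
    for m in males:
        sub = data[data["male_id"] != m]
        try:
            res = AcousticMixedModel(sub, response, **model_kw).fit()
            rows[m] = res.params
        except Exception as exc:  # refit failure is reported, not raised
            logger.warning("LOSO refit without %s failed: %s", m, exc)
            rows[m] = pd.Series(dtype=float)
    table = pd.DataFrame(rows).T
    summary = pd.DataFrame(
        {"min": table.min(), "max": table.max(),
         "spread": table.max() - table.min()}).T
    return pd.concat([table, summary])
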