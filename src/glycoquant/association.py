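"""Confounder-screened, imputation-pooled association pipeline.

Implements the inference chain used to relate the percent-glycophorin
exposure (in SD units after inverse-rank transformation) to binary plaque
outcomes and a censored 3-year composite endpoint:

* **screening** — a baseline covariate is a potential confounder when it is
  associated both with the plaque-size-adjusted exposure and with the
  outcome, each at p < 0.1;
* **imputation** — missing covariate cells are filled by chained equations
  with predictive-mean matching, m completed copies;
* **models** — Model 1 adjusts for plaque size only, Model 2 additionally
  for the screened confounders; logistic regression for binary outcomes,
  Cox proportional hazards for the composite endpoint, effects reported per
  1-SD increment of the exposure; estimates across imputations are pooled
  with Rubin's rules;
* **AIC selection** — among correlated candidate adjustment sets the model
  with the smallest Akaike information criterion wins, ties going to the
  smaller model;
* **stratification** — main fits are repeated within men and women;
* **recovery harness** — repeats generate → (mask → impute) → fit over many
  replicates and reports bias, spread and CI coverage per effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .cohort import CohortGenerator, GeneratorConfig, inject_missingness
from .stats_core import irnt_values

logger = logging.getLogger(__name__)

EXPOSURE = "glyc_sd"
PLAQUE = "plaque_sd"

#: Adjustment set used for correctly specified (Model 2) fits on generated
#: cohorts: every variable with a direct effect on outcomes in the generator.
DEFAULT_ADJUSTMENT = ("age", "sex", "smoking", "hypertension", "egfr")


class ModelFitError(RuntimeError):
    """Raised when a fit is unusable (separation, no events, non-convergence)."""


# ---------------------------------------------------------------------------
# design-matrix helpers


def _design(df: pd.DataFrame, terms: list[str], add_const: bool = True) -> pd.DataFrame:
    """Numeric design matrix; categorical/string terms expand to dummies."""
    cols = {}
    for t in terms:
        x = df[t]
        if pd.api.types.is_numeric_dtype(x):
            cols[t] = x.astype(float)
        else:
            dummies = pd.get_dummies(x, prefix=t, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
    X = pd.DataFrame(cols, index=df.index)
    if add_const:
        X.insert(0, "const", 1.0)
    return X


# ---------------------------------------------------------------------------
# confounder screening


@dataclass
class ScreenResult:
    covariate: str
    p_vs_exposure: float
    p_vs_outcome: float
    selected: bool
    alpha_screen: float = 0.1


def _select_rule(p_exposure: float, p_outcome: float, alpha: float) -> bool:
    """Double screening rule: keep iff both associations reach p < alpha."""
    return bool(p_exposure < alpha and p_outcome < alpha)


def _candidate_block_p_ols(df: pd.DataFrame, candidate: str) -> float:
    """p-value of the candidate block in OLS of exposure on candidate + plaque size."""
    sub = df[[EXPOSURE, PLAQUE, candidate]].dropna()
    X = _design(sub, [candidate, PLAQUE])
    cand_cols = [c for c in X.columns if c == candidate or c.startswith(f"{candidate}_")]
    res = sm.OLS(sub[EXPOSURE].astype(float), X).fit()
    if len(cand_cols) == 1:
        return float(res.pvalues[cand_cols[0]])
    contrast = np.zeros((len(cand_cols), X.shape[1]))
    for i, c in enumerate(cand_cols):
        contrast[i, list(X.columns).index(c)] = 1.0
    return float(res.f_test(contrast).pvalue)


def _candidate_p_outcome(df: pd.DataFrame, candidate: str, outcome: str, family: str) -> float:
    """Univariable association p of candidate with the outcome."""
    if family == "logistic":
        sub = df[[outcome, candidate]].dropna()
        X = _design(sub, [candidate])
        cand_cols = [c for c in X.columns if c != "const"]
        res = sm.Logit(sub[outcome].astype(float), X).fit(disp=0, maxiter=200)
        if len(cand_cols) == 1:
            return float(res.pvalues[cand_cols[0]])
        contrast = np.zeros((len(cand_cols), X.shape[1]))
        for i, c in enumerate(cand_cols):
            contrast[i, list(X.columns).index(c)] = 1.0
        return float(res.wald_test(contrast, scalar=True).pvalue)
    if family == "cox":
        sub = df[["mace_time", "mace_event", candidate]].dropna()
        X = _design(sub, [candidate], add_const=False)
        cand_cols = list(X.columns)
        full = pd.concat([X, sub[["mace_time", "mace_event"]]], axis=1)
        cph = CoxPHFitter().fit(full, duration_col="mace_time", event_col="mace_event")
        null = CoxPHFitter().fit(
            sub[["mace_time", "mace_event"]].assign(_z=0.0),
            duration_col="mace_time",
            event_col="mace_event",
        )
        lr = 2.0 * (cph.log_likelihood_ - null.log_likelihood_)
        return float(stats.chi2.sf(max(lr, 0.0), df=len(cand_cols)))
    raise ValueError("family must be 'logistic' or 'cox'")


def screen_confounders(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    family: str = "logistic",
    alpha: float = 0.1,
) -> list[ScreenResult]:
    """Double-rule confounder screen on complete cases per candidate.

    Exposure-side test: linear model of the SD-unit exposure on the
    candidate plus SD-unit plaque size (candidate block p).  Outcome-side
    test: univariable logistic (or Cox for the time-to-event endpoint).
    Constant candidates are excluded with a logged warning.
    """
    forbidden = {EXPOSURE, PLAQUE, outcome, "percent_glyc", "plaque_size_um2"}
    results = []
    for cand in candidates:
        if cand in forbidden:
            raise ValueError(f"candidate {cand!r} overlaps exposure/outcome columns")
        if cohort[cand].dropna().nunique() < 2:
            logger.warning("candidate %r is constant; excluded from screening", cand)
            continue
        p_exp = _candidate_block_p_ols(cohort, cand)
        p_out = _candidate_p_outcome(cohort, cand, outcome, family)
        results.append(
            ScreenResult(
                covariate=cand,
                p_vs_exposure=p_exp,
                p_vs_outcome=p_out,
                selected=_select_rule(p_exp, p_out, alpha),
                alpha_screen=alpha,
            )
        )
    return results


# ---------------------------------------------------------------------------
# chained-equations imputation with predictive-mean matching


@dataclass
class ImputationSet:
    m: int
    completed_tables: list[pd.DataFrame]
    iterations: int
    seed: int


def _pmm_impute_column(
    work: pd.DataFrame,
    col: str,
    miss: np.ndarray,
    rng: np.random.Generator,
    n_donors: int = 5,
) -> None:
    """One chained-equation step: Bayesian linear draw + PMM for one column."""
    predictors = [c for c in work.columns if c != col]
    X = work[predictors].to_numpy(float)
    X = np.column_stack([np.ones(len(X)), X])
    y = work[col].to_numpy(float)
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    xtx = Xo.T @ Xo + 1e-6 * np.eye(X.shape[1])
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(len(yo) - X.shape[1], 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    beta_draw = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv, method="cholesky")
    yhat_obs = Xo @ beta_hat
    yhat_mis = X[miss] @ beta_draw
    order = np.argsort(yhat_obs)
    sorted_obs = yhat_obs[order]
    donors_y = yo[order]
    pos = np.searchsorted(sorted_obs, yhat_mis)
    imputed = np.empty(len(yhat_mis))
    k = min(n_donors, len(donors_y))
    for i, p in enumerate(pos):
        lo = int(np.clip(p - k // 2, 0, len(donors_y) - k))
        imputed[i] = donors_y[lo + rng.integers(k)]
    vals = work[col].to_numpy(float)
    vals[miss] = imputed
    work[col] = vals


def impute_chained(
    cohort: pd.DataFrame,
    m: int = 10,
    iterations: int = 20,
    seed: int = 0,
) -> ImputationSet:
    """Multiple imputation by chained equations with PMM draws.

    Each of the m chains runs its own seeded random stream; within a chain,
    columns with missing cells are visited ``iterations`` times, each visit
    refitting a linear model on the other columns (categoricals coded
    numerically) and imputing by predictive-mean matching with 5 donors, so
    imputed values are always observed values of the column.  Columns with
    more than 50% missing cells are rejected.
    """
    miss_frac = cohort.isna().mean()
    over = miss_frac[miss_frac > 0.5]
    if not over.empty:
        raise ValueError(f"columns with >50% missing cannot be imputed: {list(over.index)}")
    target_cols = [c for c in cohort.columns if cohort[c].isna().any()]
    if not target_cols:
        return ImputationSet(m=m, completed_tables=[cohort.copy() for _ in range(m)],
                             iterations=iterations, seed=seed)

    # numeric working copy: categoricals become integer codes
    codecs = {}
    numeric = pd.DataFrame(index=cohort.index)
    for c in cohort.columns:
        col = cohort[c]
        if pd.api.types.is_numeric_dtype(col):
            numeric[c] = col.astype(float)
        else:
            cat = col.astype("category")
            codecs[c] = cat.cat.categories
            codes = cat.cat.codes.astype(float)
            numeric[c] = codes.where(codes >= 0, np.nan)

    miss_masks = {c: numeric[c].isna().to_numpy() for c in target_cols}
    chains = np.random.SeedSequence(seed).spawn(m)
    completed = []
    for chain_seq in chains:
        rng = np.random.default_rng(chain_seq)
        work = numeric.copy()
        for c in target_cols:  # initialize from observed empirical distribution
            obs_vals = work[c].dropna().to_numpy()
            vals = work[c].to_numpy(float)
            vals[miss_masks[c]] = rng.choice(obs_vals, size=miss_masks[c].sum())
            work[c] = vals
        for _ in range(iterations):
            for c in target_cols:
                _pmm_impute_column(work, c, miss_masks[c], rng)
        out = cohort.copy()
        for c in target_cols:
            if c in codecs:
                codes = work[c].round().astype(int).clip(0, len(codecs[c]) - 1)
                out[c] = pd.Categorical.from_codes(codes, categories=codecs[c]).astype(str)
            else:
                filled = work[c].to_numpy()
                if pd.api.types.is_integer_dtype(cohort[c].dtype):
                    filled = np.round(filled)
                out[c] = filled
        completed.append(out)
    return ImputationSet(m=m, completed_tables=completed, iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# model fitting and Rubin pooling


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    family: str = "logistic"  # logistic | cox
    model_tier: str = "model2"  # model1 | model2
    exposure: str = EXPOSURE
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT
    strata: str = "all"  # all | men | women

    def terms(self) -> list[str]:
        base = [self.exposure, PLAQUE]
        if self.model_tier == "model2":
            base += [a for a in self.adjustment if a not in base]
        return base

    def validate(self) -> None:
        if self.family not in ("logistic", "cox"):
            raise ValueError("family must be 'logistic' or 'cox'")
        if self.model_tier not in ("model1", "model2"):
            raise ValueError("model_tier must be 'model1' or 'model2'")
        if self.strata not in ("all", "men", "women"):
            raise ValueError("strata must be all|men|women")


@dataclass
class ModelResult:
    """Per-term estimates on the log scale with ratios, CIs and p-values."""

    terms: pd.DataFrame  # index: term; columns: estimate, se, ratio, ci_low, ci_high, p
    family: str
    aic: float
    n_used: int
    pooled: bool = False
    stratum: str = "all"

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    @property
    def exposure_ratio(self) -> float:
        return float(self.terms.loc[EXPOSURE, "ratio"])


def _subset_for_stratum(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return df
    if "sex" not in df.columns:
        raise ValueError("stratified fit requires a 'sex' column")
    sex = "male" if stratum == "men" else "female"
    sub = df[df["sex"] == sex]
    if len(sub) < 50:
        warnings.warn(
            f"stratum {stratum!r} has only {len(sub)} subjects; fit attempted anyway",
            stacklevel=2,
        )
    return sub


def _terms_frame(params, ses, pvalues=None, dof=np.inf) -> pd.DataFrame:
    params = pd.Series(params)
    ses = pd.Series(ses, index=params.index)
    crit = stats.t.ppf(0.975, dof) if np.isfinite(dof) else stats.norm.ppf(0.975)
    if pvalues is None:
        tstat = params / ses
        if np.isfinite(dof):
            pvalues = 2 * stats.t.sf(np.abs(tstat), dof)
        else:
            pvalues = 2 * stats.norm.sf(np.abs(tstat))
    return pd.DataFrame(
        {
            "estimate": params,
            "se": ses,
            "ratio": np.exp(params),
            "ci_low": np.exp(params - crit * ses),
            "ci_high": np.exp(params + crit * ses),
            "p": np.asarray(pvalues, dtype=float),
        }
    )


def _fit_logistic_once(spec: ModelSpec, df: pd.DataFrame) -> ModelResult:
    cols = spec.terms() + [spec.outcome] + (["sex"] if spec.strata != "all" else [])
    sub = _subset_for_stratum(df[list(dict.fromkeys(cols))].dropna(), spec.strata)
    y = sub[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ModelFitError(f"outcome {spec.outcome!r} has a single level in this subset")
    strat_terms = [t for t in spec.terms() if not (spec.strata != "all" and t == "sex")]
    X = _design(sub, strat_terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes PerfectSeparationError
        raise ModelFitError(f"logistic fit failed for {spec.outcome!r}: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
        raise ModelFitError(f"separation or non-convergence for {spec.outcome!r}")
    terms = _terms_frame(res.params, res.bse, res.pvalues)
    return ModelResult(terms=terms, family="logistic", aic=float(res.aic),
                       n_used=int(res.nobs), stratum=spec.strata)


def _fit_cox_once(spec: ModelSpec, df: pd.DataFrame) -> ModelResult:
    cols = spec.terms() + ["mace_time", "mace_event"] + (
        ["sex"] if spec.strata != "all" else []
    )
    sub = _subset_for_stratum(df[list(dict.fromkeys(cols))].dropna(), spec.strata)
    if sub["mace_event"].sum() == 0:
        raise ModelFitError("no events observed; Cox model is not estimable")
    if (sub["mace_time"] <= 0).any():
        raise ModelFitError("event times must be positive")
    strat_terms = [t for t in spec.terms() if not (spec.strata != "all" and t == "sex")]
    X = _design(sub, strat_terms, add_const=False)
    data = pd.concat([X, sub[["mace_time", "mace_event"]]], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="mace_time", event_col="mace_event")
    except Exception as exc:
        raise ModelFitError(f"Cox fit failed: {exc}") from exc
    k = len(cph.params_)
    aic = 2.0 * k - 2.0 * cph.log_likelihood_
    terms = _terms_frame(cph.params_, cph.standard_errors_,
                         cph.summary["p"].to_numpy())
    return ModelResult(terms=terms, family="cox", aic=float(aic),
                       n_used=int(len(data)), stratum=spec.strata)


def _pool_rubin(results: list[ModelResult]) -> ModelResult:
    """Rubin's rules: combine within- and between-imputation variance."""
    m = len(results)
    index = results[0].terms.index
    q = np.stack([r.terms["estimate"].reindex(index).to_numpy() for r in results])
    u = np.stack([r.terms["se"].reindex(index).to_numpy() ** 2 for r in results])
    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    t = ubar + (1.0 + 1.0 / m) * b
    se = np.sqrt(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / ubar
        dof = np.where(b > 0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
    rows = []
    for i, term in enumerate(index):
        d = dof[i]
        crit = stats.t.ppf(0.975, d) if np.isfinite(d) else stats.norm.ppf(0.975)
        z = qbar[i] / se[i]
        p = 2 * (stats.t.sf(abs(z), d) if np.isfinite(d) else stats.norm.sf(abs(z)))
        rows.append((qbar[i], se[i], np.exp(qbar[i]), np.exp(qbar[i] - crit * se[i]),
                     np.exp(qbar[i] + crit * se[i]), p))
    terms = pd.DataFrame(
        rows, index=index,
        columns=["estimate", "se", "ratio", "ci_low", "ci_high", "p"],
    )
    return ModelResult(
        terms=terms,
        family=results[0].family,
        aic=float(np.mean([r.aic for r in results])),
        n_used=results[0].n_used,
        pooled=True,
        stratum=results[0].stratum,
    )


def fit_binary_model(spec: ModelSpec, data) -> ModelResult:
    """Per-1-SD logistic fit; ImputationSet input is pooled by Rubin's rules."""
    spec.validate()
    if spec.family != "logistic":
        raise ValueError("fit_binary_model requires a logistic ModelSpec")
    if isinstance(data, ImputationSet):
        fits = [_fit_logistic_once(spec, t) for t in data.completed_tables]
        return _pool_rubin(fits)
    return _fit_logistic_once(spec, data)


def fit_cox_model(spec: ModelSpec, data) -> ModelResult:
    """Per-1-SD proportional-hazards fit with the same pooling contract."""
    spec.validate()
    if spec.family != "cox":
        raise ValueError("fit_cox_model requires a cox ModelSpec")
    if isinstance(data, ImputationSet):
        fits = [_fit_cox_once(spec, t) for t in data.completed_tables]
        return _pool_rubin(fits)
    return _fit_cox_once(spec, data)


def fit_model(spec: ModelSpec, data) -> ModelResult:
    return fit_cox_model(spec, data) if spec.family == "cox" else fit_binary_model(spec, data)


def select_by_aic(candidate_specs: list[ModelSpec], data) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit all candidates and return the AIC argmin, ties to fewer parameters."""
    if len(candidate_specs) < 2:
        raise ValueError("need at least 2 candidate specifications")
    outcomes = {s.outcome for s in candidate_specs}
    if len(outcomes) > 1:
        raise ValueError("candidates must share one outcome")
    rows = []
    for s in candidate_specs:
        res = fit_model(s, data)
        rows.append((s, res.aic, len(res.terms)))
    table = pd.DataFrame(
        [(s.model_tier, s.family, aic, k) for s, aic, k in rows],
        columns=["model_tier", "family", "aic", "n_params"],
    )
    best = min(rows, key=lambda r: (round(r[1], 9), r[2]))
    return best[0], table


def run_stratified(spec_base: ModelSpec, data) -> dict[str, ModelResult]:
    """Fit on the full cohort and within each sex stratum."""
    frame = data.completed_tables[0] if isinstance(data, ImputationSet) else data
    if "sex" not in frame.columns:
        raise ValueError("sex column is required for stratified analysis")
    out = {}
    for stratum in ("all", "men", "women"):
        spec = ModelSpec(
            outcome=spec_base.outcome,
            family=spec_base.family,
            model_tier=spec_base.model_tier,
            exposure=spec_base.exposure,
            adjustment=spec_base.adjustment,
            strata=stratum,
        )
        out[stratum] = fit_model(spec, data)
    return out


# ---------------------------------------------------------------------------
# recovery harness


@dataclass
class RecoveryReport:
    outcome: str
    family: str
    generating_ratio: float
    mean_ratio: float
    mean_log_estimate: float
    bias_log: float
    empirical_sd_log: float
    ci_coverage: float
    n_replicates: int
    seed: int


def _generating_ratio(config: GeneratorConfig, outcome: str) -> float:
    if outcome == "iph":
        return float(np.exp(config.beta_iph_per_sd))
    if outcome == "symptomatic":
        return float(np.exp(config.beta_sympt_per_sd))
    if outcome == "mace":
        return float(np.exp(config.hr_mace_per_sd))
    if outcome in config.trait_betas_per_sd:
        return float(np.exp(config.trait_betas_per_sd[outcome]))
    raise ValueError(f"unknown outcome {outcome!r}")


def run_recovery(
    config: GeneratorConfig,
    outcomes: tuple[str, ...] = ("iph", "symptomatic", "lipid_core", "mace"),
    n_replicates: int = 200,
    seed: int = 0,
    with_missingness: bool = False,
    m_imputations: int = 5,
    imputation_iterations: int = 10,
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> dict[str, RecoveryReport]:
    """Simulate → (mask → impute) → fit, repeatedly; summarize per outcome.

    Each replicate draws a fresh cohort at config.n, optionally injects the
    configured missingness and imputes it, then fits the Model 2 regression
    for every requested outcome.  Reports mean ratio (OR/HR), log-scale bias
    and spread, and 95% CI coverage of the generating value.
    """
    if n_replicates < 100:
        raise ValueError("recovery needs at least 100 replicates")
    gen = CohortGenerator(config)
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2**31)
    logs: dict[str, list[float]] = {o: [] for o in outcomes}
    cover: dict[str, list[bool]] = {o: [] for o in outcomes}
    for r in range(n_replicates):
        cohort = gen.generate(int(rep_seeds[2 * r]))
        data: pd.DataFrame | ImputationSet = cohort
        if with_missingness:
            masked = inject_missingness(
                cohort, config.missingness_rates, int(rep_seeds[2 * r + 1])
            )
            data = impute_chained(
                masked, m=m_imputations, iterations=imputation_iterations,
                seed=int(rep_seeds[2 * r + 1]),
            )
        for outcome in outcomes:
            family = "cox" if outcome == "mace" else "logistic"
            spec = ModelSpec(outcome=outcome, family=family, model_tier="model2",
                             adjustment=adjustment)
            res = fit_model(spec, data)
            row = res.term(EXPOSURE)
            logs[outcome].append(float(row["estimate"]))
            target = _generating_ratio(config, outcome)
            cover[outcome].append(bool(row["ci_low"] <= target <= row["ci_high"]))
    reports = {}
    for outcome in outcomes:
        family = "cox" if outcome == "mace" else "logistic"
        arr = np.asarray(logs[outcome])
        gen_ratio = _generating_ratio(config, outcome)
        reports[outcome] = RecoveryReport(
            outcome=outcome,
            family=family,
            generating_ratio=gen_ratio,
            mean_ratio=float(np.mean(np.exp(arr))),
            mean_log_estimate=float(arr.mean()),
            bias_log=float(arr.mean() - np.log(gen_ratio)),
            empirical_sd_log=float(arr.std(ddof=1)),
            ci_coverage=float(np.mean(cover[outcome])),
            n_replicates=n_replicates,
            seed=seed,
        )
    return reports


# ---------------------------------------------------------------------------
# end-to-end analysis of one cohort table


def run_analysis(
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = ("iph", "symptomatic"),
    candidates: tuple[str, ...] | None = DEFAULT_ADJUSTMENT,
    alpha_screen: float = 0.1,
    m_imputations: int = 10,
    imputation_iterations: int = 20,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Screen → impute (if needed) → Model 1 and Model 2 fits → stratify.

    Returns a tidy results table (one row per outcome × model × stratum ×
    term) and a run log with screening decisions and imputation settings.
    If no candidates are supplied, only Model 1 is fitted.
    """
    cohort = cohort.copy()
    if EXPOSURE not in cohort.columns:
        cohort[EXPOSURE] = irnt_values(cohort["percent_glyc"])
    if PLAQUE not in cohort.columns:
        cohort[PLAQUE] = irnt_values(cohort["plaque_size_um2"])

    log: dict = {"seed": seed, "alpha_screen": alpha_screen, "screening": {}}
    rows = []
    for outcome in outcomes:
        family = "cox" if outcome == "mace" else "logistic"
        selected: list[str] = []
        if candidates:
            screen = screen_confounders(
                cohort.dropna(subset=[EXPOSURE, PLAQUE, outcome] if family == "logistic"
                              else [EXPOSURE, PLAQUE, "mace_time", "mace_event"]),
                outcome=outcome, candidates=list(candidates),
                family=family, alpha=alpha_screen,
            )
            selected = [s.covariate for s in screen if s.selected]
            log["screening"][outcome] = {
                s.covariate: {"p_vs_exposure": s.p_vs_exposure,
                              "p_vs_outcome": s.p_vs_outcome,
                              "selected": s.selected}
                for s in screen
            }
        model_cols = [EXPOSURE, PLAQUE] + selected
        needs_imputation = cohort[model_cols].isna().any().any()
        if needs_imputation:
            data = impute_chained(cohort, m=m_imputations,
                                  iterations=imputation_iterations, seed=seed)
            log["imputation"] = {"m": m_imputations,
                                 "iterations": imputation_iterations, "seed": seed}
        else:
            data = cohort
        tiers = [("model1", ())]
        if selected:
            tiers.append(("model2", tuple(selected)))
        for tier, adj in tiers:
            strata = ("all", "men", "women") if stratify else ("all",)
            for stratum in strata:
                spec = ModelSpec(outcome=outcome, family=family, model_tier=tier,
                                 adjustment=adj, strata=stratum)
                try:
                    res = fit_model(spec, data)
                except ModelFitError as exc:
                    logger.warning("fit skipped (%s %s %s): %s",
                                   outcome, tier, stratum, exc)
                    continue
                for term, vals in res.terms.iterrows():
                    rows.append({
                        "outcome": outcome, "family": family, "model": tier,
                        "stratum": stratum, "term": term,
                        "estimate": vals["estimate"], "ratio": vals["ratio"],
                        "ci_low": vals["ci_low"], "ci_high": vals["ci_high"],
                        "p": vals["p"], "aic": res.aic, "n": res.n_used,
                        "pooled": res.pooled,
                    })
    return pd.DataFrame(rows), log
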