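"""Synthetic carotid-endarterectomy cohort generator.

Simulates patient-level tables with the statistical structure the
association pipeline assumes: a right-skewed percent-glycophorin exposure
with sex-specific log-normal marginals, baseline cardiovascular covariates
with realistic marginals, binary plaque outcomes (intraplaque hemorrhage,
pre-procedural symptoms, five dichotomized plaque traits) driven by
per-1-SD logistic effects on the inverse-rank-transformed exposure, and a
3-year composite cardiovascular endpoint with exponential event times.

The generator is calibrated: outcome-model intercepts are solved by
Monte-Carlo bisection so marginal prevalences hit their configured targets,
and the exposure's latent construction preserves the configured per-sex
median/IQR exactly while still being confounded by age, smoking,
hypertension and kidney function (so confounder screening has true
positives and plaque-size-only adjustment is genuinely biased).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .stats_core import irnt_values

#: Published baseline counts of the reference carotid endarterectomy cohort
#: used to calibrate the generator and recompute headline proportions.
REFERENCE_COHORT_COUNTS = {
    "n_total": 1819,
    "n_female": 542,
    "n_symptoms_assessed": 1813,
    "n_asymptomatic": 234,
    "hx_cad_male": (471, 1277),
    "hx_cad_female": (131, 541),
}

#: Columns that may never be masked: exposure, plaque size, and outcomes.
PROTECTED_COLUMNS = frozenset(
    {
        "patient_id",
        "sex",
        "percent_glyc",
        "plaque_size_um2",
        "glyc_sd",
        "plaque_sd",
        "iph",
        "symptomatic",
        "symptoms_detail",
        "plaque_phenotype",
        "lipid_core",
        "macrophages",
        "calcifications",
        "collagen",
        "smc",
        "mace_event",
        "mace_time",
    }
)


def sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-normal σ implied by reported quartiles: (ln q3 − ln q1) / (2·Φ⁻¹(0.75))."""
    if not 0 < q1 < q3:
        raise ValueError("need 0 < q1 < q3")
    return (math.log(q3) - math.log(q1)) / (2.0 * norm.ppf(0.75))


@dataclass
class GeneratorConfig:
    """All calibrated simulation parameters.

    Medians/IQRs are in percent of plaque area; betas are log-odds (or
    log-hazard) per 1-SD increment of the inverse-rank-transformed exposure.
    """

    n: int = 1819
    p_female: float = 0.298
    glyc_median_male: float = 7.15
    glyc_q1_male: float = 3.37
    glyc_q3_male: float = 13.41
    glyc_median_female: float = 4.06
    glyc_q1_female: float = 1.98
    glyc_q3_female: float = 8.32
    plaque_logmean: float = math.log(1.5e7)  # μm², a few-mm² culprit section
    plaque_logsd: float = 0.6
    plaque_male_logshift: float = 0.2
    beta_iph_per_sd: float = math.log(1.90)
    beta_sympt_per_sd: float = math.log(1.34)
    beta_sympt_male: float | None = None  # None → shared beta_sympt_per_sd
    beta_sympt_female: float | None = None
    trait_betas_per_sd: dict = field(
        default_factory=lambda: {
            "lipid_core": math.log(1.85),
            "macrophages": math.log(1.87),
            "calcifications": math.log(0.81),
            "collagen": math.log(0.70),
            "smc": math.log(0.60),
        }
    )
    hr_mace_per_sd: float = math.log(1.14)
    target_prev_iph: float = 0.624
    target_prev_sympt: float = 0.871
    trait_prevalence: float = 0.5
    target_prev_mace: float = 0.14
    beta_plaque_per_sd: float = math.log(1.20)
    confounder_exposure_rho: float = 0.18
    confounder_outcome_betas: dict = field(
        default_factory=lambda: {
            "age_std": 0.15,
            "female": -0.25,
            "current_smoker": 0.20,
            "hypertension": 0.15,
            "egfr_std": -0.10,
        }
    )
    missingness_rates: dict = field(
        default_factory=lambda: {
            "total_cholesterol": 0.08,
            "ldl": 0.08,
            "hdl": 0.08,
            "bmi": 0.05,
            "egfr": 0.05,
            "smoking": 0.05,
            "hypertension": 0.02,
            "hypercholesterolemia": 0.07,
        }
    )
    horizon_years: float = 3.0
    calibration_n: int = 100_000
    seed: int = 20231010

    def validate(self) -> None:
        if self.n < 50:
            raise ValueError("n must be >= 50")
        for name in ("p_female", "target_prev_iph", "target_prev_sympt",
                     "trait_prevalence", "target_prev_mace"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")
        for med, q1, q3 in (
            (self.glyc_median_male, self.glyc_q1_male, self.glyc_q3_male),
            (self.glyc_median_female, self.glyc_q1_female, self.glyc_q3_female),
        ):
            if not q1 < med < q3:
                raise ValueError("IQR bounds must bracket the median")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if not 0.0 <= self.confounder_exposure_rho < 1.0:
            raise ValueError("confounder_exposure_rho must be in [0, 1)")

    @property
    def sigma_male(self) -> float:
        return sigma_from_iqr(self.glyc_q1_male, self.glyc_q3_male)

    @property
    def sigma_female(self) -> float:
        return sigma_from_iqr(self.glyc_q1_female, self.glyc_q3_female)

    def glyc_piecewise_sigmas(self, sex: str) -> tuple[float, float]:
        """Lower/upper-tail σ of the split log-normal exposure for one sex.

        Reported quartiles of percent stain are asymmetric around the median
        on the log scale, so the exposure uses a two-piece log-normal whose
        halves are scaled separately: σ_lo = (ln med − ln q1)/Φ⁻¹(0.75) and
        σ_hi = (ln q3 − ln med)/Φ⁻¹(0.75).  Their mean equals the single-σ
        IQR formula of :func:`sigma_from_iqr`, and median, q1 and q3 all
        match the configured values exactly.
        """
        if sex == "male":
            med, q1, q3 = self.glyc_median_male, self.glyc_q1_male, self.glyc_q3_male
        elif sex == "female":
            med, q1, q3 = self.glyc_median_female, self.glyc_q1_female, self.glyc_q3_female
        else:
            raise ValueError("sex must be 'male' or 'female'")
        z75 = norm.ppf(0.75)
        return (
            (math.log(med) - math.log(q1)) / z75,
            (math.log(q3) - math.log(med)) / z75,
        )


TRAIT_NAMES = ("lipid_core", "macrophages", "calcifications", "collagen", "smc")


def calibrate_intercept(
    linear_predictor_sampler,
    target_prevalence: float,
    n: int = 100_000,
) -> float:
    """Intercept (log-odds) that makes the marginal logistic prevalence hit target.

    ``linear_predictor_sampler`` is either a callable returning n draws of
    the intercept-free linear predictor, or an array of such draws.  The
    intercept is found by root bracketing on the Monte-Carlo mean of
    expit(lp + c), which matches the target prevalence to well within
    ±0.005 at n = 1e5.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be strictly inside (0, 1)")
    lp = linear_predictor_sampler(n) if callable(linear_predictor_sampler) else np.asarray(
        linear_predictor_sampler, dtype=float
    )
    if lp.size == 0:
        raise ValueError("empty linear-predictor sample")
    if np.allclose(lp, 0.0):
        return float(logit(target_prevalence))
    return float(brentq(lambda c: expit(lp + c).mean() - target_prevalence, -30.0, 30.0))


def _calibrate_base_rate(lp: np.ndarray, target: float, horizon: float) -> float:
    """Baseline exponential hazard such that P(event ≤ horizon) hits target."""
    def f(log_lam0):
        lam = math.exp(log_lam0) * np.exp(lp)
        return (1.0 - np.exp(-lam * horizon)).mean() - target

    return math.exp(brentq(f, -20.0, 5.0))


def sample_percent_glyc(
    n: int, sex: str, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw percent-glycophorin values from one sex's marginal log-normal."""
    if sex == "male":
        mu = math.log(config.glyc_median_male)
    elif sex == "female":
        mu = math.log(config.glyc_median_female)
    else:
        raise ValueError("sex must be 'male' or 'female'")
    sig_lo, sig_hi = config.glyc_piecewise_sigmas(sex)
    z = rng.standard_normal(n)
    return np.exp(mu + np.where(z < 0, sig_lo, sig_hi) * z)


def _zscore_within(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Standardize x to mean 0, SD 1 within each group label."""
    out = np.empty_like(x, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        v = x[sel]
        out[sel] = (v - v.mean()) / (v.std() + 1e-12)
    return out


class CohortGenerator:
    """Calibrated cohort simulator.

    Intercepts for every binary outcome and the baseline hazard for the
    composite endpoint are solved once at construction on a large
    calibration sample (``config.calibration_n``), then reused for every
    draw, so repeated ``generate`` calls are cheap and share one calibrated
    regime.
    """

    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11B]))
        frame = self._raw(config.calibration_n, rng)
        lps = self._linear_predictors(frame)
        self.intercepts = {
            "iph": calibrate_intercept(lps["iph"], config.target_prev_iph),
            "symptomatic": calibrate_intercept(lps["symptomatic"], config.target_prev_sympt),
        }
        for t in TRAIT_NAMES:
            self.intercepts[t] = calibrate_intercept(lps[t], config.trait_prevalence)
        self.mace_base_rate = _calibrate_base_rate(
            lps["mace"], config.target_prev_mace, config.horizon_years
        )

    # -- covariates and exposure ------------------------------------------

    def _raw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        c = self.config
        female = rng.random(n) < c.p_female
        male = ~female

        age = rng.normal(69, 9, n)
        systolic = rng.normal(153, 26, n)
        diastolic = rng.normal(82, 25, n)
        hypertension = rng.random(n) < np.where(female, 0.81, 0.73)
        diabetes = rng.random(n) < 0.25
        hypchol = rng.random(n) < np.where(female, 0.72, 0.70)

        def logn(median_m, q1_m, q3_m, median_f, q1_f, q3_f):
            mu = np.where(female, math.log(median_f), math.log(median_m))
            sg = np.where(
                female, sigma_from_iqr(q1_f, q3_f), sigma_from_iqr(q1_m, q3_m)
            )
            return np.exp(mu + sg * rng.standard_normal(n))

        total_chol = logn(4.50, 3.81, 5.34, 5.00, 4.03, 5.91)
        ldl = logn(2.60, 2.02, 3.30, 2.79, 2.20, 3.78)
        hdl = logn(1.07, 0.90, 1.30, 1.30, 1.05, 1.60)
        trig = logn(1.50, 1.07, 2.10, 1.40, 1.09, 1.95)
        bmi = logn(26.2, 24.2, 28.7, 25.7, 23.2, 28.7)
        egfr = np.where(female, rng.normal(70.3, 21.1, n), rng.normal(74.5, 21.5, n))

        u = rng.random(n)
        p_cur = np.where(female, 0.42, 0.32)
        p_ex = np.where(female, 0.38, 0.57)
        smoking = np.where(u < p_cur, "current", np.where(u < p_cur + p_ex, "ex", "never"))

        hx_cad = rng.random(n) < np.where(female, 0.24, 0.37)
        hx_paod = rng.random(n) < 0.21
        hx_periph = rng.random(n) < np.where(female, 0.23, 0.20)
        hx_tia_stroke = rng.random(n) < 0.78
        antihypertensives = rng.random(n) < 0.76
        statins = rng.random(n) < 0.80
        antiplatelets = rng.random(n) < np.where(female, 0.90, 0.87)
        anticoagulants = rng.random(n) < np.where(female, 0.091, 0.12)

        v = rng.random(n)
        p0, p1 = np.where(female, 0.006, 0.006), np.where(female, 0.054, 0.092)
        stenosis_ipsi = np.where(v < p0, "0-50", np.where(v < p0 + p1, "50-70", "70-99"))
        stenosis_contra = np.where(rng.random(n) < 0.43, "50-100", "0-50")

        # latent exposure: confounded but marginally exact per sex
        age_std = (age - 69.0) / 9.0
        egfr_std = (egfr - 73.2) / 21.5
        current_smoker = (smoking == "current").astype(float)
        u_raw = (
            0.40 * age_std
            + 0.30 * current_smoker
            + 0.25 * hypertension.astype(float)
            - 0.20 * egfr_std
        )
        u_conf = _zscore_within(u_raw, female)
        rho = c.confounder_exposure_rho
        z = rho * u_conf + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        mu_g = np.where(female, math.log(c.glyc_median_female), math.log(c.glyc_median_male))
        sig_lo_m, sig_hi_m = c.glyc_piecewise_sigmas("male")
        sig_lo_f, sig_hi_f = c.glyc_piecewise_sigmas("female")
        sg_g = np.where(
            female,
            np.where(z < 0, sig_lo_f, sig_hi_f),
            np.where(z < 0, sig_lo_m, sig_hi_m),
        )
        percent_glyc = np.exp(mu_g + sg_g * z)

        plaque = np.exp(
            c.plaque_logmean
            + c.plaque_male_logshift * male.astype(float)
            + c.plaque_logsd * rng.standard_normal(n)
        )

        frame = pd.DataFrame(
            {
                "patient_id": np.arange(1, n + 1),
                "sex": np.where(female, "female", "male"),
                "age": age,
                "systolic_bp": systolic,
                "diastolic_bp": diastolic,
                "hypertension": hypertension.astype(int),
                "diabetes": diabetes.astype(int),
                "hypercholesterolemia": hypchol.astype(int),
                "total_cholesterol": total_chol,
                "ldl": ldl,
                "hdl": hdl,
                "triglycerides": trig,
                "bmi": bmi,
                "egfr": egfr,
                "smoking": smoking,
                "hx_cad": hx_cad.astype(int),
                "hx_paod": hx_paod.astype(int),
                "hx_peripheral_intervention": hx_periph.astype(int),
                "hx_tia_stroke": hx_tia_stroke.astype(int),
                "antihypertensives": antihypertensives.astype(int),
                "statins": statins.astype(int),
                "antiplatelets": antiplatelets.astype(int),
                "anticoagulants": anticoagulants.astype(int),
                "stenosis_ipsilateral": stenosis_ipsi,
                "stenosis_contralateral": stenosis_contra,
                "percent_glyc": percent_glyc,
                "plaque_size_um2": plaque,
            }
        )
        frame["glyc_sd"] = irnt_values(percent_glyc)
        frame["plaque_sd"] = irnt_values(plaque)
        return frame

    def _confounder_lp(self, frame: pd.DataFrame) -> np.ndarray:
        b = self.config.confounder_outcome_betas
        cols = {
            "age_std": (frame["age"].to_numpy() - 69.0) / 9.0,
            "female": (frame["sex"] == "female").to_numpy(float),
            "current_smoker": (frame["smoking"] == "current").to_numpy(float),
            "hypertension": frame["hypertension"].to_numpy(float),
            "egfr_std": (frame["egfr"].to_numpy() - 73.2) / 21.5,
        }
        lp = np.zeros(len(frame))
        for name, beta in b.items():
            lp += beta * cols[name]
        return lp

    def _linear_predictors(self, frame: pd.DataFrame) -> dict[str, np.ndarray]:
        c = self.config
        g = frame["glyc_sd"].to_numpy()
        pl = frame["plaque_sd"].to_numpy()
        conf = self._confounder_lp(frame)
        base = c.beta_plaque_per_sd * pl + conf
        female = (frame["sex"] == "female").to_numpy()
        b_m = c.beta_sympt_male if c.beta_sympt_male is not None else c.beta_sympt_per_sd
        b_f = c.beta_sympt_female if c.beta_sympt_female is not None else c.beta_sympt_per_sd
        lps = {
            "iph": c.beta_iph_per_sd * g + base,
            "symptomatic": np.where(female, b_f, b_m) * g + base,
            "mace": c.hr_mace_per_sd * g + base,
        }
        for t in TRAIT_NAMES:
            lps[t] = c.trait_betas_per_sd[t] * g + base
        return lps

    # -- outcomes ----------------------------------------------------------

    def generate(self, seed: int | None = None) -> pd.DataFrame:
        """Draw one fully observed cohort table, reproducible from the seed."""
        c = self.config
        seed = c.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD47A]))
        frame = self._raw(c.n, rng)
        lps = self._linear_predictors(frame)

        for name in ("iph", "symptomatic", *TRAIT_NAMES):
            p = expit(lps[name] + self.intercepts[name])
            frame[name] = (rng.random(c.n) < p).astype(int)

        # 4-level symptom detail, consistent with the binary collapse
        detail = np.full(c.n, "asymptomatic", dtype=object)
        sympt = frame["symptomatic"].to_numpy(bool)
        kinds = rng.choice(
            ["ocular", "tia", "stroke"], size=c.n, p=[0.2115, 0.4775, 0.3110]
        )
        detail[sympt] = kinds[sympt]
        frame["symptoms_detail"] = detail

        # 3-level overall phenotype, ordered in the exposure
        latent = frame["glyc_sd"].to_numpy() + 0.8 * rng.standard_normal(c.n)
        frame["plaque_phenotype"] = np.where(
            latent < -0.45,
            "fibrous",
            np.where(latent < 0.55, "fibroatheromatous", "atheromatous"),
        )

        lam = self.mace_base_rate * np.exp(lps["mace"])
        t_event = rng.exponential(1.0 / lam)
        frame["mace_event"] = (t_event <= c.horizon_years).astype(int)
        frame["mace_time"] = np.minimum(t_event, c.horizon_years)
        return frame


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """One-shot convenience wrapper: calibrate, then draw a single cohort."""
    return CohortGenerator(config).generate(seed)


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Mask covariate cells completely at random at per-column rates.

    Exposure, plaque size, and outcome columns are protected and may not be
    masked; rates above 0.5 are rejected as implausible.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for col, rate in rates.items():
        if col in PROTECTED_COLUMNS:
            raise ValueError(f"column {col!r} is protected and cannot be masked")
        if col not in out.columns:
            raise ValueError(f"unknown column {col!r}")
        if not 0.0 <= rate <= 0.5:
            raise ValueError(f"missingness rate for {col!r} must be in [0, 0.5]")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# provenance sidecars


def write_cohort(out_csv: str | Path, cohort: pd.DataFrame, config: GeneratorConfig) -> None:
    """CSV + data-dictionary JSON + YAML echo of the generator configuration."""
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out_csv, index=False)
    dictionary = {
        col: {"dtype": str(cohort[col].dtype), "protected": col in PROTECTED_COLUMNS}
        for col in cohort.columns
    }
    out_csv.with_suffix(".dictionary.json").write_text(json.dumps(dictionary, indent=2))
    out_csv.with_suffix(".config.yaml").write_text(yaml.safe_dump(asdict(config)))
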