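"""Random-intercept linear mixed models and the model-comparison ladder.

The analysis stage mirrors the study design: a response (VPT in dB, or
time-to-complete in s) is modeled as fixed factor effects plus a
participant random intercept,

    y_ij = X_ij beta + u_i + eps_ij,   u_i ~ N(0, tau^2), eps ~ N(0, sigma^2).

Models are fitted by maximum likelihood (ML) while being compared with
likelihood-ratio tests, and the final selected model is refitted by REML
for unbiased variance components.  Inference on fixed effects uses a
Wald t approximation with the residual degrees-of-freedom convention

    DF = n_obs - n_groups - (p - 1),

where p counts fixed coefficients including the intercept.  Effect sizes
use r = sqrt(t^2 / (t^2 + DF)).

Model fitting is delegated to :mod:`statsmodels` (``MixedLM``); this
module owns the DF convention, Wald-t inference, effect sizes, and the
ladder logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import FitError

DEFAULT_FACTORS = ("frequency_hz", "method", "location")

#: default reference level per factor column (the study's intercept cell:
#: index finger, 250 Hz, continuous tracking, male).
DEFAULT_REFERENCES: Dict[str, object] = {
    "frequency_hz": 250.0,
    "method": "bekesy",
    "location": "index",
    "gender": "male",
}


@dataclass(frozen=True)
class FixedEffect:
    name: str
    b: float
    se: float
    df: int
    t: float
    p: float
    ci_low: float
    ci_high: float
    r: float


@dataclass
class LMMFit:
    """Summary of one fitted model (mixed, or plain OLS for the baseline)."""

    fixed_effects: List[FixedEffect]
    tau2: Optional[float]      # random-intercept variance; None for OLS baseline
    sigma2: float
    estimation: str            # "ML" or "REML"
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int              # fixed coefficients + variance components
    formula: str
    reference_levels: Dict[str, object] = field(default_factory=dict)

    def coef(self, substring: str) -> FixedEffect:
        """Return the unique fixed effect whose name contains ``substring``."""
        hits = [fe for fe in self.fixed_effects if substring in fe.name]
        if len(hits) != 1:
            raise KeyError(
                f"{substring!r} matches {len(hits)} coefficients: "
                f"{[fe.name for fe in self.fixed_effects]}"
            )
        return hits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(fe) for fe in self.fixed_effects])


@dataclass(frozen=True)
class LRTResult:
    chisq: float
    df: int
    p: float


def effect_size_r(t: float, df: float) -> float:
    """Pearson-r effect size from a t statistic: r = sqrt(t^2/(t^2 + df))."""
    if not df > 0:
        raise ValueError(f"df must be positive, got {df}")
    return float(np.sqrt(t * t / (t * t + df)))


def _term(factor: str, references: Dict[str, object]) -> str:
    ref = references.get(factor, DEFAULT_REFERENCES.get(factor))
    if ref is None:
        return f"C({factor})"
    return f"C({factor}, Treatment(reference={ref!r}))"


def _build_formula(response: str, factors: Sequence[str], references: Dict[str, object]) -> str:
    if not factors:
        return f"{response} ~ 1"
    terms = " + ".join(_term(f, references) for f in factors)
    return f"{response} ~ {terms}"


def _clean_name(name: str) -> str:
    # "C(frequency_hz, Treatment(reference=250.0))[T.375.0]" -> "frequency_hz[375.0]"
    if name == "Intercept":
        return name
    if name.startswith("C(") and "[T." in name:
        col = name[2:].split(",")[0].split(")")[0]
        lvl = name.split("[T.")[1].rstrip("]")
        return f"{col}[{lvl}]"
    return name


def _summarize_fixed(params, bses, df: int) -> List[FixedEffect]:
    tcrit = sps.t.ppf(0.975, df)
    out = []
    for name, b in params.items():
        se = float(bses[name])
        t = b / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
        out.append(FixedEffect(
            name=_clean_name(name), b=float(b), se=se, df=df, t=float(t), p=p,
            ci_low=float(b - tcrit * se), ci_high=float(b + tcrit * se),
            r=effect_size_r(t, df),
        ))
    return out


def fit_random_intercept_lmm(
    tidy: pd.DataFrame,
    fixed_factors: Sequence[str] = DEFAULT_FACTORS,
    estimation: str = "REML",
    reference_levels: Optional[Dict[str, object]] = None,
    response: str = "vpt_db",
    group: str = "participant_id",
) -> LMMFit:
    """Fit ``response ~ fixed factors + (1 | participant)``.

    Rows with a missing response are excluded first.  Wald-t inference
    uses DF = n_obs - n_groups - (p - 1); CIs are b +/- t_{.975,DF} SE.
    """
    if estimation not in ("ML", "REML"):
        raise ValueError(f"estimation must be 'ML' or 'REML', got {estimation!r}")
    references = dict(reference_levels or {})
    data = tidy.dropna(subset=[response]).copy()
    groups = data[group].value_counts()
    if len(groups) < 2 or (groups >= 2).sum() < 2:
        raise FitError(
            f"need >= 2 participants with >= 2 rows each; got group sizes "
            f"{groups.to_dict()}"
        )
    formula = _build_formula(response, fixed_factors, references)
    model = smf.mixedlm(formula, data=data, groups=data[group])
    result = None
    last_exc: Optional[Exception] = None
    for optimizer in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=(estimation == "REML"), method=optimizer)
                fe_params = result.fe_params
                bse_fe = result.bse_fe
            break
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            result = None
    if result is None:
        raise FitError(
            f"mixed-model fit failed for {formula!r}: {last_exc}") from last_exc
    n_obs = int(len(data))
    n_groups = int(data[group].nunique())
    p = len(fe_params)
    df = n_obs - n_groups - (p - 1)
    if df <= 0:
        raise FitError(f"non-positive residual DF ({df}) for {formula!r}")
    tau2 = float(result.cov_re.iloc[0, 0])
    sigma2 = float(result.scale)
    return LMMFit(
        fixed_effects=_summarize_fixed(fe_params, bse_fe, df),
        tau2=tau2,
        sigma2=sigma2,
        estimation=estimation,
        loglik=float(result.llf),
        n_obs=n_obs,
        n_groups=n_groups,
        n_params=p + 2,  # fixed coefficients + tau^2 + sigma^2
        formula=formula,
        reference_levels=references,
    )


def fit_baseline_ols(
    tidy: pd.DataFrame,
    response: str = "vpt_db",
    group: str = "participant_id",
) -> LMMFit:
    """Intercept-only model with no random effect (the ladder's baseline)."""
    data = tidy.dropna(subset=[response])
    n_obs = int(len(data))
    if n_obs < 3:
        raise FitError("baseline model needs at least 3 observations")
    y = data[response].to_numpy(dtype=float)
    result = sm.OLS(y, np.ones((n_obs, 1))).fit()
    df = n_obs - 1
    params = pd.Series({"Intercept": float(result.params[0])})
    bses = pd.Series({"Intercept": float(result.bse[0])})
    return LMMFit(
        fixed_effects=_summarize_fixed(params, bses, df),
        tau2=None,
        sigma2=float(result.scale),
        estimation="ML",
        loglik=float(result.llf),
        n_obs=n_obs,
        n_groups=int(data[group].nunique()),
        n_params=2,  # intercept + sigma^2
        formula=f"{response} ~ 1",
    )


def lrt(fit_reduced: LMMFit, fit_full: LMMFit) -> LRTResult:
    """Likelihood-ratio chi-square between nested ML fits."""
    if fit_reduced.estimation != "ML" or fit_full.estimation != "ML":
        raise ValueError("likelihood-ratio tests require ML fits on both sides")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError(
            f"fits use different rows (n={fit_reduced.n_obs} vs {fit_full.n_obs}); "
            "refit both on the same data"
        )
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    chisq = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(sps.chi2.sf(chisq, df)) if df > 0 else 1.0
    return LRTResult(chisq=chisq, df=df, p=p)


@dataclass
class LadderStep:
    name: str
    fit: LMMFit
    lrt_vs_previous: Optional[LRTResult]


@dataclass
class ModelLadder:
    steps: List[LadderStep]
    final: LMMFit  # selected model refitted by REML
    selected_factors: Tuple[str, ...]


def model_ladder(
    tidy: pd.DataFrame,
    response: str = "vpt_db",
    factors: Sequence[str] = ("frequency_hz", "method", "location", "gender"),
    alpha: float = 0.05,
    reference_levels: Optional[Dict[str, object]] = None,
) -> ModelLadder:
    """Sequential model comparison by ML likelihood-ratio tests.

    Fits the intercept-only baseline, adds the participant random
    intercept, then adds each factor in order, testing every addition
    against the previous model.  Factors whose addition is significant at
    ``alpha`` are retained; the selected model is refitted by REML.
    """
    data = tidy.dropna(subset=[response])
    steps: List[LadderStep] = []

    baseline = fit_baseline_ols(data, response=response)
    steps.append(LadderStep("baseline", baseline, None))

    previous = fit_random_intercept_lmm(
        data, fixed_factors=(), estimation="ML",
        reference_levels=reference_levels, response=response)
    steps.append(LadderStep("random_intercept", previous, lrt(baseline, previous)))

    selected: List[str] = []
    current_factors: List[str] = []
    for factor in factors:
        current_factors.append(factor)
        fit = fit_random_intercept_lmm(
            data, fixed_factors=tuple(current_factors), estimation="ML",
            reference_levels=reference_levels, response=response)
        test = lrt(previous, fit)
        steps.append(LadderStep(f"+{factor}", fit, test))
        if test.p < alpha:
            selected.append(factor)
            previous = fit
        else:
            current_factors.pop()
    final = fit_random_intercept_lmm(
        data, fixed_factors=tuple(selected), estimation="REML",
        reference_levels=reference_levels, response=response)
    return ModelLadder(steps=steps, final=final, selected_factors=tuple(selected))


def summarize_conditions(
    tidy: pd.DataFrame,
    variable: str = "vpt_db",
) -> pd.DataFrame:
    """Per-cell descriptive table: mean (SD) [min, max] and 95% CI.

    Cells are (method, frequency, location); missing values are excluded
    per cell.  The CI uses the normal approximation mean +/- 1.96 SD/sqrt(n).
    """
    z = sps.norm.ppf(0.975)
    rows = []
    grouped = tidy.groupby(["method", "frequency_hz", "location"], sort=True)
    for (method, freq, loc), g in grouped:
        vals = g[variable].dropna().to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            rows.append(dict(method=method, frequency_hz=freq, location=loc, n=0,
                             mean=np.nan, sd=np.nan, min=np.nan, max=np.nan,
                             ci95_low=np.nan, ci95_high=np.nan))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        if n > 1:
            half = z * sd / np.sqrt(n)
            ci_low, ci_high = mean - half, mean + half
        else:
            ci_low = ci_high = np.nan
        rows.append(dict(method=method, frequency_hz=freq, location=loc, n=n,
                         mean=mean, sd=sd, min=float(vals.min()),
                         max=float(vals.max()), ci95_low=ci_low, ci95_high=ci_high))
    return pd.DataFrame(rows)
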