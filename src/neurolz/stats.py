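"""Inferential layer: state contrasts and dose-response shape selection.

Two families of analysis are provided:

* pairwise condition contrasts — one-way ANOVA with Tukey-HSD adjusted
  post-hoc comparisons, each carrying a pooled-SD Cohen's d;
* polynomial hierarchical models — complexity regressed on a numeric
  predictor (sleep-state code or centred ketamine dose) with random
  intercepts for cat and, where sessions repeat, session nested in cat.
  Competing degrees (linear / quadratic / cubic) are compared through
  Bayes factors approximated from BIC differences,
  ``BF_ab = exp((BIC_b - BIC_a) / 2)`` (unit-information prior). A BF
  above 5 is flagged as substantial evidence.

Models entering a BIC comparison are fitted by maximum likelihood, not
REML: REML likelihoods are not comparable across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "ModelComparison",
    "PairwiseEffect",
    "cohens_d",
    "anova_tukey",
    "fit_poly_mixed",
    "bayes_factor",
    "select_shape",
    "stim_dose_model",
    "baseline_cortex_model",
    "STATE_CODES",
]

#: Numeric coding of sleep states along the wake -> deep-sleep -> REM
#: progression; complexity is expected to be U-shaped in this coordinate.
STATE_CODES: dict[str, int] = {"W": 0, "LS": 1, "SWS": 2, "REM": 3}

SUBSTANTIAL_BF = 5.0
_MAX_LOG_BF = 700.0  # exp(709) overflows float64; cap keeps BF finite


@dataclass(frozen=True)
class ModelFit:
    """A fitted polynomial (mixed) model and its BIC.

    ``k_params`` counts fixed-effect coefficients plus variance components
    plus the residual variance; ``BIC = -2*loglik + k_params*ln(n_obs)``.
    """

    degree: int
    coefficients: np.ndarray
    coef_se: np.ndarray
    loglik: float
    BIC: float
    n_obs: int
    k_params: int
    random_spec: str
    converged: bool
    label: str = ""

    @property
    def beta2(self) -> float | None:
        return float(self.coefficients[2]) if self.degree >= 2 else None


@dataclass(frozen=True)
class ModelComparison:
    model_a: ModelFit
    model_b: ModelFit
    BF_ab: float
    log10_BF_ab: float
    preferred: str
    substantial: bool


@dataclass(frozen=True)
class PairwiseEffect:
    pair: tuple[str, str]
    mean_diff: float
    p_adj: float
    d: float
    eta_sq: float | None = None


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference, ``(mean(a)-mean(b))/s_p``.

    The pooled SD weights the two sample variances by their degrees of
    freedom, ``s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def anova_tukey(
    groups: dict[str, np.ndarray],
) -> tuple[float, float, list[PairwiseEffect]]:
    """One-way ANOVA plus all Tukey-HSD pairwise contrasts with Cohen's d.

    Returns ``(F, p, effects)`` where each effect carries the Tukey-adjusted
    p-value (studentized-range distribution; Tukey-Kramer for unbalanced
    groups) and the pooled-SD Cohen's d of the pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=np.float64) for n in names]
    if all(s.var(ddof=1) == 0 for s in samples):
        raise ValueError("degenerate data: zero variance in every group")
    F, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    effects = []
    for i, j in combinations(range(len(names)), 2):
        effects.append(
            PairwiseEffect(
                pair=(names[i], names[j]),
                mean_diff=float(samples[i].mean() - samples[j].mean()),
                p_adj=float(hsd.pvalue[i, j]),
                d=cohens_d(samples[i], samples[j]),
            )
        )
    return float(F), float(p), effects


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([x**p for p in range(degree + 1)])


def fit_poly_mixed(
    table: pd.DataFrame,
    degree: int,
    random_spec: str = "cat",
    *,
    value_col: str = "C",
    x_col: str = "x",
    reml: bool = False,
    label: str = "",
) -> ModelFit:
    """Fit C ~ polynomial(x) with the requested random-intercept structure.

    ``random_spec`` is one of ``"none"`` (ordinary least squares),
    ``"cat"`` (random intercept per cat) or ``"cat+session"`` (random
    intercepts for cat and for session nested within cat). Fits are by
    maximum likelihood by default so BICs are comparable across
    fixed-effect structures; pass ``reml=True`` only when variance
    components themselves are of interest.

    Non-convergence is recorded on the returned fit, never silently
    dropped; a variance component estimated at the boundary triggers a
    warning but the fit is retained.
    """
    if degree not in (0, 1, 2, 3):
        raise ValueError("degree must be in {0, 1, 2, 3}")
    y = table[value_col].to_numpy(dtype=np.float64)
    x = table[x_col].to_numpy(dtype=np.float64)
    n = y.size
    n_fixed = degree + 1
    if random_spec == "none":
        X = _poly_design(x, degree)
        res = sm.OLS(y, X).fit()
        k = n_fixed + 1  # + residual variance
        llf = float(res.llf)
        coefs, ses = np.asarray(res.params), np.asarray(res.bse)
        converged = True
    elif random_spec in ("cat", "cat+session"):
        # response renamed internally: a column literally named "C" would
        # shadow patsy's categorical marker C() in the vc formula
        data = pd.DataFrame({"y": y, "x": x, "cat": table["cat"].to_numpy()})
        terms = " + ".join(f"I(x**{p})" for p in range(1, degree + 1))
        formula = "y ~ 1" + (f" + {terms}" if terms else "")
        vc = None
        n_vc = 1  # cat intercept variance
        if random_spec == "cat+session":
            data["session"] = table["session"].to_numpy()
            vc = {"session": "0 + C(session)"}
            n_vc = 2
        res = _fit_mixed(formula, data, vc, reml=reml)
        k = n_fixed + n_vc + 1
        llf = float(res.llf)
        coefs = np.asarray(res.fe_params)
        ses = np.asarray(res.bse_fe)
        converged = bool(res.converged)
        if np.any(np.asarray(res.cov_re).diagonal() <= 1e-12):
            warnings.warn("variance component at boundary; fit retained",
                          stacklevel=2)
    else:
        raise ValueError(f"unknown random_spec {random_spec!r}")
    if n <= k:
        raise ValueError(f"n_obs={n} too small for k_params={k}")
    bic = -2.0 * llf + k * np.log(n)
    return ModelFit(
        degree=degree, coefficients=coefs, coef_se=ses, loglik=llf, BIC=float(bic),
        n_obs=n, k_params=k, random_spec=random_spec, converged=converged, label=label,
    )


def bayes_factor(fit_a: ModelFit, fit_b: ModelFit) -> ModelComparison:
    """BIC-approximated Bayes factor in favour of model a over model b.

    ``BF_ab = exp((BIC_b - BIC_a)/2)``; overflow is guarded by capping the
    log Bayes factor, so an overwhelming preference stays finite.
    ``substantial`` is True when the winning direction exceeds 5.
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError(
            f"fits compare different data: n_obs {fit_a.n_obs} vs {fit_b.n_obs}"
        )
    log_bf = (fit_b.BIC - fit_a.BIC) / 2.0
    log_bf = float(np.clip(log_bf, -_MAX_LOG_BF, _MAX_LOG_BF))
    bf = float(np.exp(log_bf))
    preferred = (fit_a.label or f"degree{fit_a.degree}") if bf >= 1 else (
        fit_b.label or f"degree{fit_b.degree}")
    substantial = max(bf, 1.0 / bf) > SUBSTANTIAL_BF
    return ModelComparison(
        model_a=fit_a, model_b=fit_b, BF_ab=bf,
        log10_BF_ab=log_bf / np.log(10.0), preferred=preferred,
        substantial=substantial,
    )


def select_shape(
    table: pd.DataFrame,
    degrees: tuple[int, ...] = (1, 2, 3),
    random_spec: str = "cat+session",
    *,
    value_col: str = "C",
    x_col: str = "x",
) -> tuple[dict[str, ModelComparison], str, dict[int, ModelFit]]:
    """Fit competing polynomial degrees and label the dose-response shape.

    Reports the quadratic-vs-linear and cubic-vs-linear Bayes factors. The
    label is ``"inverted-U"`` when the quadratic model is substantially
    preferred over the linear one with negative curvature, ``"U"`` with
    positive curvature, ``"cubic"`` when the cubic model is substantially
    preferred over both, and ``"linear"`` otherwise.
    """
    fits = {
        deg: fit_poly_mixed(table, deg, random_spec, value_col=value_col,
                            x_col=x_col, label=f"degree{deg}")
        for deg in degrees
    }
    comparisons: dict[str, ModelComparison] = {}
    if 2 in fits and 1 in fits:
        comparisons["quadratic_vs_linear"] = bayes_factor(fits[2], fits[1])
    if 3 in fits and 1 in fits:
        comparisons["cubic_vs_linear"] = bayes_factor(fits[3], fits[1])

    label = "linear"
    qvl = comparisons.get("quadratic_vs_linear")
    cvl = comparisons.get("cubic_vs_linear")
    if qvl is not None and qvl.BF_ab > SUBSTANTIAL_BF:
        label = "inverted-U" if fits[2].beta2 < 0 else "U"
        if cvl is not None and 3 in fits and 2 in fits:
            cvq = bayes_factor(fits[3], fits[2])
            if cvl.BF_ab > SUBSTANTIAL_BF and cvq.BF_ab > SUBSTANTIAL_BF:
                label = "cubic"
    elif cvl is not None and cvl.BF_ab > SUBSTANTIAL_BF:
        label = "cubic"
    return comparisons, label, fits


def _fit_mixed(formula: str, data: pd.DataFrame, vc: dict | None, *,
               reml: bool = False):
    """Fit a MixedLM, falling back to Powell when the default optimizer
    returns a non-finite likelihood or fails to converge."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["cat"], re_formula="1",
                            vc_formula=vc)
        res = model.fit(reml=reml)
        if not np.isfinite(res.llf) or not res.converged:
            res = model.fit(reml=reml, method="powell")
    return res


def _mixed_bic(formula: str, data: pd.DataFrame, extra_fixed: int,
               nested_session: bool = True) -> tuple[float, float, object]:
    """Helper: ML mixed fit -> (BIC, llf, results)."""
    vc = {"session": "0 + C(session)"} if nested_session else None
    res = _fit_mixed(formula, data, vc)
    n_vc = 2 if nested_session else 1
    k = len(res.fe_params) + n_vc + 1
    bic = -2.0 * float(res.llf) + k * np.log(len(data))
    return bic, float(res.llf), res


def _guarded_bf(bic_reduced: float, bic_full: float) -> float:
    return float(np.exp(np.clip((bic_reduced - bic_full) / 2.0,
                                -_MAX_LOG_BF, _MAX_LOG_BF)))


def stim_dose_model(table: pd.DataFrame, *, value_col: str = "C") -> dict:
    """Auditory-stimulation analysis: stim, dose and stim x dose terms.

    Dose enters as a categorical factor (so any response shape is
    absorbed) alongside the stimulation flag and their interaction, with
    cat and session-nested random intercepts. Each term is scored by

    * a Bayes factor against the model without that term (interaction
      tested against the additive model; each main effect against the
      model with the other main effect only),
    * an eta-squared (proportion of total sum of squares) from the
      fixed-effect ANOVA decomposition, and
    * the Wald p-value of the term in the full mixed fit.

    A term is labelled reliable only when p < 0.01 and BF > 5.
    """
    if table["stim"].nunique() < 2:
        raise ValueError("both stimulation levels must be present")
    doses_with_both = (
        table.groupby("dose")["stim"].nunique().pipe(lambda s: s[s == 2]).index
    )
    if len(doses_with_both) < 2:
        missing = sorted(set(table["dose"]) - set(doses_with_both))
        raise ValueError(
            f"need both stim levels at >= 2 doses; incomplete cells at doses {missing}"
        )
    # response renamed to "y": a column named "C" would shadow patsy's C()
    data = pd.DataFrame(
        {
            "y": table[value_col].to_numpy(dtype=np.float64),
            "dose": table["dose"].to_numpy(),
            "stim": table["stim"].astype(int).to_numpy(),
            "cat": table["cat"].to_numpy(),
            "session": table["session"].to_numpy(),
        }
    )

    bic_full, _, res_full = _mixed_bic("y ~ C(dose) * stim", data, 0)
    bic_add, _, _ = _mixed_bic("y ~ C(dose) + stim", data, 0)
    bic_dose, _, _ = _mixed_bic("y ~ C(dose)", data, 0)
    bic_stim, _, _ = _mixed_bic("y ~ stim", data, 0)

    # eta^2 from the fixed-effects-only sequential decomposition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols_fit = smf.ols("y ~ C(dose) * stim", data).fit()
        aov = sm.stats.anova_lm(ols_fit, typ=2)
    ss_total = float(aov["sum_sq"].sum())
    eta = {
        "dose": float(aov.loc["C(dose)", "sum_sq"]) / ss_total,
        "stim": float(aov.loc["stim", "sum_sq"]) / ss_total,
        "interaction": float(aov.loc["C(dose):stim", "sum_sq"]) / ss_total,
    }

    pvals = res_full.pvalues
    p_stim = float(pvals.get("stim", np.nan))
    inter_terms = [t for t in pvals.index if ":stim" in t]
    p_inter = float(min(pvals[t] for t in inter_terms)) if inter_terms else np.nan
    dose_terms = [t for t in pvals.index if t.startswith("C(dose)") and ":" not in t]
    p_dose = float(min(pvals[t] for t in dose_terms)) if dose_terms else np.nan

    report = {}
    for term, bf, p in (
        ("stim", _guarded_bf(bic_dose, bic_add), p_stim),
        ("dose", _guarded_bf(bic_stim, bic_add), p_dose),
        ("interaction", _guarded_bf(bic_add, bic_full), p_inter),
    ):
        report[term] = {
            "BF": bf,
            "p": p,
            "eta_sq": eta[term],
            "reliable": bool(p < 0.01 and bf > SUBSTANTIAL_BF),
        }
    return report


def baseline_cortex_model(
    table: pd.DataFrame, *, value_col: str = "C"
) -> ModelComparison:
    """Contrast a cortex fixed effect against an intercept-only null.

    Both models carry cat and session-nested random intercepts and are fit
    by ML; the Bayes factor is reported in favour of the cortex model.
    """
    cortices = table["cortex"].unique()
    if len(cortices) < 2:
        raise ValueError("need at least 2 cortices to contrast baselines")
    data = pd.DataFrame(
        {
            "y": table[value_col].to_numpy(dtype=np.float64),
            "cortex": table["cortex"].to_numpy(),
            "cat": table["cat"].to_numpy(),
            "session": table["session"].to_numpy(),
        }
    )
    bic_cortex, llf_c, res_c = _mixed_bic("y ~ C(cortex)", data, 0)
    bic_null, llf_0, _ = _mixed_bic("y ~ 1", data, 0)

    n = len(data)
    fit_c = ModelFit(
        degree=1, coefficients=np.asarray(res_c.fe_params),
        coef_se=np.asarray(res_c.bse_fe), loglik=llf_c, BIC=bic_cortex,
        n_obs=n, k_params=len(res_c.fe_params) + 3, random_spec="cat+session",
        converged=bool(res_c.converged), label="cortex",
    )
    fit_0 = ModelFit(
        degree=0, coefficients=np.zeros(1), coef_se=np.zeros(1), loglik=llf_0,
        BIC=bic_null, n_obs=n, k_params=4, random_spec="cat+session",
        converged=True, label="null",
    )
    return bayes_factor(fit_c, fit_0)
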