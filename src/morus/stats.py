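"""Inferential layer: rank and t tests, the dive-cost mixed model and
AIC-window model averaging, and the dive-rate model.

The dive-cost model is a linear mixed model (random intercept per bird,
fitted by maximum likelihood so AICs are comparable across fixed-effect
structures).  All fixed-effect subsets respecting marginality are
enumerated; candidates within six AIC units of the best are retained and
conditionally averaged with Akaike weights, the adjusted standard error
folding in between-model coefficient spread.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# simple tests
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    statistic: float     # Mann-Whitney U for sample a
    p_value: float
    effect_size_r: float  # rank-biserial correlation
    method: str


def rank_test(sample_a, sample_b) -> RankTestResult:
    """Two-sided Mann-Whitney-Wilcoxon test with rank-biserial effect size.

    Uses the exact permutation null when min(n_a, n_b) <= 8 (and there are
    no ties), the normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    exact = min(len(a), len(b)) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    r = 1.0 - 2.0 * u / (len(a) * len(b))  # rank-biserial
    return RankTestResult(u, float(res.pvalue), r, method)


@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float


def two_sample_t(sample_a, sample_b) -> TTestResult:
    """Unpaired two-sided t test with the Welch correction."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


# ---------------------------------------------------------------------------
# dive-cost mixed model
# ---------------------------------------------------------------------------

FULL_TERMS = ("year", "sex", "mass", "type", "sex:type")


@dataclass
class FittedModel:
    """A fitted candidate: fixed terms, coefficients, SEs, AIC."""

    terms: tuple
    coef: dict
    se: dict
    aic: float
    llf: float
    converged: bool = True
    singular: bool = False


def _formula(terms: tuple) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"cost_kj ~ {rhs}"


def fit_dive_cost_model(data: pd.DataFrame,
                        terms: tuple = FULL_TERMS,
                        group_col: str = "bird_id") -> FittedModel:
    """Linear mixed model for per-attempt cost with a bird random intercept.

    ``data`` needs columns cost_kj, bird_id and the covariates named in
    ``terms`` (categorical: sex, type, year; continuous: mass).  Fitted by
    ML; a singular (zero-variance) random effect is flagged but the fit is
    retained.  Needs at least two birds.
    """
    if data[group_col].nunique() < 2:
        raise ValueError("mixed model needs at least two birds")
    df = data.copy()
    for col in ("sex", "type"):
        if col in df.columns:
            df[col] = df[col].astype("category")
    if "year" in df.columns:
        df["year"] = pd.Categorical(df["year"].astype(int))
    model = smf.mixedlm(_formula(terms), df, groups=df[group_col])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs")
    k = len(fit.fe_params) + 2  # fixed effects + RE variance + residual
    aic = -2.0 * fit.llf + 2.0 * k
    singular = bool(np.asarray(fit.cov_re).item() < 1e-8)
    return FittedModel(terms=tuple(terms),
                       coef=dict(fit.fe_params),
                       se=dict(fit.bse_fe),
                       aic=float(aic), llf=float(fit.llf),
                       converged=bool(fit.converged), singular=singular)


def candidate_term_sets(full: tuple = FULL_TERMS) -> list[tuple]:
    """All fixed-effect subsets of the full model respecting marginality
    (an interaction only with both main effects present)."""
    mains = [t for t in full if ":" not in t]
    inters = [t for t in full if ":" in t]
    out = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            base = tuple(combo)
            out.append(base)
            for inter in inters:
                a, b = inter.split(":")
                if a in combo and b in combo:
                    out.append(base + (inter,))
    return out


@dataclass
class AveragedModel:
    """Result of conditional (natural) model averaging over an AIC window."""

    retained: pd.DataFrame   # model label, aic, delta, weight
    table: pd.DataFrame      # term, coefficient, se, adjusted se, z, p
    window: float


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights, invariant to adding a constant to every AIC."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    raw = np.exp(-0.5 * delta)
    return raw / raw.sum()


def aic_model_average(fits: list[FittedModel], window: float = 6.0,
                      mode: str = "conditional") -> AveragedModel:
    """Retain candidates with delta AIC <= window and average coefficients.

    Conditional (natural) averaging: each term is averaged only over the
    retained models containing it, with weights renormalised.  The
    adjusted SE folds between-model coefficient spread into the
    within-model SE.  ``mode="full"`` averages over all retained models,
    treating absent terms as zero with zero variance.
    """
    if not fits:
        raise ValueError("no candidate fits")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    keep = delta <= window
    kept = [f for f, k in zip(fits, keep) if k]
    kept_delta = delta[keep]
    w = np.exp(-0.5 * kept_delta)
    w = w / w.sum()
    retained = pd.DataFrame({
        "terms": [" + ".join(f.terms) if f.terms else "(intercept)"
                  for f in kept],
        "aic": [f.aic for f in kept],
        "delta": kept_delta,
        "weight": w,
    }).sort_values("aic").reset_index(drop=True)

    coef_names: list[str] = []
    for f in kept:
        for name in f.coef:
            if name not in coef_names:
                coef_names.append(name)
    rows = []
    for name in coef_names:
        has = np.array([name in f.coef for f in kept])
        if mode == "conditional":
            wi = w[has] / w[has].sum()
            betas = np.array([f.coef[name] for f, h in zip(kept, has) if h])
            ses = np.array([f.se[name] for f, h in zip(kept, has) if h])
        else:
            wi = w
            betas = np.array([f.coef.get(name, 0.0) for f in kept])
            ses = np.array([f.se.get(name, 0.0) for f in kept])
        beta_bar = float(np.sum(wi * betas))
        adj_se = float(np.sum(wi * np.sqrt(ses ** 2 + (betas - beta_bar) ** 2)))
        z = beta_bar / adj_se if adj_se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"term": name, "coefficient": beta_bar,
                     "se": float(np.sum(wi * ses)), "adjusted_se": adj_se,
                     "z": z, "p": p})
    return AveragedModel(retained=retained, table=pd.DataFrame(rows),
                         window=window)


# ---------------------------------------------------------------------------
# dive-rate model
# ---------------------------------------------------------------------------

@dataclass
class DiveRateResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


def dive_rate_model(rates, sexes) -> DiveRateResult:
    """One-way linear model F test of sex on per-bird dive rate."""
    rates = np.asarray(rates, dtype=float)
    sexes = np.asarray(sexes)
    groups = [rates[sexes == s] for s in np.unique(sexes)]
    if len(groups) != 2:
        raise ValueError("exactly two sexes are required")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each sex needs at least two birds")
    x = (sexes == np.unique(sexes)[0]).astype(float)
    X = sm.add_constant(x)
    fit = sm.OLS(rates, X).fit()
    return DiveRateResult(float(fit.fvalue), int(fit.df_model),
                          int(fit.df_resid), float(fit.f_pvalue))
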