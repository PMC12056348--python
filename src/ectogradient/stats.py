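"""OLS models on the elevational gradient with AICc selection and post hocs.

The comparison stage fits ordinary least squares models of each
microclimate summary or life-history trait on elevation and the site's
occurrence class (and, for traits, species and their pairwise
interactions), simplifies by small-sample AICc with a ΔAICc > 2 rule that
favours the simpler model, runs Tukey–Kramer pairwise contrasts on the
occurrence factor, and reports residual diagnostics (normality,
heteroscedasticity, Q–Q coordinates).

Conventions fixed here: treatment (dummy) coding with the first level in
sorted order as reference — for the study grid that makes *I. horvathi*
the species reference and ``allotopy_horvathi`` the occurrence-class
reference; AICc counts the error variance as a fitted parameter
(k = number of coefficients + 1); NA rows are dropped listwise before the
design matrix is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class RegressionResult:
    terms: list
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    k: int                    # fitted parameters incl. error variance
    rss: float
    aicc: float
    formula: str = ""
    cov: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)
    df_resid: int = 0

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n": self.n,
            "k": self.k,
            "rss": self.rss,
            "aicc": self.aicc,
            "coefficients": [
                {"term": t, "beta": float(b), "se": float(s),
                 "t": float(tt), "p": float(pp)}
                for t, b, s, tt, pp in zip(self.terms, self.beta, self.se, self.t, self.p)
            ],
        }


@dataclass
class ContrastResult:
    pair: tuple
    estimate: float
    se: float
    adjusted_p: float


# ---------------------------------------------------------------------------
# formula handling

def parse_formula(formula: str) -> tuple[str, list[tuple]]:
    """Parse ``y ~ a + b + a:b`` (with ``*`` expansion) into term tuples."""
    if "~" not in formula:
        raise StatsError(f"formula must contain '~': {formula!r}")
    lhs, rhs = (part.strip() for part in formula.split("~", 1))
    terms: list[tuple] = []
    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            from itertools import combinations

            for r in range(1, len(factors) + 1):
                for combo in combinations(factors, r):
                    if combo not in terms:
                        terms.append(combo)
        else:
            combo = tuple(f.strip() for f in chunk.split(":"))
            if combo not in terms:
                terms.append(combo)
    return lhs, terms


def _levels(col: pd.Series) -> list:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return list(col.cat.categories)
    return sorted(col.dropna().unique())


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col)


def design_matrix(table: pd.DataFrame, formula_terms) -> tuple[np.ndarray, list]:
    """Numeric design matrix (intercept first) with treatment coding.

    ``formula_terms`` is a list of tuples of variable names; interaction
    columns are element-wise products of the main-effect columns.  The
    reference level of each categorical variable is the first in category
    (or sorted) order.  Raises on unknown variables and on rank
    deficiency, naming the offending column where detectable.
    """
    n = len(table)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    def main_effect(var: str) -> list[tuple[str, np.ndarray]]:
        if var not in table.columns:
            raise StatsError(f"unknown term {var!r}")
        col = table[var]
        if _is_categorical(col):
            levels = _levels(col)
            if len(col.dropna().unique()) < 2:
                raise StatsError(f"factor {var!r} has fewer than 2 observed levels")
            return [
                (f"{var}[T.{lv}]", (col == lv).to_numpy(dtype=float))
                for lv in levels[1:]
            ]
        return [(var, col.to_numpy(dtype=float))]

    for term in formula_terms:
        parts = [main_effect(v) for v in term]
        combo: list[tuple[str, np.ndarray]] = parts[0]
        for nxt in parts[1:]:
            combo = [
                (f"{nm1}:{nm2}", c1 * c2) for nm1, c1 in combo for nm2, c2 in nxt
            ]
        for nm, c in combo:
            names.append(nm)
            columns.append(c)

    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.allclose(X[:, j], X[:, j].mean()):
                raise StatsError(f"rank deficiency: column {names[j]!r} is constant")
        raise StatsError("rank-deficient design matrix")
    return X, names


# ---------------------------------------------------------------------------
# fitting

def fit_ols(y, X, names=None, formula: str = "") -> RegressionResult:
    """Ordinary least squares with AICc (error variance counted in k)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k_coef = X.shape
    if n <= k_coef:
        raise StatsError(f"need n > number of columns ({n} <= {k_coef})")
    names = list(names) if names is not None else [f"x{j}" for j in range(k_coef)]
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k_coef:
        raise StatsError("singular X'X (rank-deficient design)")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k_coef
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    k = k_coef + 1
    aicc = n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return RegressionResult(
        terms=names, beta=beta, se=se, t=t, p=p, n=n, k=k, rss=rss,
        aicc=aicc, formula=formula, cov=cov, residuals=resid, df_resid=df,
    )


def fit_formula(table: pd.DataFrame, formula: str) -> RegressionResult:
    """Fit an OLS model from a formula after listwise NA deletion."""
    lhs, terms = parse_formula(formula)
    if lhs not in table.columns:
        raise StatsError(f"unknown response {lhs!r}")
    used = {lhs} | {v for term in terms for v in term}
    sub = table.dropna(subset=[c for c in used if c in table.columns])
    X, names = design_matrix(sub, terms)
    return fit_ols(sub[lhs].to_numpy(dtype=float), X, names, formula)


def select_model(full: RegressionResult, reduced: RegressionResult):
    """AICc simplification: keep the full model only if it beats the
    reduced one by more than 2 AICc units.  Order-invariant; the reduced
    (fewer-parameter) model wins ties."""
    if full.n != reduced.n:
        raise StatsError("models must be fitted to the same observations")
    if full.k < reduced.k:
        full, reduced = reduced, full
    delta = reduced.aicc - full.aicc  # >0 means the full model is better
    chosen = full if delta > 2.0 else reduced
    return chosen, {
        "delta_aicc": float(delta),
        "chosen": chosen.formula or ("full" if chosen is full else "reduced"),
        "rule": "full only if AICc(reduced) - AICc(full) > 2",
    }


# ---------------------------------------------------------------------------
# post hoc and diagnostics

def tukey_pairwise(
    fit: RegressionResult, factor_name: str, table: pd.DataFrame
) -> list[ContrastResult]:
    """Tukey–Kramer pairwise contrasts of a factor's adjusted means.

    Works on models additive in the factor (the dummy coefficients are the
    adjusted-mean differences); p-values come from the studentized range
    with the model's residual degrees of freedom.
    """
    if factor_name not in table.columns:
        raise StatsError(f"unknown factor {factor_name!r}")
    levels = _levels(table[factor_name])
    k = len(levels)
    if k < 2:
        raise StatsError("factor needs at least 2 levels")
    prefix = f"{factor_name}[T."
    dummy_idx = {lv: None for lv in levels[1:]}
    for j, nm in enumerate(fit.terms):
        if nm.startswith(prefix) and nm.endswith("]") and ":" not in nm:
            dummy_idx[nm[len(prefix):-1]] = j
    if any(j is None for j in dummy_idx.values()):
        raise StatsError(f"factor {factor_name!r} not in fitted model")

    def contrast_vec(lv):
        c = np.zeros(len(fit.terms))
        if lv != levels[0]:
            c[dummy_idx[lv]] = 1.0
        return c

    out = []
    for i in range(k):
        for j in range(i + 1, k):
            c = contrast_vec(levels[j]) - contrast_vec(levels[i])
            est = float(c @ fit.beta)
            se = float(np.sqrt(c @ fit.cov @ c))
            if se == 0:
                padj = 1.0 if est == 0 else 0.0
            else:
                q = math.sqrt(2.0) * abs(est) / se
                padj = float(sps.studentized_range.sf(q, k, fit.df_resid))
            out.append(ContrastResult((levels[i], levels[j]), est, se, min(1.0, padj)))
    return out


def diagnostics(fit: RegressionResult, y=None, X=None) -> dict:
    """Residual diagnostics: Shapiro–Wilk normality, Breusch–Pagan
    heteroscedasticity, and Q–Q plot coordinates (both axes ascending)."""
    resid = fit.residuals
    n = resid.size
    if n < 8:
        return {"skipped": True, "reason": f"n = {n} < 8"}
    sw_stat, sw_p = sps.shapiro(resid)
    report = {
        "skipped": False,
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
    }
    if X is not None:
        from statsmodels.stats.diagnostic import het_breuschpagan

        bp_stat, bp_p, _, _ = het_breuschpagan(resid, np.asarray(X, dtype=float))
        report["breusch_pagan_stat"] = float(bp_stat)
        report["breusch_pagan_p"] = float(bp_p)
    order = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    report["qq_theoretical"] = sps.norm.ppf(order).tolist()
    report["qq_sample"] = np.sort(resid).tolist()
    return report


# ---------------------------------------------------------------------------
# study-level wrappers

def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    """Fix categorical orderings so references are the documented ones."""
    df = table.copy()
    for col in ("occurrence", "species"):
        if col in df.columns and _is_categorical(df[col]):
            df[col] = pd.Categorical(df[col], categories=sorted(df[col].dropna().unique()))
    return df


def gradient_model(
    table: pd.DataFrame,
    response: str,
    full_formula: str,
    reduced_formula: str,
    posthoc_factor: str = "occurrence",
) -> dict:
    """Fit full vs reduced OLS, apply the ΔAICc>2 rule, post hoc, diagnose."""
    df = _prepare(table).dropna(subset=[response])
    full = fit_formula(df, full_formula)
    reduced = fit_formula(df, reduced_formula)
    chosen, rationale = select_model(full, reduced)
    report = {
        "response": response,
        "full": full.to_dict(),
        "reduced": reduced.to_dict(),
        "selection": rationale,
        "chosen_formula": chosen.formula,
        "diagnostics": diagnostics(chosen),
    }
    base = chosen if any(t.startswith(f"{posthoc_factor}[T.") for t in chosen.terms) else reduced
    try:
        report["tukey"] = [
            {"pair": list(c.pair), "estimate": c.estimate, "se": c.se,
             "adjusted_p": c.adjusted_p}
            for c in tukey_pairwise(base, posthoc_factor, df)
        ]
    except StatsError:
        report["tukey"] = []
    return report


def microclimate_gradient_stats(site_summary: pd.DataFrame) -> dict:
    """Per-variable OLS ``variable ~ elevation + occurrence`` reports."""
    out = {}
    for var in [c for c in site_summary.columns
                if c not in ("name", "lat", "lon", "elevation", "occurrence")]:
        out[var] = gradient_model(
            site_summary, var,
            f"{var} ~ elevation * occurrence",
            f"{var} ~ elevation + occurrence",
        )
    return out


def trait_gradient_stats(trait_table: pd.DataFrame) -> dict:
    """Per-trait, per-season OLS with species × elevation × occurrence."""
    from .lifecycle import TRAIT_COLUMNS

    out = {}
    for season in sorted(trait_table["season_set"].unique()):
        sub = trait_table[trait_table["season_set"] == season]
        season_report = {}
        for trait in TRAIT_COLUMNS:
            season_report[trait] = gradient_model(
                sub, trait,
                f"{trait} ~ elevation + species + occurrence + "
                f"elevation:species + elevation:occurrence + species:occurrence",
                f"{trait} ~ elevation + species + occurrence",
            )
        out[season] = season_report
    return out
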