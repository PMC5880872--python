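"""Generalized linear models of guide positioning error.

Three GLMs (normal distribution, identity link — equivalent to ordinary
least squares) relate mTRE, ΔT and ΔR to the categorical predictors
*Location* (reference: distal), *Extension* (reference: extended, i.e. the
guide has the lateral extension), their interaction, and the potential
confounders *Operator* and *Geometry*.  Effects are tested with Wald
chi-square statistics and nonsignificant predictors are removed one at a
time (largest p first, interactions before their main effects become
eligible) until every remaining effect is significant.

Two solution paths are implemented — iteratively reweighted least squares
via statsmodels and a direct normal-equations solve — and agree to
numerical precision; the normal-equations path doubles as an internal
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .phantom import DESIGNS, LOCATIONS

__all__ = [
    "GLMResult",
    "build_design_matrix",
    "fit_glm",
    "stepwise_reduce",
    "recover_effects",
    "simulate_trials_table",
    "normality_report",
    "DEFAULT_EFFECTS",
    "RESPONSES",
]

RESPONSES = ("mTRE", "dT", "dR")
DEFAULT_EFFECTS = ("Extension", "Location", "Location*Extension", "Operator", "Geometry")

# reference categories: distal location, extended ("Extension = yes") design
_REFERENCES = {"Location": "distal", "Extension": "extended"}


@dataclass
class GLMResult:
    """Fit of one error response against categorical effects."""

    response: str
    effects: tuple[str, ...]
    coefficients: pd.DataFrame  # term, effect, beta, se, ci_low, ci_high, wald_chi2, df, p
    effect_tests: pd.DataFrame  # effect, chi2, df, p
    nobs: int
    scale: float  # residual variance estimate
    params: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def effect_p(self, effect: str) -> float:
        row = self.effect_tests[self.effect_tests["effect"] == effect]
        if row.empty:
            raise KeyError(effect)
        return float(row["p"].iloc[0])


def _effect_columns(table: pd.DataFrame, effect: str) -> pd.DataFrame:
    """Dummy columns for one effect with the reference level absorbed."""
    if "*" in effect:
        parts = effect.split("*")
        left = _effect_columns(table, parts[0])
        right = _effect_columns(table, parts[1])
        cols = {}
        for ln, lv in left.items():
            for rn, rv in right.items():
                cols[f"{ln} * {rn}"] = lv * rv
        return pd.DataFrame(cols, index=table.index)
    source = {
        "Extension": table["design"],
        "Location": table["location"],
        "Operator": table["operator"],
        "Geometry": table["geometry"],
    }[effect]
    levels = sorted(source.unique())
    ref = _REFERENCES.get(effect, levels[0])
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} absent for effect {effect}")
    cols = {
        f"{effect}={lvl}": (source == lvl).astype(float)
        for lvl in levels
        if lvl != ref
    }
    return pd.DataFrame(cols, index=table.index)


def build_design_matrix(
    table: pd.DataFrame, effects: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept plus dummy-coded columns; returns (X, effect -> columns)."""
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    groups: dict[str, list[str]] = {}
    for effect in effects:
        cols = _effect_columns(table, effect)
        if cols.shape[1] == 0:
            raise ValueError(f"effect {effect} has fewer than 2 levels")
        groups[effect] = list(cols.columns)
        X = pd.concat([X, cols], axis=1)
    return X, groups


def fit_glm(
    table: pd.DataFrame,
    response: str,
    effects: tuple[str, ...] = DEFAULT_EFFECTS,
    method: str = "glm",
) -> GLMResult:
    """Fit one error response by maximum likelihood (normal, identity link).

    ``method="glm"`` uses statsmodels IRLS; ``method="ols"`` solves the
    normal equations directly.  Under the normal/identity model both give
    the ordinary-least-squares solution, with coefficient covariance
    ``scale · (XᵀX)⁻¹`` and ``scale = RSS / (n − p)``.  Wald chi-squares are
    ``(β/SE)²`` per coefficient and the quadratic form ``βᵀV⁻¹β`` per
    multi-column effect; 95% CIs are β ± 1.96·SE.
    """
    X, groups = build_design_matrix(table, tuple(effects))
    y = table[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more columns than observations")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < p:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (columns: {list(X.columns)})"
        )
    if method == "glm":
        model = sm.GLM(y, Xv, family=sm.families.Gaussian())
        fit = model.fit()
        beta = fit.params
        cov = fit.cov_params()
        scale = float(fit.scale)
        resid = y - Xv @ beta
    elif method == "ols":
        xtx = Xv.T @ Xv
        beta = np.linalg.solve(xtx, Xv.T @ y)
        resid = y - Xv @ beta
        scale = float(resid @ resid / (n - p))
        cov = scale * np.linalg.inv(xtx)
    else:
        raise ValueError("method must be 'glm' or 'ols'")

    se = np.sqrt(np.diag(cov))
    chi2 = (beta / se) ** 2
    coef = pd.DataFrame(
        {
            "term": X.columns,
            "effect": ["Intercept"]
            + [
                next(e for e, cols in groups.items() if c in cols)
                for c in X.columns[1:]
            ],
            "beta": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "wald_chi2": chi2,
            "df": 1,
            "p": sps.chi2.sf(chi2, 1),
        }
    )
    rows = []
    col_index = {c: i for i, c in enumerate(X.columns)}
    for effect, cols in groups.items():
        idx = [col_index[c] for c in cols]
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append(
            {"effect": effect, "chi2": stat, "df": df, "p": float(sps.chi2.sf(stat, df))}
        )
    return GLMResult(
        response=response,
        effects=tuple(effects),
        coefficients=coef,
        effect_tests=pd.DataFrame(rows),
        nobs=n,
        scale=scale,
        params=beta,
        cov=cov,
        residuals=resid,
    )


def _interaction_parents(effect: str) -> set[str]:
    return set(effect.split("*")) if "*" in effect else set()


def stepwise_reduce(
    table: pd.DataFrame,
    response: str,
    full_effects: tuple[str, ...] = DEFAULT_EFFECTS,
    alpha: float = 0.05,
    method: str = "glm",
) -> list[GLMResult]:
    """Backward elimination of nonsignificant effects, one per step.

    At each step the effect with the largest p ≥ alpha is removed (a main
    effect is protected while an interaction containing it is still in the
    model); ties break toward larger df, then alphabetical.  The
    full trace of fits is returned, the last entry being the final model.
    """
    effects = list(full_effects)
    trace = [fit_glm(table, response, tuple(effects), method=method)]
    while True:
        current = trace[-1]
        protected = set()
        for e in effects:
            protected |= _interaction_parents(e)
        candidates = []
        for _, row in current.effect_tests.iterrows():
            e = row["effect"]
            if row["p"] >= alpha and e not in protected:
                candidates.append((row["p"], row["df"], e))
        if not candidates:
            break
        # largest p first; ties -> larger df, then alphabetical
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        drop = candidates[0][2]
        effects.remove(drop)
        if not effects:
            break
        trace.append(fit_glm(table, response, tuple(effects), method=method))
    return trace


def recover_effects(result: GLMResult, true_betas: dict[str, float]) -> pd.DataFrame:
    """Compare fitted coefficients against known simulated effect sizes.

    ``true_betas`` maps coefficient term names (e.g. ``"Location=mid-shaft"``)
    to the effect sizes injected by the simulation; the report adds the
    estimation error and whether the 95% CI covers the truth.
    """
    rows = []
    coef = result.coefficients.set_index("term")
    for term, truth in true_betas.items():
        if term not in coef.index:
            raise KeyError(f"term {term!r} not in fitted model")
        r = coef.loc[term]
        rows.append(
            {
                "term": term,
                "true_beta": truth,
                "beta": r["beta"],
                "error": r["beta"] - truth,
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "covered": bool(r["ci_low"] <= truth <= r["ci_high"]),
            }
        )
    return pd.DataFrame(rows)


def simulate_trials_table(
    location_effects: dict[str, float] | None = None,
    extension_effect: float = 1.36,
    intercept: float = 1.0,
    residual_sd: float = 1.5,
    n_operators: int = 4,
    n_geometries: int = 6,
    response: str = "mTRE",
    seed: int = 0,
) -> pd.DataFrame:
    """Direct draw of a factorial error table with known cell means.

    The mean model is ``intercept + location effect + extension effect``
    (extension_effect applies to the standard design, mirroring the
    reference categories) plus normal residuals — the harness for CI
    coverage and type-I-error experiments where the imaging chain would
    only add cost, not information.
    """
    if location_effects is None:
        location_effects = {"distal": 0.0, "proximal": 0.88, "mid-shaft": 1.83}
    rng = np.random.default_rng(seed)
    rows = []
    for op in range(n_operators):
        for g in range(n_geometries):
            for loc in LOCATIONS:
                for des in DESIGNS:
                    mu = (
                        intercept
                        + location_effects[loc]
                        + (extension_effect if des == "standard" else 0.0)
                    )
                    rows.append(
                        {
                            "operator": f"op{op + 1}",
                            "geometry": f"g{g + 1}",
                            "location": loc,
                            "design": des,
                            response: mu + rng.standard_normal() * residual_sd,
                        }
                    )
    return pd.DataFrame(rows)


def normality_report(table: pd.DataFrame, responses=RESPONSES) -> pd.DataFrame:
    """Shapiro–Wilk statistics per response (advisory preliminary check)."""
    rows = []
    for r in responses:
        if r in table.columns:
            w, p = sps.shapiro(table[r])
            rows.append({"response": r, "W": float(w), "p": float(p)})
    return pd.DataFrame(rows)
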