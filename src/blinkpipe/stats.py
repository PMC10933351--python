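"""Mixed-effects group comparison with per-day post hoc contrasts.

Every Results-style comparison in this package runs through the same layer:
a linear mixed-effects (LME) model with the assay's fixed effects (group,
day, beam width, interactions) and random intercepts for mouse — plus a
crossed random intercept for trial or run where the assay design states one.
Fixed terms are tested with ANOVA-style Wald F-tests; per-day group
contrasts are Holm–Bonferroni corrected; model quality is reported as
log-likelihood, AIC and BIC (maximum-likelihood based, so models with
different fixed effects remain comparable).

Denominator degrees of freedom use a containment (within/between) rule:
terms constant within mouse are tested against ``n_mice - rank(between
design)``; terms varying within mouse against ``n_obs - n_mice -
rank(within design)``. On the balanced 28-mouse, 10-day eyeblink design this
yields F(1, 26) for group and F(9, 234) for day and the interaction. The
rule is exact for balanced random-intercept designs and conservative
otherwise; the method used is recorded in every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMESpec",
    "LMEResult",
    "MixedEffectsComparison",
    "fit_lme",
    "holm_adjust",
    "per_day_contrasts",
    "compare_fits",
]

DEFAULT_CATEGORICAL = ("group", "day", "beam_width_mm", "trial_or_run")


@dataclass(frozen=True)
class LMESpec:
    """Specification of one mixed-effects comparison.

    ``fixed_effects`` are column names or ``a:b`` interactions;
    ``random`` lists random-intercept grouping factors, the mouse factor
    first (always present), optional crossed factors (trial, run) after it.
    """

    outcome: str
    fixed_effects: tuple[str, ...] = ("group",)
    random: tuple[str, ...] = ("mouse_id",)
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL
    alpha: float = 0.05
    df_method: str = "containment"
    correction: str = "holm"

    def __post_init__(self) -> None:
        if not self.random:
            raise ValueError("at least one random grouping factor (mouse)")
        if self.correction not in ("holm", "bonferroni"):
            raise ValueError(f"unknown correction: {self.correction!r}")


@dataclass
class LMEResult:
    """Outcome of one LME fit: term tests, contrasts, fit criteria."""

    spec: LMESpec
    formula: str
    n_obs: int
    n_mice: int
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    terms: pd.DataFrame  # term, F, df1, df2, p
    contrasts: Optional[pd.DataFrame]
    llf_reml: float
    llf_ml: float
    df_model: int
    aic: float
    bic: float
    df_method: str
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    singular: bool
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable summary (term tests, contrasts, fit criteria)."""
        return {
            "formula": self.formula,
            "n_obs": self.n_obs,
            "n_mice": self.n_mice,
            "df_method": self.df_method,
            "terms": self.terms.to_dict("records"),
            "contrasts": (
                None
                if self.contrasts is None
                else self.contrasts.to_dict("records")
            ),
            "llf": self.llf_ml,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "singular": self.singular,
            "messages": self.messages,
        }


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if len(p) == 0:
        return np.asarray(p)
    return multipletests(p, method=method)[1]


class MixedEffectsComparison(BaseEstimator):
    """scikit-learn-style front end for the LME comparison layer.

    ``fit`` expects a tidy DataFrame with the outcome column, the fixed
    effect columns, and every random grouping factor.

    Attributes (after ``fit``): ``result_`` (:class:`LMEResult`),
    ``anova_`` (per-term F table), ``contrasts_`` (per-day group contrasts
    with Holm adjustment, when group and day are both fixed effects),
    ``aic_``, ``bic_``, ``llf_``.
    """

    def __init__(
        self,
        outcome: str = "value",
        fixed_effects: tuple[str, ...] = ("group",),
        random: tuple[str, ...] = ("mouse_id",),
        categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
        alpha: float = 0.05,
        df_method: str = "containment",
        correction: str = "holm",
    ):
        self.outcome = outcome
        self.fixed_effects = fixed_effects
        self.random = random
        self.categorical = categorical
        self.alpha = alpha
        self.df_method = df_method
        self.correction = correction

    def spec(self) -> LMESpec:
        return LMESpec(
            outcome=self.outcome,
            fixed_effects=tuple(self.fixed_effects),
            random=tuple(self.random),
            categorical=tuple(self.categorical),
            alpha=self.alpha,
            df_method=self.df_method,
            correction=self.correction,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "MixedEffectsComparison":
        self.result_ = fit_lme(X, self.spec())
        self.anova_ = self.result_.terms
        self.contrasts_ = self.result_.contrasts
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.llf_ = self.result_.llf_ml
        return self


# ---------------------------------------------------------------------------


def _term_expr(term: str, categorical: Sequence[str]) -> str:
    # sum-to-zero coding so main-effect Wald tests are averaged over the
    # other factors (ANOVA-style), not evaluated at a reference level
    parts = [
        f"C({p}, Sum)" if p in categorical else p for p in term.split(":")
    ]
    return ":".join(parts)


def _clean_term(name: str) -> str:
    """Map a patsy term name back to the spec's plain column syntax."""
    return name.replace("C(", "").replace(", Sum)", "").replace(")", "")


def _used_columns(spec: LMESpec) -> list[str]:
    cols = [spec.outcome]
    for t in spec.fixed_effects:
        cols.extend(t.split(":"))
    cols.extend(spec.random)
    seen: list[str] = []
    for c in cols:
        if c not in seen:
            seen.append(c)
    return seen


def fit_lme(table: pd.DataFrame, spec: LMESpec) -> LMEResult:
    """Fit the specified mixed model and test its fixed terms.

    The variance structure is fitted by REML; the reported llf/AIC/BIC come
    from a parallel ML fit so that models with different fixed effects can
    be compared. Raises on a constant outcome; a singular variance estimate
    is reported in the result diagnostics, never silently dropped.
    """
    missing = [c for c in _used_columns(spec) if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    data = table.dropna(subset=_used_columns(spec)).copy()
    y = pd.to_numeric(data[spec.outcome], errors="raise")
    if len(data) < 3:
        raise ValueError("too few complete rows to fit")
    if float(np.var(y)) == 0.0:
        raise ValueError(f"outcome {spec.outcome!r} has zero variance")
    if "group" in {p for t in spec.fixed_effects for p in t.split(":")}:
        if data["group"].nunique() < 2:
            raise ValueError("need at least 2 levels of group")

    messages: list[str] = []
    fixed_terms = []
    for t in spec.fixed_effects:
        levels_ok = all(
            p not in spec.categorical or data[p].nunique() > 1
            for p in t.split(":")
        )
        if levels_ok:
            fixed_terms.append(t)
        else:
            messages.append(f"dropped term {t!r}: factor has a single level")
    rhs = " + ".join(_term_expr(t, spec.categorical) for t in fixed_terms)
    formula = f"{spec.outcome} ~ {rhs}" if rhs else f"{spec.outcome} ~ 1"

    mouse = spec.random[0]
    extra = spec.random[1:]
    if extra:
        vc = {r: f"0 + C({r})" for r in spec.random}
        groups = np.ones(len(data))
        model = smf.mixedlm(formula, data, groups=groups, vc_formula=vc)
    else:
        model = smf.mixedlm(formula, data, groups=data[mouse])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=True)
        try:
            res_ml = model.fit(reml=False)
        except Exception as exc:  # pragma: no cover - ML retry path
            messages.append(f"ML refit failed ({exc}); using REML likelihood")
            res_ml = res
    for w in caught:
        if "convergence" in str(w.message).lower() or "singular" in str(
            w.message
        ).lower():
            messages.append(str(w.message))

    singular = bool(np.any(np.diag(np.atleast_2d(res.cov_re)) < 1e-8)) or (
        hasattr(res, "vcomp") and res.vcomp.size and np.any(res.vcomp < 1e-8)
    )
    if singular:
        messages.append(
            "singular variance estimate: at least one random-effect variance "
            "is at the boundary (~0); fixed-effect tests approach the OLS ones"
        )

    fe_names = list(res.fe_params.index)
    k_fe = len(fe_names)
    fe = res.fe_params.to_numpy()
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    design_info = model.data.design_info
    exog = np.asarray(model.exog)
    groups_arr = data[mouse].to_numpy()

    df_between, df_within, is_between_col = _containment_dfs(
        exog, groups_arr
    )

    rows = []
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        idx = np.arange(sl.start, sl.stop)
        if idx.size == 0:
            continue
        L = np.zeros((idx.size, k_fe))
        L[np.arange(idx.size), idx] = 1.0
        fstat, df1 = _wald_f(L, fe, cov_fe)
        between = bool(np.all(is_between_col[idx]))
        df2 = df_between if between else df_within
        p = float(sps.f.sf(fstat, df1, df2))
        rows.append(
            {
                "term": _clean_term(name),
                "F": fstat,
                "df1": df1,
                "df2": df2,
                "p": p,
                "scope": "between" if between else "within",
            }
        )
    terms = pd.DataFrame(rows)

    contrasts = None
    fixed_parts = {p for t in fixed_terms for p in t.split(":")}
    if "group" in fixed_parts and "day" in data.columns and "day" in {
        p for t in spec.fixed_effects for p in t.split(":")
    }:
        contrasts = _per_day_group_contrasts(
            data, design_info, fe, cov_fe, df_between, spec
        )

    df_model = k_fe + _n_variance_params(res) + 1
    llf_ml = float(res_ml.llf)
    aic = -2.0 * llf_ml + 2.0 * df_model
    bic = -2.0 * llf_ml + np.log(len(data)) * df_model

    return LMEResult(
        spec=spec,
        formula=formula,
        n_obs=len(data),
        n_mice=int(data[mouse].nunique()),
        fe_params=res.fe_params,
        cov_fe=pd.DataFrame(cov_fe, index=fe_names, columns=fe_names),
        terms=terms,
        contrasts=contrasts,
        llf_reml=float(res.llf),
        llf_ml=llf_ml,
        df_model=df_model,
        aic=float(aic),
        bic=float(bic),
        df_method=spec.df_method,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        converged=bool(getattr(res, "converged", True)),
        singular=singular,
        messages=messages,
    )


def _n_variance_params(res) -> int:
    n = np.atleast_2d(res.cov_re).shape[0]
    if hasattr(res, "vcomp"):
        n += int(np.size(res.vcomp))
    return n


def _wald_f(L: np.ndarray, fe: np.ndarray, cov: np.ndarray) -> tuple[float, int]:
    est = L @ fe
    mid = L @ cov @ L.T
    q = int(np.linalg.matrix_rank(mid))
    stat = float(est @ np.linalg.solve(mid, est)) / max(q, 1)
    return stat, max(q, 1)


def _containment_dfs(
    exog: np.ndarray, groups: np.ndarray
) -> tuple[int, int, np.ndarray]:
    """Containment denominator dfs and between/within column classification.

    A design column is between-mouse when it is constant within every mouse.
    Between terms are tested against the mouse stratum (``n_mice - rank of
    the mouse-level between design``), within terms against the residual
    stratum (``n_obs - n_mice - within rank``).
    """
    n_obs, p = exog.shape
    codes, _ = pd.factorize(groups)
    n_groups = int(codes.max()) + 1
    is_between = np.empty(p, dtype=bool)
    group_means = np.zeros((n_groups, p))
    for j in range(p):
        col = exog[:, j]
        means = np.bincount(codes, weights=col) / np.bincount(codes)
        spread = np.abs(col - means[codes])
        is_between[j] = np.max(spread) < 1e-10
        group_means[:, j] = means
    rank_total = int(np.linalg.matrix_rank(exog))
    between_cols = group_means[:, is_between]
    rank_between = (
        int(np.linalg.matrix_rank(between_cols)) if between_cols.size else 0
    )
    rank_within = rank_total - rank_between
    df_between = max(n_groups - rank_between, 1)
    df_within = max(n_obs - n_groups - rank_within, 1)
    return df_between, df_within, is_between


def _per_day_group_contrasts(
    data: pd.DataFrame,
    design_info,
    fe: np.ndarray,
    cov_fe: np.ndarray,
    df_between: int,
    spec: LMESpec,
) -> pd.DataFrame:
    """Group contrast (enriched - standard adjusted difference) at each day.

    The contrast vector at day *d* is the difference between the design rows
    of the two groups with day fixed at *d* and any continuous covariates at
    their overall mean; this is exact regardless of the coding patsy chose.
    """
    days = sorted(data["day"].unique())
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ValueError("per-day contrasts need exactly two groups")
    covariate_cols = [
        c
        for c in data.columns
        if c not in ("group", "day")
        and c in {p for t in spec.fixed_effects for p in t.split(":")}
    ]
    rows = []
    for d in days:
        frames = []
        for g in groups:
            row = {"group": g, "day": d}
            for c in covariate_cols:
                if c in spec.categorical:
                    row[c] = data[c].mode().iloc[0]
                else:
                    row[c] = float(pd.to_numeric(data[c]).mean())
            frames.append(row)
        (X,) = build_design_matrices([design_info], pd.DataFrame(frames))
        X = np.asarray(X)
        L = X[1] - X[0]  # second group minus first (alphabetical order)
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov_fe @ L))
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), df_between))
        rows.append(
            {
                "day": d,
                "contrast": f"{groups[1]} - {groups[0]}",
                "estimate": est,
                "se": se,
                "t": t,
                "df": df_between,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = _adjust(out["p_raw"].to_numpy(), spec.correction)
    out["significant"] = out["p_adj"] < spec.alpha
    return out


def per_day_contrasts(table: pd.DataFrame, spec: LMESpec) -> pd.DataFrame:
    """Per-day group contrasts with multiplicity adjustment.

    Fits the spec's model and returns one two-group contrast per day with
    raw and adjusted p-values. With a single day of data this reduces to one
    two-group comparison and the adjustment is the identity.
    """
    if "day" not in table.columns:
        raise ValueError("table lacks a 'day' column")
    result = fit_lme(table, spec)
    if result.contrasts is None:
        raise ValueError(
            "spec does not include both group and day fixed effects"
        )
    return result.contrasts


def compare_fits(results: Sequence[LMEResult]) -> pd.DataFrame:
    """Model-comparison table: ΔAIC, ΔBIC and LR tests for nested pairs.

    All fits must share the outcome and the rows they were fitted to.
    Each model is LR-tested against the largest strictly-nested competitor
    (nesting judged from fixed-term sets with identical random structure);
    non-nested pairs are marked not applicable.
    """
    if len(results) < 2:
        raise ValueError("need at least two fits to compare")
    first = results[0]
    for r in results[1:]:
        if r.spec.outcome != first.spec.outcome or r.n_obs != first.n_obs:
            raise ValueError(
                "fits must share the same outcome and fitted rows"
            )
    rows = []
    best_aic = min(r.aic for r in results)
    best_bic = min(r.bic for r in results)
    for i, r in enumerate(results):
        terms_i = set(r.spec.fixed_effects)
        lr_stat = lr_df = lr_p = np.nan
        lr_vs = None
        nested = [
            (j, s)
            for j, s in enumerate(results)
            if j != i
            and set(s.spec.fixed_effects) < terms_i
            and s.spec.random == r.spec.random
        ]
        if nested:
            j, s = max(nested, key=lambda js: len(js[1].spec.fixed_effects))
            lr_stat = 2.0 * (r.llf_ml - s.llf_ml)
            lr_df = r.df_model - s.df_model
            lr_p = float(sps.chi2.sf(max(lr_stat, 0.0), max(lr_df, 1)))
            lr_vs = j
        rows.append(
            {
                "model": i,
                "fixed_effects": " + ".join(r.spec.fixed_effects) or "1",
                "df_model": r.df_model,
                "llf": r.llf_ml,
                "aic": r.aic,
                "bic": r.bic,
                "delta_aic": r.aic - best_aic,
                "delta_bic": r.bic - best_bic,
                "lr_vs_model": lr_vs,
                "lr_stat": lr_stat,
                "lr_df": lr_df,
                "lr_p": lr_p,
            }
        )
    return pd.DataFrame(rows)
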