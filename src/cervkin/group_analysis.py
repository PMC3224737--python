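"""Group comparison and discriminant classification of kinematic variables.

Because the patient group is on average older than the controls and some
kinematic variables correlate with age, those variables (by default Peak
Speed, ROM and NPA) are replaced by residuals from an ordinary
least-squares regression on age fitted to the pooled sample before group
comparisons and discriminant analysis.

Classification uses Fisher linear discriminant analysis with a pooled
within-group covariance and, by default, equal priors; sensitivity is the
proportion of patients (NS) correctly classified under leave-one-out
cross-validation and specificity the proportion of controls (CON).
Forward-stepwise variable selection uses the partial F change of Wilks'
lambda with conventional enter/remove thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "DiscriminantResult",
    "AGE_ADJUSTED_VARIABLES",
    "age_adjust",
    "compare_groups",
    "lda_loo",
    "stepwise_lda",
    "subgroup_compare",
]

#: Variables found to correlate with age on the pooled sample, hence
#: age-adjusted before group-difference and discriminant analyses.
AGE_ADJUSTED_VARIABLES = ("peak_speed", "rom", "npa")

KINEMATIC_VARIABLES = ("peak_speed", "rom", "npa", "ad_ratio", "sid", "cm")


@dataclass
class FeatureTable:
    """Subject-level feature matrix: group label, age and the six kinematic
    variable means (optionally a low-back-pain comorbidity flag)."""

    frame: pd.DataFrame  # columns: subject_id, group, age + variables

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "age"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        groups = set(self.frame["group"])
        if not groups <= {"NS", "CON"}:
            raise ValueError(f"unknown group labels {groups - {'NS', 'CON'}}")
        if "NS" not in groups or "CON" not in groups:
            raise ValueError("both NS and CON groups must be non-empty")

    def values(self, variable: str) -> np.ndarray:
        v = self.frame[variable].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"missing values in {variable!r}")
        return v

    @property
    def is_ns(self) -> np.ndarray:
        return (self.frame["group"] == "NS").to_numpy()


@dataclass
class DiscriminantResult:
    selected_variables: list[str]
    coefficients: dict[str, float]  # standardized discriminant weights
    sensitivity: float
    specificity: float
    per_variable_f: dict[str, float] = field(default_factory=dict)


def age_adjust(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residuals of value ~ age by OLS on the pooled sample."""
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if values.size != ages.size or values.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(ages) == 0:
        raise ValueError("constant age: regression is rank-deficient")
    X = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def _maybe_adjust(ft: FeatureTable, variable: str, adjust_for_age: bool) -> np.ndarray:
    v = ft.values(variable)
    if adjust_for_age:
        return age_adjust(v, ft.values("age"))
    return v


def compare_groups(
    ft: FeatureTable, variable: str, adjust_for_age: bool | None = None
) -> dict:
    """Independent-samples t-test of NS vs CON for one variable.

    By default the variable is age-adjusted exactly when it is in
    :data:`AGE_ADJUSTED_VARIABLES`; pass ``adjust_for_age`` to override.
    Group means ± SD are reported on the raw scale.
    """
    if adjust_for_age is None:
        adjust_for_age = variable in AGE_ADJUSTED_VARIABLES
    raw = ft.values(variable)
    v = _maybe_adjust(ft, variable, adjust_for_age)
    ns, con = v[ft.is_ns], v[~ft.is_ns]
    if ns.size < 2 or con.size < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(ns, ddof=1) + np.var(con, ddof=1) == 0:
        raise ValueError("zero pooled variance: t-test degenerate")
    t, p = stats.ttest_ind(ns, con)
    raw_ns, raw_con = raw[ft.is_ns], raw[~ft.is_ns]
    return {
        "variable": variable,
        "t": float(t),
        "p": float(p),
        "adjusted_for_age": adjust_for_age,
        "ns_mean": float(raw_ns.mean()),
        "ns_sd": float(raw_ns.std(ddof=1)),
        "con_mean": float(raw_con.mean()),
        "con_sd": float(raw_con.std(ddof=1)),
        "n_ns": int(ns.size),
        "n_con": int(con.size),
    }


def _design(ft: FeatureTable, variables: list[str], adjust_for_age: bool) -> np.ndarray:
    cols = [
        _maybe_adjust(ft, v, adjust_for_age and v in AGE_ADJUSTED_VARIABLES)
        for v in variables
    ]
    return np.column_stack(cols)


def _lda_direction(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fisher direction w = S_pooled⁻¹ (μ1 − μ0) with class means and pooled
    within-group covariance."""
    X0, X1 = X[~y], X[y]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = X0.shape[0], X1.shape[0]
    S = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
         + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
         ) / (n0 + n1 - 2)
    cond = np.linalg.cond(S)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"singular pooled covariance (condition number {cond:.1e}); "
            "check for collinear variables"
        )
    w = np.linalg.solve(S, mu1 - mu0)
    return w, mu0, mu1, S


def _classify(X: np.ndarray, w: np.ndarray, mu0: np.ndarray, mu1: np.ndarray) -> np.ndarray:
    # equal priors: threshold midway between projected class means
    z = X @ w
    c = 0.5 * (mu0 @ w + mu1 @ w)
    return z > c


def lda_loo(
    ft: FeatureTable, variables: list[str], adjust_for_age: bool = True
) -> DiscriminantResult:
    """Fisher LDA with pooled covariance, equal priors and leave-one-out
    cross-validated sensitivity (NS) and specificity (CON).

    Standardized coefficients are the discriminant weights multiplied by the
    pooled within-group SD of each variable, normalised to unit length.
    """
    y = ft.is_ns  # True = NS (the "positive" class)
    X = _design(ft, list(variables), adjust_for_age)
    n, p = X.shape
    if min(y.sum(), (~y).sum()) <= p + 1:
        raise ValueError("each group must exceed the number of variables + 1")
    correct = np.zeros(n, bool)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        w, mu0, mu1, _ = _lda_direction(X[mask], y[mask])
        pred = _classify(X[i : i + 1], w, mu0, mu1)[0]
        correct[i] = pred == y[i]
    sens = float(correct[y].mean())
    spec = float(correct[~y].mean())
    w, mu0, mu1, S = _lda_direction(X, y)
    sd = np.sqrt(np.diag(S))
    std_coef = w * sd
    std_coef = std_coef / np.linalg.norm(std_coef)
    per_f = {}
    for j, name in enumerate(variables):
        t, _ = stats.ttest_ind(X[y, j], X[~y, j])
        per_f[name] = float(t**2)
    return DiscriminantResult(
        selected_variables=list(variables),
        coefficients={name: float(c) for name, c in zip(variables, std_coef)},
        sensitivity=sens,
        specificity=spec,
        per_variable_f=per_f,
    )


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' Λ = det(W)/det(T) for the two-group one-way layout."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for cls in (False, True):
        Xc = X[y == cls]
        W += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
    detT = np.linalg.det(T)
    if detT <= 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


def _partial_f(lam_old: float, lam_new: float, n: int, g: int, p_in: int) -> float:
    """F-to-enter for adding one variable to a p_in-variable model."""
    if lam_new <= 0:
        return np.inf
    return (n - g - p_in) / (g - 1) * (lam_old / lam_new - 1.0)


def stepwise_lda(
    ft: FeatureTable,
    variables: list[str],
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    adjust_for_age: bool = True,
) -> DiscriminantResult:
    """Forward-stepwise variable selection by Wilks'-lambda partial F, then a
    leave-one-out LDA fit of the selected set.

    Variables enter while their F-to-enter exceeds ``f_enter`` and are
    removed when their F-to-remove drops below ``f_remove`` (the SPSS-style
    defaults 3.84/2.71).  An empty selection returns a chance-level result.
    """
    y = ft.is_ns
    names = list(variables)
    X_all = _design(ft, names, adjust_for_age)
    n, g = X_all.shape[0], 2
    selected: list[int] = []
    while True:
        changed = False
        lam_cur = _wilks_lambda(X_all[:, selected], y) if selected else 1.0
        # entry step
        best_j, best_f = None, f_enter
        for j in range(len(names)):
            if j in selected:
                continue
            cols = selected + [j]
            Xc = X_all[:, cols]
            if np.linalg.matrix_rank(Xc - Xc.mean(axis=0)) < len(cols):
                continue  # collinear with current model: partial F undefined
            lam_new = _wilks_lambda(Xc, y)
            f = _partial_f(lam_cur, lam_new, n, g, len(selected))
            if f > best_f:
                best_j, best_f = j, f
        if best_j is not None:
            selected.append(best_j)
            changed = True
        # removal step
        if len(selected) > 1:
            lam_cur = _wilks_lambda(X_all[:, selected], y)
            worst_j, worst_f = None, f_remove
            for j in list(selected):
                rest = [k for k in selected if k != j]
                lam_red = _wilks_lambda(X_all[:, rest], y)
                f = _partial_f(lam_red, lam_cur, n, g, len(rest))
                if f < worst_f:
                    worst_j, worst_f = j, f
            if worst_j is not None:
                selected.remove(worst_j)
                changed = True
        if not changed:
            break
    if not selected:
        return DiscriminantResult(
            selected_variables=[], coefficients={}, sensitivity=0.5, specificity=0.5
        )
    sel_names = [names[j] for j in selected]
    result = lda_loo(ft, sel_names, adjust_for_age=adjust_for_age)
    # report F-to-remove of each selected variable in the final model
    lam_full = _wilks_lambda(X_all[:, selected], y)
    for j, name in zip(selected, sel_names):
        rest = [k for k in selected if k != j]
        lam_red = _wilks_lambda(X_all[:, rest], y) if rest else 1.0
        result.per_variable_f[name] = _partial_f(lam_red, lam_full, n, g, len(rest))
    return result


def subgroup_compare(ft: FeatureTable, variable: str = "peak_speed") -> dict:
    """Effect of concurrent low-back pain within the patient group.

    Independent t-tests of (a) NS with vs without low-back pain and (b) NS
    without low-back pain vs CON, on the raw variable.
    """
    if "low_back_pain" not in ft.frame.columns:
        raise ValueError("feature table has no low_back_pain flag")
    ns = ft.frame[ft.frame["group"] == "NS"]
    if ns["low_back_pain"].isna().any():
        raise ValueError("low_back_pain flag missing for some NS subjects")
    with_lbp = ns[ns["low_back_pain"].astype(bool)][variable].to_numpy(float)
    without_lbp = ns[~ns["low_back_pain"].astype(bool)][variable].to_numpy(float)
    con = ft.frame[ft.frame["group"] == "CON"][variable].to_numpy(float)
    if min(with_lbp.size, without_lbp.size) < 2:
        raise ValueError("low-back-pain subgroup too small")
    t1, p1 = stats.ttest_ind(with_lbp, without_lbp)
    t2, p2 = stats.ttest_ind(without_lbp, con)
    return {
        "variable": variable,
        "with_lbp_mean": float(with_lbp.mean()),
        "with_lbp_sd": float(with_lbp.std(ddof=1)),
        "n_with_lbp": int(with_lbp.size),
        "without_lbp_mean": float(without_lbp.mean()),
        "without_lbp_sd": float(without_lbp.std(ddof=1)),
        "n_without_lbp": int(without_lbp.size),
        "t_within_ns": float(t1),
        "p_within_ns": float(p1),
        "t_without_vs_con": float(t2),
        "p_without_vs_con": float(p2),
    }
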