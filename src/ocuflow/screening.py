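"""Group comparisons and the stepwise logistic screening score.

This module reproduces the statistical machinery of the case-control
analysis: Shapiro-Wilk-gated t / Mann-Whitney group comparisons, Pearson
chi-square on 2x2 tables (no continuity correction), maximum-likelihood
logistic regression by iteratively reweighted least squares, forward
(score-test) / backward (Wald) stepwise selection, Nagelkerke pseudo-R2,
the Hosmer-Lemeshow calibration test over deciles of fitted risk, ROC
analysis with operating-point metrics, and a ranked multi-model
diagnostic-accuracy report.

The screening model is exposed both as plain functions and as a
scikit-learn-compatible estimator, :class:`StepwiseLogisticScreener`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted

from .biomarkers import shapiro_wilk_gate
from .tables import CohortTable, GROUP_CASE, GROUP_CONTROL

__all__ = [
    "ComparisonResult",
    "LogisticScreeningModel",
    "RocCurve",
    "StepwiseTrace",
    "StepRecord",
    "compare_groups",
    "chi_square_2x2",
    "fit_logistic",
    "stepwise_wald",
    "replay_trace",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "roc_analysis",
    "model_comparison_report",
    "format_report",
    "StepwiseLogisticScreener",
    "SeparationError",
]


# ===================================================================== tests
@dataclass
class ComparisonResult:
    variable: str
    test_name: str                      # "t-test" | "Mann-Whitney" | "chi-square"
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    group_summaries: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ComparisonResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Layout: rows are groups, columns the trait — ``[[a, b], [c, d]]``.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(rows, cols) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    pct = lambda x, m: f"{int(x)}/{int(m)} ({100 * x / m:.1f}%)"
    return ComparisonResult(
        variable="", test_name="chi-square", statistic=chi2,
        degrees_of_freedom=1, p_value=p,
        group_summaries={"row1": pct(a, a + b), "row2": pct(c, c + d)},
        extra={"counts": counts.astype(int).tolist()})


def compare_groups(table: CohortTable, variable: str) -> ComparisonResult:
    """Two-group comparison following the normality gate.

    Continuous variables: independent t-test when both groups pass the
    Shapiro-Wilk gate, else Mann-Whitney U (both the median/IQR and
    mean-rank summaries are reported for the rank branch).  Binary
    variables delegate to the 2x2 Pearson chi-square.
    """
    meta = table.meta(variable)
    ctrl = table.group_values(variable, GROUP_CONTROL).to_numpy(dtype=float)
    case = table.group_values(variable, GROUP_CASE).to_numpy(dtype=float)
    if len(ctrl) < 3 or len(case) < 3:
        raise ValueError(f"{variable}: need >= 3 non-missing values per group")

    values = np.concatenate([ctrl, case])
    is_binary = (meta.kind == "binary"
                 or np.isin(np.unique(values), [0.0, 1.0]).all())
    if is_binary:
        res = chi_square_2x2(int(ctrl.sum()), int(len(ctrl) - ctrl.sum()),
                             int(case.sum()), int(len(case) - case.sum()))
        res.variable = variable
        res.group_summaries = {
            GROUP_CONTROL: res.group_summaries.pop("row1"),
            GROUP_CASE: res.group_summaries.pop("row2")}
        return res

    msd = lambda x: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    summaries = {GROUP_CONTROL: msd(ctrl), GROUP_CASE: msd(case)}
    normal = (shapiro_wilk_gate(ctrl).is_normal
              and shapiro_wilk_gate(case).is_normal)
    if normal:
        t, p = stats.ttest_ind(ctrl, case)
        return ComparisonResult(
            variable=variable, test_name="t-test", statistic=float(t),
            degrees_of_freedom=float(len(ctrl) + len(case) - 2),
            p_value=float(p), group_summaries=summaries)
    u, p = stats.mannwhitneyu(ctrl, case, alternative="two-sided")
    ranks = stats.rankdata(values)
    extra = {
        "median_control": float(np.median(ctrl)),
        "median_case": float(np.median(case)),
        "iqr_control": [float(q) for q in np.percentile(ctrl, [25, 75])],
        "iqr_case": [float(q) for q in np.percentile(case, [25, 75])],
        "mean_rank_control": float(ranks[:len(ctrl)].mean()),
        "mean_rank_case": float(ranks[len(ctrl):].mean()),
    }
    return ComparisonResult(
        variable=variable, test_name="Mann-Whitney", statistic=float(u),
        degrees_of_freedom=None, p_value=float(p),
        group_summaries=summaries, extra=extra)


# ================================================================= logistic
class SeparationError(RuntimeError):
    """Raised when maximum-likelihood estimates diverge (perfect separation)."""


@dataclass
class LogisticScreeningModel:
    """A fitted logistic model with the audit trail the report needs."""

    variables: list[str]                # predictor names (no intercept)
    coefficients: np.ndarray            # [intercept, beta_1, ...]
    standard_errors: np.ndarray
    wald_statistics: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    model_chi2: float
    model_df: int
    model_p: float
    n_obs: int
    converged: bool
    separation: bool
    fitted_probabilities: np.ndarray
    y: np.ndarray
    classification_cut: float = 0.5

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def nagelkerke_r2(self) -> float:
        return nagelkerke_r2(self.log_likelihood, self.null_log_likelihood,
                             self.n_obs)

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        eta = self.coefficients[0] + X @ self.coefficients[1:]
        return _expit(eta)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": ["intercept"] + self.variables,
            "beta": self.coefficients,
            "se": self.standard_errors,
            "wald": self.wald_statistics,
            "p": self.p_values,
        })


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        cols = [(["intercept"] + list(names))[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {cols}")


def fit_logistic(y: np.ndarray, X: np.ndarray | pd.DataFrame,
                 feature_names: Sequence[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 50) -> LogisticScreeningModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence when the log-likelihood changes by < ``tol`` (or after
    ``max_iter`` Newton steps).  Standard errors come from the observed
    information at the optimum; Wald statistics are (beta/SE)^2 against
    chi-square(1).  Perfect separation is flagged (``separation=True``)
    when the linear predictor diverges, rather than returned silently.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(k)]
    if n != len(y):
        raise ValueError("y and X have different lengths")
    if n < k + 2:
        raise ValueError(f"need n >= number of parameters + 1 (n={n}, k={k})")
    if k and (np.ptp(X, axis=0) == 0).any():
        j = int(np.flatnonzero(np.ptp(X, axis=0) == 0)[0])
        raise ValueError(f"predictor {feature_names[j]!r} is constant")
    A = np.column_stack([np.ones(n), X])
    _check_rank(A, feature_names)

    beta = np.zeros(k + 1)
    ll_old = -np.inf
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = A @ beta
        if np.max(np.abs(eta)) > 30:
            separation = True
        p = _expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = A.T @ (y - p)
        info = (A * w[:, None]).T @ A
        try:
            step = linalg.solve(info, grad, assume_a="pos")
        except linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        ll = _bernoulli_ll(y, _expit(A @ beta))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    p = _expit(A @ beta)
    w = np.clip(p * (1 - p), 1e-10, None)
    info = (A * w[:, None]).T @ A
    cov = linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = stats.chi2.sf(wald, 1)
    ll1 = _bernoulli_ll(y, p)
    pbar = y.mean()
    ll0 = _bernoulli_ll(y, np.full(n, pbar))
    chi2 = 2.0 * (ll1 - ll0)
    return LogisticScreeningModel(
        variables=list(feature_names),
        coefficients=beta, standard_errors=se, wald_statistics=wald,
        p_values=pvals, log_likelihood=ll1, null_log_likelihood=ll0,
        model_chi2=chi2, model_df=k,
        model_p=float(stats.chi2.sf(chi2, k)) if k else 1.0,
        n_obs=n, converged=converged, separation=separation,
        fitted_probabilities=p, y=y.astype(int))


def _score_test(y: np.ndarray, X_cur: np.ndarray, p_cur: np.ndarray,
                x_new: np.ndarray) -> tuple[float, float]:
    """Rao score test for adding one predictor at the current MLE."""
    n = len(y)
    A = np.column_stack([np.ones(n), X_cur, x_new])
    g = A.T @ (y - p_cur)
    w = np.clip(p_cur * (1 - p_cur), 1e-10, None)
    info = (A * w[:, None]).T @ A
    try:
        stat = float(g @ linalg.solve(info, g, assume_a="pos"))
    except linalg.LinAlgError:
        return 0.0, 1.0
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, 1))


# ================================================================= stepwise
@dataclass
class StepRecord:
    step: int
    action: str         # "enter" | "remove"
    variable: str
    statistic: float    # score statistic on entry, Wald on removal
    p_value: float


@dataclass
class StepwiseTrace:
    records: list[StepRecord] = field(default_factory=list)

    def final_variables(self) -> list[str]:
        current: list[str] = []
        for rec in self.records:
            if rec.action == "enter":
                current.append(rec.variable)
            else:
                current.remove(rec.variable)
        return current

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _stepwise_core(y: np.ndarray, X: pd.DataFrame, p_enter: float,
                   p_remove: float) -> tuple[LogisticScreeningModel, StepwiseTrace]:
    candidates = list(X.columns)
    included: list[str] = []
    trace = StepwiseTrace()
    step = 0
    max_steps = 4 * len(candidates) + 10
    while step < max_steps:
        # forward: smallest score-test entry p below p_enter, with a
        # Bonferroni adjustment over the candidates examined so the
        # family-wise entry rate stays at the nominal level
        current = fit_logistic(y, X[included]) if included else \
            fit_logistic(y, np.empty((len(y), 0)), feature_names=[])
        p_cur = current.fitted_probabilities
        Xc = X[included].to_numpy(dtype=float) if included else \
            np.empty((len(y), 0))
        n_examined = len(candidates) - len(included)
        best: tuple[float, float, str] | None = None
        for name in candidates:
            if name in included:
                continue
            stat, p = _score_test(y, Xc, p_cur, X[name].to_numpy(dtype=float))
            p = min(1.0, p * n_examined)
            if p < p_enter and (best is None or p < best[1]):
                best = (stat, p, name)
        if best is None:
            break
        step += 1
        trace.records.append(StepRecord(step, "enter", best[2], best[0],
                                        best[1]))
        included.append(best[2])
        # backward: drop any included variable whose Wald p exceeds p_remove
        while True:
            fit = fit_logistic(y, X[included])
            worst_j = int(np.argmax(fit.p_values[1:])) if included else -1
            if worst_j < 0 or fit.p_values[1 + worst_j] <= p_remove:
                break
            step += 1
            name = included[worst_j]
            trace.records.append(StepRecord(
                step, "remove", name, float(fit.wald_statistics[1 + worst_j]),
                float(fit.p_values[1 + worst_j])))
            included.remove(name)
            if not included:
                break
    final = (fit_logistic(y, X[included]) if included
             else fit_logistic(y, np.empty((len(y), 0)), feature_names=[]))
    return final, trace


def stepwise_wald(table: CohortTable, outcome: str, candidates: Sequence[str],
                  p_enter: float = 0.05, p_remove: float = 0.10
                  ) -> tuple[LogisticScreeningModel, StepwiseTrace]:
    """Forward (score test) / backward (Wald) logistic selection.

    ``outcome`` is a binary column (or ``"group"``, coded case = 1).
    Complete cases across all candidates are used throughout, so every
    nested fit shares the same rows.  An empty candidate list or no
    qualifying entry yields the intercept-only model with an empty trace.
    """
    y, X = _design_from_table(table, outcome, candidates)
    if candidates and len(y) < 10 * len(candidates):
        raise ValueError(
            f"only {len(y)} complete-case rows for {len(candidates)} "
            "candidates; need >= 10 per candidate")
    return _stepwise_core(y, X, p_enter, p_remove)


def replay_trace(table: CohortTable, outcome: str, candidates: Sequence[str],
                 trace: StepwiseTrace) -> LogisticScreeningModel:
    """Re-fit the final model implied by a recorded trace."""
    y, X = _design_from_table(table, outcome, candidates)
    final = trace.final_variables()
    return (fit_logistic(y, X[final]) if final
            else fit_logistic(y, np.empty((len(y), 0)), feature_names=[]))


def _design_from_table(table: CohortTable, outcome: str,
                       candidates: Sequence[str]
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    for name in candidates:
        if name not in table.data.columns:
            raise KeyError(f"unknown variable {name!r}")
    if outcome == "group":
        y_all = (table.data["group"] == GROUP_CASE).astype(float)
    else:
        y_all = table.data[outcome].astype(float)
    df = pd.concat([y_all.rename("__y"), table.data[list(candidates)]], axis=1)
    df = df.dropna()
    return df["__y"].to_numpy(), df[list(candidates)]


# ============================================================ model quality
def nagelkerke_r2(log_likelihood: float, null_log_likelihood: float,
                  n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R2, bounded in [0, 1]."""
    if log_likelihood < null_log_likelihood - 1e-9:
        raise ValueError("fitted log-likelihood below the null model's "
                         "(impossible for nested MLE)")
    cox_snell = 1.0 - np.exp(2.0 * (null_log_likelihood - log_likelihood) / n)
    max_cs = 1.0 - np.exp(2.0 * null_log_likelihood / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


@dataclass
class HosmerLemeshowResult:
    chi2: float
    df: int
    p_value: float
    n_groups: int
    merged: bool
    table: pd.DataFrame


def hosmer_lemeshow(fit: LogisticScreeningModel,
                    g: int = 10) -> HosmerLemeshowResult:
    """Calibration chi-square over ``g`` groups of fitted risk, df = g - 2.

    Groups are deciles of the fitted probability with ties kept together;
    groups with zero expected events are merged into their neighbour and
    the merge recorded.
    """
    p = fit.fitted_probabilities
    y = fit.y
    if len(p) < 2 * g:
        raise ValueError(f"need n >= 2g observations (n={len(p)}, g={g})")
    if g - 2 < 1:
        raise ValueError("Hosmer-Lemeshow requires g >= 3 (df = g - 2 >= 1)")
    bins = pd.qcut(p, g, duplicates="drop")
    df_ = pd.DataFrame({"y": y, "p": p, "bin": bins})
    grouped = df_.groupby("bin", observed=True).agg(
        n=("y", "size"), observed=("y", "sum"), mean_p=("p", "mean"))
    grouped["expected"] = grouped["n"] * grouped["mean_p"]
    merged = len(grouped) < g
    # merge any group whose expected count vanishes
    while ((grouped["expected"] <= 0)
           | (grouped["expected"] >= grouped["n"])).any() and len(grouped) > 3:
        bad = int(np.argmax((grouped["expected"] <= 0).to_numpy()
                            | (grouped["expected"] >= grouped["n"]).to_numpy()))
        tgt = bad - 1 if bad > 0 else bad + 1
        rows = grouped.reset_index(drop=True)
        rows.loc[tgt, ["n", "observed"]] += rows.loc[bad, ["n", "observed"]]
        rows.loc[tgt, "mean_p"] = (
            (rows.loc[tgt, "expected"] + rows.loc[bad, "expected"])
            / rows.loc[tgt, "n"])
        rows.loc[tgt, "expected"] = rows.loc[tgt, "n"] * rows.loc[tgt, "mean_p"]
        grouped = rows.drop(index=bad).reset_index(drop=True)
        merged = True
    n_groups = len(grouped)
    df_free = n_groups - 2
    if df_free < 1:
        raise ValueError("fewer than 3 usable risk groups after merging")
    chi2 = float((((grouped["observed"] - grouped["expected"]) ** 2)
                  / (grouped["expected"] * (1 - grouped["mean_p"]))).sum())
    return HosmerLemeshowResult(
        chi2=chi2, df=df_free, p_value=float(stats.chi2.sf(chi2, df_free)),
        n_groups=n_groups, merged=merged,
        table=grouped.reset_index(drop=True))


# ===================================================================== ROC
@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    operating_point: dict[str, float]   # at the classification cut
    youden_point: dict[str, float]
    classification_cut: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("AUROC outside [0, 1]")


def _operating_metrics(scores: np.ndarray, labels: np.ndarray,
                       cut: float) -> dict[str, float]:
    pred = scores >= cut
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / len(labels)
    return {"threshold": float(cut), "sensitivity": sens, "specificity": spec,
            "ppv": ppv, "npv": npv, "accuracy": acc}


def roc_analysis(scores: Sequence[float], labels: Sequence[int],
                 classification_cut: float = 0.5) -> RocCurve:
    """ROC curve with trapezoidal AUROC and operating-point metrics.

    Thresholds sit at every distinct score; tied scores are handled by the
    trapezoid (midrank) rule, so the AUROC equals the Mann-Whitney
    concordance probability.  The operating point is evaluated at
    ``classification_cut`` (predict positive when score >= cut); the
    Youden-optimal point is reported alongside.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    op = _operating_metrics(scores, labels, classification_cut)
    j = int(np.argmax(tpr - fpr))
    youden_cut = float(thr[j]) if np.isfinite(thr[j]) else float(scores.max())
    youden = _operating_metrics(scores, labels, youden_cut)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auroc=auroc, operating_point=op, youden_point=youden,
                    classification_cut=classification_cut)


# ================================================================== report
def model_comparison_report(table: CohortTable,
                            model_specs: Sequence[Sequence[str]],
                            outcome: str = "group",
                            classification_cut: float = 0.5) -> pd.DataFrame:
    """Ranked diagnostic-accuracy report over candidate variable sets.

    For each spec the logistic model is fitted on complete cases, scored
    in-sample, and summarised as AUROC plus sensitivity / specificity /
    PPV / NPV (percent) at the classification cut.  Rows are sorted by
    AUROC, descending.
    """
    rows = []
    for spec_vars in model_specs:
        spec_vars = list(spec_vars)
        if not spec_vars:
            raise ValueError("empty variable set in model spec")
        y, X = _design_from_table(table, outcome, spec_vars)
        fit = fit_logistic(y, X)
        roc = roc_analysis(fit.fitted_probabilities, fit.y,
                           classification_cut)
        op = roc.operating_point
        label = ", ".join(table.meta(v).display_name for v in spec_vars)
        rows.append({
            "model": label,
            "variables": tuple(spec_vars),
            "auroc": roc.auroc,
            "sensitivity_pct": 100 * op["sensitivity"],
            "specificity_pct": 100 * op["specificity"],
            "ppv_pct": 100 * op["ppv"],
            "npv_pct": 100 * op["npv"],
            "nagelkerke_r2": fit.nagelkerke_r2,
        })
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values("auroc", ascending=False,
                                    kind="stable").reset_index(drop=True)
    return report


def format_report(report: pd.DataFrame) -> str:
    """Render the model-comparison report as aligned text."""
    if report.empty:
        return "(no models)"
    hdr = (f"{'Model':48s} {'AUROC':>6s} {'Sens%':>6s} {'Spec%':>6s} "
           f"{'PPV%':>6s} {'NPV%':>6s}")
    lines = [hdr, "-" * len(hdr)]
    for _, r in report.iterrows():
        lines.append(
            f"{r['model'][:48]:48s} {r['auroc']:6.3f} "
            f"{r['sensitivity_pct']:6.1f} {r['specificity_pct']:6.1f} "
            f"{r['ppv_pct']:6.1f} {r['npv_pct']:6.1f}")
    return "\n".join(lines)


# ============================================================ sklearn facade
class StepwiseLogisticScreener(BaseEstimator, ClassifierMixin):
    """Stepwise-Wald logistic screening score as a sklearn classifier.

    Forward selection by score test (entry at ``p_enter``), backward
    elimination by Wald (removal above ``p_remove``), iterated to a fixed
    point.  After :meth:`fit`, the selected variables, coefficients, the
    full selection trace and the fit diagnostics (Nagelkerke R2,
    Hosmer-Lemeshow, training ROC) are available as attributes.

    Examples
    --------
    >>> screener = StepwiseLogisticScreener(p_enter=0.05, p_remove=0.10)
    >>> screener.fit(X, y).variables_        # doctest: +SKIP
    ['log10 NT-proBNP', 'log10 adiponectin', 'vs']
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 classification_cut: float = 0.5,
                 hosmer_lemeshow_groups: int = 10):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.classification_cut = classification_cut
        self.hosmer_lemeshow_groups = hosmer_lemeshow_groups

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "StepwiseLogisticScreener":
        if isinstance(X, pd.DataFrame):
            X_df = X.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D")
            X_df = pd.DataFrame(X, columns=[f"x{i + 1}"
                                            for i in range(X.shape[1])])
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary outcome required")
        y_bin = (y == self.classes_[1]).astype(float)
        keep = ~(X_df.isna().any(axis=1) | pd.isna(y_bin))
        X_df, y_bin = X_df.loc[keep].reset_index(drop=True), y_bin[keep.to_numpy()]

        model, trace = _stepwise_core(y_bin, X_df, self.p_enter, self.p_remove)
        model.classification_cut = self.classification_cut
        self.model_ = model
        self.trace_ = trace
        self.variables_ = list(model.variables)
        self.coef_ = model.coefficients[1:].reshape(1, -1)
        self.intercept_ = np.array([model.intercept])
        self.n_features_in_ = X_df.shape[1]
        self.feature_names_in_ = np.asarray(X_df.columns, dtype=object)
        self.nagelkerke_r2_ = model.nagelkerke_r2
        try:
            self.hosmer_lemeshow_ = hosmer_lemeshow(
                model, self.hosmer_lemeshow_groups)
        except ValueError:
            self.hosmer_lemeshow_ = None
        if model.variables:
            self.roc_ = roc_analysis(model.fitted_probabilities, model.y,
                                     self.classification_cut)
        else:
            self.roc_ = None
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            return X[self.variables_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        sel = [list(self.feature_names_in_).index(v) for v in self.variables_]
        return X[:, sel]

    def decision_function(self, X) -> np.ndarray:
        Xs = self._prepare(X)
        return self.intercept_[0] + Xs @ self.coef_.ravel()

    def predict_proba(self, X) -> np.ndarray:
        p = _expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.classification_cut).astype(int)]
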