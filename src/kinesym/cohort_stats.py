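"""Cohort-level statistics.

LID-presence classification against a control-referenced threshold,
per-task success criteria (control mean + 2 SD for time and errors),
Kruskal-Wallis group comparison, maximum-likelihood logistic regression with
purposeful variable selection (significance plus ≥15% change-in-estimate
confounding), ROC curves with Youden-index cutpoints, and nearest-in-time
pairing of sequential symptom assessments with task executions.

Sample standard deviations (n−1) are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

#: coefficients beyond this magnitude are treated as evidence of separation
_SEPARATION_COEF = 20.0


# ---------------------------------------------------------------------------
# LID presence
# ---------------------------------------------------------------------------

@dataclass
class LidPresenceResult:
    threshold: float
    labels: dict[str, bool]
    overridden: dict[str, str]  # participant -> reason
    confusion: dict[str, int] | None = None


def lid_presence_classify(
    participant_stats: dict[str, float],
    control_stats: np.ndarray,
    overrides: dict[str, tuple[bool, str]] | None = None,
    truth: dict[str, bool] | None = None,
) -> LidPresenceResult:
    """Label participants LID-positive when their maximum movement-time LID
    statistic exceeds the control mean + 1 SD threshold.

    ``overrides`` maps participant id to (label, reason) and replaces the
    manual video-based readjustment of the groups; every override is logged.
    When ``truth`` labels are supplied a confusion count is emitted.
    """
    control_stats = np.asarray(list(control_stats), dtype=float)
    if len(control_stats) < 2:
        raise ValueError("at least 2 control statistics are required")
    threshold = float(np.mean(control_stats) + np.std(control_stats, ddof=1))

    labels = {pid: bool(stat > threshold) for pid, stat in participant_stats.items()}
    overridden: dict[str, str] = {}
    for pid, (label, reason) in (overrides or {}).items():
        if pid in labels and labels[pid] != label:
            labels[pid] = label
            overridden[pid] = reason

    confusion = None
    if truth is not None:
        tp = sum(labels[p] and truth[p] for p in labels if p in truth)
        fp = sum(labels[p] and not truth[p] for p in labels if p in truth)
        fn = sum(not labels[p] and truth[p] for p in labels if p in truth)
        tn = sum(not labels[p] and not truth[p] for p in labels if p in truth)
        confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return LidPresenceResult(threshold, labels, overridden, confusion)


# ---------------------------------------------------------------------------
# Success criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskCriteria:
    time_threshold: float
    error_threshold: float
    n_controls: int
    degenerate_error_sd: bool = False  # control error SD was 0


def success_criteria(cohort: pd.DataFrame) -> dict[str, TaskCriteria]:
    """Per-task thresholds: control mean + 2 sample SD of time and errors.

    Tasks with fewer than 2 control rows are skipped with a warning.  A zero
    control error SD degenerates the error threshold to the control mean;
    this is flagged so reports can call it out.
    """
    criteria: dict[str, TaskCriteria] = {}
    for task, grp in cohort.groupby("task_id"):
        controls = grp[grp["group"] == "control"]
        if len(controls) < 2:
            warnings.warn(f"task {task}: fewer than 2 controls, criteria undefined",
                          stacklevel=2)
            continue
        t = controls["time_s"].to_numpy(dtype=float)
        e = controls["error_count"].to_numpy(dtype=float)
        e_sd = float(np.std(e, ddof=1))
        criteria[str(task)] = TaskCriteria(
            time_threshold=float(np.mean(t) + 2.0 * np.std(t, ddof=1)),
            error_threshold=float(np.mean(e) + 2.0 * e_sd),
            n_controls=len(controls),
            degenerate_error_sd=(e_sd == 0.0),
        )
    return criteria


def derive_success(
    cohort: pd.DataFrame, criteria: dict[str, TaskCriteria] | None = None
) -> pd.DataFrame:
    """Add a boolean ``success`` column; rows of tasks without criteria get NA."""
    if criteria is None:
        criteria = success_criteria(cohort)
    out = cohort.copy()
    success = pd.array([pd.NA] * len(out), dtype="boolean")
    for i, (_, row) in enumerate(out.iterrows()):
        crit = criteria.get(str(row["task_id"]))
        if crit is not None:
            success[i] = bool(
                row["time_s"] <= crit.time_threshold
                and row["error_count"] <= crit.error_threshold
            )
    out["success"] = success
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from chi-square.

    Implemented from the rank-sum formula (not delegated) so the test suite
    can cross-check it against an independent reference implementation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = spstats.rankdata(pooled)

    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += np.sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:  # every observation identical
        return 0.0, 1.0
    h /= denom
    p = float(spstats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    names: list[str]
    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray
    converged: bool
    separation: bool
    n_iter: int
    llf: float

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = spstats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - z * self.se, self.params + z * self.se])

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood binomial logistic fit by Newton/IRLS.

    Wald standard errors from the inverse observed information.  Diverging
    coefficients (|beta| beyond 20, the signature of separation) or
    non-convergence within ``max_iter`` iterations are flagged on the result
    rather than silently reported.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + list(names)
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"n={n} must exceed the {k} parameters")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        hess += 1e-10 * np.eye(k)  # guard against singular information
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35))), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = p * (1.0 - p)
    hess = (X * w[:, None]).T @ X + 1e-10 * np.eye(k)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * spstats.norm.sf(np.abs(z))
    separation = bool(np.max(np.abs(beta)) > _SEPARATION_COEF)
    return LogisticFit(
        names=list(names), params=beta, se=se, pvalues=pvals, cov=cov,
        converged=converged, separation=separation, n_iter=it, llf=llf,
    )


# ---------------------------------------------------------------------------
# Purposeful selection
# ---------------------------------------------------------------------------

@dataclass
class PredictorResult:
    name: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    confounder: bool


@dataclass
class SelectionResult:
    retained: list[PredictorResult]
    dropped: dict[str, str]  # name -> reason
    fit: LogisticFit | None
    converged: bool
    separation: bool
    univariate_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def retained_names(self) -> list[str]:
        return [r.name for r in self.retained]


def _max_relative_change(full: LogisticFit, reduced: LogisticFit) -> float:
    """Largest relative change of any shared non-intercept coefficient."""
    change = 0.0
    for name in reduced.names:
        if name == "intercept" or name not in full.names:
            continue
        b_full = full.coef(name)
        if abs(b_full) < 1e-8:
            continue
        change = max(change, abs((reduced.coef(name) - b_full) / b_full))
    return change


def purposeful_selection(
    y: np.ndarray,
    X: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_stay: float = 0.05,
    confound_pct: float = 15.0,
    max_rounds: int = 25,
    pvalue_method: str = "lrt",
) -> SelectionResult:
    """Purposeful variable selection for a binary outcome.

    1. Univariate logistic screen: keep predictors with p < ``alpha_enter``.
    2. Joint fit; iteratively delete the least-significant predictor with
       p >= ``alpha_stay`` unless its removal changes any remaining
       coefficient by at least ``confound_pct`` percent, in which case it is
       retained and flagged as a confounder.
    3. Re-offer every excluded predictor one at a time to the final model,
       re-admitting those now significant; repeat from 2 until stable.

    Selection decisions use likelihood-ratio p-values by default
    (``pvalue_method="wald"`` switches to Wald): under the strong effects
    and small samples where selection matters, Wald tests lose power as
    coefficients drift toward separation, while the LRT does not.  Reported
    confidence intervals remain Wald intervals.
    """
    y = np.asarray(y, dtype=float)
    candidates = list(X.columns)
    if not candidates:
        raise ValueError("at least one candidate predictor is required")
    if pvalue_method not in ("lrt", "wald"):
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")

    def joint(cols: list[str]) -> LogisticFit:
        if not cols:
            return fit_logistic(y, np.empty((len(y), 0)), names=[])
        return fit_logistic(y, X[cols])

    def term_pvalue(cols: list[str], name: str, full: LogisticFit | None = None) -> float:
        """p-value of one predictor within the model over ``cols``."""
        full = full if full is not None else joint(cols)
        if pvalue_method == "wald":
            return full.pvalue(name)
        reduced = joint([c for c in cols if c != name])
        lr = max(0.0, 2.0 * (full.llf - reduced.llf))
        return float(spstats.chi2.sf(lr, df=1))

    uni_p: dict[str, float] = {name: term_pvalue([name], name) for name in candidates}

    current = [c for c in candidates if uni_p[c] < alpha_enter]
    dropped = {c: f"univariate p={uni_p[c]:.3g} >= {alpha_enter}"
               for c in candidates if c not in current}
    confounders: set[str] = set()

    if not current:
        return SelectionResult([], dropped, None, True, False, uni_p)

    for _ in range(max_rounds):
        # -- backward pass with change-in-estimate confounding check
        changed = True
        while changed and current:
            changed = False
            fit = joint(current)
            pvals = {c: term_pvalue(current, c, fit) for c in current}
            removable = sorted(
                (c for c in current if c not in confounders and pvals[c] >= alpha_stay),
                key=lambda c: -pvals[c],
            )
            for cand in removable:
                rest = [c for c in current if c != cand]
                reduced = joint(rest)
                if rest and _max_relative_change(fit, reduced) * 100.0 >= confound_pct:
                    confounders.add(cand)
                    continue
                current = rest
                dropped[cand] = f"backward p={pvals[cand]:.3g} >= {alpha_stay}"
                changed = True
                break

        # -- forward re-entry of excluded predictors
        readmitted = []
        for cand in [c for c in candidates if c not in current]:
            if term_pvalue(current + [cand], cand) < alpha_stay:
                readmitted.append(cand)
        if not readmitted:
            break
        for cand in readmitted:
            current.append(cand)
            dropped.pop(cand, None)

    if not current:
        return SelectionResult([], dropped, None, True, False, uni_p)

    fit = joint(current)
    ci = np.clip(fit.conf_int(), -700.0, 700.0)  # exp() overflow guard
    retained = []
    for name in current:
        i = fit.names.index(name)
        retained.append(PredictorResult(
            name=name,
            coef=float(fit.params[i]),
            odds_ratio=float(np.exp(fit.params[i])),
            ci_low=float(np.exp(ci[i, 0])),
            ci_high=float(np.exp(ci[i, 1])),
            pvalue=term_pvalue(current, name, fit),
            confounder=name in confounders,
        ))
    return SelectionResult(retained, dropped, fit, fit.converged, fit.separation, uni_p)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocYouden:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_j: float
    cutpoint: float
    flipped: bool = False


def roc_youden(
    scores: np.ndarray, outcome: np.ndarray, direction: str = "as-is"
) -> RocYouden:
    """ROC curve, AUC and Youden-index cutpoint.

    ``outcome`` is 1 for the event class; a score calls the event when it is
    at or above the threshold.  The AUC is the Mann-Whitney statistic (ties
    counted half) and may fall below 0.5 under ``direction="as-is"``;
    ``direction="auto"`` flips the score sign when AUC < 0.5 and reports the
    cutpoint on the original scale with ``flipped=True``.  Ties in J break
    toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")

    ranks = spstats.rankdata(scores)
    auc = (np.sum(ranks[outcome == 1]) - len(pos) * (len(pos) + 1) / 2.0) / (
        len(pos) * len(neg)
    )
    if direction == "auto" and auc < 0.5:
        res = roc_youden(-scores, outcome, direction="as-is")
        return RocYouden(
            thresholds=-res.thresholds,
            sensitivity=res.sensitivity,
            specificity=res.specificity,
            auc=res.auc,
            youden_j=res.youden_j,
            cutpoint=-res.cutpoint,
            flipped=True,
        )
    if direction not in ("as-is", "auto"):
        raise ValueError(f"unknown direction {direction!r}")

    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    sens = np.array([np.mean(pos >= t) for t in thresholds])
    spec = np.array([np.mean(neg < t) for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first maximum -> lowest threshold on ties
    return RocYouden(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_j=float(j[best]),
        cutpoint=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# Nearest-in-time pairing
# ---------------------------------------------------------------------------

def pair_nearest_assessment(
    adl_time_s: float,
    assessment_times_s: np.ndarray,
    values: np.ndarray | None = None,
    max_gap_s: float = 600.0,
):
    """Value (or time) of the assessment closest in time to a task execution.

    Returns None when no assessment lies within ±``max_gap_s``.  Ties pick
    the earlier assessment.
    """
    times = np.asarray(assessment_times_s, dtype=float)
    if times.size == 0:
        return None
    gaps = np.abs(times - adl_time_s)
    order = np.lexsort((times, gaps))  # gap first, earlier time on ties
    best = order[0]
    if gaps[best] > max_gap_s:
        return None
    return float(times[best]) if values is None else values[best]
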