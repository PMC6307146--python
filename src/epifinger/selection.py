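"""Elastic-net selection cascade, medication filter, and fingerprint model.

The EWAS screen is deliberately liberal (FDR < 0.15), so the surviving CpGs
are distilled in two stages of penalized logistic regression: an elastic
net on the discovery cohort, then a second elastic net on an independent
refinement cohort restricted to the stage-1 non-zero CpGs.  CpGs whose
methylation change tracks starting or stopping one of seven commonly
prescribed post-MI medication classes are then removed (Bonferroni over
all CpG x class tests), and the remaining fingerprint CpGs are re-weighted
by unpenalized logistic regression.  Discrimination is summarized by the
ROC AUC with a one-sided Mann-Whitney test against AUC = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MEDICATION_CLASSES

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class SelectionResult:
    """Outcome of one elastic-net stage."""

    stage: str                      # "discovery_enet" or "refinement_enet"
    input_cpgs: list[str]
    coefficients: dict[str, float]  # original-delta-scale, all inputs
    intercept: float
    alpha: float                    # L1/L2 mixing (glmnet alpha)
    lam: float                      # chosen penalty strength
    lambda_strategy: str
    seed: int
    folds: int

    @property
    def selected(self) -> list[str]:
        return [c for c in self.input_cpgs
                if self.coefficients.get(c, 0.0) != 0.0]


@dataclass
class MedAssocRecord:
    """One CpG x medication-class joint start/stop association test."""

    cpg: str
    medication_class: str
    statistic: float
    p: float
    bonferroni_threshold: float
    significant: bool
    contrasts_tested: tuple[str, ...] = ()


@dataclass
class FingerprintModel:
    """Final CpG panel with logistic weights on the ΔCpG scale."""

    cpgs: list[str]
    intercept: float
    weights: dict[str, float]
    training_cohort: str = ""
    n: int = 0
    n_events: int = 0
    flag: str = ""  # "" or "ridge_stabilized"

    def score(self, wide: pd.DataFrame) -> np.ndarray:
        """Linear predictor for each individual in ``wide``."""
        missing = [c for c in self.cpgs if c not in wide.columns]
        if missing:
            raise ValueError(f"cohort lacks model CpGs: {missing}")
        x = wide[self.cpgs].to_numpy(dtype=float)
        w = np.array([self.weights[c] for c in self.cpgs])
        return self.intercept + x @ w


@dataclass
class RocResult:
    auc: float
    p: float                       # one-sided vs AUC = 0.5
    fpr: np.ndarray
    tpr: np.ndarray
    n: int
    n_events: int


# ---------------------------------------------------------------------------
# elastic-net logistic path with stratified cross-validated deviance
# ---------------------------------------------------------------------------

def _lambda_path(x_std: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_lambdas: int = 30) -> np.ndarray:
    # floor at 1% of lambda_max: with tens of events the deep end of the
    # path is near-separable, never CV-optimal, and very slow to fit
    n = len(y)
    resid0 = y - y.mean()
    lam_max = np.abs(x_std.T @ resid0).max() / (n * l1_ratio)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 0.01, num=n_lambdas)


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _enet_logistic_irls(x_std, y, lam, l1_ratio, coef, intercept,
                        tol=1e-7, max_outer=60, max_inner=300):
    """One elastic-net logistic fit by IRLS with coordinate descent.

    Minimizes (1/n) Σ logloss + lam * (l1_ratio*|β|₁ + (1-l1_ratio)/2*|β|²)
    over standardized predictors, warm-started from (coef, intercept).
    The quadratic subproblem is solved coordinate-wise over the active set
    with incremental residual updates; IRLS weights are floored to keep
    near-separated fits numerically stable.
    """
    n, p = x_std.shape
    l1 = lam * l1_ratio
    l2 = lam * (1.0 - l1_ratio)
    coef = coef.copy()
    eta = intercept + x_std @ coef
    for _ in range(max_outer):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        r = z - eta                       # working residual
        wx2 = (w[:, None] * x_std ** 2).sum(axis=0) / n
        active = np.flatnonzero(coef) if np.any(coef) else np.arange(p)
        full_sweep_next = active.size == p
        delta_outer = 0.0
        for _ in range(max_inner):
            max_delta = 0.0
            for j in active:
                old = coef[j]
                grad = (w * x_std[:, j] * r).sum() / n + wx2[j] * old
                new = _soft_threshold(grad, l1) / (wx2[j] + l2)
                if new != old:
                    r -= x_std[:, j] * (new - old)
                    coef[j] = new
                    max_delta = max(max_delta, abs(new - old))
            new_int = intercept + (w * r).sum() / w.sum()
            r -= new_int - intercept
            max_delta = max(max_delta, abs(new_int - intercept))
            intercept = new_int
            delta_outer = max(delta_outer, max_delta)
            if max_delta < tol:
                if full_sweep_next:
                    break
                # KKT check over all predictors: any violator joins in
                grads = (w[None, :] @ (x_std * r[:, None])).ravel() / n
                violators = np.flatnonzero(
                    (coef == 0) & (np.abs(grads) > l1 + tol))
                if violators.size == 0:
                    break
                active = np.union1d(active, violators)
                full_sweep_next = active.size == p
        eta = z - r
        if delta_outer < 10 * tol:
            break
    return coef, float(intercept)


def _path_fit(x_std, y, lambdas, l1_ratio, tol=1e-7):
    """Warm-started elastic-net logistic fits along a descending path.

    Yields (lambda, coef_std, intercept) per step.
    """
    y = np.asarray(y, dtype=float)
    p0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    coef = np.zeros(x_std.shape[1])
    intercept = float(np.log(p0 / (1 - p0)))
    for lam in lambdas:
        coef, intercept = _enet_logistic_irls(
            x_std, y, lam, l1_ratio, coef, intercept, tol=tol)
        yield lam, coef.copy(), intercept


def _binomial_deviance(y, eta) -> float:
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def elastic_net_select(
    wide: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    alpha: float = 0.5,
    lambda_strategy: str | float = "1se",
    seed: int = 0,
    folds: int = 10,
    stage: str = "discovery_enet",
) -> SelectionResult:
    """Penalized logistic selection of CpGs predictive of incident MI.

    Predictors are standardized internally; returned coefficients are on
    the original ΔCpG scale.  The penalty strength is chosen by
    stratified K-fold cross-validated binomial deviance over a glmnet-style
    geometric lambda path ("min" = deviance minimizer, "1se" = sparsest
    model within one standard error of it), or fixed when
    ``lambda_strategy`` is numeric.  ``alpha`` is the L1 fraction of the
    penalty and must be positive: a pure ridge fit never produces exact
    zeros, so "non-zero coefficient" selection would be undefined.
    """
    from sklearn.model_selection import StratifiedKFold

    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]; ridge (alpha=0) cannot "
                         "define a non-zero-coefficient selection")
    y = np.asarray(outcome, dtype=float)
    if wide.isna().to_numpy().any():
        raise ValueError("predictors contain missing values")
    x = wide.to_numpy(dtype=float)
    cpgs = list(wide.columns)
    n = len(y)
    n_events = int(y.sum())

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    x_std = (x - mean) / sd_safe

    fixed_lam = None
    if isinstance(lambda_strategy, (int, float)):
        fixed_lam = float(lambda_strategy)
        lambda_strategy = f"fixed:{fixed_lam:g}"

    if fixed_lam is None:
        if n_events < folds:
            new_folds = max(2, n_events)
            logger.warning("only %d events; reducing CV folds %d -> %d",
                           n_events, folds, new_folds)
            folds = new_folds
        lambdas = _lambda_path(x_std, y, alpha)
        dev = np.zeros((folds, len(lambdas)))
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed)
        for f, (tr, va) in enumerate(skf.split(x_std, y)):
            for k, (_, coef, b0) in enumerate(
                    _path_fit(x_std[tr], y[tr], lambdas, alpha)):
                eta = x_std[va] @ coef + b0
                dev[f, k] = _binomial_deviance(y[va], eta)
        mean_dev = dev.mean(axis=0)
        k_min = int(np.argmin(mean_dev))
        if lambda_strategy == "1se":
            se_min = dev[:, k_min].std(ddof=1) / np.sqrt(folds)
            ok = np.flatnonzero(mean_dev <= mean_dev[k_min] + se_min)
            k_choice = int(ok[0])  # path is descending: first = sparsest
        elif lambda_strategy == "min":
            k_choice = k_min
        else:
            raise ValueError(f"unknown lambda_strategy {lambda_strategy!r}")
        chosen = lambdas[k_choice]
        final_path = lambdas[:k_choice + 1]
    else:
        chosen = fixed_lam
        lam_max = _lambda_path(x_std, y, alpha)[0]
        final_path = (np.geomspace(lam_max, chosen, num=20)
                      if chosen < lam_max else np.array([chosen]))

    coef_std, b0 = None, 0.0
    for _, coef_std, b0 in _path_fit(x_std, y, final_path, alpha):
        pass
    coef_std = np.where(np.abs(coef_std) < _EPS, 0.0, coef_std)
    coef = coef_std / sd_safe
    intercept = b0 - float((coef_std * mean / sd_safe).sum())

    return SelectionResult(
        stage=stage, input_cpgs=cpgs,
        coefficients=dict(zip(cpgs, coef.tolist())),
        intercept=intercept, alpha=alpha, lam=float(chosen),
        lambda_strategy=str(lambda_strategy), seed=seed, folds=folds)


def cascade_select(
    discovery_wide: pd.DataFrame,
    discovery_outcome,
    refinement_wide: pd.DataFrame,
    refinement_outcome,
    survivors: list[str],
    alpha: float = 0.5,
    lambda_strategy: str | float = "1se",
    seed: int = 0,
    folds: int = 10,
) -> tuple[list[str], SelectionResult, SelectionResult]:
    """Two-cohort elastic-net cascade over the EWAS survivors.

    Stage 1 runs on the discovery cohort restricted to the screened CpGs;
    stage 2 reruns (with independently re-tuned penalty) on the refinement
    cohort restricted to the stage-1 non-zero set, which removes discovery
    false positives that do not predict in independent samples.
    """
    missing = [c for c in survivors
               if c not in discovery_wide.columns
               or c not in refinement_wide.columns]
    if missing:
        raise ValueError(f"survivor CpGs absent from a cohort: {missing}")
    stage1 = elastic_net_select(
        discovery_wide[survivors], discovery_outcome, alpha=alpha,
        lambda_strategy=lambda_strategy, seed=seed, folds=folds,
        stage="discovery_enet")
    if not stage1.selected:
        raise RuntimeError("stage-1 elastic net selected no CpGs; nothing "
                           "to refine")
    stage2 = elastic_net_select(
        refinement_wide[stage1.selected], refinement_outcome, alpha=alpha,
        lambda_strategy=lambda_strategy, seed=seed + 1, folds=folds,
        stage="refinement_enet")
    return stage2.selected, stage1, stage2


# ---------------------------------------------------------------------------
# medication-confounding filter
# ---------------------------------------------------------------------------

def medication_change_factor(med_baseline: pd.DataFrame,
                             med_followup: pd.DataFrame,
                             medication_class: str) -> pd.DataFrame:
    """Started/stopped indicator columns for one class (no-change = 0,0)."""
    b = med_baseline[medication_class].astype(bool)
    f = med_followup[medication_class].astype(bool)
    return pd.DataFrame({"started": (~b & f).astype(float),
                         "stopped": (b & ~f).astype(float)},
                        index=med_baseline.index)


def medication_filter(
    wide: pd.DataFrame,
    med_baseline: pd.DataFrame,
    med_followup: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
    classes=MEDICATION_CLASSES,
) -> tuple[list[str], list[MedAssocRecord]]:
    """Remove candidate CpGs whose ΔCpG tracks medication change.

    For each medication class a three-level change factor (no-change
    reference, started, stopped) is regressed against ΔCpG per CpG, and
    the start/stop contrasts are tested jointly — one Wald test per
    CpG x class.  The Bonferroni family is all performed tests
    (|candidates| x varying classes); classes nobody started or stopped
    contribute no tests.  A contrast level absent from the data (e.g.
    nobody stopped statins) is simply left out of that joint test.
    """
    import statsmodels.api as sm

    med_baseline = med_baseline.loc[wide.index]
    med_followup = med_followup.loc[wide.index]

    class_contrasts: dict[str, pd.DataFrame] = {}
    for cls in classes:
        fac = medication_change_factor(med_baseline, med_followup, cls)
        present = [c for c in ("started", "stopped") if fac[c].sum() > 0]
        if not present:
            logger.info("medication class %s: no change observed; "
                        "test skipped", cls)
            continue
        class_contrasts[cls] = fac[present]

    n_tests = len(candidates) * len(class_contrasts)
    records: list[MedAssocRecord] = []
    if n_tests == 0:
        return list(candidates), records
    threshold = alpha / n_tests

    for cls, fac in class_contrasts.items():
        design = sm.add_constant(fac.to_numpy(), has_constant="add")
        k = fac.shape[1]
        contrast = np.zeros((k, k + 1))
        contrast[:, 1:] = np.eye(k)
        for cpg in candidates:
            yv = wide[cpg].to_numpy(dtype=float)
            fit = sm.OLS(yv, design).fit()
            wald = fit.f_test(contrast)
            p = float(wald.pvalue)
            records.append(MedAssocRecord(
                cpg=cpg, medication_class=cls,
                statistic=float(wald.fvalue), p=p,
                bonferroni_threshold=threshold,
                significant=bool(p < threshold),
                contrasts_tested=tuple(fac.columns)))

    flagged = {r.cpg for r in records if r.significant}
    retained = [c for c in candidates if c not in flagged]
    return retained, records


# ---------------------------------------------------------------------------
# final logistic re-weighting and ROC evaluation
# ---------------------------------------------------------------------------

def fit_fingerprint(
    wide: pd.DataFrame,
    outcome,
    cpgs: list[str],
    training_cohort: str = "",
) -> FingerprintModel:
    """Unpenalized logistic re-fit of incident MI on the final ΔCpG panel.

    Perfect separation (common with few events and strong CpGs) makes the
    MLE diverge; in that case a ridge-stabilized fit is substituted and
    flagged — the ranking of individuals, hence the AUC, stays defined.
    """
    import statsmodels.api as sm

    if not cpgs:
        raise ValueError("final CpG list is empty")
    y = np.asarray(outcome, dtype=float)
    if y.sum() < 1:
        raise ValueError("no events in the training outcome")
    x = sm.add_constant(wide[list(cpgs)].to_numpy(dtype=float),
                        has_constant="add")

    flag = ""
    params = None
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.bse)):
            params = np.asarray(fit.params)
    except Exception:
        params = None
    if params is None:
        logger.warning("logistic MLE diverged (perfect separation?); "
                       "using ridge-stabilized fit")
        flag = "ridge_stabilized"
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
        clf.fit(wide[list(cpgs)].to_numpy(dtype=float), y)
        params = np.concatenate([clf.intercept_, clf.coef_[0]])

    return FingerprintModel(
        cpgs=list(cpgs), intercept=float(params[0]),
        weights=dict(zip(cpgs, params[1:].tolist())),
        training_cohort=training_cohort, n=len(y), n_events=int(y.sum()),
        flag=flag)


def auc_mann_whitney(scores_cases, scores_controls) -> tuple[float, float]:
    """AUC as the Mann-Whitney pair statistic plus a one-sided p-value.

    AUC = P(case score > control score) + 0.5 P(tie); the p-value tests
    AUC > 0.5 via the tie-corrected normal approximation to the U
    statistic.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    res = stats.mannwhitneyu(cases, controls, alternative="greater",
                             method="asymptotic")
    auc = float(res.statistic) / (cases.size * controls.size)
    return auc, float(res.pvalue)


def evaluate_fingerprint(
    model: FingerprintModel,
    wide: pd.DataFrame,
    outcome,
) -> RocResult:
    """Score a cohort with the fingerprint and summarize discrimination."""
    from sklearn.metrics import roc_curve

    y = np.asarray(outcome, dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("evaluation cohort needs both cases and controls")
    scores = model.score(wide)
    auc, p = auc_mann_whitney(scores[y == 1], scores[y == 0])
    fpr, tpr, _ = roc_curve(y, scores)
    return RocResult(auc=auc, p=p, fpr=fpr, tpr=tpr,
                     n=int(y.size), n_events=int(y.sum()))
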