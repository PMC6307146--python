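"""Repeated-measures GEE association of ΔCpG with incident MI.

Each CpG is tested with a Gaussian identity-link GEE on the long-format
data: two rows per individual (the cluster), outcome 0 at baseline and the
residual methylation difference at follow-up, predictors the incident-MI
indicator (0 on baseline rows) plus the clinical covariates at each row's
visit.  Inference uses the cluster-robust sandwich variance, so the
within-individual correlation induced by the paired design does not
understate the standard errors.

With the default independence working correlation the GEE point estimates
coincide exactly with OLS on the stacked rows and the sandwich has a closed
form, so the genome-wide scan is vectorized across CpGs; single-CpG fits
and the exchangeable structure go through ``statsmodels`` GEE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DeltaSet
from .simulate import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class EwasRecord:
    """Per-CpG effect of the incident-MI indicator on ΔCpG."""

    cpg: str
    beta_mi: float
    robust_se: float
    z: float
    p: float
    q: float = float("nan")
    n_clusters: int = 0
    flag: str = ""  # "", "degenerate", "fallback_independence", "failed"


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1, returned in the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _long_design(long_df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols = ["mi_indicator"] + list(covariates)
    x = np.column_stack(
        [np.ones(len(long_df))]
        + [long_df[c].to_numpy(dtype=float) for c in cols])
    return x, ["intercept"] + cols


def fit_gee_single(
    long_df: pd.DataFrame,
    covariates=COVARIATE_COLUMNS,
    working_correlation: str = "independence",
) -> EwasRecord:
    """Fit the GEE for one CpG's long-format rows.

    Outcome is ``delta_value``; clusters are individuals. Non-convergence
    of the exchangeable working-correlation iteration falls back to
    independence with a flag (the sandwich variance keeps the inference
    cluster-robust either way). A zero-variance outcome short-circuits to a
    flagged degenerate record.
    """
    import statsmodels.api as sm

    cpg = str(long_df["cpg"].iloc[0]) if "cpg" in long_df else ""
    y = long_df["delta_value"].to_numpy(dtype=float)
    groups = long_df["individual"].to_numpy()
    n_clusters = len(pd.unique(groups))
    if np.allclose(y, y[0]):
        return EwasRecord(cpg=cpg, beta_mi=0.0, robust_se=0.0,
                          z=float("nan"), p=float("nan"),
                          n_clusters=n_clusters, flag="degenerate")

    x, names = _long_design(long_df, covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        singular = _name_singular_columns(x, names)
        raise ValueError(f"singular design; offending columns: {singular}")

    structures = {"independence": sm.cov_struct.Independence,
                  "exchangeable": sm.cov_struct.Exchangeable}
    if working_correlation not in structures:
        raise ValueError(f"unknown working correlation "
                         f"{working_correlation!r}")
    flag = ""
    try:
        model = sm.GEE(y, x, groups=groups,
                       family=sm.families.Gaussian(),
                       cov_struct=structures[working_correlation]())
        result = model.fit()
        if not np.all(np.isfinite(result.bse)):
            raise ValueError("non-finite robust SE")
    except Exception:
        if working_correlation == "independence":
            raise
        logger.warning("exchangeable GEE failed for %s; falling back to "
                       "independence", cpg)
        flag = "fallback_independence"
        model = sm.GEE(y, x, groups=groups,
                       family=sm.families.Gaussian(),
                       cov_struct=sm.cov_struct.Independence())
        result = model.fit()

    j = names.index("mi_indicator")
    beta = float(result.params[j])
    se = float(result.bse[j])
    z = beta / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return EwasRecord(cpg=cpg, beta_mi=beta, robust_se=se, z=z, p=p,
                      n_clusters=n_clusters, flag=flag)


def _name_singular_columns(x: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


def _stacked_design(delta: DeltaSet, covariates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack baseline+followup rows; returns (X, cluster index, mi column)."""
    n = len(delta.individuals)
    mi = delta.outcome.to_numpy(dtype=float)
    blocks = []
    for visit in ("baseline", "followup"):
        cov = delta.covariate_frame(visit).to_numpy(dtype=float)
        mi_col = np.zeros(n) if visit == "baseline" else mi
        blocks.append(np.column_stack([np.ones(n), mi_col, cov]))
    x = np.vstack(blocks)
    cluster = np.tile(np.arange(n), 2)
    return x, cluster, mi


def run_ewas(
    delta: DeltaSet,
    covariates=COVARIATE_COLUMNS,
    working_correlation: str = "independence",
) -> pd.DataFrame:
    """Genome-wide GEE scan of ΔCpG on the incident-MI indicator.

    Returns one row per CpG (columns cpg, beta, se_robust, z, p, q,
    n_clusters, flag) sorted by p with the CpG id as the deterministic
    tie-break.  BH-FDR q-values are computed over the testable
    (non-degenerate, non-failed) CpGs only, so undefined tests do not
    inflate the correction's m.

    The independence working correlation is evaluated in closed form for
    all CpGs at once; this is the same estimator statsmodels GEE returns
    (OLS point estimates + cluster sandwich), not an approximation.
    """
    if working_correlation == "independence":
        records = _run_ewas_vectorized(delta, covariates)
    else:
        records = []
        for cpg in delta.cpgs:
            try:
                rec = fit_gee_single(delta.long([cpg]), covariates,
                                     working_correlation)
                rec.cpg = cpg
            except Exception as exc:  # keep scanning; record the failure
                logger.warning("GEE failed for %s: %s", cpg, exc)
                rec = EwasRecord(cpg=cpg, beta_mi=float("nan"),
                                 robust_se=float("nan"), z=float("nan"),
                                 p=float("nan"), flag="failed")
            records.append(rec)

    frame = pd.DataFrame(
        {"cpg": [r.cpg for r in records],
         "beta": [r.beta_mi for r in records],
         "se_robust": [r.robust_se for r in records],
         "z": [r.z for r in records],
         "p": [r.p for r in records],
         "n_clusters": [r.n_clusters for r in records],
         "flag": [r.flag for r in records]})
    testable = frame["flag"].eq("") & frame["p"].notna()
    frame["q"] = np.nan
    frame.loc[testable, "q"] = bh_fdr(frame.loc[testable, "p"].to_numpy())
    frame = frame.sort_values(["p", "cpg"], kind="stable",
                              na_position="last").reset_index(drop=True)
    return frame[["cpg", "beta", "se_robust", "z", "p", "q",
                  "n_clusters", "flag"]]


def _run_ewas_vectorized(delta: DeltaSet, covariates) -> list[EwasRecord]:
    x, cluster, _ = _stacked_design(delta, covariates)
    n_ind = len(delta.individuals)
    names = ["intercept", "mi_indicator"] + list(covariates)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design; offending columns: "
                         f"{_name_singular_columns(x, names)}")

    wide = delta.wide.to_numpy(dtype=float)          # individuals x CpGs
    y = np.vstack([np.zeros_like(wide), wide])       # stacked rows x CpGs

    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    beta_all = xtx_inv @ (x.T @ y)                   # p x CpGs
    resid = y - x @ beta_all                         # rows x CpGs

    j = 1  # mi_indicator column
    # sandwich variance of beta_j: sum over clusters of (a_j' X_c' r_c)^2
    w = x @ xtx_inv[:, j]                            # rows
    wr = resid * w[:, None]
    cluster_sum = wr[:n_ind] + wr[n_ind:]            # per-individual sums
    var_j = (cluster_sum ** 2).sum(axis=0)
    se = np.sqrt(var_j)

    degenerate = np.all(np.isclose(y, y[0], atol=0.0), axis=0) | (se == 0)
    beta_j = beta_all[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_j / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))

    records = []
    for k, cpg in enumerate(delta.cpgs):
        if degenerate[k]:
            records.append(EwasRecord(cpg=cpg, beta_mi=0.0, robust_se=0.0,
                                      z=float("nan"), p=float("nan"),
                                      n_clusters=n_ind, flag="degenerate"))
        else:
            records.append(EwasRecord(cpg=cpg, beta_mi=float(beta_j[k]),
                                      robust_se=float(se[k]),
                                      z=float(z[k]), p=float(p[k]),
                                      n_clusters=n_ind))
    return records


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-sample normal-approximation power calculation."""

    n_cases: int
    n_controls: int
    effect: float      # mean ΔCpG difference, delta units
    sd: float          # ΔCpG SD, delta units
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def posthoc_power(spec: PowerSpec) -> float:
    """Power of the two-sample z-test for a case/control ΔCpG difference.

    Accounts for the (typically extreme) imbalance between the few incident
    cases and the many controls through the usual 1/n_cases + 1/n_controls
    variance factor.
    """
    se = spec.sd * np.sqrt(1.0 / spec.n_cases + 1.0 / spec.n_controls)
    ncp = abs(spec.effect) / se
    crit = stats.norm.isf(spec.alpha / spec.sides)
    power = stats.norm.cdf(ncp - crit)
    if spec.sides == 2:
        power += stats.norm.cdf(-ncp - crit)
    return float(power)
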