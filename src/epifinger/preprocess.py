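"""Completeness filtering, technical residualization, and ΔCpG construction.

The repeated-measures design works on the *difference* in methylation
between a follow-up and a baseline blood draw for each individual.  Before
differencing, each visit's beta values are residualized per CpG on that
visit's technical covariates (control-probe principal components or
chip-position factors) plus estimated leukocyte proportions, because
technical structure differs between assay batches.  The per-individual
difference of residuals is ΔCpG; in the long format used by the GEE model
every individual contributes one baseline row with ΔCpG fixed at 0 and one
follow-up row with the observed difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)


def filter_complete_cpgs(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Keep only CpGs observed in every sample at both visits.

    Downstream penalized regression cannot handle missing predictors, so
    the analysis set is defined by complete observation: a CpG with a
    single missing beta value at either visit is dropped.

    Returns the two filtered matrices and a report with retained/dropped
    counts.
    """
    if set(baseline.columns) != set(followup.columns):
        raise ValueError(
            "baseline and follow-up matrices cover different individuals")
    followup = followup[baseline.columns]
    shared = baseline.index.intersection(followup.index)
    b = baseline.loc[shared]
    f = followup.loc[shared]
    complete = b.notna().all(axis=1) & f.notna().all(axis=1)
    n_kept = int(complete.sum())
    if n_kept == 0:
        raise ValueError("no CpG is complete at both visits")
    report = {
        "n_input_cpgs": int(len(shared)),
        "n_retained_cpgs": n_kept,
        "n_dropped_cpgs": int(len(shared) - n_kept),
    }
    logger.info("completeness filter: %(n_retained_cpgs)d of "
                "%(n_input_cpgs)d CpGs retained", report)
    return b.loc[complete], f.loc[complete], report


def _drop_collinear(design: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove linearly dependent design columns via pivoted QR.

    Columns are dropped in pivot order with the original column order as
    the deterministic tie-break, so repeated runs keep the same columns.
    """
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < design.shape[1]:
        dropped = [names[j] for j in sorted(piv[rank:])]
        logger.warning("dropping collinear technical columns: %s", dropped)
    return design[:, keep], [names[j] for j in keep]


def residualize_technical(
    meth: pd.DataFrame,
    technical: pd.DataFrame,
) -> pd.DataFrame:
    """Per-CpG OLS residuals of beta on intercept + technical covariates.

    ``technical`` is sample x covariate (control-probe PCs, chip factors,
    cell proportions) and must cover exactly the matrix's samples. Residuals
    are orthogonal to every retained regressor.
    """
    if set(meth.columns) != set(technical.index):
        raise ValueError("technical covariates not aligned to samples")
    tech = technical.loc[meth.columns]
    names = ["intercept"] + list(tech.columns)
    design = np.column_stack([np.ones(len(tech)), tech.to_numpy(dtype=float)])
    design, _ = _drop_collinear(design, names)

    y = meth.to_numpy(dtype=float).T          # samples x CpGs
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.DataFrame(resid.T, index=meth.index, columns=meth.columns)


@dataclass
class DeltaSet:
    """Residual methylation differences in wide and GEE-long form.

    ``wide`` is individual x CpG with the follow-up-minus-baseline residual
    difference. ``phenotypes`` carries both visits' covariates. The long
    format (two rows per individual per CpG, baseline outcome fixed at 0,
    MI indicator live only on follow-up rows) is materialized on demand via
    :meth:`long` because for a genome-wide matrix it is quadratically
    larger than the wide form.
    """

    wide: pd.DataFrame
    phenotypes: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.wide.index)

    @property
    def cpgs(self) -> list[str]:
        return list(self.wide.columns)

    @property
    def outcome(self) -> pd.Series:
        """Individual-level incident-MI labels, aligned to ``wide``."""
        mi = (self.phenotypes.drop_duplicates("individual")
              .set_index("individual")["incident_mi"])
        return mi.loc[self.wide.index].astype(int)

    def covariate_frame(self, visit: str) -> pd.DataFrame:
        sub = self.phenotypes[self.phenotypes["visit"] == visit]
        return (sub.set_index("individual")
                .loc[self.wide.index, list(COVARIATE_COLUMNS)]
                .astype(float))

    def long(self, cpgs: list[str] | None = None) -> pd.DataFrame:
        """Stack the GEE long format for the requested CpGs."""
        cpgs = list(self.wide.columns) if cpgs is None else list(cpgs)
        mi = self.outcome
        frames = []
        for visit in ("baseline", "followup"):
            cov = self.covariate_frame(visit)
            for cpg in cpgs:
                frame = cov.copy()
                frame.insert(0, "individual", cov.index)
                frame.insert(1, "visit", visit)
                frame.insert(2, "cpg", cpg)
                frame["delta_value"] = (
                    0.0 if visit == "baseline"
                    else self.wide[cpg].to_numpy(dtype=float))
                frame["mi_indicator"] = (
                    0 if visit == "baseline" else mi.to_numpy())
                frames.append(frame)
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["cpg", "individual", "visit"],
                               kind="stable").reset_index(drop=True)


def build_delta(
    residual_baseline: pd.DataFrame,
    residual_followup: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> DeltaSet:
    """Construct ΔCpG = follow-up residual − baseline residual per individual.

    Individuals present at only one visit (in the matrices or in the
    phenotype table) are excluded with a logged count; the paired design
    requires both draws.
    """
    if not residual_baseline.index.equals(residual_followup.index):
        shared_cpg = residual_baseline.index.intersection(
            residual_followup.index)
        residual_baseline = residual_baseline.loc[shared_cpg]
        residual_followup = residual_followup.loc[shared_cpg]

    counts = phenotypes.groupby("individual")["visit"].nunique()
    paired_pheno = set(counts[counts == 2].index)
    shared = [ind for ind in residual_baseline.columns
              if ind in residual_followup.columns and ind in paired_pheno]
    n_dropped = len(set(residual_baseline.columns)
                    | set(residual_followup.columns)) - len(shared)
    if n_dropped:
        logger.info("build_delta: excluded %d unpaired individuals",
                    n_dropped)
    if not shared:
        raise ValueError("no individual is present at both visits")

    wide = (residual_followup[shared] - residual_baseline[shared]).T
    wide.index.name = "individual"
    pheno = phenotypes[phenotypes["individual"].isin(shared)].copy()
    return DeltaSet(wide=wide, phenotypes=pheno)
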