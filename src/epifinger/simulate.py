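"""Synthetic paired-visit multi-omic cohort generator.

Emulates the statistical structure of a longitudinal blood-methylation study
of incident myocardial infarction (MI): two 450K-style beta-value matrices
(baseline and follow-up) for the same individuals, a per-visit phenotype
table with an incident-MI flag, technical covariates (control-probe PCs and
estimated leukocyte proportions), post-event medication changes, and
expression/metabolite layers linearly coupled to planted CpGs.

Methylation is simulated on the logit (M-value) scale and mapped back to the
beta scale through the logistic function, so additive technical and
biological effects never push values outside [0, 1].  Incident cases receive
an additive follow-up-only shift at a small set of planted CpGs, expressed
in units of the within-person visit-to-visit noise SD; a second disjoint set
of CpGs responds to medication change rather than to the event itself, which
is what the downstream medication-confounding filter must detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MEDICATION_CLASSES = (
    "beta_blockers",
    "ace_inhibitors",
    "diuretics",
    "angiotensin_receptor_blockers",
    "calcium_channel_blockers",
    "statins",
    "anti_platelet",
)

COVARIATE_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "diabetes",
    "hypertension",
    "physical_activity",
    "pack_years",
    "alcohol",
)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic paired cohort.

    Sizes default to a desk-scale version of a population cohort with rare
    incident events: 1,000 individuals, a 5% inter-visit event rate, and
    2,000 CpGs of which 10 respond to the event. ``effect_size`` and
    ``med_effect_size`` are mean shifts of the follow-up logit-methylation
    residual in units of the visit-to-visit noise SD (``delta_noise_sd``).
    """

    seed: int = 0
    n_individuals: int = 1000
    n_cpgs: int = 2000
    event_rate: float = 0.05
    n_effect_cpgs: int = 10
    effect_size: float = 1.5
    n_med_confounded_cpgs: int = 2
    med_effect_size: float = 2.0
    n_tech_pcs: int = 5
    tech_sd: float = 0.15
    n_cell_types: int = 5
    n_genes: int = 200
    n_metabolites: int = 50
    expr_coupling: float = 5.0
    metab_coupling: float = 1.0
    missing_rate: float = 0.0
    # nuisance scales, all on the logit-methylation scale
    delta_noise_sd: float = 0.30
    between_individual_sd: float = 0.50
    drift_sd: float = 0.10
    cell_effect_sd: float = 0.5
    # medication dynamics: event-driven initiation is elevated (3x) but a
    # per-class minority of all changers, as for any single class of the
    # seven in a population cohort
    med_baseline_rate: float = 0.15
    med_start_rate_control: float = 0.06
    med_start_rate_case: float = 0.18
    med_stop_rate: float = 0.05
    # cohorts of one multi-cohort study share planted CpG identities,
    # effect directions, and medication-class assignments: give them the
    # same truth_seed while varying seed
    truth_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.event_rate < 1.0):
            raise ValueError("event_rate must be in (0, 1)")
        if self.n_effect_cpgs + self.n_med_confounded_cpgs > self.n_cpgs:
            raise ValueError(
                "n_effect_cpgs + n_med_confounded_cpgs exceeds n_cpgs"
            )
        for name in ("n_individuals", "n_cpgs", "n_effect_cpgs",
                     "n_med_confounded_cpgs", "n_tech_pcs", "n_cell_types",
                     "n_genes", "n_metabolites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.expr_coupling):
            raise ValueError("expr_coupling must be finite")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_individuals * self.event_rate < 1.0:
            warnings.warn(
                "expected incident-case count below 1; downstream "
                "case/control contrasts will be degenerate",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class SyntheticCohort:
    """One simulated paired-visit cohort plus the planted ground truth."""

    config: SimulationConfig
    meth_baseline: pd.DataFrame   # CpG x sample beta values, may contain NaN
    meth_followup: pd.DataFrame
    phenotypes: pd.DataFrame      # one row per individual per visit
    technical_baseline: pd.DataFrame  # sample x (tech PCs + cell proportions)
    technical_followup: pd.DataFrame
    manifest: pd.DataFrame        # CpG, CHR, MAPINFO, UCSC_RefGene_Name
    truth: dict = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.meth_baseline.columns)

    def medication_usage(self, visit: str) -> pd.DataFrame:
        """Individual x medication-class usage flags at one visit."""
        sub = self.phenotypes[self.phenotypes["visit"] == visit]
        return sub.set_index("individual")[list(MEDICATION_CLASSES)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one paired-visit cohort from the generative model.

    Baseline logit-methylation per CpG and individual is a CpG-specific mean
    plus between-individual variation; follow-up adds an individual drift, a
    fresh technical component, visit-to-visit noise, the planted case shift
    at effect CpGs (follow-up only), and the medication-change shift at
    confounded CpGs.  The same seed reproduces the cohort bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_cpgs
    individuals = [f"ind{i:05d}" for i in range(n)]
    cpgs = [f"cg{i:08d}" for i in range(m)]

    # ground-truth CpG role assignment (disjoint by construction); drawn
    # from the truth seed so sister cohorts can share planted directions
    truth_rng = np.random.default_rng(
        config.seed if config.truth_seed is None else config.truth_seed)
    effect_idx = np.arange(config.n_effect_cpgs)
    med_idx = np.arange(config.n_effect_cpgs,
                        config.n_effect_cpgs + config.n_med_confounded_cpgs)
    effect_sign = truth_rng.choice([-1.0, 1.0], size=config.n_effect_cpgs)
    med_sign = truth_rng.choice([-1.0, 1.0],
                                size=config.n_med_confounded_cpgs)
    med_class_of_cpg = [MEDICATION_CLASSES[i % len(MEDICATION_CLASSES)]
                        for i in range(config.n_med_confounded_cpgs)]

    # CpG-level means on the beta scale, kept away from the boundaries
    mu_beta = 0.1 + 0.8 * rng.beta(2.0, 2.0, size=m)
    mu_logit = _logit(mu_beta)

    # stable biology: individual offsets persist across visits
    indiv_offset = rng.normal(0.0, config.between_individual_sd, size=(m, n))
    base_bio = mu_logit[:, None] + indiv_offset

    # technical structure, redrawn per visit (new chips at follow-up)
    tech_load = rng.normal(0.0, config.tech_sd, size=(m, config.n_tech_pcs))
    tech0 = rng.normal(0.0, 1.0, size=(n, config.n_tech_pcs))
    tech1 = rng.normal(0.0, 1.0, size=(n, config.n_tech_pcs))

    # cell proportions: Dirichlet per individual, jittered at follow-up
    alpha = np.linspace(6.0, 2.0, num=max(config.n_cell_types, 1))
    cells0 = rng.dirichlet(alpha, size=n)
    jitter = rng.normal(0.0, 0.02, size=cells0.shape)
    cells1 = np.clip(cells0 + jitter, 1e-3, None)
    cells1 /= cells1.sum(axis=1, keepdims=True)
    cell_load = rng.normal(0.0, config.cell_effect_sd,
                           size=(m, max(config.n_cell_types, 1)))
    cell_center = cells0.mean(axis=0)

    # incident events and medication trajectories
    mi = (rng.random(n) < config.event_rate).astype(int)
    med0 = rng.random((n, len(MEDICATION_CLASSES))) < config.med_baseline_rate
    start_p = np.where(mi[:, None] == 1,
                       config.med_start_rate_case,
                       config.med_start_rate_control)
    u = rng.random((n, len(MEDICATION_CLASSES)))
    started = (~med0) & (u < start_p)
    stopped = med0 & (u < config.med_stop_rate)
    med1 = (med0 | started) & ~stopped
    med_changed = med0 != med1

    m0 = (base_bio
          + tech_load @ tech0.T
          + cell_load @ (cells0 - cell_center).T)

    drift = rng.normal(0.0, config.drift_sd, size=n)
    noise = rng.normal(0.0, config.delta_noise_sd, size=(m, n))
    m1 = (base_bio
          + tech_load @ tech1.T
          + cell_load @ (cells1 - cell_center).T
          + drift[None, :]
          + noise)

    # planted follow-up-only shifts
    if config.n_effect_cpgs:
        shift = (config.effect_size * config.delta_noise_sd
                 * effect_sign[:, None] * mi[None, :])
        m1[effect_idx] += shift
    for k, j in enumerate(med_idx):
        changed = med_changed[:, MEDICATION_CLASSES.index(med_class_of_cpg[k])]
        m1[j] += (config.med_effect_size * config.delta_noise_sd
                  * med_sign[k] * changed.astype(float))

    beta0 = _expit(m0)
    beta1 = _expit(m1)
    if config.missing_rate > 0:
        beta0[rng.random(beta0.shape) < config.missing_rate] = np.nan
        beta1[rng.random(beta1.shape) < config.missing_rate] = np.nan

    meth_baseline = pd.DataFrame(beta0, index=cpgs, columns=individuals)
    meth_followup = pd.DataFrame(beta1, index=cpgs, columns=individuals)

    phenotypes = _simulate_phenotypes(rng, individuals, mi, med0, med1)

    tech_cols = [f"tech_pc{k + 1}" for k in range(config.n_tech_pcs)]
    cell_cols = [f"cell{k + 1}" for k in range(max(config.n_cell_types, 1))]
    technical_baseline = pd.DataFrame(
        np.hstack([tech0, cells0]), index=individuals,
        columns=tech_cols + cell_cols)
    technical_followup = pd.DataFrame(
        np.hstack([tech1, cells1]), index=individuals,
        columns=tech_cols + cell_cols)

    manifest = _simulate_manifest(rng, cpgs)

    truth = {
        "effect_cpgs": [cpgs[i] for i in effect_idx],
        "effect_sizes": dict(zip(
            (cpgs[i] for i in effect_idx),
            config.effect_size * config.delta_noise_sd * effect_sign)),
        "med_confounded_cpgs": [cpgs[i] for i in med_idx],
        "med_class_of_cpg": dict(zip(
            (cpgs[i] for i in med_idx), med_class_of_cpg)),
        "mi": pd.Series(mi, index=individuals, name="incident_mi"),
    }
    return SyntheticCohort(
        config=config,
        meth_baseline=meth_baseline,
        meth_followup=meth_followup,
        phenotypes=phenotypes,
        technical_baseline=technical_baseline,
        technical_followup=technical_followup,
        manifest=manifest,
        truth=truth,
    )


def _simulate_phenotypes(rng, individuals, mi, med0, med1) -> pd.DataFrame:
    n = len(individuals)
    age0 = rng.normal(55.0, 9.0, size=n).clip(25.0, 80.0)
    sex = rng.integers(0, 2, size=n)
    bmi0 = rng.normal(27.7, 4.5, size=n).clip(16.0, 50.0)
    bmi1 = (bmi0 + rng.normal(0.4, 1.5, size=n)).clip(16.0, 55.0)
    diab0 = (rng.random(n) < 0.04).astype(int)
    diab1 = np.maximum(diab0, (rng.random(n) < 0.06).astype(int))
    hyp0 = (rng.random(n) < 0.45).astype(int)
    hyp1 = np.maximum(hyp0, (rng.random(n) < 0.05).astype(int))
    act0 = (rng.random(n) < 0.5).astype(int)
    act1 = np.where(rng.random(n) < 0.9, act0, 1 - act0)
    pack0 = np.where(rng.random(n) < 0.5,
                     rng.exponential(12.0, size=n), 0.0)
    pack1 = pack0 + np.where(pack0 > 0, rng.exponential(1.5, size=n), 0.0)
    alc0 = rng.exponential(12.0, size=n)
    alc1 = (alc0 + rng.normal(0.0, 4.0, size=n)).clip(0.0, None)

    rows = []
    for visit, age, bmi, diab, hyp, act, pack, alc, med in (
            ("baseline", age0, bmi0, diab0, hyp0, act0, pack0, alc0, med0),
            ("followup", age0 + 7.0, bmi1, diab1, hyp1, act1, pack1, alc1,
             med1)):
        frame = pd.DataFrame({
            "individual": individuals,
            "visit": visit,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "diabetes": diab,
            "hypertension": hyp,
            "physical_activity": act,
            "pack_years": pack,
            "alcohol": alc,
            "incident_mi": mi,
        })
        for k, cls in enumerate(MEDICATION_CLASSES):
            frame[cls] = med[:, k].astype(int)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def _simulate_manifest(rng, cpgs) -> pd.DataFrame:
    """Illumina-manifest-style CpG coordinates on 22 autosomes."""
    m = len(cpgs)
    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(1, 200_000_000, size=m)
    gene = np.array([f"GENE{i % max(m // 4, 1):04d}" for i in range(m)])
    gene[rng.random(m) < 0.1] = ""  # some CpGs lack a proximity gene
    return pd.DataFrame({
        "CpG": cpgs,
        "CHR": chrom,
        "MAPINFO": pos,
        "UCSC_RefGene_Name": gene,
    })


def simulate_expression_metabolites(
    cohort: SyntheticCohort,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression and metabolite layers coupled to the planted CpGs.

    Each planted effect CpG is assigned a cis gene placed within 400 kb of
    it in the synthetic manifest; that gene's expression is
    ``expr_coupling`` times the CpG's follow-up beta value plus unit noise.
    Coupled metabolites are ``metab_coupling`` times their gene's expression
    plus unit noise; everything else is independent noise.

    Returns ``(expression, metabolites, gene_annotation, true_couplings)``
    where expression/metabolites are feature x sample matrices over the
    cohort's individuals and ``true_couplings`` lists the planted
    (cpg, gene, metabolite) links for recovery tests.
    """
    config = config or cohort.config
    if not np.isfinite(config.expr_coupling):
        raise ValueError("expr_coupling must be finite")
    if cohort.meth_followup is None or cohort.meth_followup.empty:
        raise ValueError("cohort has no follow-up methylation matrix")

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x9E37]).generate_state(1)[0])
    individuals = cohort.individuals
    n = len(individuals)
    genes = [f"GENEX{i:04d}" for i in range(config.n_genes)]
    probes = [f"ILMN_{1000000 + i}" for i in range(config.n_genes)]

    manifest = cohort.manifest.set_index("CpG")
    effect_cpgs = cohort.truth["effect_cpgs"]
    n_coupled = min(len(effect_cpgs), config.n_genes)

    gene_chr = rng.integers(1, 23, size=config.n_genes)
    gene_pos = rng.integers(1, 200_000_000, size=config.n_genes)
    expr = rng.normal(0.0, 1.0, size=(config.n_genes, n))

    coupling_rows = []
    for k in range(n_coupled):
        cpg = effect_cpgs[k]
        gene_chr[k] = manifest.loc[cpg, "CHR"]
        gene_pos[k] = max(
            1, int(manifest.loc[cpg, "MAPINFO"])
            + int(rng.integers(-400_000, 400_001)))
        meth = cohort.meth_followup.loc[cpg].to_numpy(dtype=float)
        meth = np.nan_to_num(meth, nan=float(np.nanmean(meth)))
        expr[k] = config.expr_coupling * meth + rng.normal(0.0, 1.0, size=n)
        coupling_rows.append({"cpg": cpg, "gene": genes[k],
                              "probe": probes[k]})

    metabolites = [f"metab{i:03d}" for i in range(config.n_metabolites)]
    metab = rng.normal(0.0, 1.0, size=(config.n_metabolites, n))
    for j in range(config.n_metabolites):
        k = j % max(n_coupled, 1)
        if n_coupled and j < 2 * n_coupled:  # couple two metabolites per gene
            metab[j] = (config.metab_coupling * expr[k]
                        + rng.normal(0.0, 1.0, size=n))
            coupling_rows.append({"cpg": effect_cpgs[k], "gene": genes[k],
                                  "probe": probes[k],
                                  "metabolite": metabolites[j]})

    expression = pd.DataFrame(expr, index=probes, columns=individuals)
    metabolite_df = pd.DataFrame(metab, index=metabolites,
                                 columns=individuals)
    gene_annotation = pd.DataFrame({
        "probe": probes,
        "gene": genes,
        "chr": gene_chr,
        "pos": gene_pos,
    })
    true_couplings = pd.DataFrame(
        coupling_rows, columns=["cpg", "gene", "probe", "metabolite"])
    return expression, metabolite_df, gene_annotation, true_couplings


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the standard pipeline input files for one cohort.

    Beta matrices and the phenotype table go out as TSV, the manifest as
    CSV with Illumina-style headers. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "meth_baseline": outdir / "meth_baseline.tsv",
        "meth_followup": outdir / "meth_followup.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "technical_baseline": outdir / "technical_baseline.tsv",
        "technical_followup": outdir / "technical_followup.tsv",
        "manifest": outdir / "manifest.csv",
        "truth_effect": outdir / "truth_effect_cpgs.tsv",
        "truth_med": outdir / "truth_med_confounded_cpgs.tsv",
    }
    cohort.meth_baseline.to_csv(paths["meth_baseline"], sep="\t",
                                index_label="CpG")
    cohort.meth_followup.to_csv(paths["meth_followup"], sep="\t",
                                index_label="CpG")
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.technical_baseline.to_csv(paths["technical_baseline"], sep="\t",
                                     index_label="individual")
    cohort.technical_followup.to_csv(paths["technical_followup"], sep="\t",
                                     index_label="individual")
    cohort.manifest.to_csv(paths["manifest"], index=False)
    pd.DataFrame({
        "cpg": cohort.truth["effect_cpgs"],
        "true_effect": [cohort.truth["effect_sizes"][c]
                        for c in cohort.truth["effect_cpgs"]],
    }).to_csv(paths["truth_effect"], sep="\t", index=False)
    pd.DataFrame({
        "cpg": cohort.truth["med_confounded_cpgs"],
        "medication_class": [cohort.truth["med_class_of_cpg"][c]
                             for c in cohort.truth["med_confounded_cpgs"]],
    }).to_csv(paths["truth_med"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def config_dict(config: SimulationConfig) -> dict:
    return asdict(config)
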