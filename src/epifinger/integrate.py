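"""cis eQTM association and tri-partite CpG–gene–metabolite network assembly.

Fingerprint CpGs are linked to transcription by regressing each cis gene's
expression (all genes within a 1 Mb window of the CpG) on the CpG's
methylation, adjusted for age, sex, estimated cell proportions, and
technical factors, with a per-CpG Bonferroni correction for the number of
genes in its window.  The expression layer is then joined to a published
Spearman-correlation transcriptome–metabolome edge table: per-edge p-values
come from the t transform of rho, FDR is computed over all edges, and the
kept edges (suggestive p < 0.001 for expression–metabolite, nominal
p < 0.05 for methylation–expression) assemble into a typed tri-partite
graph exportable as SIF and GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class ProbeAnnotation:
    """CpG coordinates plus gene/expression-probe coordinates.

    ``cpgs``: columns CpG, CHR, MAPINFO (1-based bp).
    ``genes``: columns probe, gene, chr, pos — one row per expression
    probe, with the gene's representative (TSS-like) coordinate.
    """

    cpgs: pd.DataFrame
    genes: pd.DataFrame

    def cpg_position(self, cpg: str) -> tuple[str, int]:
        row = self.cpgs.loc[self.cpgs["CpG"] == cpg]
        if row.empty or pd.isna(row["MAPINFO"].iloc[0]):
            raise KeyError(f"no coordinates for CpG {cpg!r}")
        return str(row["CHR"].iloc[0]), int(row["MAPINFO"].iloc[0])


@dataclass
class AssociationRecord:
    """One CpG x cis expression-probe linear association."""

    cpg: str
    probe: str
    gene: str
    beta: float
    se: float
    p: float
    n_window_genes: int
    window_bonferroni_significant: bool


def cis_gene_window(
    cpg: str,
    annotation: ProbeAnnotation,
    window_bp: int = 1_000_000,
    half_window: bool = True,
) -> pd.DataFrame:
    """Expression probes whose gene lies in the cis window of a CpG.

    The default reads "1 Mb window" as a total span centered on the CpG
    (± window_bp/2 = ±500 kb); ``half_window=False`` switches to
    ± window_bp.  Returns the matching rows of the gene table; the number
    of *distinct* genes among them defines the per-CpG Bonferroni family.
    """
    chrom, pos = annotation.cpg_position(cpg)
    radius = window_bp // 2 if half_window else window_bp
    genes = annotation.genes
    same = genes["chr"].astype(str) == chrom
    near = (genes["pos"].astype(int) - pos).abs() <= radius
    return genes.loc[same & near].reset_index(drop=True)


def associate_expression(
    methylation: pd.DataFrame,      # CpG x sample follow-up beta values
    expression: pd.DataFrame,       # expression probe x sample
    covariates: pd.DataFrame,       # sample x (age, sex, cells, tech ...)
    annotation: ProbeAnnotation,
    cpgs: list[str] | None = None,
    alpha: float = 0.05,
    window_bp: int = 1_000_000,
    half_window: bool = True,
) -> list[AssociationRecord]:
    """Per-(CpG, cis probe) adjusted linear eQTM models.

    Expression is the outcome, methylation the predictor, with the
    supplied covariates as adjustments.  Each CpG's tests are
    Bonferroni-corrected for the number of distinct genes in its window.
    """
    import statsmodels.api as sm

    samples = [s for s in methylation.columns
               if s in expression.columns and s in covariates.index]
    if len(samples) < 10:
        raise ValueError(f"only {len(samples)} shared samples; need >= 10")
    cov = covariates.loc[samples].to_numpy(dtype=float)
    cpgs = list(methylation.index) if cpgs is None else list(cpgs)

    records: list[AssociationRecord] = []
    for cpg in cpgs:
        window = cis_gene_window(cpg, annotation, window_bp, half_window)
        window = window[window["probe"].isin(expression.index)]
        if window.empty:
            logger.info("no cis genes for %s; skipped", cpg)
            continue
        n_genes = int(window["gene"].nunique())
        meth = methylation.loc[cpg, samples].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(samples)), meth, cov])
        for _, row in window.iterrows():
            yv = expression.loc[row["probe"], samples].to_numpy(dtype=float)
            fit = sm.OLS(yv, design).fit()
            p = float(fit.pvalues[1])
            records.append(AssociationRecord(
                cpg=cpg, probe=str(row["probe"]), gene=str(row["gene"]),
                beta=float(fit.params[1]), se=float(fit.bse[1]), p=p,
                n_window_genes=n_genes,
                window_bonferroni_significant=bool(p < alpha / n_genes)))
    return records


def spearman_edge_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a reported Spearman correlation.

    Uses the t transform t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees
    of freedom; |rho| = 1 gives p = 0 exactly.
    """
    if abs(rho) > 1.0:
        raise ValueError("|rho| must be <= 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_network(
    meth_expr: list[AssociationRecord],
    expr_metab: pd.DataFrame,         # columns gene, metabolite, rho, n
    nominal_alpha: float = 0.05,
    suggestive_alpha: float = 0.001,
    fdr_alpha: float = 0.05,
) -> nx.Graph:
    """Assemble the tri-partite CpG–gene–metabolite graph.

    Methylation–expression edges enter at nominal significance;
    expression–metabolite edges enter at suggestive significance with an
    FDR tier (q < ``fdr_alpha``, computed by BH over *all* supplied
    correlation-table edges) marked on the surviving ones.  Edge signs
    follow the sign of the underlying statistic.  Genes named in the
    correlation table but absent from the expression layer's annotation
    are kept with an ``unanchored`` node flag.
    """
    g = nx.Graph()
    anchored_genes = set()
    for rec in meth_expr:
        if not (rec.p < nominal_alpha):
            continue
        anchored_genes.add(rec.gene)
        g.add_node(rec.cpg, type="cpg")
        g.add_node(rec.gene, type="gene", unanchored=False)
        g.add_edge(rec.cpg, rec.gene, layer="meth-expr",
                   sign=int(np.sign(rec.beta)) or 1,
                   statistic=rec.beta, p=rec.p,
                   tier="nominal")

    if len(expr_metab):
        tab = expr_metab.reset_index(drop=True)
        pvals = np.array([spearman_edge_pvalue(r, int(nn))
                          for r, nn in zip(tab["rho"], tab["n"])])
        qvals = bh_fdr(pvals)
        for i, row in tab.iterrows():
            p, q = float(pvals[i]), float(qvals[i])
            if not (p < suggestive_alpha):
                continue
            gene, metab = str(row["gene"]), str(row["metabolite"])
            if gene == metab:
                raise ValueError(f"self-edge on {gene!r}")
            tier = "FDR" if q < fdr_alpha else "suggestive"
            if gene not in g:
                g.add_node(gene, type="gene",
                           unanchored=gene not in anchored_genes)
            g.add_node(metab, type="metabolite")
            g.add_edge(gene, metab, layer="expr-metab",
                       sign=int(np.sign(row["rho"])) or 1,
                       statistic=float(row["rho"]), p=p, q=q, tier=tier)
    return g


_SUPPORTED_FORMATS = ("sif", "graphml")


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as SIF or GraphML.

    SIF lines are ``node <tab> layer:sign <tab> node``; isolated nodes use
    the single-column SIF form.  GraphML keeps all node and edge
    attributes and round-trips losslessly through networkx.
    """
    fmt = fmt.lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: "
                         f"{', '.join(_SUPPORTED_FORMATS)}")
    if fmt == "graphml":
        nx.write_graphml(net, path)
        return
    with open(path, "w") as fh:
        written = set()
        for u, v, attrs in sorted(net.edges(data=True)):
            sign = "+" if attrs.get("sign", 1) >= 0 else "-"
            rel = f"{attrs.get('layer', 'edge')}{sign}"
            fh.write(f"{u}\t{rel}\t{v}\n")
            written.update((u, v))
        for node in sorted(set(net.nodes) - written):
            fh.write(f"{node}\n")


def associations_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cpg": r.cpg, "probe": r.probe, "gene": r.gene, "beta": r.beta,
        "se": r.se, "p": r.p, "n_window_genes": r.n_window_genes,
        "window_bonferroni_significant": r.window_bonferroni_significant,
    } for r in records])
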