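"""End-to-end orchestration: regulator clustering -> phenotype signature ->
m6Sig score -> survival stratification.

This is a thin composition of the stage modules with the defaults wired
the way the analysis is meant to run; every stage remains individually
callable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix, load_regulator_catalog
from .signature import (
    CutpointResult,
    SigScoreModel,
    cox_screen,
    m6sig_score,
    optimal_cutpoint,
    phenotype_signature,
    rfe_select,
)
from .subtyping import ConsensusResult, consensus_cluster, minmax_rows, select_rank
from .survival_stats import SurvFit, km_logrank

__all__ = ["PipelineResult", "cluster_regulators", "run_m6sig_pipeline"]


@dataclass
class PipelineResult:
    consensus: ConsensusResult
    cluster_labels: pd.Series
    signature_genes: list[str]
    screened: pd.DataFrame
    selected_genes: list[str]
    model: SigScoreModel
    cutpoint: CutpointResult
    km: SurvFit


def cluster_regulators(
    expr: ExpressionMatrix,
    k_range: range | list[int] = (2, 3, 4, 5, 6),
    nruns: int = 200,
    seed: int = 0,
    genes: list[str] | None = None,
) -> ConsensusResult:
    """Consensus-NMF clustering of the regulator block of a cohort.

    The regulator x sample submatrix is min-max scaled per gene to [0, 1]
    (non-negativity for the KL factorization, equal leverage per gene)
    before consensus clustering.
    """
    genes = genes or load_regulator_catalog().symbols()
    sub = expr.subset_genes(genes)
    A = minmax_rows(sub)
    result = consensus_cluster(A, k_range=list(k_range), nruns=nruns, seed=seed)
    select_rank(result)
    return result


def run_m6sig_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    k: int | None = 3,
    k_range: range | list[int] = (2, 3, 4, 5, 6),
    nruns: int = 50,
    seed: int = 0,
    deg_alpha: float = 0.001,
    cox_alpha: float = 0.05,
    minprop: float = 0.1,
) -> PipelineResult:
    """Full analysis on one cohort with survival data.

    With ``k=None`` the cluster number is chosen by the rescaled-metric
    rule over ``k_range``; otherwise consensus clustering runs at the
    fixed ``k``. Downstream: one-vs-rest moderated-t DEGs intersected into
    the phenotype signature, univariate Cox screening (p < ``cox_alpha``),
    random-forest RFE against the cluster labels, PCA scoring (PC1 + PC2,
    oriented so high score = worse outcome) and a maximally selected
    log-rank cutpoint.
    """
    ks = [k] if k is not None else list(k_range)
    consensus = cluster_regulators(expr, k_range=ks, nruns=nruns, seed=seed)
    labels = consensus.labels()

    sig_genes = phenotype_signature(expr, labels, alpha=deg_alpha)
    if len(sig_genes) < 3:
        warnings.warn(
            "phenotype signature too small; relaxing threshold to 0.05", stacklevel=2
        )
        sig_genes = phenotype_signature(expr, labels, alpha=0.05)

    screened = cox_screen(expr, clinical, sig_genes, alpha=cox_alpha)
    kept = list(screened.index[screened["keep"]])
    if len(kept) < 5:
        warnings.warn(
            "fewer than 5 prognostic genes; keeping full signature", stacklevel=2
        )
        kept = sig_genes

    sub = expr.subset_genes(kept)
    selected = rfe_select(sub, labels, seed=seed)
    model = m6sig_score(expr, selected, clinical=clinical)
    cut = optimal_cutpoint(model.scores, clinical, minprop=minprop)
    model.screened = screened
    model.cutpoint = cut.cutpoint
    model.groups = cut.groups
    km = km_logrank(clinical, cut.groups)
    return PipelineResult(
        consensus=consensus,
        cluster_labels=labels,
        signature_genes=sig_genes,
        screened=screened,
        selected_genes=selected,
        model=model,
        cutpoint=cut,
        km=km,
    )
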