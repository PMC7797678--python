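"""The m6A phenotype gene signature and the per-sample m6Sig score.

Stages: (1) empirical-Bayes moderated-t differential expression per
cluster, one-vs-rest, intersected into a phenotype signature; (2)
univariate Cox screening of signature genes; (3) recursive feature
elimination with a random forest and cross-validation; (4) PCA of the
selected genes — the m6Sig score of sample i is PC1_i + PC2_i, with
component signs oriented so a higher score means worse outcome; (5) a
maximally selected log-rank cutpoint splitting the cohort into high/low
score groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from scipy.optimize import brentq
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core_io import ClinicalTable, ExpressionMatrix
from .enrichment import bh_adjust
from .survival_stats import logrank_z

__all__ = [
    "DgeTable",
    "SigScoreModel",
    "CutpointResult",
    "moderated_dge",
    "phenotype_signature",
    "cox_screen",
    "rfe_select",
    "m6sig_score",
    "optimal_cutpoint",
]


@dataclass
class DgeTable:
    table: pd.DataFrame  # per gene: lfc, t_ordinary, t_moderated, p, q
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance

    def significant(self, alpha: float = 0.001) -> list[str]:
        return list(self.table.index[self.table["q"] < alpha])


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    tri = lambda y: polygamma(1, y)
    lo, hi = 1e-8, 1e8
    if tri(lo) < x:
        return lo
    if tri(hi) > x:
        return hi
    return float(brentq(lambda y: tri(y) - x, lo, hi, xtol=1e-10))


def _fit_f_dist(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Smyth (2004) moment estimation of the variance prior (d0, s0^2)."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    t2 = evar - float(polygamma(1, d / 2.0))
    if t2 <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(t2)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_dge(
    expr: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    contrast: tuple,
) -> DgeTable:
    """Two-group moderated-t differential expression (log-scale input).

    ``contrast = (a, b)`` compares label a against label b; ``(a, "rest")``
    compares a against everything else. Per-gene residual variances are
    shrunk toward an empirical-Bayes prior, s~^2 = (d0 s0^2 + d s^2) /
    (d0 + d), and p-values use d0 + d degrees of freedom with BH
    adjustment across genes.
    """
    lab = pd.Series(np.asarray(labels), index=expr.sample_ids)
    a, b = contrast
    mask_a = (lab == a).to_numpy()
    mask_b = ~mask_a if (isinstance(b, str) and b == "rest") else (lab == b).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"contrast {contrast!r}: both groups must be non-empty")
    X = expr.values
    A, B = X[:, mask_a], X[:, mask_b]
    lfc = A.mean(axis=1) - B.mean(axis=1)
    d = n_a + n_b - 2
    if d < 1:
        warnings.warn(
            "one sample per group: prior unestimable, ordinary t undefined",
            stacklevel=2,
        )
        d = 1
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / max(n_a + n_b - 2, 1)
    scale = np.sqrt(1.0 / n_a + 1.0 / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = lfc / (np.sqrt(s2) * scale)
    t_ord = np.nan_to_num(t_ord, nan=0.0, posinf=np.inf, neginf=-np.inf)

    d0, s0_sq = _fit_f_dist(s2[s2 > 0], float(max(n_a + n_b - 2, 1)))
    if np.isfinite(d0):
        s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        s2_mod = np.full_like(s2, s0_sq)
        df_total = 1e6
    t_mod = lfc / (np.sqrt(s2_mod) * scale)
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {"lfc": lfc, "t_ordinary": t_ord, "t_moderated": t_mod, "p": p,
         "q": bh_adjust(p)},
        index=expr.gene_ids,
    )
    return DgeTable(table=table, d0=float(d0), s0_sq=float(s0_sq))


def phenotype_signature(
    expr: ExpressionMatrix,
    cluster_labels: pd.Series | np.ndarray,
    alpha: float = 0.001,
) -> list[str]:
    """Genes differential in *every* one-vs-rest cluster contrast.

    The per-contrast criterion is BH-adjusted p < ``alpha``; the signature
    is the intersection across clusters. An empty intersection yields an
    empty list with a warning, not an error.
    """
    lab = pd.Series(np.asarray(cluster_labels), index=expr.sample_ids)
    levels = sorted(pd.unique(lab))
    if len(levels) < 2:
        raise ValueError("need at least two clusters")
    sig: set[str] | None = None
    for level in levels:
        degs = set(moderated_dge(expr, lab, (level, "rest")).significant(alpha))
        sig = degs if sig is None else sig & degs
    assert sig is not None
    if not sig:
        warnings.warn("phenotype signature is empty at this threshold", stacklevel=2)
    return [g for g in expr.gene_ids if g in sig]


def cox_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox fit per gene; returns log-HR and p, flagging keepers.

    Efron tie handling via the shared Cox machinery. Genes whose fit fails
    to converge are dropped with a warning. The returned table has columns
    ``coef``, ``p``, ``keep`` (p < alpha).
    """
    from .survival_stats import cox_fit

    genes = genes if genes is not None else expr.gene_ids
    if int(clinical.event.sum()) < 10:
        warnings.warn("fewer than 10 events; screening will be unstable", stacklevel=2)
    rows = {}
    sub = expr.data.loc[[g for g in genes if g in expr.data.index], clinical.sample_ids]
    for gene in sub.index:
        design = sub.loc[[gene]].T
        design.columns = ["x"]
        try:
            fit = cox_fit(clinical, design)
        except Exception as err:  # non-convergence / degenerate gene
            warnings.warn(f"dropping gene {gene!r}: {err}", stacklevel=2)
            continue
        rows[gene] = (float(fit.table.loc["x", "coef"]), float(fit.table.loc["x", "p"]))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["coef", "p"])
    table["keep"] = table["p"] < alpha
    return table


def rfe_select(
    expr: ExpressionMatrix,
    response_labels: pd.Series | np.ndarray,
    fold_count: int = 10,
    seed: int = 0,
    size_grid: list[int] | None = None,
    n_estimators: int = 100,
) -> list[str]:
    """Random-forest recursive feature elimination with CV and one-SE rule.

    Starting from all genes, the lowest-importance genes are dropped down a
    halving subset-size grid; each size's mean cross-validated accuracy is
    recorded, and the final size is the smallest whose mean accuracy is
    within one standard error of the best (preferring fewer genes). The
    model is refit on the full data at each elimination step.
    """
    y = np.asarray(pd.Series(np.asarray(response_labels), index=expr.sample_ids))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("response must have at least two classes")
    folds = int(min(fold_count, counts.min()))
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    X = expr.data.T  # samples x genes
    genes = list(X.columns)
    if size_grid is None:
        size_grid = []
        s = len(genes)
        while s >= 5:
            size_grid.append(s)
            s //= 2
        if not size_grid:
            size_grid = [len(genes)]
    size_grid = sorted(set(min(s, len(genes)) for s in size_grid), reverse=True)

    rng = np.random.RandomState(seed)
    current = genes
    records = []  # (size, mean_acc, se_acc, genes)
    for size in size_grid:
        if len(current) > size:
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=rng.randint(2**31 - 1)
            )
            rf.fit(X[current], y)
            order = np.argsort(rf.feature_importances_)[::-1]
            current = [current[i] for i in order[:size]]
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=rng.randint(2**31 - 1))
        scores = cross_val_score(
            RandomForestClassifier(
                n_estimators=n_estimators, random_state=rng.randint(2**31 - 1)
            ),
            X[current], y, cv=cv,
        )
        records.append(
            (size, float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(folds)),
             list(current))
        )
    best_mean = max(r[1] for r in records)
    best_se = min(r[2] for r in records if r[1] == best_mean)
    threshold = best_mean - best_se
    # smallest size whose accuracy is within one SE of the best
    eligible = [r for r in records if r[1] >= threshold]
    chosen = min(eligible, key=lambda r: r[0])
    return chosen[3]


@dataclass
class SigScoreModel:
    """Frozen scoring model: z-score parameters + PC loadings + cutpoint."""

    genes: list[str]
    gene_means: pd.Series
    gene_sds: pd.Series
    loadings: pd.DataFrame  # genes x [PC1, PC2]
    scores: pd.Series
    pc_scores: pd.DataFrame  # samples x [PC1, PC2]
    screened: pd.DataFrame | None = None
    cutpoint: float | None = None
    groups: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def score(self, expr: ExpressionMatrix) -> pd.Series:
        """Apply the frozen model to a new cohort."""
        missing = [g for g in self.genes if g not in expr.data.index]
        if missing:
            raise KeyError(f"cohort lacks signature genes: {missing[:5]}")
        Z = (
            expr.data.loc[self.genes]
            .sub(self.gene_means, axis=0)
            .div(self.gene_sds, axis=0)
        )
        proj = Z.T @ self.loadings
        return proj["PC1"] + proj["PC2"]

    def save(self, path) -> None:
        payload = {
            "genes": self.genes,
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "loadings_pc1": self.loadings["PC1"].tolist(),
            "loadings_pc2": self.loadings["PC2"].tolist(),
            "cutpoint": self.cutpoint,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SigScoreModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        genes = payload["genes"]
        idx = pd.Index(genes)
        loadings = pd.DataFrame(
            {"PC1": payload["loadings_pc1"], "PC2": payload["loadings_pc2"]}, index=idx
        )
        return cls(
            genes=genes,
            gene_means=pd.Series(payload["gene_means"], index=idx),
            gene_sds=pd.Series(payload["gene_sds"], index=idx),
            loadings=loadings,
            scores=pd.Series(dtype=float),
            pc_scores=pd.DataFrame(columns=["PC1", "PC2"]),
            cutpoint=payload.get("cutpoint"),
        )


def m6sig_score(
    expr: ExpressionMatrix,
    selected_genes: list[str],
    clinical: ClinicalTable | None = None,
) -> SigScoreModel:
    """Per-sample m6Sig score: projection on PC1 plus projection on PC2.

    Genes are z-scored across samples before the PCA, so the score is
    invariant to per-gene affine rescaling and to gene order. When a
    clinical table is supplied, each component's sign is oriented so its
    Cox log-HR is >= 0 (higher score, worse outcome). A component with
    (near-)zero variance contributes 0 to every score.
    """
    genes = [g for g in selected_genes if g in expr.data.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 signature genes present")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = expr.data.loc[genes]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = sub.sub(mu, axis=0).div(sd, axis=0)  # genes x samples
    # PCA via SVD of the sample-centered matrix (z-scoring already centers rows;
    # columns are additionally centered so components describe sample variation)
    M = Z.T.to_numpy()
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if Vt.shape[0] < 2:
        raise ValueError("fewer than 2 principal components available")
    tol = max(M.shape) * np.finfo(float).eps * (S[0] if len(S) else 0.0)
    comps = []
    for c in range(2):
        v = Vt[c]
        proj = M @ v
        if S[c] <= tol:  # degenerate direction contributes nothing
            proj = np.zeros(M.shape[0])
            v = np.zeros_like(v)
        comps.append((v, proj))

    if clinical is not None:
        from .survival_stats import cox_fit

        for c, (v, proj) in enumerate(comps):
            if np.allclose(proj, 0) or np.std(proj) == 0:
                continue
            design = pd.DataFrame({"x": proj}, index=expr.sample_ids)
            try:
                coef = float(cox_fit(clinical, design).table.loc["x", "coef"])
            except Exception:
                continue
            if coef < 0:
                comps[c] = (-v, -proj)

    loadings = pd.DataFrame(
        {"PC1": comps[0][0], "PC2": comps[1][0]}, index=pd.Index(genes)
    )
    pc_scores = pd.DataFrame(
        {"PC1": comps[0][1], "PC2": comps[1][1]}, index=expr.sample_ids
    )
    scores = pc_scores["PC1"] + pc_scores["PC2"]
    scores.name = "m6Sig"
    return SigScoreModel(
        genes=genes,
        gene_means=mu,
        gene_sds=sd,
        loadings=loadings,
        scores=scores,
        pc_scores=pc_scores,
    )


@dataclass
class CutpointResult:
    cutpoint: float
    groups: pd.Series  # 'high' / 'low'
    statistic: float  # |standardized log-rank| at the cutpoint


def optimal_cutpoint(
    scores: pd.Series,
    clinical: ClinicalTable,
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint over the admissible score band.

    Candidate cutpoints are the distinct score values leaving at least a
    ``minprop`` fraction of samples on each side; the returned cutpoint
    maximizes the absolute standardized two-group log-rank statistic, ties
    broken toward the lower value. Samples with score > cutpoint are
    labelled 'high'.
    """
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    s = scores.loc[clinical.sample_ids].to_numpy(dtype=float)
    n = len(s)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all scores identical; no cutpoint exists")
    lo_needed = int(np.ceil(minprop * n))
    candidates = [
        v for v in uniq[:-1]
        if lo_needed <= (s <= v).sum() <= n - lo_needed
    ]
    if not candidates:
        raise ValueError("no admissible cutpoint within the minprop band")
    time, event = clinical.time, clinical.event
    best_v, best_stat = None, -np.inf
    for v in candidates:  # ascending, so strict > keeps the lowest tie
        stat = abs(logrank_z(time, event, s > v))
        if stat > best_stat + 1e-12:
            best_stat, best_v = stat, v
    groups = pd.Series(
        np.where(s > best_v, "high", "low"), index=clinical.sample_ids, name="group"
    )
    return CutpointResult(cutpoint=float(best_v), groups=groups, statistic=float(best_stat))
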