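"""Single-sample gene-set scoring and composite tumor-microenvironment scores.

``ssgsea_scores`` is the rank-weighted ECDF statistic of Barbie et al.
(2009): per sample, genes are ranked by expression, and the enrichment
score is the sum over all rank positions of the difference between the
weighted in-set ECDF (weights rank^alpha) and the unweighted out-of-set
ECDF. It depends on ranks only, so any strictly monotone transform of a
sample leaves its scores unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "EnrichmentScores",
    "EstimateScores",
    "IpsResult",
    "ssgsea_scores",
    "estimate_scores",
    "ips_score",
    "ora_test",
    "bh_adjust",
]

#: IPS class sign convention: effector cells and antigen presentation count
#: in favour of immunogenicity, suppressor cells and checkpoints against.
DEFAULT_IPS_WEIGHTS = {"MHC": 1.0, "EC": 1.0, "CP": -1.0, "SC": -1.0}


@dataclass
class EnrichmentScores:
    raw: pd.DataFrame  # samples x sets
    normalized: pd.DataFrame | None
    alpha: float

    @property
    def scores(self) -> pd.DataFrame:
        return self.normalized if self.normalized is not None else self.raw


@dataclass
class EstimateScores:
    table: pd.DataFrame  # samples x [immune, stromal, combined, purity]


@dataclass
class IpsResult:
    class_scores: pd.DataFrame  # samples x classes (averaged Z)
    ips: pd.Series
    weights: dict[str, float]


def _single_sample_es(
    ranks: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """ES for one sample: genes walked in descending-expression order."""
    order = np.argsort(-ranks, kind="stable")
    member = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(member, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    n_out = (~member).sum()
    p_out = np.cumsum(~member) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> EnrichmentScores:
    """Per-sample enrichment scores for every set in the collection.

    Set members absent from the matrix are dropped; a set with no member
    present is an error (listing the offenders), as is a set covering every
    gene (the out-of-set ECDF would be empty). With ``normalize=True`` each
    set's scores are additionally min-max rescaled to [0, 1] across samples.
    """
    genes = expr.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    memberships = {}
    fully_absent = []
    for name in sets.names():
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if not idx:
            fully_absent.append(name)
            continue
        if len(idx) == len(genes):
            raise ValueError(f"set {name!r} covers every gene in the matrix")
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        memberships[name] = mask
    if fully_absent:
        raise ValueError(f"gene sets with no member present: {fully_absent}")

    X = expr.values
    n_samples = X.shape[1]
    raw = np.zeros((n_samples, len(memberships)))
    set_names = list(memberships)
    for j in range(n_samples):
        ranks = rankdata(X[:, j])  # average ties; top gene gets rank N
        for s, name in enumerate(set_names):
            raw[j, s] = _single_sample_es(ranks, memberships[name], alpha)
    raw_df = pd.DataFrame(raw, index=expr.sample_ids, columns=set_names)
    norm_df = None
    if normalize:
        lo, hi = raw_df.min(axis=0), raw_df.max(axis=0)
        span = (hi - lo).replace(0.0, np.nan)
        norm_df = raw_df.sub(lo, axis=1).div(span, axis=1).fillna(0.0)
    return EnrichmentScores(raw=raw_df, normalized=norm_df, alpha=alpha)


# ESTIMATE purity calibration constants (Yoshihara et al. 2013).
_PURITY_A = 0.6049872018
_PURITY_B = 0.0001467884


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: list[str] | GeneSetCollection,
    immune_set: list[str] | None = None,
) -> EstimateScores:
    """Immune/stromal infiltration scores and the derived tumor purity.

    Scores are raw (unnormalized) single-sample enrichment scores at
    alpha = 0.25; purity = cos(0.6049872018 + 0.0001467884 * (immune +
    stromal)) clipped into (0, 1]. Purity decreases as the combined
    infiltration score grows.
    """
    if isinstance(stromal_set, GeneSetCollection):
        coll = stromal_set
        if set(coll.names()) != {"stromal", "immune"}:
            raise ValueError("collection must contain exactly 'stromal' and 'immune'")
    else:
        if immune_set is None:
            raise ValueError("immune_set required when passing plain gene lists")
        coll = GeneSetCollection({"stromal": list(stromal_set), "immune": list(immune_set)})
    es = ssgsea_scores(expr, coll, alpha=0.25, normalize=False).raw
    combined = es["immune"] + es["stromal"]
    purity = np.cos(_PURITY_A + _PURITY_B * combined).clip(1e-9, 1.0)
    table = pd.DataFrame(
        {
            "immune": es["immune"],
            "stromal": es["stromal"],
            "combined": combined,
            "purity": purity,
        }
    )
    return EstimateScores(table=table)


def ips_score(
    expr: ExpressionMatrix,
    class_panels: GeneSetCollection,
    class_weights: dict[str, float] | None = None,
) -> IpsResult:
    """Immunophenoscore-style weighted sum of class-averaged gene Z-scores.

    Every panel carries ``metadata[name]['ips_class']`` (one of MHC, EC,
    CP, SC by convention) and optionally a per-panel ``weight`` used when
    averaging panels within a class. Genes are Z-scored across samples
    (zero-variance genes contribute 0 with a warning); the IPS is the sum
    over classes of class weight x class-averaged Z.
    """
    weights = dict(DEFAULT_IPS_WEIGHTS)
    if class_weights:
        weights.update(class_weights)

    X = expr.data
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    flat = sd <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their Z set to 0", stacklevel=2
        )
    Z = X.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)

    by_class: dict[str, list[tuple[float, pd.Series]]] = {}
    for name in class_panels.names():
        meta = class_panels.metadata.get(name, {})
        cls = meta.get("ips_class")
        if cls is None:
            raise ValueError(f"panel {name!r} lacks 'ips_class' metadata")
        members = [g for g in class_panels[name] if g in Z.index]
        if not members:
            continue  # missing panel genes are dropped, not imputed
        panel_avg = Z.loc[members].mean(axis=0)
        by_class.setdefault(cls, []).append((float(meta.get("weight", 1.0)), panel_avg))
    if not by_class:
        raise ValueError("no panel has any gene present in the matrix")

    class_scores = {}
    for cls, entries in by_class.items():
        ws = np.array([w for w, _ in entries])
        mat = pd.concat([s for _, s in entries], axis=1)
        class_scores[cls] = mat.mul(ws, axis=1).sum(axis=1) / ws.sum()
    class_df = pd.DataFrame(class_scores)
    ips = sum(
        weights.get(cls, 1.0) * class_df[cls] for cls in class_df.columns
    )
    return IpsResult(class_scores=class_df, ips=pd.Series(ips, name="IPS"),
                     weights=weights)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


def ora_test(
    query_genes: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Returns a table with overlap counts, upper-tail hypergeometric p and
    the BH-adjusted p across all tested sets. Set members outside the
    universe are ignored.
    """
    uni = set(universe)
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    M, N = len(uni), len(query)
    rows = []
    for name in sets.names():
        members = set(sets[name]) & uni
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, len(members), N)) if members else 1.0
        rows.append((name, k, len(members), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table
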