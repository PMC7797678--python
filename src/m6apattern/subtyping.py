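"""Consensus NMF clustering of regulator expression and rank selection.

``nmf_factorize`` implements the multiplicative KL-divergence update scheme
of Brunet et al. (2004); repeated factorizations with random restarts are
aggregated into a consensus co-clustering matrix, and the cluster number is
chosen from cophenetic, dispersion and silhouette diagnostics.

Clustering input convention: callers pass a non-negative matrix; for
log-scale expression use :func:`minmax_rows` first (per-gene min-max to
[0, 1]), which both enforces non-negativity and gives every regulator equal
leverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .core_io import ExpressionMatrix

__all__ = [
    "NmfFactors",
    "ConsensusResult",
    "minmax_rows",
    "nmf_factorize",
    "consensus_cluster",
    "select_rank",
]


@dataclass
class NmfFactors:
    """One A ~ WH factorization with its KL objective trace."""

    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples
    divergence: float
    n_iter: int
    objective_trace: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        """Hard sample assignment: dominant metagene of each column of H."""
        return np.argmax(self.H, axis=0)


@dataclass
class RankDiagnostics:
    consensus: np.ndarray
    labels: np.ndarray  # 1..k
    cophenetic: float
    dispersion: float
    silhouette: float
    empty_cluster_runs: int = 0


@dataclass
class ConsensusResult:
    """Per-rank consensus matrices, hard labels and selection diagnostics."""

    sample_ids: list[str]
    per_rank: dict[int, RankDiagnostics]
    nruns: int
    warnings: list[str] = field(default_factory=list)
    chosen_k: int | None = None

    @property
    def k_range(self) -> list[int]:
        return sorted(self.per_rank)

    def labels(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        if k is None:
            raise ValueError("no rank chosen yet; call select_rank first")
        return pd.Series(self.per_rank[k].labels, index=self.sample_ids, name="cluster")

    def metric_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cophenetic": {k: d.cophenetic for k, d in self.per_rank.items()},
                "dispersion": {k: d.dispersion for k, d in self.per_rank.items()},
                "silhouette": {k: d.silhouette for k, d in self.per_rank.items()},
            }
        )


def minmax_rows(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max rescale to [0, 1]; constant genes map to 0.5."""
    df = expr.data if isinstance(expr, ExpressionMatrix) else expr
    lo = df.min(axis=1)
    span = df.max(axis=1) - lo
    out = df.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    return out.fillna(0.5)


def _kl_divergence(A: np.ndarray, WH: np.ndarray) -> float:
    mask = A > 0
    div = np.sum(A[mask] * np.log(A[mask] / WH[mask])) - A.sum() + WH.sum()
    return float(div)


def nmf_factorize(
    A: np.ndarray | pd.DataFrame,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> NmfFactors:
    """Multiplicative KL-update NMF with random uniform initialization.

    The objective D(A || WH) = sum(A log(A/WH) - A + WH) is non-increasing
    under the updates; iteration stops when its relative change over a
    10-iteration window drops below ``tol``.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("NMF input must be non-negative")
    if np.any(A.sum(axis=1) == 0):
        raise ValueError("NMF input has all-zero rows; drop them first")
    m, n = A.shape
    if not 1 <= k < min(m, n):
        raise ValueError(f"rank k={k} out of range for a {m}x{n} matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    scale = np.sqrt(A.mean() / (0.25 * k))
    W = rng.uniform(1e-4, 1.0, size=(m, k)) * scale
    H = rng.uniform(1e-4, 1.0, size=(k, n)) * scale

    eps = 1e-12
    trace = []
    prev = None
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        WH = W @ H + eps
        H *= (W.T @ (A / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((A / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        if it % 10 == 0 or it == max_iter:
            obj = _kl_divergence(A, W @ H + eps)
            trace.append(obj)
            if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
                n_iter = it
                break
            prev = obj
    final = _kl_divergence(A, W @ H + eps)
    if not trace or trace[-1] != final:
        trace.append(final)
    return NmfFactors(W=W, H=H, divergence=final, n_iter=n_iter,
                      objective_trace=np.asarray(trace))


def _dispersion(consensus: np.ndarray) -> float:
    return float(np.mean(4.0 * (consensus - 0.5) ** 2))


def consensus_cluster(
    A: np.ndarray | pd.DataFrame,
    k_range: range | list[int],
    nruns: int = 200,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    sample_ids: list[str] | None = None,
) -> ConsensusResult:
    """Aggregate ``nruns`` random-restart factorizations per rank.

    consensus[i, j] is the fraction of runs assigning samples i and j to the
    same metagene; hard labels come from average-linkage hierarchical
    clustering of 1 - consensus cut at k. If more than half the runs at some
    rank leave a cluster empty, a warning is recorded on the result.
    """
    if isinstance(A, pd.DataFrame):
        sample_ids = sample_ids or list(A.columns)
        A = A.to_numpy(dtype=float)
    n = A.shape[1]
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    if nruns < 2:
        raise ValueError("consensus clustering needs nruns >= 2")
    ks = sorted(set(int(k) for k in k_range))

    root = np.random.SeedSequence(seed)
    per_rank: dict[int, RankDiagnostics] = {}
    messages: list[str] = []
    for k in ks:
        streams = root.spawn(nruns)
        consensus = np.zeros((n, n))
        empty_runs = 0
        for r in range(nruns):
            fac = nmf_factorize(
                A, k, seed=np.random.default_rng(streams[r]),
                max_iter=max_iter, tol=tol,
            )
            lab = fac.labels
            if len(np.unique(lab)) < k:
                empty_runs += 1
            consensus += lab[:, None] == lab[None, :]
        consensus /= nruns
        np.fill_diagonal(consensus, 1.0)
        consensus = 0.5 * (consensus + consensus.T)
        if empty_runs > nruns / 2:
            messages.append(
                f"k={k}: empty cluster in {empty_runs}/{nruns} runs"
            )

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        link = average(condensed)
        labels = fcluster(link, t=k, criterion="maxclust")
        if condensed.std() > 0:
            coph = float(np.corrcoef(cophenet(link), condensed)[0, 1])
        else:
            coph = 1.0
        if 1 < len(np.unique(labels)) < n:
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        else:
            sil = 0.0
        per_rank[k] = RankDiagnostics(
            consensus=consensus,
            labels=labels,
            cophenetic=coph,
            dispersion=_dispersion(consensus),
            silhouette=sil,
            empty_cluster_runs=empty_runs,
        )
    return ConsensusResult(
        sample_ids=sample_ids, per_rank=per_rank, nruns=nruns, warnings=messages
    )


def select_rank(result: ConsensusResult) -> int:
    """Pick the rank maximizing the mean of min-max-rescaled diagnostics.

    Each of (cophenetic, dispersion, silhouette) is rescaled to [0, 1]
    across the tested ranks (constant metrics contribute 0.5 everywhere);
    ties break toward the smaller rank.
    """
    ks = result.k_range
    if len(ks) == 1:
        warnings.warn("only one rank tested; returning it", stacklevel=2)
        result.chosen_k = ks[0]
        return ks[0]
    table = result.metric_table().loc[ks]
    lo, hi = table.min(axis=0), table.max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)
    scaled = table.sub(lo, axis=1).div(span, axis=1).fillna(0.5)
    combined = scaled.mean(axis=1).round(12)  # round so float dust cannot mask ties
    best = int(combined.idxmax())  # idxmax returns the first (smallest) k on ties
    result.chosen_k = best
    return best
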