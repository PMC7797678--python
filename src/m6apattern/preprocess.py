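"""Cross-cohort harmonization: unit conversion, quantile normalization,
and empirical-Bayes batch adjustment.

The batch adjustment is the parametric ComBat model (Johnson, Li & Rabinovic
2007): per-gene standardization, normal/inverse-gamma shrinkage of per-batch
location and scale, then removal. No covariate-preservation terms are
modelled. Inputs are expected on a roughly Gaussian (log2) scale; linear
matrices are log2(x+1)-transformed first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = ["BatchDesign", "fpkm_to_tpm", "quantile_normalize", "batch_adjust"]


class BatchDesign:
    """sample_id -> batch label; every batch needs at least two samples."""

    def __init__(self, labels: dict[str, str] | pd.Series):
        self.labels = pd.Series(labels, dtype=object)
        counts = self.labels.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"batches with fewer than 2 samples: {small}")

    @property
    def batches(self) -> list[str]:
        return sorted(self.labels.unique(), key=str)

    def for_samples(self, samples: list[str]) -> pd.Series:
        missing = [s for s in samples if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a batch label: {missing[:5]}")
        return self.labels.loc[samples]


def fpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so expression sums to 1e6.

    FPKM is already length-normalized, so TPM_g = FPKM_g / sum(FPKM) * 1e6
    requires no gene lengths.
    """
    if expr.scale != "linear":
        raise ValueError("fpkm_to_tpm expects a linear-scale matrix")
    totals = expr.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero expression for sample(s): {list(zero.index)}")
    return ExpressionMatrix(expr.data / totals * 1e6, scale="linear")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the per-sample sorted value
    vectors; ties within a sample get the mean of the quantile values their
    positions would have received.
    """
    X = expr.values
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(n_samples):
        col = X[:, j]
        idx = order[:, j]
        assigned = np.empty(n_genes)
        assigned[idx] = reference
        # average reference values over tie groups
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inv, minlength=len(uniq))
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        scale=expr.scale,
    )


def _squeeze_batch_scale(dsq: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters for batch variances."""
    m = float(np.mean(dsq))
    s2 = float(np.var(dsq, ddof=1)) if len(dsq) > 1 else 0.0
    if s2 <= 0:
        return 2.0, m  # flat-ish prior when variances are constant
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def batch_adjust(
    expr: ExpressionMatrix,
    design: BatchDesign,
    *,
    max_iter: int = 100,
    conv: float = 1e-4,
) -> ExpressionMatrix:
    """Remove batch location/scale effects with parametric EB shrinkage.

    Genes with zero overall variance are passed through unadjusted with a
    warning. With a single batch the input is returned unchanged. The
    per-gene grand mean (batch-size weighted) is preserved.
    """
    work = expr.to_log2()
    batches = design.for_samples(work.sample_ids)
    levels = sorted(pd.unique(batches), key=str)
    if len(levels) == 1:
        return expr
    X = work.values.copy()
    n_genes, n_samples = X.shape
    groups = [np.flatnonzero((batches == b).to_numpy()) for b in levels]
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        raise ValueError("every batch must contain at least 2 samples")

    batch_means = np.stack([X[:, g].mean(axis=1) for g in groups], axis=1)
    grand = batch_means @ (sizes / n_samples)
    # pooled variance of residuals about the batch means (canonical
    # standardization step), so batch location shifts do not inflate it
    resid_ss = np.zeros(n_genes)
    for i, g in enumerate(groups):
        resid_ss += ((X[:, g] - batch_means[:, [i]]) ** 2).sum(axis=1)
    var_pooled = resid_ss / n_samples
    degenerate = var_pooled <= 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) passed through unadjusted",
            stacklevel=2,
        )
    ok = ~degenerate
    sd = np.sqrt(var_pooled[ok])
    Z = (X[ok] - grand[ok, None]) / sd[:, None]

    out = X.copy()
    Zadj = Z.copy()
    for i, g in enumerate(groups):
        n_i = sizes[i]
        gamma_hat = Z[:, g].mean(axis=1)
        delta_hat = Z[:, g].var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1)) if len(gamma_hat) > 1 else 1.0
        tau2 = max(tau2, 1e-12)
        a_prior, b_prior = _squeeze_batch_scale(delta_hat)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (n_i * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_i * tau2 + delta_star
            )
            ss = ((Z[:, g] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * ss) / (n_i / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - gamma_star)), np.max(np.abs(d_new - delta_star))
            )
            gamma_star, delta_star = g_new, d_new
            if change < conv:
                break
        Zadj[:, g] = (Z[:, g] - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out[ok] = Zadj * sd[:, None] + grand[ok, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=work.gene_ids, columns=work.sample_ids), scale="log2"
    )
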