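"""Synthetic multi-pattern cohorts with known ground truth.

The generator plants exactly the structure the downstream stages assume:
a small block of regulator genes whose means differ by pattern, immune-cell
panel genes shifted per pattern, a set of pan-differential signature genes,
exponential survival whose hazard depends on the pattern, independent
uniform censoring, and optional batch location/scale effects applied last.
Expression is drawn on a Gaussian log2-like scale (microarray-like);
exponentiate for a linear-scale cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MafTable,
    load_regulator_catalog,
)

__all__ = ["CohortSimulationParams", "SyntheticCohort", "generate_cohort", "generate_maf"]


def _default_immune_panels() -> dict[str, list[str]]:
    panels = {}
    for cell in ("CD8_T", "NK", "Macrophage", "Treg"):
        panels[cell] = [f"IMM_{cell}_{i:02d}" for i in range(8)]
    return panels


def _default_immune_shifts() -> np.ndarray:
    # patterns x panels; pattern 0 is immune-hot, pattern 2 immune-cold
    return np.array(
        [
            [1.5, 1.5, 0.5, 0.5],
            [0.0, 0.0, 0.0, 0.0],
            [-1.5, -1.5, -0.5, -0.5],
        ]
    )


@dataclass
class CohortSimulationParams:
    """Knobs of the planted-cohort generator.

    Shifts are additive on the log2 scale in units of the baseline SD
    (``baseline_sd`` defaults to 1, so a shift of 2.0 means 2 SD).
    ``pattern_log_hazard`` couples survival to the pattern: sample i with
    pattern p has hazard ``baseline_hazard * exp(pattern_log_hazard[p])``
    per month. ``censoring_rate`` is the target fraction censored by an
    independent Uniform(0, c) time whose upper bound is calibrated to it.
    """

    n_per_pattern: tuple[int, ...] = (60, 60, 60)
    n_background_genes: int = 300
    regulator_shift: float = 2.0
    regulator_shift_matrix: np.ndarray | None = None  # patterns x 23 overrides
    n_signature_genes: int = 50
    signature_shift: float = 3.0
    immune_panels: dict[str, list[str]] = field(default_factory=_default_immune_panels)
    immune_shifts: np.ndarray = field(default_factory=_default_immune_shifts)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    n_batches: int = 1
    batch_location: float = 0.0
    batch_scale: float = 1.0
    baseline_hazard: float = 0.02
    pattern_log_hazard: tuple[float, ...] = (-0.5, 0.0, 0.5)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_pattern):
            raise ValueError("all pattern sizes must be > 0")
        if self.n_background_genes <= 0 or self.n_signature_genes < 0:
            raise ValueError("gene counts must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if len(self.pattern_log_hazard) != len(self.n_per_pattern):
            raise ValueError("pattern_log_hazard must match number of patterns")
        self.immune_shifts = np.asarray(self.immune_shifts, dtype=float)
        if self.immune_shifts.shape != (len(self.n_per_pattern), len(self.immune_panels)):
            raise ValueError("immune_shifts must be patterns x panels")

    @property
    def n_patterns(self) -> int:
        return len(self.n_per_pattern)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_pattern))


@dataclass
class SyntheticCohort:
    """A generated cohort plus every piece of planted ground truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    pattern_labels: pd.Series  # true pattern per sample (0-based)
    immune_truth: pd.DataFrame  # samples x panels planted shift levels
    batch_labels: pd.Series
    immune_panels: GeneSetCollection
    signature_genes: list[str]
    regulator_assignment: pd.Series  # regulator -> pattern whose program it marks
    true_log_hazard: pd.Series  # per sample planted log relative hazard
    params: CohortSimulationParams


def _calibrate_censoring_bound(times: np.ndarray, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting ``rate`` on average.

    P(censored | T_i) = P(C < T_i) = min(T_i / c, 1); monotone decreasing
    in c, so bisection on the empirical mean converges.
    """
    lo, hi = 1e-6, float(times.max()) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(np.minimum(times / mid, 1.0)))
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(params: CohortSimulationParams) -> SyntheticCohort:
    """Draw one cohort; identical seed gives a bit-identical cohort."""
    streams = np.random.SeedSequence(params.seed).spawn(4)
    rng_expr = np.random.default_rng(streams[0])
    rng_surv = np.random.default_rng(streams[1])
    rng_cens = np.random.default_rng(streams[2])
    rng_batch = np.random.default_rng(streams[3])

    catalog = load_regulator_catalog()
    regulators = catalog.symbols()
    sig_genes = [f"SIG_{i:04d}" for i in range(params.n_signature_genes)]
    panel_genes = [g for genes in params.immune_panels.values() for g in genes]
    if len(set(panel_genes)) != len(panel_genes):
        raise ValueError("immune panels share genes; panels must be disjoint")
    bg_genes = [f"BG_{i:04d}" for i in range(params.n_background_genes)]
    genes = regulators + sig_genes + panel_genes + bg_genes
    if len(set(genes)) != len(genes):
        raise ValueError("immune panel genes collide with the reserved gene universe")

    n_pat = params.n_patterns
    pattern = np.repeat(np.arange(n_pat), params.n_per_pattern)
    n = params.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    mean = np.full((len(genes), n), params.baseline_mean)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # regulator programs: by default each pattern elevates its own block
    if params.regulator_shift_matrix is not None:
        shift_mat = np.asarray(params.regulator_shift_matrix, dtype=float)
        if shift_mat.shape != (n_pat, len(regulators)):
            raise ValueError("regulator_shift_matrix must be patterns x 23")
    else:
        shift_mat = np.zeros((n_pat, len(regulators)))
        blocks = np.array_split(np.arange(len(regulators)), n_pat)
        for p, block in enumerate(blocks):
            shift_mat[p, block] = params.regulator_shift
    reg_assign = pd.Series(
        np.argmax(shift_mat, axis=0) if shift_mat.any() else np.zeros(len(regulators), int),
        index=regulators,
        name="pattern",
    )
    for j, g in enumerate(regulators):
        mean[gene_pos[g]] += shift_mat[pattern, j]

    # signature genes: each up-shifted in one pattern (round-robin), which
    # makes every gene differential in every one-vs-rest contrast
    for i, g in enumerate(sig_genes):
        up = i % n_pat
        mean[gene_pos[g], pattern == up] += params.signature_shift

    # immune panels
    panel_names = list(params.immune_panels)
    for c, pname in enumerate(panel_names):
        for g in params.immune_panels[pname]:
            mean[gene_pos[g]] += params.immune_shifts[pattern, c]

    values = mean + rng_expr.normal(0.0, params.baseline_sd, size=mean.shape)

    # batch effects applied last: location + scale on the log2 scale
    batch = pd.Series(np.arange(n) % params.n_batches, index=samples, name="batch")
    if params.n_batches > 1 and (params.batch_location != 0 or params.batch_scale != 1):
        for b in range(params.n_batches):
            cols = batch.to_numpy() == b
            loc = params.batch_location * b
            scale = params.batch_scale**b
            centered = values[:, cols] - params.baseline_mean
            values[:, cols] = params.baseline_mean + centered * scale + loc
            _ = rng_batch  # stream reserved for stochastic batch models

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )

    # survival: exponential with pattern hazards, uniform independent censoring
    log_hr = np.asarray(params.pattern_log_hazard)[pattern]
    rate = params.baseline_hazard * np.exp(log_hr)
    latent = rng_surv.exponential(1.0 / rate)
    if params.censoring_rate > 0:
        cmax = _calibrate_censoring_bound(latent, params.censoring_rate)
        cens = rng_cens.uniform(0.0, cmax, size=n)
        time = np.minimum(latent, cens)
        event = (latent <= cens).astype(int)
    else:
        time, event = latent, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    clinical = ClinicalTable(
        pd.DataFrame(
            {"time": time, "event": event, "pattern": pattern, "batch": batch.to_numpy()},
            index=samples,
        )
    )
    immune_truth = pd.DataFrame(
        params.immune_shifts[pattern], index=samples, columns=panel_names
    )
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        pattern_labels=pd.Series(pattern, index=samples, name="pattern"),
        immune_truth=immune_truth,
        batch_labels=batch,
        immune_panels=GeneSetCollection({k: list(v) for k, v in params.immune_panels.items()}),
        signature_genes=sig_genes,
        regulator_assignment=reg_assign,
        true_log_hazard=pd.Series(log_hr, index=samples, name="log_hazard"),
        params=params,
    )


# ---------------------------------------------------------------------------
# Mutation data

_NONSYN_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
)
_NONSYN_WEIGHTS = (0.70, 0.08, 0.07, 0.05, 0.03, 0.03, 0.04)


def generate_maf(
    n_samples: int,
    per_group_gene_rates: dict[str, dict[str, float]] | dict[str, float] | None = None,
    signature_profiles: np.ndarray | None = None,
    exposures: np.ndarray | None = None,
    *,
    mutations_per_sample: float = 50.0,
    nonsyn_fraction: float = 0.75,
    group_labels: list[str] | None = None,
    seed: int = 0,
) -> MafTable:
    """Simulate a MAF with planted gene mutation rates and 96-context mixes.

    Two independent layers:

    * driver layer — for each listed gene, each sample mutates it with its
      group's Bernoulli rate (one missense record per hit);
    * passenger layer — Poisson(``mutations_per_sample``) records per sample
      on filler genes, nonsynonymous with probability ``nonsyn_fraction``.

    Every record draws a trinucleotide context from the sample's exposure
    mixture over ``signature_profiles`` (rows must sum to 1), so the
    per-sample 96-context counts are multinomial in the planted mixture.
    """
    from .genomics import CONTEXTS_96

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = [f"T{i:04d}" for i in range(n_samples)]
    if group_labels is None:
        group_labels = ["all"] * n_samples
    if len(group_labels) != n_samples:
        raise ValueError("group_labels must have one entry per sample")

    if per_group_gene_rates is None:
        per_group_gene_rates = {}
    if per_group_gene_rates and not isinstance(
        next(iter(per_group_gene_rates.values())), dict
    ):
        per_group_gene_rates = {g: dict(per_group_gene_rates) for g in set(group_labels)}
    for grp, rates in per_group_gene_rates.items():
        for gene, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {gene!r} in group {grp!r} outside [0, 1]")

    if signature_profiles is not None:
        signature_profiles = np.asarray(signature_profiles, dtype=float)
        if signature_profiles.ndim == 1:
            signature_profiles = signature_profiles[None, :]
        if signature_profiles.shape[1] != 96:
            raise ValueError("signature profiles must be 96-vectors")
        sums = signature_profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature profiles must each sum to 1")
        if exposures is None:
            exposures = np.full((n_samples, signature_profiles.shape[0]), 1.0)
        exposures = np.asarray(exposures, dtype=float)
        if exposures.ndim == 1:
            exposures = np.tile(exposures, (n_samples, 1))
        if (exposures < 0).any():
            raise ValueError("exposures must be non-negative")
        exposures = exposures / exposures.sum(axis=1, keepdims=True)
        mixes = exposures @ signature_profiles  # samples x 96
    else:
        mixes = np.full((n_samples, 96), 1.0 / 96)

    records: list[tuple[str, str, str, str, str]] = []
    context_ids = np.arange(96)
    for i, sample in enumerate(samples):
        grp = group_labels[i]
        mix = mixes[i]
        rates = per_group_gene_rates.get(grp, {})
        for gene, r in rates.items():
            if rng.random() < r:
                ctx = CONTEXTS_96[rng.choice(context_ids, p=mix)]
                records.append((gene, sample, "Missense_Mutation", ctx, grp))
        n_pass = rng.poisson(mutations_per_sample)
        if n_pass:
            nonsyn = rng.random(n_pass) < nonsyn_fraction
            ctxs = rng.choice(context_ids, size=n_pass, p=mix)
            for j in range(n_pass):
                if nonsyn[j]:
                    cls = _NONSYN_CLASSES[
                        rng.choice(len(_NONSYN_CLASSES), p=_NONSYN_WEIGHTS)
                    ]
                else:
                    cls = "Silent"
                records.append(
                    (f"PASSENGER_{j % 500:03d}", sample, cls, CONTEXTS_96[ctxs[j]], grp)
                )

    df = pd.DataFrame(
        records,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "Trinucleotide_Context",
            "group",
        ],
    )
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "Hugo_Symbol",
                "Tumor_Sample_Barcode",
                "Variant_Classification",
                "Trinucleotide_Context",
                "group",
            ]
        )
    return MafTable(df)
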