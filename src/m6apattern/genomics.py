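"""MAF-derived summaries: tumor mutation load, group-wise mutation-rate
comparison, and 96-context mutational-signature extraction.

Signature extraction reuses the KL-divergence NMF engine on the samples x
96 trinucleotide-context count matrix; extracted profiles are row-
normalized and optionally annotated against user-supplied reference
profiles (e.g. COSMIC, never bundled) by cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_io import MAF_NONSYNONYMOUS, MafTable
from .enrichment import bh_adjust
from .subtyping import nmf_factorize

__all__ = [
    "CONTEXTS_96",
    "TmlResult",
    "MutSignatureResult",
    "tumor_mutation_load",
    "compare_mutation_rates",
    "context_matrix",
    "extract_signatures",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical ordering of the 96 trinucleotide mutation contexts:
#: substitution-major, then 5' flank, then 3' flank (COSMIC ordering).
CONTEXTS_96: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]


@dataclass
class TmlResult:
    counts: pd.Series  # sample_id -> nonsynonymous variant count


@dataclass
class MutSignatureResult:
    profiles: pd.DataFrame  # k x 96, rows sum to 1
    contributions: pd.DataFrame  # samples x k exposures
    annotation: pd.DataFrame | None  # per signature: best reference + cosine


def tumor_mutation_load(
    maf: MafTable,
    sample_ids: list[str] | None = None,
    nonsynonymous: frozenset[str] = MAF_NONSYNONYMOUS,
) -> TmlResult:
    """Per-sample count of nonsynonymous variants.

    Counted classes: frameshift, in-frame indel, missense, nonsense and
    splice-site. Unknown classifications are ignored with a warning;
    ``sample_ids``, if given, fixes the output index (zero-filled), which
    keeps samples with no nonsynonymous variants in view.
    """
    df = maf.data
    unknown = df.loc[~df["known_class"], "Variant_Classification"].unique()
    if len(unknown):
        warnings.warn(f"ignoring unknown classes: {sorted(unknown)}", stacklevel=2)
    hits = df[df["Variant_Classification"].isin(nonsynonymous)]
    counts = hits.groupby("Tumor_Sample_Barcode").size()
    if sample_ids is not None:
        counts = counts.reindex(sample_ids, fill_value=0)
    counts.name = "tml"
    return TmlResult(counts=counts.astype(int))


def compare_mutation_rates(
    maf: MafTable,
    group_labels: pd.Series | dict,
    genes: list[str],
) -> pd.DataFrame:
    """Two-group Fisher exact comparison of per-gene mutation frequencies.

    ``group_labels`` maps every cohort sample (mutated or not) to one of
    exactly two groups; the per-gene 2x2 table is mutated/wild-type x
    group. Returns rates, the two-sided exact p and the BH q across genes.
    Genes absent from the MAF keep a 0/0 row with p = 1.
    """
    labels = pd.Series(group_labels)
    groups = sorted(labels.unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    members = {g: set(labels.index[labels == g]) for g in groups}
    if any(len(m) == 0 for m in members.values()):
        raise ValueError("both groups must be non-empty")
    df = maf.data
    mutated = {
        gene: set(df.loc[df["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
        for gene in genes
    }
    rows = []
    for gene in genes:
        hit = mutated[gene]
        a = len(hit & members[groups[0]])
        b = len(members[groups[0]]) - a
        c = len(hit & members[groups[1]])
        d = len(members[groups[1]]) - c
        if a + c == 0:
            p = 1.0
        else:
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append(
            (gene, a / (a + b), c / (c + d), p)
        )
    out = pd.DataFrame(
        rows, columns=["gene", f"rate_{groups[0]}", f"rate_{groups[1]}", "p"]
    ).set_index("gene")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def context_matrix(maf: MafTable, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Samples x 96 trinucleotide-context count matrix from a MAF.

    Requires a ``Trinucleotide_Context`` column with labels like
    ``A[C>T]G``; rows with missing or malformed contexts are skipped with
    a warning.
    """
    df = maf.data
    if "Trinucleotide_Context" not in df.columns:
        raise ValueError("MAF lacks a Trinucleotide_Context column")
    valid = df["Trinucleotide_Context"].isin(CONTEXTS_96)
    if (~valid).any():
        warnings.warn(
            f"skipping {int((~valid).sum())} row(s) with malformed context",
            stacklevel=2,
        )
    sub = df[valid]
    counts = (
        sub.groupby(["Tumor_Sample_Barcode", "Trinucleotide_Context"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=CONTEXTS_96, fill_value=0)
    )
    if sample_ids is not None:
        counts = counts.reindex(sample_ids, fill_value=0)
    return counts.astype(int)


def fisher_randomized_p(
    a: int, b: int, c: int, d: int, rng: np.random.Generator
) -> float:
    """Randomized (CDF-uniformized) two-sided Fisher p for a 2x2 table.

    The exact conditional test is discrete, so its p-values are stepped and
    conservative under the null; the randomized version — probability-mass
    ordering with a uniform draw spread over the tied mass — is exactly
    Uniform(0, 1) when the null holds, which is what calibration checks
    need. Never use this for inference on real data.
    """
    from scipy.stats import hypergeom

    n1, n2 = a + b, c + d
    k = a + c
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = hypergeom.pmf(support, n1 + n2, n1, k)
    obs = hypergeom.pmf(a, n1 + n2, n1, k)
    less = pmf[pmf < obs - 1e-12].sum()
    tied = pmf[np.abs(pmf - obs) <= 1e-12].sum()
    return float(less + rng.uniform() * tied)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def extract_signatures(
    counts96: pd.DataFrame,
    k: int,
    seed: int = 0,
    reference_profiles: pd.DataFrame | None = None,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> MutSignatureResult:
    """KL-NMF factorization of the mutation portrait into k signatures.

    The 96 x samples matrix is factorized as W (96 x k, the signatures)
    times H (k x samples, the activities); signature profiles are
    normalized to sum to 1 with activities rescaled to compensate, so
    profiles @ activities still reconstructs the counts. Contexts never
    observed in the cohort get probability 0. With reference profiles
    (rows = reference signatures over the same 96 contexts) each extracted
    signature is annotated with its cosine-nearest reference.
    """
    V = counts96.to_numpy(dtype=float).T  # 96 x samples
    if (V < 0).any():
        raise ValueError("mutation counts must be non-negative")
    if V.sum() == 0:
        raise ValueError("all-zero mutation matrix")
    n_samples = V.shape[1]
    if not 1 <= k <= min(96, n_samples):
        raise ValueError(f"k={k} out of range for {n_samples} samples")
    seen = V.sum(axis=1) > 0
    fac = nmf_factorize(V[seen], k, seed=seed, max_iter=max_iter, tol=tol)
    W = np.zeros((96, k))
    W[seen] = fac.W
    H = fac.H
    totals = W.sum(axis=0)
    totals[totals == 0] = 1.0
    profiles = (W / totals).T  # k x 96
    contributions = (H * totals[:, None]).T  # samples x k

    names = [f"Sig{i + 1}" for i in range(k)]
    prof_df = pd.DataFrame(profiles, index=names, columns=list(counts96.columns))
    contrib_df = pd.DataFrame(contributions, index=counts96.index, columns=names)

    annotation = None
    if reference_profiles is not None:
        ref = reference_profiles.reindex(columns=counts96.columns).to_numpy(dtype=float)
        rows = []
        for i, name in enumerate(names):
            sims = [_cosine(profiles[i], ref[j]) for j in range(ref.shape[0])]
            j = int(np.argmax(sims))
            rows.append((name, reference_profiles.index[j], float(sims[j])))
        annotation = pd.DataFrame(
            rows, columns=["signature", "best_match", "cosine"]
        ).set_index("signature")
    return MutSignatureResult(
        profiles=prof_df, contributions=contrib_df, annotation=annotation
    )
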