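"""Domain containers and plain-text readers shared by every pipeline stage.

All tabular inputs are one-header-row, tab-separated UTF-8. Expression
matrices are genes x samples with the gene symbol in the first column;
gene symbols are matched case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "RegulatorCatalog",
    "ClinicalTable",
    "MafTable",
    "MAF_NONSYNONYMOUS",
    "MAF_SILENT",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "read_maf",
    "load_regulator_catalog",
]


class ParseError(ValueError):
    """A malformed cell or line in a text input, located for the user."""


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with an explicit measurement scale.

    ``scale`` is ``"linear"`` (FPKM/TPM-like, non-negative) or ``"log2"``
    (microarray-like). Downstream stages check the scale they need instead
    of guessing from the values.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}; use 'linear' or 'log2'")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (values < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` that are present, preserving request order."""
        present = [g for g in genes if g in self.data.index]
        if not present:
            raise KeyError("none of the requested genes are present")
        return ExpressionMatrix(self.data.loc[present].copy(), scale=self.scale)

    def to_log2(self) -> "ExpressionMatrix":
        """log2(x+1) transform; identity when already on log2 scale."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), scale="log2")


def read_expression_matrix(path, scale_hint: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples TSV; first column gene symbols, header samples.

    Duplicated gene symbols are collapsed by the per-gene maximum (standard
    microarray convention: keep the strongest probe). Non-numeric cells and
    duplicated sample ids are hard errors naming the offending location.
    """
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    names = [h.strip() for h in header[1:]]
    seen_dups = sorted({n for n in names if names.count(n) > 1})
    if seen_dups:
        raise ParseError(f"duplicated sample ids in header: {seen_dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicated sample ids in header: {dups}")
    converted: dict[str, pd.Series] = {}
    for col in raw.columns:
        try:
            # python float() parsing is correctly rounded, unlike the
            # pandas fast path, so write->read round-trips bit-exactly
            converted[col] = raw[col].astype(float)
        except (ValueError, TypeError):
            for gene, value in raw[col].items():
                try:
                    float(value)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"non-numeric value {value!r} at gene {gene!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
    numeric = pd.DataFrame(converted, index=raw.index)
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        col = numeric.columns[numeric.loc[gene].isna()][0]
        raise ParseError(f"missing value at gene {gene!r}, sample {col!r}")
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).max()
    return ExpressionMatrix(numeric, scale=scale_hint)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "gene"
    # shortest round-trip float representation, so write->read is bit-exact
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set metadata (e.g. IPS class/weight)."""

    sets: dict[str, list[str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            self.sets[name] = deduped

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, members; tab-separated)."""
    sets: dict[str, list[str]] = {}
    meta: dict[str, dict] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0].strip(), fields[1]
            members = [g.strip() for g in fields[2:] if g.strip()]
            if name in sets:
                raise ParseError(f"line {lineno}: duplicated set name {name!r}")
            if not members:
                raise ParseError(f"line {lineno}: set {name!r} has no members")
            sets[name] = members
            meta[name] = {"description": desc}
    return GeneSetCollection(sets, meta)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.sets.items():
            desc = collection.metadata.get(name, {}).get("description", "na")
            handle.write("\t".join([name, str(desc), *members]) + "\n")


# ---------------------------------------------------------------------------
# Regulator catalog

_WRITERS = ("CBLL1", "KIAA1429", "METTL14", "METTL3", "RBM15", "RBM15B", "WTAP", "ZC3H13")
_ERASERS = ("ALKBH5", "FTO")
_READERS = (
    "ELAVL1", "FMR1", "HNRNPA2B1", "HNRNPC", "IGF2BP1", "IGF2BP2", "IGF2BP3",
    "LRPPRC", "YTHDC1", "YTHDC2", "YTHDF1", "YTHDF2", "YTHDF3",
)


@dataclass(frozen=True)
class RegulatorCatalog:
    """The 23 curated m6A regulators partitioned into writers/erasers/readers."""

    roles: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.roles)

    def symbols(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.roles)
        if role not in ("writer", "eraser", "reader"):
            raise ValueError(f"unknown role {role!r}")
        return [g for g, r in self.roles.items() if r == role]


def load_regulator_catalog() -> RegulatorCatalog:
    """The curated m6A machinery: 8 writers, 2 erasers, 13 readers."""
    roles: dict[str, str] = {}
    roles.update({g: "writer" for g in _WRITERS})
    roles.update({g: "eraser" for g in _ERASERS})
    roles.update({g: "reader" for g in _READERS})
    assert len(roles) == 23
    return RegulatorCatalog(roles)


# ---------------------------------------------------------------------------
# Clinical


@dataclass
class ClinicalTable:
    """Per-sample follow-up: time (months, > 0), event in {0,1}, covariates."""

    data: pd.DataFrame  # index sample_id; columns time, event, covariates
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("clinical table needs 'time' and 'event' columns")
        if self.data.index.duplicated().any():
            raise ValueError("duplicated sample ids in clinical table")
        times = self.data["time"].to_numpy(dtype=float)
        if (times <= 0).any() or not np.isfinite(times).all():
            raise ValueError("follow-up times must be finite and > 0")
        events = self.data["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def subset(self, samples: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[samples].copy(), time_unit=self.time_unit)


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# MAF

#: Variant classes counted as nonsynonymous for tumor mutation load.
MAF_NONSYNONYMOUS = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Splice_Site",
    }
)
MAF_SILENT = frozenset({"Silent", "Synonymous"})

#: Controlled vocabulary accepted without a flag.
MAF_KNOWN_CLASSES = MAF_NONSYNONYMOUS | MAF_SILENT | frozenset(
    {"3'UTR", "5'UTR", "Intron", "IGR", "RNA", "Nonstop_Mutation", "Translation_Start_Site"}
)

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


@dataclass
class MafTable:
    """Somatic variant records; minimal 3-column MAF dialect.

    Rows whose classification falls outside the controlled vocabulary are
    retained with ``known_class == False`` so downstream counts can skip
    them with a warning instead of silently dropping data.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _MAF_REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"MAF table is missing mandatory column {col!r}")
        if "known_class" not in self.data.columns:
            self.data = self.data.copy()
            self.data["known_class"] = self.data["Variant_Classification"].isin(
                MAF_KNOWN_CLASSES
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["Tumor_Sample_Barcode"].unique())


def read_maf(path) -> MafTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise ParseError(f"MAF file is missing mandatory column {col!r}")
    maf = MafTable(df)
    unknown = maf.data.loc[~maf.data["known_class"], "Variant_Classification"].unique()
    if len(unknown):
        warnings.warn(
            f"unrecognized variant classifications retained but flagged: {sorted(unknown)}",
            stacklevel=2,
        )
    return maf


def write_maf(maf: MafTable, path) -> None:
    cols = [c for c in maf.data.columns if c != "known_class"]
    maf.data[cols].to_csv(path, sep="\t", index=False)
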