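"""Readers, writers and domain containers for the EV proteome pipeline.

All tabular formats are plain TSV (UTF-8, ``.`` decimal).  Peptide tables
follow the MaxQuant LFQ dialect: one row per peptide, a gene-symbol protein
column, one intensity column per sample, and ``0`` or blank meaning *not
detected* (left-censored), never "measured as zero".  Gene sets use the GMT
layout; flat gene lists are one upper-cased symbol per line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Subtype",
    "Scale",
    "PeptideTable",
    "SampleDesign",
    "SignatureCollection",
    "ProteinMatrix",
    "RunConfig",
    "read_peptide_table",
    "write_peptide_table",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_protein_matrix",
    "write_protein_matrix",
]


class Subtype(str, Enum):
    """Prostate cancer molecular subtype labels used throughout the pipeline."""

    AR_POS = "AR_POS"
    AR_NEG_NE_POS = "AR_NEG_NE_POS"
    AR_NEG_NE_NEG = "AR_NEG_NE_NEG"
    PATIENT = "PATIENT"
    UNKNOWN = "UNKNOWN"


#: The three cell-line subtypes, in the fixed reporting order
#: (AR+ adenocarcinoma, neuroendocrine, double negative).
CELL_LINE_SUBTYPES = (Subtype.AR_POS, Subtype.AR_NEG_NE_POS, Subtype.AR_NEG_NE_NEG)


class Scale(str, Enum):
    """Scale tag carried by every protein matrix so stages cannot be mis-chained."""

    LINEAR = "LINEAR"
    LOG2 = "LOG2"
    GLOG = "GLOG"


@dataclass
class SampleDesign:
    """Sample annotation: one row per intensity column of a peptide table."""

    table: pd.DataFrame  # columns: sample_id, cell_line, subtype, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "cell_line", "subtype", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        pair = self.table[["cell_line", "replicate"]]
        if pair.duplicated().any():
            raise ValueError("duplicate (cell_line, replicate) in design")
        self.table = self.table.assign(
            subtype=[Subtype(s) for s in self.table["subtype"]]
        ).reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subtype_of(self, sample_id: str) -> Subtype:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return Subtype(row["subtype"].iloc[0])

    def samples_of(self, subtype: Subtype | str) -> list[str]:
        subtype = Subtype(subtype)
        mask = self.table["subtype"] == subtype
        return list(self.table.loc[mask, "sample_id"])

    def cell_line_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["cell_line"].iloc[0])


@dataclass
class PeptideTable:
    """Peptide-level LFQ intensities with an explicit detection mask.

    ``intensities`` holds linear-scale values (imputed cells are filled in by
    the preprocessing stage); ``detected`` records which cells were observed
    before any imputation, so downstream detection calls always refer to real
    measurements.
    """

    protein_ids: pd.Series  # index: peptide_id -> gene symbol
    intensities: pd.DataFrame  # peptide x sample, linear scale
    detected: pd.DataFrame  # peptide x sample, bool

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.protein_ids.index):
            raise ValueError("intensities and protein_ids indices differ")
        if not self.intensities.index.equals(self.detected.index):
            raise ValueError("intensities and detected indices differ")
        if list(self.intensities.columns) != list(self.detected.columns):
            raise ValueError("intensities and detected columns differ")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        vals = self.intensities.to_numpy()
        det = self.detected.to_numpy()
        if np.any(vals[det] <= 0):
            raise ValueError("detected intensities must be positive")

    @property
    def peptide_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def n_missing(self) -> int:
        return int((~self.detected.to_numpy()).sum())

    def copy(self) -> "PeptideTable":
        return PeptideTable(
            self.protein_ids.copy(), self.intensities.copy(), self.detected.copy()
        )


@dataclass
class SignatureCollection:
    """Named gene sets, optionally with a reference expression profile.

    The reference profile is only meaningful for correlation-style scores
    (the neuroendocrine score correlates each sample against a published
    NEPC meta-profile); it maps gene symbol -> reference level.
    """

    sets: dict[str, list[str]]
    reference_profile: pd.Series | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate genes within set {name!r}")
            if len(genes) < 2:
                raise ValueError(f"set {name!r} has fewer than 2 genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ProteinMatrix:
    """Protein x sample matrix with an explicit scale tag.

    ``n_peptides`` records how many peptides backed each protein after the
    minimum-peptide filter; it is carried so reports can audit the filter.
    """

    values: pd.DataFrame  # protein x sample
    scale: Scale
    n_peptides: pd.Series | None = None

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.scale is Scale.LINEAR and (self.values.to_numpy() <= 0).any():
            raise ValueError("LINEAR-scale matrix must be strictly positive")
        if self.n_peptides is not None and not self.n_peptides.index.equals(
            self.values.index
        ):
            raise ValueError("n_peptides index does not match matrix rows")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RunConfig:
    """Tunable knobs of the pipeline with the study defaults.

    impute_quantile
        Centre of the imputation normal, as a quantile of all detected log2
        intensities (left-censoring assumption: missing = low).
    min_peptides
        Minimum peptides per protein for quantification and detection calls.
    q_threshold
        FDR threshold for volcano significance.
    n_permutations / gsea_weight
        Gene-set permutation count and the weighted-statistic exponent.
    """

    seed: int = 0
    impute_quantile: float = 0.01
    min_peptides: int = 2
    q_threshold: float = 0.05
    n_permutations: int = 100
    gsea_weight: float = 1.0
    impute_per_sample: bool = False  # global quantile is the default reading
    vsn_trim: float = 0.25
    ne_correlation: str = "pearson"  # or "spearman"
    qvalue_method: str = "bh"  # or "storey"
    gsea_fdr: str = "nes"  # sign-stratified NES pooling, or "bh"
    patient_score: str = "zscore"  # or "raw"

    def __post_init__(self) -> None:
        if not 0 < self.impute_quantile < 1:
            raise ValueError("impute_quantile must be in (0, 1)")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.vsn_trim < 0.5:
            raise ValueError("vsn_trim must be in [0, 0.5)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# peptide table / design IO


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table.copy()
    out["subtype"] = [Subtype(s).value for s in out["subtype"]]
    out.to_csv(path, sep="\t", index=False)


def read_peptide_table(path: str | Path, design: SampleDesign) -> PeptideTable:
    """Parse a peptide TSV; zeros and blanks become ``detected=False``.

    The intensity columns are taken in *design* order, so files whose columns
    are permuted parse to the same table.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_id": str})
    for col in ("peptide_id", "protein_id"):
        if col not in df.columns:
            raise ValueError(f"peptide table missing {col!r} column")
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"peptide table missing sample columns: {missing}")
    if df["peptide_id"].duplicated().any():
        raise ValueError("duplicate peptide_id rows")

    df = df.set_index("peptide_id")
    protein_ids = df["protein_id"].str.upper()
    inten = df[design.sample_ids].apply(pd.to_numeric, errors="raise")
    if (inten.fillna(0).to_numpy() < 0).any():
        raise ValueError("negative intensity in peptide table")
    detected = inten.notna() & (inten != 0)
    inten = inten.fillna(0.0).astype(float)
    table = PeptideTable(protein_ids, inten, detected.astype(bool))
    logger.info(
        "read %d peptides x %d samples (%d censored cells) from %s",
        inten.shape[0], inten.shape[1], table.n_missing(), path,
    )
    return table


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    out = table.intensities.where(table.detected, 0.0)
    out = out.copy()
    out.insert(0, "protein_id", table.protein_ids)
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> SignatureCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``"""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        genes: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            g = g.strip().upper()
            if not g:
                continue
            if g in seen:
                logger.warning("%s:%d: duplicate gene %s in set %s", path, lineno, g, name)
                continue
            seen.add(g)
            genes.append(g)
        sets[name] = genes
    return SignatureCollection(sets)


def write_gmt(collection: SignatureCollection, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path, name: str = "gene_list") -> SignatureCollection:
    """Read a flat gene list (one symbol per line) as a single signature."""
    genes: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        g = line.strip().upper()
        if not g or g in seen:
            continue
        seen.add(g)
        genes.append(g)
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    return SignatureCollection({name: genes})


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# protein matrices


def read_protein_matrix(path: str | Path, scale: Scale | str) -> ProteinMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_pep = None
    if "n_peptides" in df.columns:
        n_pep = df.pop("n_peptides").astype(int)
    df.index = df.index.astype(str).str.upper()
    return ProteinMatrix(df.astype(float), Scale(scale), n_pep)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    if matrix.n_peptides is not None:
        out.insert(0, "n_peptides", matrix.n_peptides)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
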