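"""Readers, writers and expression preprocessing.

File dialects handled here:

* GMT (Broad dialect) for gene sets: one set per line,
  ``name<TAB>description<TAB>gene1<TAB>gene2...``.
* Tab-separated expression matrices: first column gene identifiers,
  header row of sample identifiers, empty cells or ``NA`` mark missing
  values.
* MAF-like tab-separated mutation tables with the columns
  ``Tumor_Sample_Barcode``, ``Hugo_Symbol``, ``Variant_Classification``,
  ``t_alt_count``, ``t_ref_count`` (renameable via a column map).
* Clinical tab-separated tables with columns ``sample``, ``time``,
  ``event``.

Expression preprocessing follows the analysis convention: FPKM is
rescaled to TPM per sample, genes with more than ``max_missing_frac``
missing values are dropped, surviving missing entries are imputed to 0,
and the matrix is log2(x + 1) transformed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ithimmune")


class Units(str, Enum):
    """Unit state of an expression matrix."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2TPM = "LOG2TPM"


class FormatError(ValueError):
    """A file violated the expected dialect."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with an explicit unit state.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
        May contain NaN (missing) entries until preprocessing.
    unit_state
        One of :class:`Units`. Non-log states must be non-negative.
    """

    values: pd.DataFrame
    unit_state: Units

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicated gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicated sample identifiers: {dups}")
        if self.unit_state in (Units.FPKM, Units.TPM):
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise FormatError(
                    f"negative values not allowed in {self.unit_state.value} units"
                )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape


def read_expression(path, unit_state: Units = Units.FPKM) -> ExpressionMatrix:
    """Read a tab-separated gene-by-sample matrix.

    Empty cells and ``NA`` are kept as missing values; the unit state is
    supplied by the caller (configuration), never guessed from content.
    Ragged rows and duplicated gene identifiers raise :class:`FormatError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    n_fields = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_fields:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {n_fields}"
            )
    sample_ids = header[1:]
    gene_ids = [r[0] for r in rows[1:]]
    data = np.full((len(gene_ids), len(sample_ids)), np.nan)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            data[i, j] = float(cell)
    df = pd.DataFrame(data, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=df, unit_state=unit_state)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write an expression matrix as a tab-separated table (NaN as ``NA``)."""
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM to TPM: per sample, value / column sum * 1e6.

    Missing values are ignored in the column sum and stay missing.
    A sample whose (non-missing) values sum to zero is an error.
    """
    if m.unit_state is not Units.FPKM:
        raise ValueError(f"expected FPKM input, got {m.unit_state.value}")
    arr = m.values.to_numpy(dtype=float)
    colsum = np.nansum(arr, axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        bad = [m.sample_ids[j] for j in zero]
        raise ValueError(f"sample(s) with zero total expression: {bad}")
    tpm = arr / colsum * 1e6
    return ExpressionMatrix(
        values=pd.DataFrame(tpm, index=m.values.index, columns=m.values.columns),
        unit_state=Units.TPM,
    )


def preprocess_expression(
    m: ExpressionMatrix, max_missing_frac: float = 0.5
) -> ExpressionMatrix:
    """Filter high-missingness genes, impute and log-transform TPM.

    Genes missing in strictly more than ``max_missing_frac`` of samples
    are removed; remaining missing entries are imputed to 0; values become
    log2(TPM + 1).
    """
    if m.unit_state is not Units.TPM:
        raise ValueError(f"expected TPM input, got {m.unit_state.value}")
    arr = m.values.to_numpy(dtype=float)
    miss_frac = np.isnan(arr).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    if not keep.any():
        raise ValueError("all genes removed by the missing-value filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("preprocess_expression: dropped %d genes (> %.0f%% missing)",
                    n_dropped, 100 * max_missing_frac)
    sub = arr[keep]
    sub = np.where(np.isnan(sub), 0.0, sub)
    out = np.log2(sub + 1.0)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index[keep], columns=m.values.columns),
        unit_state=Units.LOG2TPM,
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, ordered gene lists (pathways or cell-marker sets)."""

    sets: Dict[str, List[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> List[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def gene_multiplicity(self) -> Dict[str, int]:
        """Number of sets each gene belongs to, across the collection."""
        mult: Dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                mult[g] = mult.get(g, 0) + 1
        return mult


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Within-set duplicate genes are dropped (first occurrence wins) with a
    logged warning; a duplicated set name or a line with fewer than three
    fields is an error.
    """
    path = Path(path)
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes: List[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s: set %s: duplicate gene %s dropped",
                                   path.name, name, g)
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Mutation table (MAF-like)
# ---------------------------------------------------------------------------

MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Classification",
    "alt_count": "t_alt_count",
    "ref_count": "t_ref_count",
}


@dataclass
class MutationTable:
    """Per-sample somatic variant records with variant allele fractions.

    ``records`` holds columns sample, gene, variant_class, alt_count,
    ref_count and vaf; vaf is derived as alt/(alt+ref) when counts are
    present and total coverage is positive.
    """

    records: pd.DataFrame

    REQUIRED = ("sample", "gene", "variant_class", "alt_count", "ref_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        rec = self.records
        if "vaf" not in rec.columns:
            total = rec["alt_count"].astype(float) + rec["ref_count"].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                vaf = rec["alt_count"].astype(float) / total
            vaf[total <= 0] = np.nan
            self.records = rec.assign(vaf=vaf)
        bad = self.records["vaf"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise FormatError("vaf values outside [0, 1]")

    @property
    def sample_ids(self) -> List[str]:
        return sorted(self.records["sample"].unique())

    def vafs_for(self, sample: str) -> np.ndarray:
        sub = self.records.loc[self.records["sample"] == sample, "vaf"]
        return sub.dropna().to_numpy(dtype=float)


def read_mutations(path, column_map: Optional[Mapping[str, str]] = None) -> MutationTable:
    """Read a MAF-like tab-separated mutation table.

    ``column_map`` maps internal names (``sample``, ``gene``,
    ``variant_class``, ``alt_count``, ``ref_count``, optionally ``vaf``)
    to the file's column headers; defaults to the standard MAF headers.
    """
    cmap = dict(MAF_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    return MutationTable(records=df)


def write_mutations(muts: MutationTable, path) -> None:
    out = muts.records.rename(columns=MAF_COLUMNS)
    cols = [MAF_COLUMNS[c] for c in MutationTable.REQUIRED]
    out[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Survival records: sample, follow-up time, event indicator (0/1)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample", "time", "event"):
            if col not in self.records.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        rec = self.records
        if rec["sample"].duplicated().any():
            dups = sorted(rec.loc[rec["sample"].duplicated(), "sample"])
            raise FormatError(f"duplicated clinical sample ids: {dups}")
        if (rec["time"].astype(float) < 0).any():
            raise FormatError("negative follow-up times")
        if not rec["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.records["sample"])


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(records=df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.records.to_csv(path, sep="\t", index=False)
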