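"""Readers, writers and validated domain containers.

Every stage of the analysis consumes one of four containers defined here:

``ExpressionMatrix``
    a dense log2-scale gene x sample grid,
``GeneSet`` / ``RegulatorPanel``
    named gene lists (signature membership, or the m6A writer/eraser/reader
    panel),
``ClinicalTable``
    per-sample progression-free-survival records with optional staging,
    Gleason score, PSA, immune-subtype and RECIST response fields.

Loaders validate on entry so downstream code can assume complete, finite,
uniquely-indexed data.  Joins between clinical and expression data are always
by sample ID, never by position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("writer", "eraser", "reader")
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")

#: The 24-gene m6A regulator panel: 8 writers, 2 erasers, 14 readers.
DEFAULT_REGULATORS: tuple[tuple[str, str], ...] = (
    ("WTAP", "writer"),
    ("KIAA1429", "writer"),
    ("CBLL1", "writer"),
    ("RBM15", "writer"),
    ("RBM15B", "writer"),
    ("ZC3H13", "writer"),
    ("METTL3", "writer"),
    ("METTL14", "writer"),
    ("FTO", "eraser"),
    ("ALKBH5", "eraser"),
    ("ELAVL1", "reader"),
    ("FMR1", "reader"),
    ("HNRNPA2B1", "reader"),
    ("HNRNPC", "reader"),
    ("IGF2BP1", "reader"),
    ("IGF2BP2", "reader"),
    ("IGF2BP3", "reader"),
    ("LRPPRC", "reader"),
    ("RBMX", "reader"),
    ("YTHDC1", "reader"),
    ("YTHDC2", "reader"),
    ("YTHDF1", "reader"),
    ("YTHDF2", "reader"),
    ("YTHDF3", "reader"),
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass
class ExpressionMatrix:
    """Dense log2-scale expression, genes as rows, samples as columns."""

    data: pd.DataFrame  # index = gene IDs, columns = sample IDs
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            raise ValidationError("duplicate gene IDs in expression matrix")
        if cols.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("non-finite values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict_genes(self, genes: Iterable[str], *, warn_missing: bool = True) -> "ExpressionMatrix":
        """Subset to ``genes`` (order of the request, missing genes skipped)."""
        wanted = [g for g in genes]
        present = [g for g in wanted if g in self.data.index]
        missing = sorted(set(wanted) - set(present))
        if missing and warn_missing:
            logger.warning("%d requested genes absent from matrix: %s",
                           len(missing), ", ".join(missing[:10]))
        return ExpressionMatrix(self.data.loc[present])

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        absent = [s for s in samples if s not in self.data.columns]
        if absent:
            raise ValidationError(f"samples absent from matrix: {absent[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class RegulatorPanel:
    """Gene panel with writer/eraser/reader roles."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_REGULATORS

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate genes in regulator panel")
        bad = {r for _, r in self.entries} - set(VALID_ROLES)
        if bad:
            raise ValidationError(f"invalid regulator roles: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.entries if r == role]


@dataclass
class ClinicalTable:
    """Per-sample clinical records indexed by sample ID.

    Required columns: ``pfs_time`` (days, >= 0) and ``pfs_event`` (0/1).
    Optional: ``t_stage``, ``n_stage``, ``m_stage``, ``gleason``, ``psa``,
    ``immune_subtype``, ``response`` (CR/PR/SD/PD or NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("pfs_time", "pfs_event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in clinical table")
        if (df["pfs_time"] < 0).any():
            raise ValidationError("negative pfs_time")
        if not df["pfs_event"].isin((0, 1)).all():
            raise ValidationError("pfs_event must be 0 or 1")
        if "response" in df.columns:
            bad = df["response"].dropna()[~df["response"].dropna().isin(RESPONSE_CATEGORIES)]
            if len(bad):
                raise ValidationError(f"invalid response categories: {sorted(set(bad))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def join_expression(self, expr: ExpressionMatrix) -> tuple["ClinicalTable", ExpressionMatrix]:
        """Intersect with an expression matrix by sample ID (never position)."""
        common = [s for s in expr.sample_ids if s in self.data.index]
        n_lost = (len(self.data) - len(common)) + (expr.n_samples - len(common))
        if n_lost:
            logger.info("sample-ID join dropped %d unmatched records; cohort size %d",
                        n_lost, len(common))
        if not common:
            raise ValidationError("no overlapping samples between clinical and expression data")
        return ClinicalTable(self.data.loc[common]), expr.restrict_samples(common)


# ---------------------------------------------------------------------------
# expression I/O

def read_expression(path, dialect: str = "tsv", log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes x samples table (first column gene IDs, header sample IDs).

    Duplicate gene rows are collapsed by mean (a warning is logged); duplicate
    sample columns are an error; rows containing missing values are dropped and
    counted in ``n_dropped_missing``.  ``log2_transform`` applies log2(x+1) for
    matrices supplied on the raw scale.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = [s for i, s in enumerate(header) if s in header[:i]]
    if dups:
        raise ValidationError(f"duplicate sample IDs: {sorted(set(dups))[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(non_numeric):
        for col in non_numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric value at row {bad[0]!r}, column {col!r}")
            df[col] = coerced
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene rows with missing values", n_missing)
        df = df.dropna(axis=0)
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, n_dropped_missing=n_missing)


def write_expression(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    expr.data.to_csv(path, sep=sep, index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT I/O

def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate members within a line are deduplicated; a line with fewer than
    three fields raises :class:`FormatError` with its line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, description, *genes = fields
            members = frozenset(g for g in genes if g)
            if len(members) < len([g for g in genes if g]):
                logger.debug("GMT line %d (%s): duplicate members deduplicated", lineno, name)
            sets.append(GeneSet(name=name, description=description, members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_panel_gmt(path) -> RegulatorPanel:
    """Read a regulator panel stored as one GMT line per role (writer/eraser/reader)."""
    sets = read_gmt(path)
    entries: list[tuple[str, str]] = []
    for gs in sets:
        role = gs.name.lower().rstrip("s")
        if role not in VALID_ROLES:
            raise ValidationError(f"panel GMT set name {gs.name!r} is not a regulator role")
        entries.extend((g, role) for g in sorted(gs.members))
    return RegulatorPanel(tuple(entries))


def write_panel_gmt(panel: RegulatorPanel, path) -> None:
    sets = [GeneSet(role + "s", "m6A regulator role", frozenset(panel.genes_with_role(role)))
            for role in VALID_ROLES if panel.genes_with_role(role)]
    write_gmt(sets, path)


# ---------------------------------------------------------------------------
# clinical I/O

def read_clinical(path, dialect: str = "csv") -> ClinicalTable:
    """Read a clinical CSV/TSV keyed by ``sample_id``.

    Unknown response strings are mapped to missing with a warning; negative
    survival times are a validation error.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise FormatError("clinical table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if "response" in df.columns:
        resp = df["response"].astype("object")
        unknown = resp.notna() & ~resp.isin(RESPONSE_CATEGORIES)
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} unknown response labels mapped to missing "
                f"({sorted(set(resp[unknown]))})", stacklevel=2)
            resp[unknown] = np.nan
        df["response"] = resp
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path, dialect: str = "csv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    clin.data.to_csv(path, sep=sep, index_label="sample_id")
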