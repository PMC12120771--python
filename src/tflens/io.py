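"""Readers and writers for expression matrices, TF catalogs, gene sets and labels.

All tabular output is plain TSV with ``#``-prefixed header comments recording
the parameters of the run, so results stay auditable. Gene symbols are
canonicalised (uppercase, stripped) on input; hyphenated symbols such as
``NKX3-1`` are kept verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TFCatalog",
    "GeneSet",
    "MatrixReadReport",
    "normalize_symbol",
    "read_expression_matrix",
    "write_matrix",
    "read_catalog",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "subset_by_catalog",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped, uppercased, hyphens kept."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix of non-negative values.

    ``values`` is a pandas DataFrame with normalised gene symbols in the index
    and unique sample identifiers in the columns. ``unit_tag`` records the
    expression units (normalized counts / FPKM / TPM / array intensity);
    ``log_transformed`` marks matrices already on a log scale, for which the
    non-negativity requirement is lifted.
    """

    values: pd.DataFrame
    unit_tag: str = "unspecified"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.values
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after normalization: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if not self.log_transformed and (arr < 0).any():
            raise ValueError("negative values in a non-log matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TFCatalog:
    """An ordered catalog of unique transcription-factor gene symbols."""

    symbols: list[str]
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        normed = [normalize_symbol(s) for s in self.symbols]
        if any(not s for s in normed):
            raise ValueError("catalog contains empty symbols")
        seen: set[str] = set()
        unique = []
        for s in normed:
            if s not in seen:
                seen.add(s)
                unique.append(s)
        if len(unique) < len(normed):
            logger.warning(
                "catalog %s: dropped %d duplicate symbols",
                self.source_label,
                len(normed) - len(unique),
            )
        self.symbols = unique

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class GeneSet:
    """A named set of gene symbols (GMT record)."""

    name: str
    description: str = ""
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        normed = [normalize_symbol(m) for m in self.members]
        seen: set[str] = set()
        self.members = [m for m in normed if not (m in seen or seen.add(m))]
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MatrixReadReport:
    n_genes: int
    n_samples: int
    n_duplicates_collapsed: int


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    unit_tag: str = "unspecified",
    log_transformed: bool = False,
    transpose: bool = False,
) -> tuple[ExpressionMatrix, MatrixReadReport]:
    """Read a gene x sample matrix (first column gene ids, header sample ids).

    Duplicate gene rows (after symbol normalisation) are collapsed by
    arithmetic mean with a logged warning. Returns the matrix and a read
    report with gene/sample/duplicate counts.
    """
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}; expected tsv or csv")
    # pandas silently renames duplicate header fields; check the raw header
    with open(path) as fh:
        header = next(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), ""
        )
    raw_ids = [c.strip() for c in header.rstrip("\n").split(_SEPS[dialect])[1:]]
    dup_ids = sorted({c for c in raw_ids if raw_ids.count(c) > 1})
    if dup_ids and not transpose:
        raise ValueError(f"{path}: duplicate sample ids {dup_ids}")
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0, comment="#")
    if transpose:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    # locate non-numeric cells precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"{path}: non-numeric value {df.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {gene!r}")
    numeric.index = [normalize_symbol(g) for g in numeric.index]
    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        logger.warning("%s: collapsed %d duplicate gene rows by mean", path, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    matrix = ExpressionMatrix(numeric, unit_tag=unit_tag, log_transformed=log_transformed)
    report = MatrixReadReport(matrix.shape[0], matrix.shape[1], n_dup)
    return matrix, report


def write_matrix(
    df: pd.DataFrame,
    path: str | Path,
    dialect: str = "tsv",
    header_comments: Sequence[str] = (),
) -> None:
    """Write a gene x sample table as TSV/CSV with optional ``#`` header lines."""
    sep = _SEPS[dialect]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index_label="gene")


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path, source_label: str | None = None) -> TFCatalog:
    """Read a plain one-symbol-per-line gene list; ``#`` comments and blank
    lines are skipped; duplicates dropped with a warning."""
    symbols: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    if not symbols:
        raise ValueError(f"{path}: catalog file contains no symbols")
    return TFCatalog(symbols, source_label=source_label or str(path))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            name, description, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=description, members=members))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# phenotype labels
# ---------------------------------------------------------------------------

def read_labels(
    path: str | Path,
    dialect: str = "two_column",
    sample_ids: Sequence[str] | None = None,
) -> dict[str, str]:
    """Read sample->group labels from CLS or a two-column TSV.

    For CLS, ``sample_ids`` supplies the sample order of the matrix the labels
    refer to (CLS files carry no sample names). The returned mapping covers
    exactly those samples.
    """
    if dialect == "cls":
        return _read_cls(path, sample_ids)
    if dialect == "two_column":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
                sample, group = fields[0].strip(), fields[1].strip()
                if sample in mapping:
                    raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
                mapping[sample] = group
        if not mapping:
            raise ValueError(f"{path}: no labels found")
        return mapping
    raise ValueError(f"unknown label dialect {dialect!r}")


def _read_cls(path: str | Path, sample_ids: Sequence[str] | None) -> dict[str, str]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS needs header, class-name line and body")
    header = lines[0].split()
    if len(header) < 2:
        raise ValueError(f"{path}: malformed CLS header {lines[0]!r}")
    n_samples, n_classes = int(header[0]), int(header[1])
    name_line = lines[1].split()
    if not name_line or name_line[0] != "#":
        raise ValueError(f"{path}: second CLS line must start with '#'")
    class_names = name_line[1:]
    if len(class_names) != n_classes:
        raise ValueError(
            f"{path}: header declares {n_classes} classes, "
            f"{len(class_names)} names listed"
        )
    body = lines[2].split()
    if len(body) != n_samples:
        raise ValueError(
            f"{path}: header declares {n_samples} samples, {len(body)} listed"
        )
    # body entries are class names or 0-based indices
    groups: list[str] = []
    for tok in body:
        if tok in class_names:
            groups.append(tok)
        elif tok.isdigit() and int(tok) < n_classes:
            groups.append(class_names[int(tok)])
        else:
            raise ValueError(f"{path}: unknown class token {tok!r}")
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError(
            f"{path}: CLS declares {n_samples} samples but matrix has "
            f"{len(sample_ids)}"
        )
    return dict(zip(sample_ids, groups))


# ---------------------------------------------------------------------------
# catalog subsetting
# ---------------------------------------------------------------------------

def subset_by_catalog(
    matrix: ExpressionMatrix, catalog: TFCatalog
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to the catalog genes, in catalog order.

    Returns the subset matrix and the list of catalog symbols absent from it.
    """
    index = set(matrix.values.index)
    present = [s for s in catalog.symbols if s in index]
    missing = [s for s in catalog.symbols if s not in index]
    if not present:
        raise ValueError("catalog disjoint from matrix: no catalog gene present")
    sub = ExpressionMatrix(
        matrix.values.loc[present],
        unit_tag=matrix.unit_tag,
        log_transformed=matrix.log_transformed,
    )
    return sub, missing


def labels_to_frame(mapping: Mapping[str, str]) -> pd.Series:
    """Sample->group mapping as a pandas Series (sample id index)."""
    return pd.Series(dict(mapping), name="group")
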