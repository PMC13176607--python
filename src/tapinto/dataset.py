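"""Expression-matrix data model and tabular I/O.

The central container is :class:`ExpressionDataset`: a dense, non-negative
genes × samples FPKM matrix together with a tumor/normal role per sample.
Matrices travel as TSV (default) or CSV with a ``gene_id`` header column;
roles travel as a two-column sidecar (``sample_id<TAB>role``) or an in-memory
mapping.  Candidate universes (e.g. membrane-protein gene lists) are plain
text, one symbol per line, ``#`` comments allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MatrixFormatError, MatrixValueError, RoleConfigError, InputError

TUMOR = "tumor"
NORMAL = "normal"
_VALID_ROLES = frozenset({TUMOR, NORMAL})


@dataclass
class ExpressionDataset:
    """Gene × sample non-negative expression matrix with sample roles.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.  All entries
        must be finite and >= 0; FPKM or any non-negative normalized unit.
    roles
        Series mapping every sample ID (in matrix column order) to
        ``"tumor"`` or ``"normal"``.  At least one tumor sample is required;
        normal samples may be absent, in which case fold changes are
        undefined downstream.
    """

    values: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate gene ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample ID {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            _raise_bad_cell(self.values)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValueError(
                f"invalid expression value {arr[i, j]!r} for gene "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.roles.index]
        if missing:
            raise RoleConfigError(f"samples missing from role map: {missing[:5]}")
        self.roles = self.roles.reindex(self.values.columns)
        unknown = set(self.roles.unique()) - _VALID_ROLES
        if unknown:
            raise RoleConfigError(
                f"unknown sample roles {sorted(unknown)!r}; expected tumor/normal"
            )
        if (self.roles == TUMOR).sum() < 1:
            raise RoleConfigError("dataset must contain at least one tumor sample")

    # -- identifiers ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == TUMOR])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == NORMAL])

    @property
    def n_tumor(self) -> int:
        return int((self.roles == TUMOR).sum())

    @property
    def n_normal(self) -> int:
        return int((self.roles == NORMAL).sum())

    # -- per-gene access --------------------------------------------------
    def tumor_values(self, gene_id: str) -> np.ndarray:
        """Tumor expression vector for ``gene_id`` in sample order."""
        return self._gene_row(gene_id)[self.roles.to_numpy() == TUMOR]

    def normal_values(self, gene_id: str) -> np.ndarray:
        """Adjacent-normal expression vector for ``gene_id`` in sample order."""
        return self._gene_row(gene_id)[self.roles.to_numpy() == NORMAL]

    def _gene_row(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise InputError(f"gene {gene_id!r} not in dataset")
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass
class GeneList:
    """A case-sensitive set of gene symbols used to subset candidate genes."""

    symbols: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.symbols = set(self.symbols)
        if not self.symbols:
            raise InputError("gene list is empty")


@dataclass
class SubsetResult:
    dataset: ExpressionDataset
    unmatched: list[str]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _raise_bad_cell(df: pd.DataFrame) -> None:
    # locate the first non-numeric cell for a precise error message
    for gene, row in df.iterrows():
        for sample, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                raise MatrixValueError(
                    f"non-numeric expression value {v!r} for gene {gene!r}, "
                    f"sample {sample!r}"
                ) from None
    raise MatrixValueError("matrix contains non-numeric values")


def read_roles(path: str | Path) -> pd.Series:
    """Read the two-column role sidecar (header ``sample_id<TAB>role``)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if list(df.columns[:2]) != ["sample_id", "role"]:
        raise RoleConfigError(
            f"role sidecar {path} must start with header 'sample_id\\trole', "
            f"got {list(df.columns[:2])!r}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise RoleConfigError(f"duplicate sample ID {dup!r} in role sidecar")
    return pd.Series(df["role"].to_numpy(), index=df["sample_id"].to_numpy())


def read_expression(
    path: str | Path,
    role_map: str | Path | Mapping[str, str] | pd.Series,
) -> ExpressionDataset:
    """Read an expression matrix plus its sample-role annotation.

    ``path`` must be a TSV/CSV whose header row holds sample IDs and whose
    first column (``gene_id``) holds gene IDs; row and column order are
    preserved.  ``role_map`` is either a sidecar file path or a
    sample -> role mapping covering every sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate gene ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixFormatError(f"duplicate sample ID {dup!r} in {path}")
    try:
        numeric = df.astype(float)
    except (TypeError, ValueError):
        _raise_bad_cell(df)
    numeric.index.name = None
    numeric.columns.name = None
    if isinstance(role_map, (str, Path)):
        roles = read_roles(role_map)
    elif isinstance(role_map, pd.Series):
        roles = role_map.astype(str)
    else:
        roles = pd.Series(dict(role_map), dtype=str)
    return ExpressionDataset(values=numeric, roles=roles)


def write_expression(
    ds: ExpressionDataset,
    path: str | Path,
    roles_path: str | Path | None = None,
) -> None:
    """Write the matrix (and optionally the role sidecar) back to disk.

    Values are written with shortest round-trip ``repr`` so that
    ``read_expression(write_expression(ds))`` is value-identical.
    """
    path = Path(path)
    ds.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")
    if roles_path is not None:
        roles_path = Path(roles_path)
        pd.DataFrame(
            {"sample_id": ds.roles.index, "role": ds.roles.to_numpy()}
        ).to_csv(roles_path, sep=_sep_for(roles_path), index=False)


def read_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list: one symbol per line, ``#`` comments."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GeneList(symbols=set(symbols))


def subset_genes(ds: ExpressionDataset, genes: GeneList) -> SubsetResult:
    """Row-subset ``ds`` to the symbols in ``genes``.

    Retained rows keep the dataset's original order and values; symbols with
    no match are reported in :attr:`SubsetResult.unmatched`.  An empty
    intersection is an error (the candidate universe would be void).
    """
    keep = [g for g in ds.gene_ids if g in genes.symbols]
    unmatched = sorted(genes.symbols - set(ds.gene_ids))
    if not keep:
        raise InputError(
            "no gene-list symbol matches the dataset; first unmatched: "
            f"{unmatched[:10]}"
        )
    sub = ExpressionDataset(values=ds.values.loc[keep], roles=ds.roles.copy())
    return SubsetResult(dataset=sub, unmatched=unmatched)
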