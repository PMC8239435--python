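"""Reading and writing single-cell expression data, metadata and gene lists.

Supported on-disk formats:

* Matrix-Market coordinate triplets in the CellRanger layout
  (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, genes as rows,
  1-based indices),
* dense CSV / TSV matrices with gene and barcode headers,
* TSV cell-metadata tables,
* plain-text gene lists (one symbol per line, ``#`` comments).

Counts are normalised with a median-library-size scaling followed by a
``log(1+x)`` transform.  This is a deliberately simple scheme; matrices
normalised externally (e.g. by pooled deconvolution) can be supplied
directly wherever a normalised layer is expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_signature",
    "normalize_counts",
]

_MTX_NAMES = ("matrix.mtx",)
_GENE_SIDECARS = ("genes.tsv", "features.tsv")
_BARCODE_SIDECARS = ("barcodes.tsv",)


@dataclass
class ExpressionMatrix:
    """A cells × genes expression matrix with identifier sidecars.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` array.  The ``counts`` layer holds
        non-negative integers (UMI counts); the ``normalized`` layer holds
        non-negative reals (log-transformed expression).
    gene_ids, cell_ids
        Ordered, duplicate-free gene symbols and cell barcodes.
    layer_tag
        Either ``"counts"`` or ``"normalized"``.
    """

    values: np.ndarray
    gene_ids: list[str] = field(repr=False)
    cell_ids: list[str] = field(repr=False)
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {kind} identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.layer_tag not in ("counts", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "counts" and not _is_integral(self.values):
            raise ValueError("counts layer must be integer-valued")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a cells × genes DataFrame view of the matrix."""
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def gene_index(self, symbols: Sequence[str]) -> list[int]:
        """Column indices for ``symbols`` present in the matrix (order kept)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return [lookup[s] for s in symbols if s in lookup]


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered set of gene symbols defining one programme axis."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def _is_integral(values: np.ndarray) -> bool:
    return bool(np.all(values == np.round(values)))


def _infer_layer(values: np.ndarray) -> str:
    return "counts" if _is_integral(values) else "normalized"


def _find_sidecar(directory: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"missing {what} sidecar next to matrix (looked for {', '.join(names)} in {directory})"
    )


def read_expression(
    path: str | Path,
    format: str | None = None,
    orientation: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX triplet or dense CSV/TSV.

    Parameters
    ----------
    path
        For ``mtx``: the ``matrix.mtx`` file or its directory (gene and
        barcode sidecar files must sit alongside).  For ``csv``/``tsv``: a
        dense matrix with the first column holding row identifiers.
    format
        ``mtx``, ``csv`` or ``tsv``; inferred from the file suffix when
        omitted (a directory implies ``mtx``).
    orientation
        ``cells_x_genes`` or ``genes_x_cells`` describing the on-disk
        layout.  Defaults to ``genes_x_cells`` for MTX (the CellRanger
        convention) and ``cells_x_genes`` for dense files.  The returned
        matrix is always cells × genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix in (".csv", ".tsv", ".txt"):
            format = "tsv" if path.suffix == ".tsv" else "csv"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    format = format.lower()
    if format == "mtx":
        orientation = orientation or "genes_x_cells"
        return _read_mtx(path, orientation)
    if format in ("csv", "tsv"):
        orientation = orientation or "cells_x_genes"
        return _read_dense(path, sep="," if format == "csv" else "\t", orientation=orientation)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path, orientation: str) -> ExpressionMatrix:
    if path.is_dir():
        directory = path
        mtx_path = _find_sidecar(directory, _MTX_NAMES, "matrix")
    else:
        directory, mtx_path = path.parent, path
    genes_path = _find_sidecar(directory, _GENE_SIDECARS, "gene")
    barcodes_path = _find_sidecar(directory, _BARCODE_SIDECARS, "barcode")
    matrix = scipy.io.mmread(mtx_path)
    values = np.asarray(
        matrix.toarray() if scipy.sparse.issparse(matrix) else matrix, dtype=float
    )
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if orientation == "genes_x_cells":
        values = values.T
    elif orientation != "cells_x_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(values, gene_ids=genes, cell_ids=barcodes, layer_tag=_infer_layer(values))


def _read_dense(path: Path, sep: str, orientation: str) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    rows = [str(r) for r in frame.index]
    cols = [str(c) for c in frame.columns]
    if orientation == "genes_x_cells":
        values, rows, cols = values.T, cols, rows
    elif orientation != "cells_x_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(values, gene_ids=cols, cell_ids=rows, layer_tag=_infer_layer(values))


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write a matrix as an MTX triplet directory or a dense CSV/TSV file.

    MTX output follows the CellRanger layout (genes as rows); dense output
    is written cells × genes.  Returns the written path (the directory for
    MTX, the file otherwise).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if (path.is_dir() or not path.suffix) else path.suffix.lstrip(".")
    format = format.lower()
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(matrix.values.T)
        field_kind = "integer" if matrix.layer_tag == "counts" else "real"
        if field_kind == "integer":
            sparse = sparse.astype(np.int64)
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field=field_kind)
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))
        return path
    if format in ("csv", "tsv"):
        frame = matrix.to_frame()
        if matrix.layer_tag == "counts":
            frame = frame.astype(np.int64)
        frame.to_csv(path, sep="," if format == "csv" else "\t")
        return path
    raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a TSV cell-metadata table (columns ``cell_id``, ``condition``, …)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in frame.columns or "condition" not in frame.columns:
        raise ValueError("metadata must contain 'cell_id' and 'condition' columns")
    if frame["cell_id"].duplicated().any():
        dupes = frame.loc[frame["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id rows in metadata: {dupes[:5]}")
    return frame


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metadata.to_csv(path, sep="\t", index=False)
    return path


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a gene list: one symbol per line, ``#`` lines are comments.

    Symbols are whitespace-stripped and matched case-sensitively downstream.
    Duplicates are removed (first occurrence kept) with a warning.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    dropped: list[str] = []
    for line in path.read_text().splitlines():
        symbol = line.strip()
        if not symbol or symbol.startswith("#"):
            continue
        if symbol in seen:
            dropped.append(symbol)
            continue
        seen.add(symbol)
        symbols.append(symbol)
    if dropped:
        logger.warning("signature %s: dropped duplicate symbols %s", path.name, sorted(set(dropped)))
    if not symbols:
        raise ValueError(f"signature file {path} is empty after comment stripping")
    return GeneSignature(name=name or path.stem, genes=tuple(symbols))


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to the median library size, then ``log1p``.

    Every cell's counts are multiplied by ``median(total counts) / total``
    so all cells share the median library size, then log-transformed.
    Requires a ``counts`` layer with a positive total per cell.
    """
    if matrix.layer_tag != "counts":
        raise ValueError("normalize_counts expects a counts layer")
    totals = matrix.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"cells with zero total counts cannot be normalised: {bad[:5]}")
    median = float(np.median(totals))
    scaled = matrix.values * (median / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled),
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        layer_tag="normalized",
    )
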