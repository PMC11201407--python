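"""Data containers and readers/writers for counts, coordinates and labels.

The canonical in-memory orientation is spots-as-rows (``N`` spots ×
``G`` genes). Three plain-text formats are supported for counts —
dense CSV/TSV, MatrixMarket coordinate triplets, and the HDF5-based
single-cell container (AnnData ``.h5ad``) — plus CSV/TSV for
coordinates and domain labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input violated a container invariant (negative counts, NaN, ...)."""


class FormatError(ValueError):
    """A file did not parse under the expected dialect."""


class AlignmentError(ValueError):
    """Identifiers of two inputs could not be reconciled."""


def _check_unique(ids: np.ndarray, kind: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = list(dupes[dupes > 1].index[:5])
        raise ValidationError(f"duplicate {kind}: {dupes}")


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, spots as rows."""

    counts: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, g = self.counts.shape
        if n < 2 or g < 1:
            raise ValidationError(f"need N >= 2 spots and G >= 1 genes, got {n} x {g}")
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValidationError("identifier lengths do not match the matrix shape")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, rtol=0, atol=0):
                raise ValidationError("counts contain fractional entries")
            self.counts = as_int.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at spot {self.spot_ids[i]!r}, gene {self.gene_ids[j]!r}")
        _check_unique(self.spot_ids, "spot_ids")
        _check_unique(self.gene_ids, "gene_ids")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(np.float64)

    def zero_fraction(self) -> float:
        return float(np.mean(self.counts == 0))


@dataclass
class CoordinateTable:
    """Planar spatial positions aligned row-for-row with a CountMatrix."""

    coords: np.ndarray
    spot_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(f"coordinates must be N x 2, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            bad = np.argwhere(~np.isfinite(self.coords))[0]
            raise ValidationError(f"non-finite coordinate at row {bad[0]}")
        if len(self.spot_ids) != len(self.coords):
            raise ValidationError("spot_ids length does not match coordinates")
        _check_unique(self.spot_ids, "spot_ids")


@dataclass
class DomainLabeling:
    """Integer spatial-domain assignment per spot (0-based)."""

    labels: np.ndarray
    domain_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) < 2:
            raise ValidationError("labels must be a 1-D vector of length >= 2")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integers")
        if self.labels.min() < 0:
            raise ValidationError("labels must be 0-based nonnegative")
        if self.domain_names is not None:
            if len(self.domain_names) <= self.labels.max():
                raise ValidationError("domain_names shorter than the label range")

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"could not parse {path}: {exc}") from exc


def read_counts(path: str | Path, format: str | None = None,
                genes_as_rows: bool = False) -> CountMatrix:
    """Read a count matrix from CSV/TSV, MatrixMarket or an ``.h5ad`` container.

    ``format`` is inferred from the suffix when omitted (``.mtx``, ``.h5ad``,
    else delimited text). MatrixMarket files are commonly written
    genes-as-rows; pass ``genes_as_rows=True`` to transpose on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".h5ad": "h5-container"}.get(path.suffix.lower(), "csv")

    if format == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = sparse.coo_matrix(mat)
        dense = np.asarray(mat.todense())
        if genes_as_rows:
            dense = dense.T
        n, g = dense.shape
        return CountMatrix(dense,
                           np.array([f"spot_{i}" for i in range(n)]),
                           np.array([f"gene_{j}" for j in range(g)]))

    if format == "h5-container":
        import anndata as ad
        adata = ad.read_h5ad(path)
        x = adata.raw.X if adata.raw is not None else adata.X
        dense = np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)
        return CountMatrix(dense, np.asarray(adata.obs_names), np.asarray(adata.var_names))

    if format == "csv":
        df = _read_table(path)
        # a non-numeric first column is taken as spot identifiers
        first = df.columns[0]
        if df[first].dtype == object:
            df = df.set_index(first)
        try:
            values = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric count entry in {path}: {exc}") from exc
        mat = values.T if genes_as_rows else values
        spot_ids = (np.asarray(df.columns) if genes_as_rows else np.asarray(df.index.astype(str)))
        gene_ids = (np.asarray(df.index.astype(str)) if genes_as_rows else np.asarray(df.columns))
        return CountMatrix(mat, spot_ids, gene_ids)

    raise ValueError(f"unknown format {format!r}")


def read_coordinates(path: str | Path, counts: CountMatrix | None = None) -> CoordinateTable:
    """Read an N×2 coordinate table, aligning to ``counts`` spot ids if given."""
    df = _read_table(path)
    numeric = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    non_numeric = [c for c in df.columns if c not in numeric]
    if len(numeric) != 2:
        raise FormatError(f"expected exactly 2 numeric coordinate columns, found {len(numeric)}")
    if len(non_numeric) > 1:
        raise FormatError(f"more than one candidate id column: {non_numeric}")

    coords = df[numeric].to_numpy(dtype=np.float64)
    if np.isnan(coords).any():
        raise ValidationError("NaN coordinate value")

    if non_numeric:
        ids = df[non_numeric[0]].astype(str).to_numpy()
        table = CoordinateTable(coords, ids)
        if counts is not None:
            want = [str(s) for s in counts.spot_ids]
            missing = sorted(set(want) - set(ids))
            extra = sorted(set(ids) - set(want))
            if missing or extra:
                raise AlignmentError(
                    f"coordinate ids do not match counts; missing={missing[:5]}, extra={extra[:5]}")
            order = pd.Index(ids).get_indexer(want)
            table = CoordinateTable(coords[order], np.asarray(want, dtype=object))
        return table

    if counts is not None:
        if len(coords) != counts.n_spots:
            raise AlignmentError(
                f"coordinate table has {len(coords)} rows but counts has {counts.n_spots} spots")
        logger.warning("coordinate file has no id column; aligning positionally")
        return CoordinateTable(coords, counts.spot_ids)
    logger.warning("coordinate file has no id column; generating positional spot ids")
    return CoordinateTable(coords, np.array([f"spot_{i}" for i in range(len(coords))]))


def write_labels(labeling: DomainLabeling, path: str | Path,
                 spot_ids: np.ndarray | None = None) -> None:
    """Write a two-column (spot_id, domain) CSV.

    Domain names are written in place of integer codes when present.
    """
    if spot_ids is None:
        spot_ids = np.array([f"spot_{i}" for i in range(len(labeling.labels))])
    if len(spot_ids) != len(labeling.labels):
        raise ValidationError("spot_ids length does not match labels")
    if labeling.domain_names is not None:
        col = [labeling.domain_names[v] for v in labeling.labels]
    else:
        col = labeling.labels
    pd.DataFrame({"spot_id": spot_ids, "domain": col}).to_csv(path, index=False)


def read_labels(path: str | Path) -> DomainLabeling:
    """Read a label CSV written by :func:`write_labels` (or any 1–2 column CSV)."""
    df = _read_table(path)
    col = df["domain"] if "domain" in df.columns else df[df.columns[-1]]
    if np.issubdtype(col.dtype, np.number):
        return DomainLabeling(col.to_numpy(dtype=np.int64))
    names = list(dict.fromkeys(col))  # order of first appearance
    index = {name: i for i, name in enumerate(names)}
    return DomainLabeling(np.array([index[v] for v in col], dtype=np.int64), names)
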