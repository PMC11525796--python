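"""The cells-by-features expression matrix and its file formats.

Cells are rows and features (genes and TFs) are columns, everywhere.  The
container is a thin dataclass over a dense float array with ordered cell and
feature names and a per-feature TF flag; ``library_size`` records an applied
per-cell normalization target.  Readers cover MTX (+ features/barcodes
sidecars), dense CSV/TSV, and a simple HDF5 layout; each writer mirrors its
reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    values: np.ndarray  # cells x features, nonnegative
    cell_ids: list[str]
    feature_ids: list[str]
    is_tf: np.ndarray = field(default=None)  # type: ignore[assignment]
    library_size: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x features)")
        n_cells, n_feat = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length mismatch")
        if len(self.feature_ids) != n_feat:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature names")
        if self.is_tf is None:
            self.is_tf = np.zeros(n_feat, dtype=bool)
        self.is_tf = np.asarray(self.is_tf, dtype=bool)
        if self.is_tf.shape != (n_feat,):
            raise ValueError("is_tf shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")
        if self.library_size is not None:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, self.library_size, rtol=1e-6, atol=0):
                raise ValueError(
                    "library_size is set but row sums do not match it"
                )

    # -- basic queries -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def tf_names(self) -> list[str]:
        return [f for f, t in zip(self.feature_ids, self.is_tf) if t]

    @property
    def gene_names(self) -> list[str]:
        return [f for f, t in zip(self.feature_ids, self.is_tf) if not t]

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_index([name])[0]]

    # -- derivation --------------------------------------------------------
    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in np.atleast_1d(idx)],
            list(self.feature_ids),
            self.is_tf.copy(),
            self.library_size,
        )

    def subset_features(self, names: Sequence[str]) -> "ExpressionMatrix":
        idx = self.feature_index(names)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.cell_ids),
            [self.feature_ids[i] for i in idx],
            self.is_tf[idx],
            None,  # feature subsetting invalidates a recorded library size
        )

    def with_tf_flags(self, tf_list: Iterable[str]) -> "ExpressionMatrix":
        tfset = set(tf_list)
        flags = np.array([f in tfset for f in self.feature_ids])
        return ExpressionMatrix(
            self.values.copy(), list(self.cell_ids), list(self.feature_ids),
            flags, self.library_size,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.cell_ids), list(self.feature_ids),
            self.is_tf.copy(), self.library_size,
        )

    def to_anndata(self):
        import anndata as adata

        a = adata.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame({"is_tf": self.is_tf}, index=self.feature_ids),
        )
        if self.library_size is not None:
            a.uns["library_size"] = self.library_size
        return a

    @classmethod
    def from_anndata(cls, a) -> "ExpressionMatrix":
        x = a.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        is_tf = (
            a.var["is_tf"].to_numpy()
            if "is_tf" in a.var
            else np.zeros(a.n_vars, dtype=bool)
        )
        return cls(
            np.asarray(x, dtype=np.float64),
            [str(i) for i in a.obs_names],
            [str(i) for i in a.var_names],
            is_tf,
            a.uns.get("library_size"),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a 10x-style directory: matrix.mtx (features x cells), features/
    genes .tsv, barcodes.tsv."""
    from scipy.io import mmread

    d = Path(directory)
    mtx = d / "matrix.mtx"
    feats = d / "features.tsv" if (d / "features.tsv").exists() else d / "genes.tsv"
    barcodes = d / "barcodes.tsv"
    m = np.asarray(mmread(mtx).todense(), dtype=np.float64).T  # -> cells x features
    feature_ids = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    return ExpressionMatrix(m, cell_ids, feature_ids)


def write_mtx(m: ExpressionMatrix, directory: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(d / "matrix.mtx", csr_matrix(m.values.T))
    pd.Series(m.feature_ids).to_csv(d / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)


def read_dense(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Dense CSV/TSV: first column cell ids, header row feature ids."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_dense(m: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.feature_ids).to_csv(path, sep=sep)


def read_h5(path: str | Path) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        cells = [s.decode() for s in f["cell_ids"][...]]
        feats = [s.decode() for s in f["feature_ids"][...]]
        is_tf = f["is_tf"][...].astype(bool)
        lib = f.attrs.get("library_size")
    return ExpressionMatrix(values, cells, feats, is_tf, None if lib is None else float(lib))


def write_h5(m: ExpressionMatrix, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f.create_dataset("cell_ids", data=np.array(m.cell_ids, dtype="S"))
        f.create_dataset("feature_ids", data=np.array(m.feature_ids, dtype="S"))
        f.create_dataset("is_tf", data=m.is_tf.astype(np.uint8))
        if m.library_size is not None:
            f.attrs["library_size"] = m.library_size


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Dispatch on path: directory -> MTX, .h5 -> HDF5, else dense CSV/TSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx(path)
    if path.suffix in {".h5", ".hdf5"}:
        return read_h5(path)
    return read_dense(path)
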