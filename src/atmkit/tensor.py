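"""Sparse 3-mode tensor with the matricization / Khatri–Rao machinery.

The tensor holds log-weighted term frequencies l = log2(1 + f) over the
(term, gene, TF) axes.  Matricization (unfolding) follows a fixed 0-based
column ordering: the mode-1 unfolding is m x (n*p) with column k*n + j
(gene index fastest, TF slowest); mode-2 is n x (m*p) with column k*m + i;
mode-3 is p x (m*n) with column j*m + i.  These orderings are exactly the
ones under which X_(1) = A diag(lambda) (C ⊙ B)', X_(2) = B ... (C ⊙ A)',
X_(3) = C ... (B ⊙ A)' hold for a tensor built from factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "SparseTensor3",
    "log_weight",
    "khatri_rao",
    "density_report",
]

AxisLabels = tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]


def log_weight(f):
    """Entrywise log2(1 + f) weighting of raw term frequencies f >= 0."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative frequency")
    res = np.log2(1.0 + arr)
    return float(res) if np.isscalar(f) or arr.ndim == 0 else res


def density_report(dims: tuple[int, int, int], nnz: int) -> tuple[int, int, float]:
    """(nnz, total cells, density) with exact integer cell count."""
    m, n, p = (int(d) for d in dims)
    if m <= 0 or n <= 0 or p <= 0:
        raise ValueError("zero-size tensor")
    total = m * n * p
    return int(nnz), total, nnz / total


def khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product; row of (u_a, v_b) is a*s + b (V is s x k)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.ndim != 2 or V.ndim != 2 or U.shape[1] != V.shape[1]:
        raise ValueError("khatri_rao requires matrices with equal column counts")
    return scipy.linalg.khatri_rao(U, V)


@dataclass
class SparseTensor3:
    """Coordinate-form 3-mode sparse tensor (terms x genes x TFs)."""

    dims: tuple[int, int, int]
    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    values: np.ndarray
    axis_labels: AxisLabels | None = field(default=None)

    @classmethod
    def from_entries(
        cls,
        dims: tuple[int, int, int],
        entries,
        axis_labels: AxisLabels | None = None,
    ) -> "SparseTensor3":
        """Build from an iterable of (i, j, k, value); duplicates are summed."""
        dims = tuple(int(d) for d in dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError("dims must be three positive integers")
        entries = list(entries)
        if entries:
            arr = np.asarray(entries, dtype=float)
            i = arr[:, 0].astype(np.int64)
            j = arr[:, 1].astype(np.int64)
            k = arr[:, 2].astype(np.int64)
            v = arr[:, 3].astype(float)
        else:
            i = j = k = np.empty(0, dtype=np.int64)
            v = np.empty(0, dtype=float)
        m, n, p = dims
        if len(i) and (
            i.min() < 0 or i.max() >= m or j.min() < 0 or j.max() >= n or k.min() < 0 or k.max() >= p
        ):
            raise ValueError("coordinate out of range")
        # merge duplicates by flat index, then sort coordinates
        flat = (i * n + j) * p + k
        uniq, inv = np.unique(flat, return_inverse=True)
        merged = np.zeros(len(uniq))
        np.add.at(merged, inv, v)
        keep = merged != 0
        uniq, merged = uniq[keep], merged[keep]
        if not np.all(np.isfinite(merged)) or np.any(merged < 0):
            raise ValueError("tensor values must be finite and non-negative")
        ii, rem = np.divmod(uniq, n * p)
        jj, kk = np.divmod(rem, p)
        if axis_labels is not None:
            axis_labels = tuple(tuple(a) for a in axis_labels)
            if tuple(len(a) for a in axis_labels) != dims:
                raise ValueError("axis label lengths must match dims")
        return cls(dims, ii, jj, kk, merged.astype(float), axis_labels)

    # -- bookkeeping --------------------------------------------------------

    @property
    def nnz(self) -> int:
        return len(self.values)

    def density_report(self) -> tuple[int, int, float]:
        return density_report(self.dims, self.nnz)

    def frobenius_norm(self) -> float:
        return math.sqrt(float(np.dot(self.values, self.values)))

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.dims)
        dense[self.i, self.j, self.k] = self.values
        return dense

    def log_weighted(self) -> "SparseTensor3":
        """Copy with values replaced by log2(1 + value)."""
        return SparseTensor3(
            self.dims, self.i.copy(), self.j.copy(), self.k.copy(),
            log_weight(self.values), self.axis_labels,
        )

    # -- matricization ------------------------------------------------------

    def matricize(self, mode: int) -> sp.csr_matrix:
        """Mode-n unfolding as a CSR matrix under the fixed column orderings."""
        m, n, p = self.dims
        if mode == 1:
            rows, cols, shape = self.i, self.k * n + self.j, (m, n * p)
        elif mode == 2:
            rows, cols, shape = self.j, self.k * m + self.i, (n, m * p)
        elif mode == 3:
            rows, cols, shape = self.k, self.j * m + self.i, (p, m * n)
        else:
            raise ValueError("mode must be 1, 2 or 3")
        return sp.csr_matrix((self.values, (rows, cols)), shape=shape)

    @classmethod
    def fold(cls, mat, mode: int, dims: tuple[int, int, int]) -> "SparseTensor3":
        """Inverse of :meth:`matricize` for the same mode and dims."""
        m, n, p = dims
        coo = sp.coo_matrix(mat)
        r, c, v = coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data
        if mode == 1:
            i, k, j = r, c // n, c % n
        elif mode == 2:
            j, k, i = r, c // m, c % m
        elif mode == 3:
            k, jj, ii = r, c // m, c % m
            i, j = ii, jj
        else:
            raise ValueError("mode must be 1, 2 or 3")
        return cls.from_entries(dims, zip(i, j, k, v))

    # -- serialization ------------------------------------------------------

    def dump_tsv(self, path: str | Path) -> None:
        """`#dims m n p` header then 0-based `i<TAB>j<TAB>k<TAB>value` lines.

        When axis labels are attached, companion files ``<path>.terms.txt``,
        ``.genes.txt`` and ``.tfs.txt`` hold the index→label maps.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("#dims %d %d %d\n" % self.dims)
            for i, j, k, v in zip(self.i, self.j, self.k, self.values):
                fh.write(f"{i}\t{j}\t{k}\t{float(v)!r}\n")
        if self.axis_labels is not None:
            for suffix, labels in zip(("terms", "genes", "tfs"), self.axis_labels):
                Path(f"{path}.{suffix}.txt").write_text("".join(f"{x}\n" for x in labels))

    @classmethod
    def load_tsv(cls, path: str | Path) -> "SparseTensor3":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().split()
            if header[:1] != ["#dims"] or len(header) != 4:
                raise ValueError("missing #dims header")
            dims = tuple(int(x) for x in header[1:])
            entries = []
            for line in fh:
                if line.strip():
                    i, j, k, v = line.split("\t")
                    entries.append((int(i), int(j), int(k), float(v)))
        labels = None
        sidecars = [Path(f"{path}.{s}.txt") for s in ("terms", "genes", "tfs")]
        if all(p.exists() for p in sidecars):
            labels = tuple(tuple(p.read_text().splitlines()) for p in sidecars)
        return cls.from_entries(dims, entries, labels)


def from_term_counts(
    vocab, gene_labels, tf_labels, entries, log_weighted: bool = True
) -> SparseTensor3:
    """Assemble the tensor from :func:`atmkit.corpus.count_terms` output."""
    dims = (len(vocab), len(gene_labels), len(tf_labels))
    labels = (tuple(vocab.terms), tuple(gene_labels), tuple(tf_labels))
    X = SparseTensor3.from_entries(dims, entries, labels)
    return X.log_weighted() if log_weighted else X


__all__.append("from_term_counts")
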