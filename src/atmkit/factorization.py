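"""Non-negative PARAFAC (CP) decomposition by multiplicative updates.

The rank-k model approximates the tensor as X ≈ Σ_r λ_r (a_r ∘ b_r ∘ c_r)
with non-negative factor matrices A (terms), B (genes), C (TFs).  Each
sweep solves the three NMF sub-problems min ||X_(mode) − F Z'||_F in
succession with the multiplicative update

    F ← F ⊙ (X_(mode) Z) ⊘ (F Z'Z + ε),   Z the Khatri–Rao of the other
                                           two factors,

where ε (default 1e-9) guards against division underflow.  Z'Z is never
formed from Z: it equals the Hadamard product of the two factor Gram
matrices, and X_(mode) Z is evaluated by a sparse MTTKRP in O(nnz·k).
Factors are initialized from the absolute values of the k leading left
singular vectors of each unfolding, making the run deterministic (random
padding, governed by ``random_state``, only enters when k exceeds the
numerical rank of an unfolding).  On convergence the factor columns are
normalized to unit 2-norm and the accumulated scale kept in λ, sorted
non-increasing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .tensor import SparseTensor3

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "NonnegativeParafac",
    "init_factors",
    "mttkrp",
    "multiplicative_update",
    "ntf",
]

_ZERO_LOCK_FLOOR = 1e-12  # initializer floor so multiplicative updates can leave 0


@dataclass
class FactorModel:
    """Normalized rank-k CP factors with component weights.

    ``A`` (m x k, terms), ``B`` (n x k, genes), ``C`` (p x k, TFs) have
    unit-norm columns; ``lam`` carries the component weights sorted
    non-increasing.  ``fit_history`` records fit = 1 − ||X − X̂||_F/||X||_F
    per sweep.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    lam: np.ndarray
    fit_history: list[float]
    rank: int
    seed: int = 0
    axis_labels: tuple | None = field(default=None)

    @property
    def fit(self) -> float:
        return self.fit_history[-1] if self.fit_history else float("nan")

    def reconstruct(self) -> np.ndarray:
        """Dense X̂ = Σ_r λ_r a_r ∘ b_r ∘ c_r (small problems only)."""
        return np.einsum("ir,jr,kr,r->ijk", self.A, self.B, self.C, self.lam)

    def save(self, prefix: str | Path) -> None:
        """JSON metadata + TSV matrices under ``prefix`` (prefix.meta.json etc.)."""
        prefix = Path(prefix)
        meta = {
            "rank": self.rank,
            "seed": self.seed,
            "iterations": len(self.fit_history),
            "fit": self.fit,
            "fit_history": self.fit_history,
            "lambda": self.lam.tolist(),
            "axis_labels": self.axis_labels,
        }
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        for name, mat in (("A", self.A), ("B", self.B), ("C", self.C)):
            np.savetxt(f"{prefix}.{name}.tsv", mat, delimiter="\t")

    @classmethod
    def load(cls, prefix: str | Path) -> "FactorModel":
        prefix = Path(prefix)
        with open(f"{prefix}.meta.json") as fh:
            meta = json.load(fh)
        mats = {
            name: np.atleast_2d(np.loadtxt(f"{prefix}.{name}.tsv", delimiter="\t", ndmin=2))
            for name in "ABC"
        }
        labels = meta.get("axis_labels")
        if labels is not None:
            labels = tuple(tuple(a) for a in labels)
        return cls(
            mats["A"], mats["B"], mats["C"], np.asarray(meta["lambda"], dtype=float),
            list(meta["fit_history"]), int(meta["rank"]), int(meta["seed"]), labels,
        )


def init_factors(
    X: SparseTensor3, k: int, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|k leading left singular vectors| of each unfolding, per mode.

    Computed through the eigendecomposition of the mode Gram matrix
    X_(mode) X_(mode)', which shares left singular vectors with the
    unfolding without forming the m x np matrix.  Columns beyond the
    numerical rank are filled with seeded uniform(0,1) values.
    """
    if k < 1:
        raise ValueError("rank k must be >= 1")
    rng = np.random.default_rng(random_state)
    factors = []
    for mode in (1, 2, 3):
        M = X.matricize(mode)
        G = (M @ M.T).toarray()
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        sv = np.sqrt(np.clip(w, 0.0, None))
        r = int(np.sum(sv > (sv[0] * 1e-8 if sv[0] > 0 else np.inf)))
        take = min(k, r, V.shape[1])
        F = np.empty((G.shape[0], k))
        lead = V[:, :take]
        # sign convention: largest-magnitude entry positive before abs
        idx = np.argmax(np.abs(lead), axis=0)
        signs = np.sign(lead[idx, np.arange(take)])
        signs[signs == 0] = 1.0
        F[:, :take] = np.abs(lead * signs)
        if take < k:
            warnings.warn(
                f"rank {k} exceeds numerical rank {take} of mode-{mode} unfolding; "
                "padding with random columns",
                stacklevel=2,
            )
            F[:, take:] = rng.uniform(size=(G.shape[0], k - take))
        factors.append(np.maximum(F, _ZERO_LOCK_FLOOR))
    return tuple(factors)


def mttkrp(X: SparseTensor3, U: np.ndarray, V: np.ndarray, mode: int) -> np.ndarray:
    """X_(mode) (U ⊙ V) without materializing the Khatri–Rao product.

    For mode 1, (U, V) = (C, B); mode 2, (C, A); mode 3, (B, A) — i.e. U is
    the slower-varying factor in the unfolding's column ordering.  Cost is
    O(nnz(X) · k).
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape[1] != V.shape[1]:
        raise ValueError("U and V must have equal column counts")
    m, n, p = X.dims
    if mode == 1:
        out_rows, u_rows, v_rows, u_dim, v_dim, out_dim = X.i, X.k, X.j, p, n, m
    elif mode == 2:
        out_rows, u_rows, v_rows, u_dim, v_dim, out_dim = X.j, X.k, X.i, p, m, n
    elif mode == 3:
        out_rows, u_rows, v_rows, u_dim, v_dim, out_dim = X.k, X.j, X.i, n, m, p
    else:
        raise ValueError("mode must be 1, 2 or 3")
    if U.shape[0] != u_dim or V.shape[0] != v_dim:
        raise ValueError("factor shapes do not match tensor dims for this mode")
    out = np.zeros((out_dim, U.shape[1]))
    if X.nnz:
        contrib = X.values[:, None] * U[u_rows] * V[v_rows]
        np.add.at(out, out_rows, contrib)
    return out


def multiplicative_update(
    F: np.ndarray,
    X: SparseTensor3,
    Z_parts: tuple[np.ndarray, np.ndarray],
    mode: int,
    eps: float = 1e-9,
) -> np.ndarray:
    """One multiplicative step F ← F ⊙ (X_(mode) Z) ⊘ (F Z'Z + ε).

    ``Z_parts`` holds the two factors whose Khatri–Rao product is Z; Z'Z is
    the Hadamard product of their Gram matrices.  Non-negativity and zeros
    of F are preserved.
    """
    U, V = Z_parts
    numer = mttkrp(X, U, V, mode)
    gram = (U.T @ U) * (V.T @ V)
    out = F * numer / (F @ gram + eps)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("numerical failure in multiplicative update")
    return out


class NonnegativeParafac(BaseEstimator):
    """Rank-k non-negative CP decomposition of a :class:`SparseTensor3`.

    Parameters
    ----------
    rank : number of components k.
    tol : stop when the absolute change in fit between sweeps drops below
        this (fit = 1 − relative Frobenius error); default 1e-4.
    max_iter : hard cap on sweeps (default 100).
    eps : denominator stabilizer of the multiplicative update, default 1e-9.
    random_state : seed for rank-deficient initializer padding (the only
        source of randomness).

    Attributes (after ``fit``)
    --------------------------
    A_, B_, C_ : unit-column factor matrices for terms, genes, TFs.
    lambda_ : non-increasing component weights.
    fit_history_ : per-sweep fit values.
    n_iter_ : number of sweeps run.
    model_ : the same content as a :class:`FactorModel`.
    """

    def __init__(self, rank=2, tol=1e-4, max_iter=100, eps=1e-9, random_state=0):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X: SparseTensor3, y=None) -> "NonnegativeParafac":
        if self.rank < 1:
            raise ValueError("rank k must be >= 1")
        if X.nnz == 0:
            raise ValueError("zero norm: cannot factorize an all-zero tensor")
        norm_x = X.frobenius_norm()
        norm_x2 = norm_x * norm_x
        A, B, C = init_factors(X, self.rank, self.random_state)
        history: list[float] = []
        prev_fit = None
        for sweep in range(self.max_iter):
            A = multiplicative_update(A, X, (C, B), 1, self.eps)
            B = multiplicative_update(B, X, (C, A), 2, self.eps)
            C = multiplicative_update(C, X, (B, A), 3, self.eps)
            fit = self._fit_value(X, A, B, C, norm_x2)
            history.append(fit)
            if prev_fit is not None and abs(fit - prev_fit) < self.tol:
                break
            prev_fit = fit
        A, B, C, lam = self._normalize_and_sort(A, B, C)
        self.A_, self.B_, self.C_, self.lambda_ = A, B, C, lam
        self.fit_history_ = history
        self.n_iter_ = len(history)
        self.model_ = FactorModel(
            A, B, C, lam, history, self.rank,
            seed=self.random_state, axis_labels=X.axis_labels,
        )
        return self

    @staticmethod
    def _fit_value(X, A, B, C, norm_x2) -> float:
        """fit = 1 − ||X − X̂||/||X|| via sparse inner product + Gram identity."""
        inner = float(np.dot(X.values, np.einsum("ri,ri,ri->r", A[X.i], B[X.j], C[X.k])))
        norm_hat2 = float(np.sum((A.T @ A) * (B.T @ B) * (C.T @ C)))
        err2 = max(norm_x2 - 2.0 * inner + norm_hat2, 0.0)
        return 1.0 - np.sqrt(err2) / np.sqrt(norm_x2)

    @staticmethod
    def _normalize_and_sort(A, B, C):
        na = np.linalg.norm(A, axis=0)
        nb = np.linalg.norm(B, axis=0)
        nc = np.linalg.norm(C, axis=0)
        lam = na * nb * nc
        safe = lambda v: np.where(v > 0, v, 1.0)  # zero columns keep lam 0
        A = A / safe(na)
        B = B / safe(nb)
        C = C / safe(nc)
        order = np.argsort(-lam, kind="stable")
        return A[:, order], B[:, order], C[:, order], lam[order]


def ntf(
    X: SparseTensor3,
    k: int,
    tol: float = 1e-4,
    max_iter: int = 100,
    eps: float = 1e-9,
    random_state: int = 0,
) -> FactorModel:
    """Functional wrapper over :class:`NonnegativeParafac`."""
    est = NonnegativeParafac(
        rank=k, tol=tol, max_iter=max_iter, eps=eps, random_state=random_state
    )
    return est.fit(X).model_
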