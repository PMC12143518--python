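"""M-band discrete wavelet transform on the gene axis.

The transform is represented explicitly as an orthogonal n x n matrix W
whose rows are circular M-shifted copies of the bank's tap sequences,
grouped approximation-first:

    rows [0, k)        shifts of h_0  -> approximation block  (subspace V)
    rows [j*k, (j+1)*k) shifts of h_j -> detail-j block       (subspace W_j)

with n = M*k.  Applied to a gene x cell matrix S (one column per cell),
``W @ S`` yields the wavelet coefficients; multiplying a single block's
rows back gives the orthogonal component reconstruction (the projection
of each cell's profile onto that block's subspace), and the components
sum back to S exactly.

A single decomposition level is used throughout: the coefficient layout
with exactly M blocks is a one-level transform by construction.
Boundary handling is periodic (circular wrap of the taps), which keeps W
exactly orthogonal for every n divisible by M.

:class:`MBandDWT` wraps the same machinery as a scikit-learn transformer
operating on ``(cells, genes)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .config import ATOL, RTOL
from .filters import FilterBank, build_filter_bank

__all__ = [
    "BlockSizeError",
    "DWTMatrix",
    "MBandDWT",
    "WaveletCoefficients",
    "build_dwt_matrix",
    "forward_dwt",
    "inverse_dwt",
    "pad_genes",
    "reconstruct_component",
]


class BlockSizeError(ValueError):
    """Signal length is incompatible with the band count."""


@dataclass(frozen=True)
class DWTMatrix:
    """An explicit orthogonal M-band DWT matrix with its block layout."""

    W: np.ndarray = field(repr=False)
    M: int
    k: int
    family: str = "custom"

    @property
    def n(self) -> int:
        return self.M * self.k

    @property
    def block_labels(self) -> list:
        return ["approx"] + [f"detail-{j}" for j in range(1, self.M)]

    def block_slice(self, which: str) -> slice:
        """Row range of a named block (``approx`` or ``detail-j``)."""
        try:
            j = self.block_labels.index(which)
        except ValueError:
            raise KeyError(
                f"unknown block {which!r}; expected one of {self.block_labels}"
            ) from None
        return slice(j * self.k, (j + 1) * self.k)


@dataclass(frozen=True)
class WaveletCoefficients:
    """Blocked coefficients of a forward transform.

    ``a`` holds the k x p approximation coefficients and ``details`` the
    M-1 detail blocks; per column the blocks carry the full energy of the
    original column (the transform is orthogonal).
    """

    a: np.ndarray = field(repr=False)
    details: tuple = field(repr=False)
    source_n: int
    source_p: int
    padding: int = 0

    @property
    def M(self) -> int:
        return len(self.details) + 1

    @property
    def k(self) -> int:
        return self.a.shape[0]

    def stacked(self) -> np.ndarray:
        """All blocks stacked back into the n x p coefficient matrix."""
        return np.vstack((self.a,) + self.details)

    def block(self, which: str) -> np.ndarray:
        if which == "approx":
            return self.a
        for j in range(1, self.M):
            if which == f"detail-{j}":
                return self.details[j - 1]
        raise KeyError(f"unknown block {which!r}")


def pad_genes(S: np.ndarray, M: int) -> tuple[np.ndarray, int]:
    """Append the minimal number of all-zero rows so ``n`` divides by M.

    Returns the (possibly unchanged) matrix and the number of pad rows.
    Idempotent when the row count is already divisible by M.
    """
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D matrix")
    pad = (-S.shape[0]) % M
    if pad == 0:
        return S, 0
    return np.vstack([S, np.zeros((pad, S.shape[1]), dtype=S.dtype)]), pad


def build_dwt_matrix(fb: FilterBank, n: int) -> DWTMatrix:
    """Build the n x n orthogonal transform matrix for a filter bank.

    Row r of block i carries ``h_i`` starting at column ``M*r`` with
    circular wrap-around.  Requires ``n`` divisible by ``fb.M`` and
    ``n >= L`` so the wrapped taps cannot self-overlap.
    """
    M, L = fb.M, fb.L
    if n % M != 0:
        raise BlockSizeError(
            f"signal length {n} not divisible by M={M}; pad the matrix first "
            "(see pad_genes)"
        )
    if n < L:
        raise BlockSizeError(f"signal length {n} shorter than filter length {L}")
    k = n // M
    W = np.zeros((n, n))
    cols = np.arange(L)
    for i, h in enumerate(fb.taps):
        for r in range(k):
            W[i * k + r, (M * r + cols) % n] = h
    wm = DWTMatrix(W=W, M=M, k=k, family=fb.family)
    defect = np.max(np.abs(W @ W.T - np.eye(n)))
    if defect > ATOL:
        raise BlockSizeError(
            f"transform not orthogonal (defect {defect:.3e}); "
            f"n={n} too short for circular shifts of length-{L} taps"
        )
    return wm


def forward_dwt(Wm: DWTMatrix, S: np.ndarray, padding: int = 0) -> WaveletCoefficients:
    """Forward transform of a gene x cell matrix: blocks of ``W @ S``."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] == 1 and Wm.n != 1 and S.shape[1] == Wm.n:
        S = S.T  # tolerate a 1-D signal passed as a row
    if S.shape[0] != Wm.n:
        raise ValueError(f"matrix has {S.shape[0]} rows, transform expects {Wm.n}")
    St = Wm.W @ S
    k = Wm.k
    return WaveletCoefficients(
        a=St[:k],
        details=tuple(St[j * k:(j + 1) * k] for j in range(1, Wm.M)),
        source_n=Wm.n,
        source_p=S.shape[1],
        padding=padding,
    )


def inverse_dwt(Wm: DWTMatrix, C: WaveletCoefficients) -> np.ndarray:
    """Invert the transform: ``W' @ [a; d_1; ...; d_{M-1}]``."""
    if C.M != Wm.M or C.k != Wm.k:
        raise ValueError(
            f"coefficients ({C.M} bands, k={C.k}) do not match transform "
            f"({Wm.M} bands, k={Wm.k})"
        )
    return Wm.W.T @ C.stacked()


def reconstruct_component(Wm: DWTMatrix, C: WaveletCoefficients, which: str) -> np.ndarray:
    """Reconstruct one orthogonal component (projection onto V or W_j).

    ``which`` is ``"approx"`` or ``"detail-j"``.  The components over all
    blocks sum to the original matrix, and distinct components are
    orthogonal column-wise.
    """
    sl = Wm.block_slice(which)
    return Wm.W[sl].T @ C.block(which)


class MBandDWT(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer applying an M-band DWT along features.

    Operates on ``(n_cells, n_genes)`` arrays (samples in rows, genes in
    columns, the scikit-learn orientation).  ``fit`` pads the gene axis
    to a multiple of ``M`` and builds the orthogonal transform matrix;
    ``transform`` returns the full coefficient array
    ``(n_cells, n_genes + padding_)`` laid out approximation block first.

    Parameters
    ----------
    M : int, default 2
        Band count (2, 3 or 4).
    family : str or None
        Filter family; ``None`` selects the per-M default (``db2`` for
        two bands).

    Attributes
    ----------
    filter_bank_ : FilterBank
    dwt_ : DWTMatrix
    padding_ : int
        Zero rows appended on the gene axis.
    block_labels_ : list of str
        ``["approx", "detail-1", ...]``.
    """

    def __init__(self, M: int = 2, family: str | None = None):
        self.M = M
        self.family = family

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (cells, genes) array")
        self.n_features_in_ = X.shape[1]
        self.filter_bank_ = build_filter_bank(self.M, self.family)
        self.padding_ = (-X.shape[1]) % self.M
        self.dwt_ = build_dwt_matrix(self.filter_bank_, X.shape[1] + self.padding_)
        self.block_labels_ = self.dwt_.block_labels
        return self

    def _pad(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, transformer fitted on {self.n_features_in_}"
            )
        padded, _ = pad_genes(X.T, self.M)
        return padded

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        return (self.dwt_.W @ self._pad(X)).T

    def inverse_transform(self, Xt) -> np.ndarray:
        check_is_fitted(self)
        S = self.dwt_.W.T @ np.asarray(Xt, dtype=float).T
        return S[: self.n_features_in_].T

    def coefficients(self, X) -> WaveletCoefficients:
        """Blocked coefficients of ``X`` in the gene x cell orientation."""
        check_is_fitted(self)
        return forward_dwt(self.dwt_, self._pad(X), padding=self.padding_)

    def component(self, X, which: str) -> np.ndarray:
        """One component reconstruction of ``X`` as ``(cells, genes)``.

        Pad rows are stripped, so columns align with the input genes.
        """
        check_is_fitted(self)
        rec = reconstruct_component(self.dwt_, self.coefficients(X), which)
        return rec[: self.n_features_in_].T


def _energy_error(C: WaveletCoefficients, S: np.ndarray) -> float:
    """Max relative per-column energy deviation (diagnostic helper)."""
    e_in = np.sum(np.asarray(S, dtype=float) ** 2, axis=0)
    e_out = np.sum(C.stacked() ** 2, axis=0)
    denom = np.where(e_in > 0, e_in, 1.0)
    return float(np.max(np.abs(e_out - e_in) / denom))
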