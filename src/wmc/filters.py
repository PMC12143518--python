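"""Orthogonal M-band filter banks.

An M-band filter bank consists of one scaling (low-pass) filter ``h_0``
and M-1 wavelet (band-pass) filters ``h_1 .. h_{M-1}``, all of the same
finite length L (a multiple of M).  Orthogonality here means the taps
and all their shifts by multiples of M form an orthonormal system:

    sum_t h_i[t] * h_j[t + M*s]  =  delta_ij * delta_s0

together with the low-pass normalisation ``sum_t h_0[t] = sqrt(M)``.
These are exactly the conditions that make the derived transform matrix
orthogonal, so every bank is validated against them at construction time
and rejected if any condition fails.

Supported families
------------------
M = 2   ``haar`` and the Daubechies family ``db1 .. db10`` (via PyWavelets;
        ``haar`` == ``db1`` up to sign convention).
M = 3,4 ``dct``     — the block DCT-II bank (L = M), the M-band
                      generalisation of the Haar transform; and
        ``lattice`` — a length-2M paraunitary bank built from the
                      one-factor lattice form E(z) = (I - vv' + vv' z^-1) Q
                      with Q the orthonormal DCT-II matrix, which is
                      paraunitary for any unit vector v.
``dct`` and ``lattice`` are also available for M = 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pywt

from .config import ATOL, SUPPORTED_BANDS

__all__ = [
    "FilterBank",
    "InvalidFilterBankError",
    "UnsupportedConfigurationError",
    "available_families",
    "build_filter_bank",
    "default_family",
    "validate_filter_bank",
]


class UnsupportedConfigurationError(ValueError):
    """Requested band count / family combination is not supported."""


class InvalidFilterBankError(ValueError):
    """A candidate filter bank violates the orthogonality invariants."""


@dataclass(frozen=True)
class FilterBank:
    """An orthogonal M-band filter bank.

    Attributes
    ----------
    M : int
        Number of bands (2, 3 or 4).
    taps : tuple of ndarray
        ``M`` tap sequences ``h_0 .. h_{M-1}`` of common length ``L``,
        ``h_0`` the scaling filter.
    family : str
        Name of the filter family the bank was built from.
    """

    M: int
    taps: tuple = field(repr=False)
    family: str = "custom"

    @property
    def L(self) -> int:
        return len(self.taps[0])

    def __post_init__(self):
        object.__setattr__(self, "taps", tuple(np.asarray(h, dtype=float) for h in self.taps))


def validate_filter_bank(fb: FilterBank, atol: float = ATOL) -> None:
    """Check all orthogonality invariants of *fb*; raise if any fails.

    Verifies unit l2 norm of every tap sequence, cross/shift orthogonality
    at all shifts by multiples of M, and the sqrt(M) sum of the scaling
    filter.
    """
    M, L = fb.M, fb.L
    if len(fb.taps) != M:
        raise InvalidFilterBankError(f"expected {M} tap sequences, got {len(fb.taps)}")
    if any(len(h) != L for h in fb.taps):
        raise InvalidFilterBankError("tap sequences have unequal lengths")
    if L % M != 0:
        raise InvalidFilterBankError(f"tap length {L} is not a multiple of M={M}")
    s0 = float(np.sum(fb.taps[0]))
    if abs(s0 - np.sqrt(M)) > atol:
        raise InvalidFilterBankError(
            f"scaling filter sums to {s0:.12g}, expected sqrt({M})={np.sqrt(M):.12g}"
        )
    n_shifts = L // M
    for i in range(M):
        for j in range(i, M):
            for s in range(n_shifts):
                hi = fb.taps[i]
                hj = fb.taps[j]
                # linear (non-circular) shift by M*s
                ip = float(np.dot(hi[M * s:], hj[: L - M * s]))
                want = 1.0 if (i == j and s == 0) else 0.0
                if abs(ip - want) > atol:
                    raise InvalidFilterBankError(
                        f"orthogonality failed: <h{i}, shift {M*s} of h{j}> = {ip:.3e}"
                    )


def _dct_matrix(M: int) -> np.ndarray:
    """Orthonormal DCT-II matrix; its first row is constant 1/sqrt(M)."""
    r = np.arange(M)
    C = np.cos(np.pi * np.outer(r, 2 * r + 1) / (2 * M)) * np.sqrt(2.0 / M)
    C[0] = 1.0 / np.sqrt(M)
    return C


def _dct_bank(M: int) -> tuple:
    return tuple(_dct_matrix(M))


def _lattice_bank(M: int) -> tuple:
    """Length-2M paraunitary bank from the one-factor lattice form.

    Polyphase E(z) = (I - vv' + vv' z^-1) Q is paraunitary for any unit v
    and orthogonal Q; taps are read off the polyphase components
    h_i[M*s + r] = E_s[i, r].  Q's constant first row gives the sqrt(M)
    low-pass sum.
    """
    Q = _dct_matrix(M)
    v = np.arange(1.0, M + 1.0)
    v /= np.linalg.norm(v)
    P = np.outer(v, v)
    E0 = (np.eye(M) - P) @ Q
    E1 = P @ Q
    return tuple(np.concatenate([E0[i], E1[i]]) for i in range(M))


def _daubechies_bank(name: str) -> tuple:
    w = pywt.Wavelet(name)
    return (np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float))


_HAAR = (
    np.array([1.0, 1.0]) / np.sqrt(2.0),
    np.array([1.0, -1.0]) / np.sqrt(2.0),
)

_DB_RE = re.compile(r"^db([1-9]|10)$")


def available_families(M: int) -> list:
    """Names of the filter families supported for a given band count."""
    if M == 2:
        return ["haar"] + [f"db{i}" for i in range(1, 11)] + ["dct", "lattice"]
    if M in SUPPORTED_BANDS:
        return ["dct", "lattice"]
    return []


def default_family(M: int) -> str:
    """The recommended family per band count (Daubechies for 2-band)."""
    return "db2" if M == 2 else "dct"


def build_filter_bank(M: int, family: str | None = None) -> FilterBank:
    """Construct and validate an orthogonal M-band filter bank.

    Parameters
    ----------
    M : int
        Band count; one of 2, 3, 4.
    family : str, optional
        Family name (see module docstring).  Defaults to
        :func:`default_family` for the given ``M``.

    Raises
    ------
    UnsupportedConfigurationError
        If ``M`` is outside {2, 3, 4} or the family is unknown for ``M``.
    InvalidFilterBankError
        If the constructed coefficients fail the orthogonality invariants
        (indicates a defective coefficient table, never expected for the
        built-in families).
    """
    if M not in SUPPORTED_BANDS:
        raise UnsupportedConfigurationError(
            f"band count M={M} unsupported; choose one of {SUPPORTED_BANDS}"
        )
    fam = default_family(M) if family is None else str(family).lower()
    if fam == "haar" and M == 2:
        taps = _HAAR
    elif _DB_RE.match(fam) and M == 2:
        taps = _daubechies_bank(fam)
    elif fam == "dct":
        taps = _dct_bank(M)
    elif fam == "lattice":
        taps = _lattice_bank(M)
    else:
        raise UnsupportedConfigurationError(
            f"family {fam!r} unsupported for M={M}; available: {available_families(M)}"
        )
    fb = FilterBank(M=M, taps=taps, family=fam)
    validate_filter_bank(fb)
    return fb
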