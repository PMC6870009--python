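"""Normalized-mutual-information functional connectivity.

Connectivity between two source time series S and Q is quantified by the
plug-in (histogram) mutual information

    MI(S, Q) = H(S) + H(Q) - H(S, Q)

normalized by the geometric mean of the marginal entropies,

    NMI(S, Q) = MI(S, Q) / sqrt(H(S) * H(Q)),

so that NMI(x, x) = 1 and independent signals give values near 0.  Marginals
use equal-width bins over each signal's own observed range; entropies are
reported in bits.  For an 80-region source space all C(80,2) = 3160
unordered pairs are evaluated, yielding a symmetric 80 x 80 matrix with a
zero diagonal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EntropyEstimate", "ConnectivityMatrix", "entropies", "nmi", "build_matrix"]


@dataclass
class EntropyEstimate:
    """Marginal and joint plug-in entropies (bits) of a signal pair."""

    H_S: float
    H_Q: float
    H_SQ: float
    bins: int


@dataclass
class ConnectivityMatrix:
    """Symmetric NMI matrix for one subject and condition."""

    values: np.ndarray
    condition: str = ""
    subject: str = ""
    bins: int = 0
    n_samples: int = 0
    degenerate_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _bin_codes(x: np.ndarray, bins: int) -> tuple[np.ndarray, bool]:
    """Equal-width bin indices over the signal's own range.

    Returns the codes and a flag marking a constant (degenerate) signal.
    """
    x = np.asarray(x, dtype=np.float64)
    lo = x.min()
    rng = x.max() - lo
    if rng == 0:
        return np.zeros(x.shape, dtype=np.intp), True
    codes = np.floor((x - lo) * (bins / rng)).astype(np.intp)
    np.clip(codes, 0, bins - 1, out=codes)
    return codes, False


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def default_bins(n_samples: int) -> int:
    """Square-root rule for the histogram bin count (8 for 61 samples).

    Capped at 32: the plug-in MI bias grows like ``(bins - 1)^2 / (2 n)``,
    so letting the bin count track sqrt(n) indefinitely would keep the bias
    roughly constant instead of letting it vanish for long signals.
    """
    return max(2, min(32, math.ceil(math.sqrt(n_samples))))


def entropies(x: np.ndarray, y: np.ndarray, bins: int) -> EntropyEstimate:
    """Plug-in marginal and joint entropies of two equal-length signals.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 8 samples, or ``bins < 2``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    cx, const_x = _bin_codes(x, bins)
    cy, const_y = _bin_codes(y, bins)
    if const_x or const_y:
        warnings.warn("constant signal: marginal entropy is 0", stacklevel=2)
    joint = np.bincount(cx * bins + cy, minlength=bins * bins)
    return EntropyEstimate(
        H_S=_entropy_bits(np.bincount(cx, minlength=bins)),
        H_Q=_entropy_bits(np.bincount(cy, minlength=bins)),
        H_SQ=_entropy_bits(joint),
        bins=bins,
    )


def nmi(
    x: np.ndarray,
    y: np.ndarray,
    bins: int | None = None,
    denominator: str = "geometric",
) -> float:
    """Normalized mutual information of two signals, in [0, 1].

    ``denominator`` is ``"geometric"`` (sqrt(H_S * H_Q), default — the only
    normalization for which identical signals give exactly 1) or
    ``"arithmetic"`` ((H_S + H_Q) / 2).  A pair involving a constant signal
    has undefined normalization and returns 0 with a warning.
    """
    n = np.asarray(x).size
    if bins is None:
        bins = default_bins(n)
    est = entropies(x, y, bins)
    return _nmi_from_entropies(est.H_S, est.H_Q, est.H_SQ, denominator)


def _nmi_from_entropies(h_s: float, h_q: float, h_sq: float, denominator: str) -> float:
    if h_s == 0.0 or h_q == 0.0:
        warnings.warn("zero marginal entropy: NMI defined as 0", stacklevel=3)
        return 0.0
    mi = h_s + h_q - h_sq
    if denominator == "geometric":
        denom = math.sqrt(h_s * h_q)
    elif denominator == "arithmetic":
        denom = 0.5 * (h_s + h_q)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return float(min(1.0, max(0.0, mi / denom)))


def build_matrix(
    rois,
    bins: int | None = None,
    denominator: str = "geometric",
    condition: str = "",
    subject: str = "",
) -> ConnectivityMatrix:
    """NMI over all unordered region pairs -> symmetric matrix, zero diagonal.

    ``rois`` is a ``regions x samples`` array or an object with a ``values``
    attribute holding one (e.g. :class:`~gatenet.inverse.ROITimeSeries`).
    All pair entropies are computed jointly from one-hot bin indicators, so
    the C(n,2) loop is a single tensor contraction.
    """
    values = np.asarray(getattr(rois, "values", rois), dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("expected a regions x samples array")
    n_roi, n_samp = values.shape
    if bins is None:
        bins = default_bins(n_samp)
    if n_samp < bins:
        raise ValueError("segment shorter than the bin count")

    codes = np.empty((n_roi, n_samp), dtype=np.intp)
    degenerate = []
    for r in range(n_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes[r], const = _bin_codes(values[r], bins)
        if const:
            degenerate.append(r)

    onehot = np.zeros((n_roi, n_samp, bins), dtype=np.float64)
    rows = np.arange(n_samp)
    for r in range(n_roi):
        onehot[r, rows, codes[r]] = 1.0

    marg = onehot.sum(axis=1)  # n_roi x bins
    h_marg = np.array([_entropy_bits(marg[r]) for r in range(n_roi)])

    # joint[i, j, a, b] = #{t : code_i(t)=a and code_j(t)=b}
    joint = np.einsum("ita,jtb->ijab", onehot, onehot, optimize=True)
    p = joint.reshape(n_roi, n_roi, bins * bins) / n_samp
    with np.errstate(divide="ignore", invalid="ignore"):
        h_joint = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=2)

    hs = h_marg[:, None]
    hq = h_marg[None, :]
    mi = hs + hq - h_joint
    if denominator == "geometric":
        denom = np.sqrt(hs * hq)
    elif denominator == "arithmetic":
        denom = 0.5 * (hs + hq)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, mi / denom, 0.0)
    np.clip(out, 0.0, 1.0, out=out)
    out = 0.5 * (out + out.T)  # symmetry to machine precision
    np.fill_diagonal(out, 0.0)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} constant region(s); their edges set to 0", stacklevel=2
        )
        out[degenerate, :] = 0.0
        out[:, degenerate] = 0.0
    return ConnectivityMatrix(
        values=out,
        condition=condition,
        subject=subject,
        bins=bins,
        n_samples=n_samp,
        degenerate_rows=degenerate,
    )
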