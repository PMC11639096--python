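"""Matrix balancing, distance-decay expected models, O/E, and Pearson matrices.

Balancing is iterative proportional fitting to equal row sums, with sparse
bins masked out first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ValidationError
from .io_formats import ContactMatrix

__all__ = [
    "BalancedMatrix",
    "ExpectedProfile",
    "balance",
    "expected_by_distance",
    "observed_over_expected",
    "pearson_matrix",
]


@dataclass
class BalancedMatrix:
    """Dense symmetric balanced matrix plus the bias vector that produced it.

    ``values[i, j] == raw[i, j] * bias[i] * bias[j]`` on unmasked bins; masked
    rows/columns are NaN. ``mask`` is True where a bin was excluded as sparse.
    """

    values: np.ndarray
    bias: np.ndarray
    mask: np.ndarray
    chrom: str = "chrU"
    bin_size: int = 1

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def unmasked(self) -> np.ndarray:
        return ~self.mask


@dataclass
class ExpectedProfile:
    """Mean balanced contact at each bin distance; NaN where unobserved."""

    values: np.ndarray  # e(d) for d = 0 .. n_bins-1

    def at(self, d: int | np.ndarray) -> np.ndarray:
        return self.values[d]

    def matrix(self, n_bins: int) -> np.ndarray:
        d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        return self.values[d]


def _as_dense(matrix) -> tuple[np.ndarray, str, int]:
    if isinstance(matrix, ContactMatrix):
        return matrix.to_dense(), matrix.chrom, matrix.bin_size
    m = np.asarray(matrix, dtype=float)
    return m, "chrU", 1


def balance(matrix, tol: float = 1e-8, max_iter: int = 1000,
            min_nnz: int = 10, chrom: str | None = None,
            bin_size: int | None = None) -> BalancedMatrix:
    """Iterative proportional fitting to equal row sums.

    Bins with fewer than ``min_nnz`` nonzero entries are masked before
    fitting.  Convergence is reached when every unmasked row sum is within
    ``tol`` (relative) of the mean row sum.
    """
    raw, m_chrom, m_bin = _as_dense(matrix)
    if chrom is not None:
        m_chrom = chrom
    if bin_size is not None:
        m_bin = bin_size
    n = raw.shape[0]
    if raw.shape != (n, n):
        raise ValidationError("matrix must be square")
    if not np.allclose(raw, raw.T):
        raise ValidationError("matrix must be symmetric")
    if (raw < 0).any():
        raise ValidationError("matrix must be non-negative")

    nnz = (raw > 0).sum(axis=1)
    mask = nnz < min(min_nnz, n)
    bias = np.ones(n)
    bias[mask] = np.nan

    work = raw[np.ix_(~mask, ~mask)].astype(float)
    if work.size == 0:
        values = np.full((n, n), np.nan)
        return BalancedMatrix(values, bias, mask, m_chrom, m_bin)

    b = np.ones(work.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        cur = work * np.outer(b, b)
        rows = cur.sum(axis=1)
        target = rows.mean()
        if target == 0:
            raise ConvergenceError("all unmasked rows sum to zero", residual=np.inf)
        residual = float(np.max(np.abs(rows / target - 1.0)))
        if residual <= tol:
            break
        scale = np.sqrt(rows / target)
        scale[scale == 0] = 1.0
        b = b / scale
    else:
        raise ConvergenceError(
            f"balancing did not converge after {max_iter} iterations",
            residual=residual,
        )

    bias[~mask] = b
    values = np.full((n, n), np.nan)
    values[np.ix_(~mask, ~mask)] = work * np.outer(b, b)
    return BalancedMatrix(values, bias, mask, m_chrom, m_bin)


def expected_by_distance(balanced: BalancedMatrix) -> ExpectedProfile:
    """Mean balanced contact over unmasked pairs at every bin distance."""
    n = balanced.n_bins
    good = balanced.unmasked()
    e = np.full(n, np.nan)
    v = balanced.values
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        ok = good[i] & good[j]
        if ok.any():
            e[d] = np.nanmean(v[i[ok], j[ok]])
    return ExpectedProfile(e)


def observed_over_expected(balanced: BalancedMatrix, expected: ExpectedProfile,
                           mode: str = "ratio") -> np.ndarray:
    """O/E ratio (default) or O-E difference; masked bins propagate as NaN."""
    if mode not in ("ratio", "difference"):
        raise ValidationError(f"unknown O/E mode {mode!r}")
    n = balanced.n_bins
    emat = expected.matrix(n)
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = balanced.values / emat
        oe[emat == 0] = np.nan
    else:
        oe = balanced.values - emat
    return oe


def pearson_matrix(oe: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation of an O/E matrix.

    Masked bins (all-NaN rows) stay NaN; rows with zero variance over the
    unmasked columns are masked too. Diagonal of valid rows is exactly 1.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    valid = ~np.all(np.isnan(oe), axis=1)
    out = np.full((n, n), np.nan)
    if valid.sum() < 2:
        return out
    sub = oe[np.ix_(valid, valid)]
    # columns with any NaN among valid rows are dropped pairwise-complete-ish:
    # we require columns observed for all valid rows, which holds after masking.
    col_ok = ~np.any(np.isnan(sub), axis=0)
    sub = sub[:, col_ok]
    sd = sub.std(axis=1)
    var_ok = sd > 0
    idx = np.flatnonzero(valid)[var_ok]
    if idx.size < 2:
        return out
    r = np.corrcoef(sub[var_ok])
    np.fill_diagonal(r, 1.0)
    out[np.ix_(idx, idx)] = r
    return out
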