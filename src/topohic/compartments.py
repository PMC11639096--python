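"""A/B compartment annotation.

The leading principal axes of the column-centered Pearson correlation matrix
are scored (each eigenvector x each sign) against a reference active-chromatin
interval set by bp Jaccard; the best-scoring signed eigenvector is returned so
that positive values mark type-A bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import TopoHiCError, ValidationError
from .io_formats import IntervalRecord

__all__ = [
    "EigenTrack",
    "top_eigenvectors",
    "merge_intervals",
    "interval_jaccard",
    "bins_above_threshold_to_intervals",
    "select_and_orient",
]


@dataclass
class EigenTrack:
    """Top eigenvector tracks (rows) with selection metadata.

    ``values`` is (k, n_bins) with NaN at masked bins; each row unit-norm over
    the unmasked bins. ``jaccards`` is filled by :func:`select_and_orient`
    with shape (k, 2) for the (+, -) sign of each eigenvector.
    """

    values: np.ndarray
    eigenvalues: np.ndarray
    selected_index: int | None = None
    orientation_sign: int | None = None
    jaccards: np.ndarray | None = None

    @property
    def oriented(self) -> np.ndarray:
        if self.selected_index is None:
            raise TopoHiCError("track not yet oriented; run select_and_orient")
        return self.orientation_sign * self.values[self.selected_index]


def top_eigenvectors(pearson: np.ndarray, k: int = 3) -> EigenTrack:
    """Leading principal axes of the column-centered correlation matrix.

    Masked (all-NaN) bins are dropped before the decomposition and carry NaN
    in the returned tracks. Rows are ordered by descending eigenvalue.
    """
    pearson = np.asarray(pearson, dtype=float)
    n = pearson.shape[0]
    valid = ~np.all(np.isnan(pearson), axis=1)
    sub = pearson[np.ix_(valid, valid)]
    if k > sub.shape[0]:
        raise ValidationError(
            f"requested {k} eigenvectors from {sub.shape[0]} unmasked bins")
    centered = sub - sub.mean(axis=0, keepdims=True)
    # right singular vectors of the centered matrix = principal axes
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    values = np.full((k, n), np.nan)
    values[:, valid] = vt[:k]
    eigenvalues = (s[:k] ** 2) / max(sub.shape[0] - 1, 1)
    return EigenTrack(values=values, eigenvalues=eigenvalues)


def merge_intervals(intervals: list[IntervalRecord],
                    warn_on_overlap: bool = False) -> list[IntervalRecord]:
    """Merge overlapping/adjacent intervals (single chromosome per call)."""
    if not intervals:
        return []
    chroms = {r.chrom for r in intervals}
    if len(chroms) > 1:
        raise ValidationError(f"intervals span multiple chromosomes: {chroms}")
    ordered = sorted(intervals, key=lambda r: r.start)
    merged = [ordered[0]]
    overlapped = False
    for r in ordered[1:]:
        last = merged[-1]
        if r.start <= last.end:
            if r.start < last.end:
                overlapped = True
            merged[-1] = IntervalRecord(last.chrom, last.start, max(last.end, r.end))
        else:
            merged.append(r)
    if overlapped and warn_on_overlap:
        warnings.warn("overlapping intervals within one set were auto-merged",
                      stacklevel=2)
    return merged


def interval_jaccard(set_a: list[IntervalRecord],
                     set_b: list[IntervalRecord]) -> float:
    """bp-level Jaccard: |intersection| / |union|; 0 when the union is empty."""
    a = merge_intervals(set_a, warn_on_overlap=True)
    b = merge_intervals(set_b, warn_on_overlap=True)
    len_a = sum(r.length for r in a)
    len_b = sum(r.length for r in b)
    inter = 0
    ia = ib = 0
    while ia < len(a) and ib < len(b):
        lo = max(a[ia].start, b[ib].start)
        hi = min(a[ia].end, b[ib].end)
        if hi > lo:
            inter += hi - lo
        if a[ia].end <= b[ib].end:
            ia += 1
        else:
            ib += 1
    union = len_a + len_b - inter
    return inter / union if union else 0.0


def bins_above_threshold_to_intervals(values: np.ndarray, chrom: str,
                                      bin_size: int,
                                      threshold: float = 0.0) -> list[IntervalRecord]:
    """Merged intervals over bins with value strictly above threshold (NaN skipped)."""
    flags = np.zeros(values.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags[~np.isnan(values)] = values[~np.isnan(values)] > threshold
    intervals = []
    start = None
    for i, on in enumerate(flags):
        if on and start is None:
            start = i
        elif not on and start is not None:
            intervals.append(IntervalRecord(chrom, start * bin_size, i * bin_size))
            start = None
    if start is not None:
        intervals.append(IntervalRecord(chrom, start * bin_size, flags.size * bin_size))
    return intervals


def select_and_orient(eigs: EigenTrack, reference: list[IntervalRecord],
                      chrom: str, bin_size: int,
                      threshold: float = 0.0) -> EigenTrack:
    """Pick the (eigenvector, sign) whose above-threshold bins best match the
    reference by Jaccard; ties go to the lower eigenvector index, then '+'.

    The oriented track is ``sign * eigenvector`` so positive values mark A.
    """
    k = eigs.values.shape[0]
    jac = np.zeros((k, 2))
    for e in range(k):
        for s_idx, sign in enumerate((1, -1)):
            intervals = bins_above_threshold_to_intervals(
                sign * eigs.values[e], chrom, bin_size, threshold)
            jac[e, s_idx] = interval_jaccard(intervals, reference)
    if np.all(jac == 0):
        raise TopoHiCError("reference uninformative: all six Jaccard scores are zero")
    best = np.unravel_index(np.argmax(jac), jac.shape)  # first max: low e, then +
    eigs.selected_index = int(best[0])
    eigs.orientation_sign = 1 if best[1] == 0 else -1
    eigs.jaccards = jac
    return eigs
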