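"""Differential boundary testing, a differential-expression stand-in, and
boundary-gene association (reldist / closest / windowed assignment).

Per-position and per-gene tests are Welch t (unequal variances, Satterthwaite
degrees of freedom) with Benjamini-Hochberg adjustment; the expression test
runs on log2-CPM with a 0.5 pseudocount. This is a documented stand-in for
moderated-variance pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DifferentialBoundaryResult",
    "DEGeneResult",
    "welch_t_two_sided",
    "bh_adjust",
    "percent_significant",
    "differential_boundaries",
    "de_genes",
    "reldist",
    "closest_boundaries",
    "window_assign",
    "count_de_near_differential",
]


@dataclass
class DifferentialBoundaryResult:
    position: int
    mean_a: float
    mean_b: float
    z_diff: float   # mean_a - mean_b
    t: float
    p: float
    padj: float


@dataclass
class DEGeneResult:
    gene: str
    log2_fc: float
    p: float
    padj: float
    chrom: str
    start: int
    end: int


def welch_t_two_sided(x, y) -> tuple[float, float]:
    """Welch t statistic and two-sided p with Satterthwaite df.

    Degenerate variance conventions: both groups constant and equal -> p = 1;
    constant but unequal -> p = 0 (flagged by t = +/- inf).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    se2 = vx / x.size + vy / y.size
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order restored, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def percent_significant(n_significant: int, n_tested: int) -> float:
    """Summary percentage, rounded to one decimal place."""
    if n_tested <= 0:
        raise ValidationError("n_tested must be positive")
    return round(100.0 * n_significant / n_tested, 1)


def differential_boundaries(feature_matrix: np.ndarray, sample_groups,
                            group_a: str, group_b: str, alpha: float = 0.05
                            ) -> tuple[list[DifferentialBoundaryResult], dict]:
    """Welch t per boundary position between two subgroups, BH over all
    tested positions (those defined in >= 2 samples per group)."""
    groups = np.asarray(sample_groups)
    x = np.asarray(feature_matrix, dtype=float)
    rows_a = np.flatnonzero(groups == group_a)
    rows_b = np.flatnonzero(groups == group_b)
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValidationError(
            f"group absent from metadata: {group_a if rows_a.size == 0 else group_b}")
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValidationError("need >= 2 samples per group")
    tested, stats_rows = [], []
    for pos in range(x.shape[1]):
        a = x[rows_a, pos]
        b = x[rows_b, pos]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        t, p = welch_t_two_sided(a, b)
        tested.append(pos)
        stats_rows.append((float(a.mean()), float(b.mean()), t, p))
    if not tested:
        raise ValidationError("no testable positions")
    padj = bh_adjust([r[3] for r in stats_rows])
    results = [
        DifferentialBoundaryResult(
            position=pos, mean_a=ma, mean_b=mb, z_diff=ma - mb,
            t=t, p=p, padj=float(q))
        for pos, (ma, mb, t, p), q in zip(tested, stats_rows, padj)
    ]
    n_sig = int(sum(r.padj < alpha for r in results))
    summary = {
        "n_tested": len(results),
        "n_significant": n_sig,
        "percent_significant": percent_significant(n_sig, len(results)),
        "group_a": group_a,
        "group_b": group_b,
        "alpha": alpha,
    }
    return results, summary


def de_genes(counts: pd.DataFrame, sample_groups, group_a: str, group_b: str,
             positions: pd.DataFrame | None = None,
             alpha: float = 0.05) -> list[DEGeneResult]:
    """Welch t on log2-CPM (0.5 pseudocount) per gene, BH adjusted."""
    groups = np.asarray(sample_groups)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    keep = lib > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {np.sum(~keep)} samples with zero library size",
                      stacklevel=2)
    mat = counts.to_numpy(dtype=float)[:, keep]
    groups = groups[keep]
    lib = lib[keep]
    logcpm = np.log2(1e6 * mat / lib[None, :] + 0.5)
    rows_a = np.flatnonzero(groups == group_a)
    rows_b = np.flatnonzero(groups == group_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValidationError("need >= 2 samples per group")
    genes, tvals, pvals, fcs = [], [], [], []
    for g, gene in enumerate(counts.index):
        a = logcpm[g, rows_a]
        b = logcpm[g, rows_b]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            continue  # e.g. an all-zero gene: undefined, excluded
        t, p = welch_t_two_sided(a, b)
        genes.append(gene)
        tvals.append(t)
        pvals.append(p)
        fcs.append(float(a.mean() - b.mean()))
    padj = bh_adjust(pvals)
    out = []
    for gene, fc, p, q in zip(genes, fcs, pvals, padj):
        chrom, start, end = ".", -1, -1
        if positions is not None and gene in positions.index:
            row = positions.loc[gene]
            chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
        out.append(DEGeneResult(str(gene), fc, float(p), float(q), chrom, start, end))
    return out


def reldist(gene_midpoints, boundary_bps) -> np.ndarray:
    """Relative distance of each point to its nearest flanking boundary,
    scaled by the flanking gap: values in [0, 0.5]; points outside the
    boundary span are excluded."""
    bounds = np.sort(np.asarray(boundary_bps, dtype=float))
    if bounds.size < 2:
        raise ValidationError("reldist needs >= 2 boundaries")
    g = np.asarray(gene_midpoints, dtype=float)
    inside = (g >= bounds[0]) & (g <= bounds[-1])
    g = g[inside]
    idx = np.clip(np.searchsorted(bounds, g, side="right") - 1, 0, bounds.size - 2)
    left = bounds[idx]
    right = bounds[idx + 1]
    span = right - left
    r = np.minimum(g - left, right - g) / span
    return r


def reldist_histogram(values: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Histogram over [0, 0.5] with the uniform expectation per bin."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    hist, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({
        "bin_lo": edges[:-1],
        "bin_hi": edges[1:],
        "count": hist,
        "fraction": hist / max(values.size, 1),
        "expected_fraction": np.full(n_bins, 1.0 / n_bins),
    })


def closest_boundaries(genes: pd.DataFrame, boundary_bps) -> pd.DataFrame:
    """Nearest boundary at or before each gene start (upstream) and at or
    after each gene end (downstream); a boundary inside the gene body counts
    as distance 0 on both sides."""
    bounds = np.sort(np.asarray(boundary_bps, dtype=np.int64))
    rows = []
    for gene, row in genes.iterrows():
        start, end = int(row["start"]), int(row["end"])
        inside = bounds[(bounds >= start) & (bounds <= end)]
        if inside.size:
            rows.append({"gene": gene, "upstream": int(inside[0]),
                         "upstream_dist": 0, "downstream": int(inside[0]),
                         "downstream_dist": 0})
            continue
        ups = bounds[bounds <= start]
        dns = bounds[bounds >= end]
        rows.append({
            "gene": gene,
            "upstream": int(ups[-1]) if ups.size else None,
            "upstream_dist": int(ups[-1] - start) if ups.size else None,
            "downstream": int(dns[0]) if dns.size else None,
            "downstream_dist": int(dns[0] - end) if dns.size else None,
        })
    return pd.DataFrame(rows).set_index("gene")


def window_assign(genes: pd.DataFrame,
                  boundary_results: list[DifferentialBoundaryResult],
                  bin_size: int, window: int = 1_000_000) -> pd.DataFrame:
    """For each gene, the most significantly differential boundary within
    +/- window of the gene span (ties: smaller p, then nearer, then smaller
    coordinate); None when no boundary is in range."""
    rows = []
    for gene, row in genes.iterrows():
        start, end = int(row["start"]), int(row["end"])
        best = None
        best_key = None
        for r in boundary_results:
            bp = (r.position + 1) * bin_size
            if bp < start - window or bp > end + window:
                continue
            dist = max(start - bp, bp - end, 0)
            key = (r.padj, r.p, dist, bp)
            if best_key is None or key < best_key:
                best, best_key = r, key
        rows.append({
            "gene": gene,
            "boundary_position": best.position if best else None,
            "boundary_bp": (best.position + 1) * bin_size if best else None,
            "padj": best.padj if best else None,
        })
    return pd.DataFrame(rows).set_index("gene")


def count_de_near_differential(de_results: list[DEGeneResult],
                               boundary_results: list[DifferentialBoundaryResult],
                               genes: pd.DataFrame, bin_size: int,
                               alpha: float = 0.05) -> tuple[int, pd.DataFrame]:
    """Count DE genes whose closest upstream or downstream boundary is
    significantly differential; returns (count, labeled gene table)."""
    sig_bounds = {(r.position + 1) * bin_size
                  for r in boundary_results if r.padj < alpha}
    all_bps = [(r.position + 1) * bin_size for r in boundary_results]
    de_sig = [r for r in de_results if r.padj < alpha]
    if not de_sig or not all_bps:
        return 0, pd.DataFrame(columns=["gene", "upstream_diff", "downstream_diff"])
    table = closest_boundaries(
        genes.loc[[r.gene for r in de_sig if r.gene in genes.index]], all_bps)
    rows = []
    count = 0
    for gene, row in table.iterrows():
        up = row["upstream"] in sig_bounds if row["upstream"] is not None else False
        dn = row["downstream"] in sig_bounds if row["downstream"] is not None else False
        rows.append({"gene": gene, "upstream_diff": up, "downstream_diff": dn})
        count += bool(up or dn)
    return count, pd.DataFrame(rows)
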