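"""Focal chromatin-loop calling.

Each candidate pixel (i, j) is compared to four local neighborhoods (donut,
lower-left quadrant, horizontal stripe, vertical stripe, all excluding the
central p-box): the neighborhood expected is

    lambda_N = e(|i-j|) * sum_N M(x, y) / sum_N e(|x-y|)

and significance is an upper-tail Poisson test P(X >= round(observed)).
Benjamini-Hochberg correction runs within log-spaced distance strata per
neighborhood; surviving pixels must also clear per-neighborhood fold-change
thresholds, and 8-connected survivors merge into a single call at the
maximum-observed pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate
from scipy.stats import poisson

from .errors import ValidationError
from .io_formats import IntervalPairRecord, IntervalRecord
from .matrix_ops import BalancedMatrix, ExpectedProfile

__all__ = [
    "LoopCall",
    "neighborhood_kernels",
    "local_expecteds",
    "loop_test",
    "call_loops",
    "loop_union",
    "rescore_at_union",
    "annotate_anchors",
    "bh_within_strata",
    "binary_loop_matrix",
]

NEIGHBORHOODS = ("donut", "lower_left", "horizontal", "vertical")
DEFAULT_ENRICH = {"donut": 1.75, "lower_left": 1.75, "horizontal": 1.5, "vertical": 1.5}


@dataclass(frozen=True)
class LoopCall:
    chrom: str
    i: int
    j: int
    resolution: int
    observed: float
    lambdas: dict[str, float]
    pvalues: dict[str, float]
    qvalues: dict[str, float]

    @property
    def anchor1(self) -> IntervalRecord:
        return IntervalRecord(self.chrom, self.i * self.resolution,
                              (self.i + 1) * self.resolution)

    @property
    def anchor2(self) -> IntervalRecord:
        return IntervalRecord(self.chrom, self.j * self.resolution,
                              (self.j + 1) * self.resolution)

    def key(self) -> tuple:
        return (self.chrom, self.i * self.resolution, self.j * self.resolution)

    def to_pair(self) -> IntervalPairRecord:
        scores = (self.observed, self.lambdas["donut"], self.lambdas["lower_left"],
                  self.lambdas["horizontal"], self.lambdas["vertical"],
                  self.qvalues["donut"], self.qvalues["lower_left"],
                  self.qvalues["horizontal"], self.qvalues["vertical"])
        return IntervalPairRecord(self.anchor1, self.anchor2, name="loop",
                                  scores=scores)


def neighborhood_kernels(p: int = 2, w: int = 5) -> dict[str, np.ndarray]:
    """Boolean footprints of the four neighborhoods in offset space, each of
    shape (2w+1, 2w+1), excluding the central (2p+1)^2 p-box."""
    if not 0 <= p < w:
        raise ValidationError("need 0 <= p < w")
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    cheb = np.maximum(np.abs(di), np.abs(dj))
    pbox = cheb <= p
    donut = (cheb > p) & (cheb <= w)
    lower_left = (di >= 1) & (di <= w) & (dj <= -1) & (dj >= -w) & ~pbox
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) <= w) & ~pbox
    vertical = (np.abs(di) <= w) & (np.abs(dj) <= 1) & ~pbox
    return {"donut": donut, "lower_left": lower_left,
            "horizontal": horizontal, "vertical": vertical}


def _lambda_fields(balanced: BalancedMatrix, expected: ExpectedProfile,
                   p: int, w: int) -> dict[str, np.ndarray]:
    """lambda_N at every pixel via 2-D correlation (NaN where undefined)."""
    n = balanced.n_bins
    m = balanced.values
    valid = np.isfinite(m)
    emat = expected.matrix(n)
    e_ok = np.isfinite(emat)
    both = valid & e_ok
    m0 = np.where(both, m, 0.0)
    e0 = np.where(both, emat, 0.0)
    fields = {}
    for name, kernel in neighborhood_kernels(p, w).items():
        k = kernel.astype(float)
        sum_m = correlate(m0, k, mode="constant", cval=0.0)
        sum_e = correlate(e0, k, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam = emat * sum_m / sum_e
        lam[sum_e == 0] = np.nan
        fields[name] = lam
    return fields


def local_expecteds(balanced: BalancedMatrix, expected: ExpectedProfile,
                    i: int, j: int, p: int = 2, w: int = 5) -> dict[str, float]:
    """The four neighborhood expecteds at a single pixel."""
    if j - i <= w:
        raise ValidationError("pixel too close to the diagonal for this w")
    n = balanced.n_bins
    m = balanced.values
    emat = expected.matrix(n)
    out = {}
    for name, kernel in neighborhood_kernels(p, w).items():
        offs = np.argwhere(kernel) - w
        xs, ys = i + offs[:, 0], j + offs[:, 1]
        ok = (xs >= 0) & (xs < n) & (ys >= 0) & (ys < n)
        xs, ys = xs[ok], ys[ok]
        mv = m[xs, ys]
        ev = emat[xs, ys]
        good = np.isfinite(mv) & np.isfinite(ev)
        if not good.any() or ev[good].sum() == 0:
            out[name] = np.nan
        else:
            out[name] = float(emat[i, j] * mv[good].sum() / ev[good].sum())
    return out


def loop_test(observed: float, lam: float) -> float:
    """Upper-tail Poisson p-value P(X >= round(observed) | rate lam)."""
    if not np.isfinite(lam) or lam <= 0:
        return np.nan
    k = int(round(observed))
    if k <= 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def bh_within_strata(pvals: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up applied separately within each stratum."""
    q = np.full_like(pvals, np.nan, dtype=float)
    for s in np.unique(strata):
        idx = np.flatnonzero((strata == s) & np.isfinite(pvals))
        if idx.size == 0:
            continue
        p = pvals[idx]
        order = np.argsort(p)
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q[idx[order]] = np.minimum(adj, 1.0)
    return q


def _distance_strata(d: np.ndarray, d_min: int) -> np.ndarray:
    """Log2-spaced distance bands starting at d_min."""
    return np.floor(np.log2(np.maximum(d, d_min) / d_min)).astype(int)


def call_loops(balanced: BalancedMatrix, expected: ExpectedProfile,
               p: int = 2, w: int = 5, fdr: float = 0.1,
               enrich: dict[str, float] | None = None,
               d_min: int | None = None, d_max: int | None = None) -> list[LoopCall]:
    """Call loops on one balanced matrix at its native resolution."""
    enrich = dict(DEFAULT_ENRICH if enrich is None else enrich)
    n = balanced.n_bins
    if d_min is None:
        d_min = w + 1
    d_min = max(d_min, w + 1)
    if d_max is None:
        d_max = n - 1
    fields = _lambda_fields(balanced, expected, p, w)
    iu, ju = np.triu_indices(n)
    d = ju - iu
    keep = (d >= d_min) & (d <= d_max)
    iu, ju, d = iu[keep], ju[keep], d[keep]
    obs = balanced.values[iu, ju]
    ok = np.isfinite(obs)
    for name in NEIGHBORHOODS:
        ok &= np.isfinite(fields[name][iu, ju])
    iu, ju, d, obs = iu[ok], ju[ok], d[ok], obs[ok]
    if iu.size == 0:
        return []
    strata = _distance_strata(d, d_min)
    k_obs = np.round(obs).astype(int)
    sig = np.ones(iu.size, dtype=bool)
    pvals_by, qvals_by, lam_by = {}, {}, {}
    for name in NEIGHBORHOODS:
        lam = fields[name][iu, ju]
        pv = poisson.sf(k_obs - 1, lam)
        pv = np.where(k_obs <= 0, 1.0, pv)
        qv = bh_within_strata(pv, strata)
        sig &= qv <= fdr
        sig &= obs >= enrich[name] * lam
        pvals_by[name], qvals_by[name], lam_by[name] = pv, qv, lam
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    # merge 8-connected significant pixels; one call per component at max obs
    pix = {(int(iu[k]), int(ju[k])): int(k) for k in idx}
    seen: set[tuple[int, int]] = set()
    calls = []
    for start in pix:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            x, y = stack.pop()
            comp.append((x, y))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nb = (x + dx, y + dy)
                    if nb in pix and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        best = max(comp, key=lambda t: balanced.values[t[0], t[1]])
        k = pix[best]
        calls.append(LoopCall(
            chrom=balanced.chrom, i=best[0], j=best[1],
            resolution=balanced.bin_size, observed=float(obs[k]),
            lambdas={nm: float(lam_by[nm][k]) for nm in NEIGHBORHOODS},
            pvalues={nm: float(pvals_by[nm][k]) for nm in NEIGHBORHOODS},
            qvalues={nm: float(qvals_by[nm][k]) for nm in NEIGHBORHOODS},
        ))
    calls.sort(key=lambda c: (c.i, c.j))
    return calls


def call_loops_multires(inputs: dict[int, tuple[BalancedMatrix, ExpectedProfile]],
                        **kwargs) -> list[LoopCall]:
    """Call at each resolution; where anchors overlap in bp keep the finer call."""
    if not inputs:
        raise ValidationError("no resolutions available")
    final: list[LoopCall] = []
    for res in sorted(inputs):  # finer first
        bal, exp = inputs[res]
        for call in call_loops(bal, exp, **kwargs):
            clash = False
            for kept in final:
                if (_bp_overlap(call.anchor1, kept.anchor1)
                        and _bp_overlap(call.anchor2, kept.anchor2)):
                    clash = True
                    break
            if not clash:
                final.append(call)
    final.sort(key=lambda c: (c.resolution, c.i, c.j))
    return final


def _bp_overlap(a: IntervalRecord, b: IntervalRecord) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def loop_union(calls_by_sample: dict[str, list[LoopCall]]) -> list[tuple]:
    """Deduplicated union of call pixels: sorted (chrom, start1, start2, res)."""
    keys = {}
    for calls in calls_by_sample.values():
        for c in calls:
            keys[c.key() + (c.resolution,)] = (c.i, c.j, c.resolution)
    return sorted(keys.values(), key=lambda t: (t[2], t[0], t[1]))


def rescore_at_union(balanced: BalancedMatrix, expected: ExpectedProfile,
                     union: list[tuple], p: int = 2, w: int = 5) -> list[dict]:
    """Observed, the four lambdas, and O/lambda_donut at every union pixel
    (no thresholding)."""
    fields = _lambda_fields(balanced, expected, p, w)
    out = []
    for (i, j, _res) in union:
        obs = balanced.values[i, j] if 0 <= i < balanced.n_bins and 0 <= j < balanced.n_bins else np.nan
        row = {"i": i, "j": j, "observed": float(obs)}
        for name in NEIGHBORHOODS:
            row[f"lambda_{name}"] = float(fields[name][i, j]) if np.isfinite(obs) else np.nan
        donut = row["lambda_donut"]
        row["oe_donut"] = float(obs / donut) if donut and np.isfinite(donut) and donut > 0 else np.nan
        out.append(row)
    return out


def annotate_anchors(loops: list[LoopCall],
                     promoters: list[IntervalRecord]) -> tuple[float, list[dict]]:
    """Fraction of loop anchors overlapping a promoter (>= 1 bp), plus labels."""
    if not loops:
        return float("nan"), []
    labels = []
    n_in = 0
    for c in loops:
        for which, anchor in (("anchor1", c.anchor1), ("anchor2", c.anchor2)):
            hit = any(_bp_overlap(anchor, pr) for pr in promoters)
            n_in += hit
            labels.append({"i": c.i, "j": c.j, "anchor": which, "promoter": bool(hit)})
    return n_in / (2 * len(loops)), labels


def binary_loop_matrix(calls_by_sample: dict[str, list[LoopCall]],
                       union: list[tuple]) -> np.ndarray:
    """Samples x union-pixels presence matrix (sample order = dict order)."""
    index = {(i, j, r): k for k, (i, j, r) in enumerate(union)}
    out = np.zeros((len(calls_by_sample), len(union)))
    for row, (_sid, calls) in enumerate(calls_by_sample.items()):
        for c in calls:
            k = index.get((c.i, c.j, c.resolution))
            if k is not None:
                out[row, k] = 1.0
    return out
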