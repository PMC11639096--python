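"""Synthetic Hi-C cohort generator with planted ground truth.

One simulated chromosome per cohort. Expected contact intensity between bins
``i <= j`` at distance ``d = j - i`` is

    mu_ij = L * Z^-1 * (1 + d)^-alpha * c_ij * t_ij * l_ij

where ``c_ij`` is the compartment checkerboard factor (``1 + gamma`` for bins
sharing a compartment label, ``1 - gamma`` otherwise), ``t_ij`` the TAD factor
(``1 + tau`` within a TAD; for pairs spanning boundaries the enrichment is
attenuated by ``prod(1 - beta)`` over the spanned boundaries, so ``beta = 1``
fully insulates and ``beta = 0`` makes the boundary invisible), ``l_ij`` a
Gaussian bump at planted loop anchors, and ``Z`` normalizes the total expected
count to the library size ``L``.  Raw counts are Poisson draws; optional SV
operators (tandem duplication, inversion, translocation-style block) are
applied to ``mu`` before sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    ContactMatrix,
    IntervalRecord,
    make_bins,
    serialize_contacts,
    serialize_counts,
    serialize_intervals,
)

__all__ = [
    "LoopSpec",
    "SVSpec",
    "DEGeneSpec",
    "CohortSpec",
    "PlantedTruth",
    "Cohort",
    "default_spec",
    "compartment_labels",
    "expected_intensity",
    "simulate_contact_map",
    "gene_table",
    "simulate_expression",
    "simulate_reference_track",
    "simulate_cohort",
    "write_cohort",
]

DEFAULT_GROUPS = (("SHH", 7), ("G3", 8), ("G4", 13), ("WNT", 1))


@dataclass(frozen=True)
class LoopSpec:
    """Planted focal loop between anchor bins ``a < b`` with amplitude >= 0."""

    a: int
    b: int
    amplitude: float = 2.0


@dataclass(frozen=True)
class SVSpec:
    """Planted structural variant.

    kind: "tandem_duplication" | "inversion" | "translocation"
    span: (start_bin, end_bin) for duplication/inversion
    loci: (bin1, bin2) breakpoints for translocation
    """

    kind: str
    span: tuple[int, int] | None = None
    loci: tuple[int, int] | None = None
    amplitude: float = 5.0
    extent: int = 40  # bins of elevated block beyond a translocation breakpoint


@dataclass(frozen=True)
class DEGeneSpec:
    """A gene with group-specific expression fold-changes, optionally pinned
    immediately downstream of a boundary position (edge between bins p, p+1)."""

    gene: str
    folds: dict[str, float]
    boundary_position: int | None = None


@dataclass
class CohortSpec:
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    chrom: str = "chrS"
    chrom_length: int = 25_000_000
    bin_size: int = 50_000
    decay_exponent: float = 1.0
    compartment_block_len: int = 2_000_000
    compartment_contrast: float = 0.3
    tad_intervals: tuple[tuple[int, int], ...] = ()
    tad_contrast: float = 1.0
    boundary_strengths: dict[str, tuple[float, ...]] = field(default_factory=dict)
    loop_anchors: tuple[LoopSpec, ...] = ()
    loop_sigma: float = 0.7
    library_size: float = 2_000_000.0
    sv_specs: dict[str, tuple[SVSpec, ...]] = field(default_factory=dict)
    n_genes: int = 200
    expr_mean: float = 100.0
    expr_dispersion: float = 0.1
    de_genes: tuple[DEGeneSpec, ...] = ()
    seed: int = 0

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.bin_size)

    @property
    def boundary_positions(self) -> list[int]:
        """Interior TAD edges as boundary positions (edge between bins p, p+1)."""
        pos = []
        for (s1, e1), (s2, _e2) in zip(self.tad_intervals, self.tad_intervals[1:]):
            if e1 == s2:
                pos.append(e1 - 1)
        return pos

    def validate(self) -> None:
        if not 0 <= self.compartment_contrast < 1:
            raise ValidationError("compartment_contrast must lie in [0, 1)")
        if self.tad_contrast < 0:
            raise ValidationError("tad_contrast must be >= 0")
        last_end = -1
        for s, e in self.tad_intervals:
            if not (0 <= s < e <= self.n_bins):
                raise ValidationError(f"TAD interval ({s}, {e}) out of range")
            if s < last_end:
                raise ValidationError("TAD intervals must be sorted and disjoint")
            last_end = e
        n_bound = len(self.boundary_positions)
        for group, betas in self.boundary_strengths.items():
            if len(betas) != n_bound:
                raise ValidationError(
                    f"group {group}: {len(betas)} boundary strengths for "
                    f"{n_bound} boundaries"
                )
            if any(not 0 <= b <= 1 for b in betas):
                raise ValidationError("boundary strengths must lie in [0, 1]")
        for lp in self.loop_anchors:
            if lp.amplitude < 0:
                raise ValidationError("loop amplitude must be >= 0")
            if not 0 <= lp.a < lp.b < self.n_bins:
                raise ValidationError(f"loop anchors ({lp.a}, {lp.b}) out of range")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for group, n in self.groups:
            for k in range(n):
                rows.append({"sample_id": f"{group}_{k + 1:02d}", "subgroup": group})
        return pd.DataFrame(rows)


@dataclass
class PlantedTruth:
    compartment_labels: np.ndarray
    tad_intervals: tuple[tuple[int, int], ...]
    boundary_positions: list[int]
    boundary_strengths: dict[str, tuple[float, ...]]
    loop_anchors: tuple[LoopSpec, ...]
    sv_records: tuple[SVSpec, ...]
    de_genes: tuple[DEGeneSpec, ...]

    def to_json(self) -> str:
        payload = {
            "compartment_labels": "".join(self.compartment_labels.tolist()),
            "tad_intervals": [list(t) for t in self.tad_intervals],
            "boundary_positions": self.boundary_positions,
            "boundary_strengths": {g: list(b) for g, b in self.boundary_strengths.items()},
            "loop_anchors": [asdict(l) for l in self.loop_anchors],
            "sv_records": [asdict(s) for s in self.sv_records],
            "de_genes": [asdict(d) for d in self.de_genes],
        }
        return json.dumps(payload, indent=2)


def default_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The stock desk-scale cohort: 500 bins of 50 kb, 25 TADs of 20 bins,
    10 boundaries with subgroup-specific strengths (delta-beta = 0.6), five
    shared loops, alternating 40-bin compartment blocks."""
    n_tads = 25
    width = 10  # 500 bins / 25 TADs / ... each TAD 20 bins
    tads = tuple((i * 20, (i + 1) * 20) for i in range(n_tads))
    n_bound = n_tads - 1
    base = [0.7] * n_bound
    # 10 differential boundaries split 3/3/4 between the three large subgroups.
    # Even indices only: odd-indexed TAD edges coincide with compartment block
    # flips (both fall on 40-bin multiples) and saturate the insulation signal.
    diff_idx = [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
    strengths: dict[str, list[float]] = {}
    for group, _ in DEFAULT_GROUPS:
        strengths[group] = list(base)
    for j, b_idx in enumerate(diff_idx):
        if j < 3:
            hot = "SHH"
        elif j < 6:
            hot = "G3"
        else:
            hot = "G4"
        # hot/cold straddle the steep part of the insulation response curve
        # (near-1 strengths saturate the rank statistic at realistic depth)
        for group, _ in DEFAULT_GROUPS:
            strengths[group][b_idx] = 0.75 if group == hot else 0.15
    loops = tuple(
        LoopSpec(a, b, 2.0)
        for a, b in [(30, 45), (110, 140), (210, 230), (310, 350), (410, 425)]
    )
    # DE genes pinned just downstream of five of the differential boundaries
    de = tuple(
        DEGeneSpec(
            gene=f"DE_{k}",
            folds={"G4": 4.0},
            boundary_position=(b_idx + 1) * 20 - 1,
        )
        for k, b_idx in enumerate([4, 8, 12, 16, 20])
    )
    spec = CohortSpec(
        tad_intervals=tads,
        boundary_strengths={g: tuple(v) for g, v in strengths.items()},
        loop_anchors=loops,
        de_genes=de,
        seed=seed,
    )
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise ValidationError(f"unknown CohortSpec field {key!r}")
        setattr(spec, key, _coerce_field(key, value))
    spec.validate()
    return spec


def _coerce_field(key: str, value):
    """Accept plain-list YAML forms for structured CohortSpec fields."""
    if key == "groups":
        return tuple((str(g), int(n)) for g, n in value)
    if key == "tad_intervals":
        return tuple((int(s), int(e)) for s, e in value)
    if key == "boundary_strengths":
        return {g: tuple(float(b) for b in betas) for g, betas in value.items()}
    if key == "loop_anchors":
        return tuple(lp if isinstance(lp, LoopSpec) else LoopSpec(*lp)
                     for lp in value)
    if key == "de_genes":
        return tuple(d if isinstance(d, DEGeneSpec) else DEGeneSpec(**d)
                     for d in value)
    if key == "sv_specs":
        return {sid: tuple(s if isinstance(s, SVSpec) else SVSpec(**s)
                           for s in svs)
                for sid, svs in value.items()}
    return value


def compartment_labels(spec: CohortSpec) -> np.ndarray:
    """Alternating A/B blocks of ``compartment_block_len`` bp."""
    block_bins = max(1, spec.compartment_block_len // spec.bin_size)
    idx = np.arange(spec.n_bins) // block_bins
    return np.where(idx % 2 == 0, "A", "B")


def _tad_factor(spec: CohortSpec, group: str) -> np.ndarray:
    """Symmetric matrix of TAD enrichment factors for one subgroup."""
    n = spec.n_bins
    tau = spec.tad_contrast
    tad_of = np.full(n, -1)
    for k, (s, e) in enumerate(spec.tad_intervals):
        tad_of[s:e] = k
    betas = spec.boundary_strengths.get(group)
    if betas is None:
        betas = tuple(0.0 for _ in spec.boundary_positions)
    # Pairs spanning boundaries keep TAD enrichment tau * prod(1 - beta) over
    # the spanned edges; accumulate in log space (beta clipped just below 1 so
    # differences of cumulative sums stay finite).
    log_step = np.zeros(n)
    for p, beta in zip(spec.boundary_positions, betas):
        log_step[p] = np.log(max(1.0 - beta, 1e-300))
    log_cum = np.concatenate([[0.0], np.cumsum(log_step)])
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    atten = np.exp(log_cum[hi] - log_cum[lo])
    t = np.ones((n, n))
    covered = (tad_of[ii] >= 0) & (tad_of[jj] >= 0)
    t[covered] = 1.0 + tau * atten[covered]
    return t


def expected_intensity(spec: CohortSpec, group: str,
                       sv_specs: tuple[SVSpec, ...] = ()) -> np.ndarray:
    """Full symmetric expected-count matrix mu, normalized then SV-operated."""
    spec.validate()
    n = spec.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = (1.0 + d) ** (-spec.decay_exponent)

    labels = compartment_labels(spec)
    same = labels[:, None] == labels[None, :]
    gamma = spec.compartment_contrast
    mu = mu * np.where(same, 1.0 + gamma, 1.0 - gamma)

    mu = mu * _tad_factor(spec, group)

    if spec.loop_anchors:
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        bump = np.zeros((n, n))
        s2 = 2.0 * spec.loop_sigma ** 2
        for lp in spec.loop_anchors:
            for (a, b) in ((lp.a, lp.b), (lp.b, lp.a)):
                bump += lp.amplitude * np.exp(-((ii - a) ** 2 + (jj - b) ** 2) / s2)
        mu = mu * (1.0 + bump)

    # normalize total expected count (upper triangle incl. diagonal) to L
    total = np.triu(mu).sum()
    mu *= spec.library_size / total
    base_scale = spec.library_size / total  # per-unit-decay count scale

    for sv in sv_specs:
        mu = _apply_sv(mu, sv, spec, base_scale)
    return mu


def _apply_sv(mu: np.ndarray, sv: SVSpec, spec: CohortSpec,
              base_scale: float) -> np.ndarray:
    n = mu.shape[0]
    alpha = spec.decay_exponent
    unit = base_scale  # expected count per unit of raw decay intensity
    mu = mu.copy()
    if sv.kind == "tandem_duplication":
        s, e = sv.span
        mu[s:e, :] *= 2.0
        mu[:, s:e] *= 2.0
        # junction block: copy-1 end re-ligated to copy-2 start, elevated
        # contacts at the (s, e) corner of the span
        ii, jj = np.meshgrid(np.arange(s, e), np.arange(s, e), indexing="ij")
        jd = (ii - s) + (e - 1 - jj)
        block = sv.amplitude * unit * (1.0 + jd) ** (-alpha)
        upper = jj > ii
        add = np.where(upper, block, 0.0)
        mu[s:e, s:e] += add + add.T
    elif sv.kind == "inversion":
        s, e = sv.span
        idx = np.arange(n)
        idx[s:e] = idx[s:e][::-1]
        mu = mu[np.ix_(idx, idx)]
    elif sv.kind == "translocation":
        p1, p2 = sorted(sv.loci)
        e1 = min(p1 + sv.extent, n)
        e2 = min(p2 + sv.extent, n)
        ii, jj = np.meshgrid(np.arange(p1, e1), np.arange(p2, e2), indexing="ij")
        block = sv.amplitude * unit * (1.0 + (ii - p1) + (jj - p2)) ** (-alpha)
        mu[p1:e1, p2:e2] += block
        mu[p2:e2, p1:e1] += block.T
    else:
        raise ValidationError(f"unknown SV kind {sv.kind!r}")
    return mu


def simulate_contact_map(spec: CohortSpec, group: str, sample_seed: int,
                         sv_specs: tuple[SVSpec, ...] = ()
                         ) -> tuple[ContactMatrix, PlantedTruth]:
    """Poisson-sample one contact matrix for a sample of the given subgroup."""
    mu = expected_intensity(spec, group, sv_specs)
    n = spec.n_bins
    rng = np.random.default_rng([spec.seed, int(sample_seed)])
    iu = np.triu_indices(n)
    draws = rng.poisson(mu[iu])
    matrix = ContactMatrix(spec.chrom, spec.bin_size, n)
    nz = draws > 0
    for i, j, v in zip(iu[0][nz].tolist(), iu[1][nz].tolist(), draws[nz].tolist()):
        matrix.counts[(i, j)] = float(v)
    truth = PlantedTruth(
        compartment_labels=compartment_labels(spec),
        tad_intervals=spec.tad_intervals,
        boundary_positions=spec.boundary_positions,
        boundary_strengths=dict(spec.boundary_strengths),
        loop_anchors=spec.loop_anchors,
        sv_records=tuple(sv_specs),
        de_genes=spec.de_genes,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# expression

def gene_table(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic gene positions on the simulated chromosome.

    DE genes pinned to boundary positions are placed immediately downstream of
    the boundary edge; the remainder are scattered uniformly. Gene bodies are
    10 kb.
    """
    rng = np.random.default_rng([spec.seed, 7777])
    gene_len = 10_000
    rows = []
    used = set()
    for de in spec.de_genes:
        if de.boundary_position is not None:
            start = (de.boundary_position + 1) * spec.bin_size + 1000
        else:
            start = int(rng.integers(0, spec.chrom_length - gene_len))
        rows.append({"gene": de.gene, "chrom": spec.chrom,
                     "start": start, "end": start + gene_len})
        used.add(de.gene)
    n_null = spec.n_genes - len(rows)
    starts = rng.integers(0, spec.chrom_length - gene_len, size=max(n_null, 0))
    for k in range(n_null):
        rows.append({"gene": f"G{k:04d}", "chrom": spec.chrom,
                     "start": int(starts[k]), "end": int(starts[k]) + gene_len})
    df = pd.DataFrame(rows).set_index("gene")
    return df.astype({"start": np.int64, "end": np.int64})


def _base_means(spec: CohortSpec) -> pd.Series:
    genes = gene_table(spec)
    rng = np.random.default_rng([spec.seed, 8888])
    lognoise = rng.normal(0.0, 0.25, size=len(genes))
    return pd.Series(spec.expr_mean * np.exp(lognoise), index=genes.index)


def simulate_expression(spec: CohortSpec, group: str, sample_seed: int) -> pd.Series:
    """Negative-binomial counts for one sample (mean m_g * fold, dispersion phi)."""
    means = _base_means(spec).copy()
    for de in spec.de_genes:
        fold = de.folds.get(group, 1.0)
        means.loc[de.gene] *= fold
    phi = spec.expr_dispersion
    rng = np.random.default_rng([spec.seed, 31, int(sample_seed)])
    if phi <= 0:
        counts = rng.poisson(means.to_numpy())
    else:
        r = 1.0 / phi
        p = r / (r + means.to_numpy())
        counts = rng.negative_binomial(r, p)
    return pd.Series(counts.astype(np.int64), index=means.index)


# ---------------------------------------------------------------------------
# reference track

def simulate_reference_track(spec: CohortSpec, epsilon: float = 0.0,
                             seed: int | None = None) -> list[IntervalRecord]:
    """Merged intervals over planted A-compartment bins with an epsilon
    fraction of bin labels flipped (the active-chromatin reference stand-in)."""
    labels = compartment_labels(spec) == "A"
    if epsilon > 0:
        rng = np.random.default_rng(spec.seed + 101 if seed is None else seed)
        flip = rng.random(labels.size) < epsilon
        labels = labels ^ flip
    return _bins_to_intervals(labels, spec.chrom, spec.bin_size, spec.chrom_length)


def _bins_to_intervals(flags: np.ndarray, chrom: str, bin_size: int,
                       chrom_length: int) -> list[IntervalRecord]:
    intervals = []
    start = None
    for i, on in enumerate(flags):
        if on and start is None:
            start = i
        elif not on and start is not None:
            intervals.append(IntervalRecord(chrom, start * bin_size, i * bin_size))
            start = None
    if start is not None:
        intervals.append(IntervalRecord(
            chrom, start * bin_size, min(len(flags) * bin_size, chrom_length)))
    return intervals


# ---------------------------------------------------------------------------
# whole cohorts

@dataclass
class Cohort:
    spec: CohortSpec
    metadata: pd.DataFrame
    matrices: dict[str, ContactMatrix]
    counts: pd.DataFrame  # genes x samples
    gene_positions: pd.DataFrame
    truths: dict[str, PlantedTruth]


def simulate_cohort(spec: CohortSpec, with_expression: bool = True,
                    groups_subset: tuple[str, ...] | None = None) -> Cohort:
    """Simulate every sample in the spec's cohort table."""
    meta = spec.sample_table()
    if groups_subset is not None:
        meta = meta[meta["subgroup"].isin(groups_subset)].reset_index(drop=True)
    matrices, truths = {}, {}
    expr = {}
    for k, row in meta.iterrows():
        sid, group = row["sample_id"], row["subgroup"]
        svs = tuple(spec.sv_specs.get(sid, ()))
        matrix, truth = simulate_contact_map(spec, group, sample_seed=k, sv_specs=svs)
        matrices[sid] = matrix
        truths[sid] = truth
        if with_expression:
            expr[sid] = simulate_expression(spec, group, sample_seed=k)
    genes = gene_table(spec)
    counts = pd.DataFrame(expr, index=genes.index) if expr else pd.DataFrame(index=genes.index)
    return Cohort(spec, meta, matrices, counts, genes, truths)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write per-sample COO matrices, counts TSV, metadata TSV, and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    for sid, matrix in cohort.matrices.items():
        serialize_contacts(matrix, outdir / f"{sid}.coo.txt")
    cohort.metadata.assign(sex=".", biotype="tumor").to_csv(
        outdir / "metadata.tsv", sep="\t", index=False)
    if not cohort.counts.empty:
        serialize_counts(cohort.counts, cohort.gene_positions, outdir / "counts.tsv")
    ref = simulate_reference_track(spec)
    serialize_intervals(ref, outdir / "reference_active.bed")
    promoters = []
    for gene, row in cohort.gene_positions.iterrows():
        tss = int(row["start"])
        promoters.append(IntervalRecord(
            spec.chrom, max(0, tss - 3000), tss + 3000, name=str(gene)))
    serialize_intervals(promoters, outdir / "promoters.bed")
    any_truth = next(iter(cohort.truths.values()))
    (outdir / "truth.json").write_text(any_truth.to_json())
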