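"""End-to-end orchestration: simulate/load -> balance -> features -> unions ->
feature matrices -> fusion/NMF -> differential -> association -> SV scan."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boundaries as bnd
from . import compartments as cmp
from . import differential_assoc as diff
from . import domains as dom
from . import integrate as integ
from . import loops as lps
from . import matrix_ops as mox
from . import sv_scan as sv
from .errors import ValidationError
from .io_formats import make_bins, serialize_track
from .synthetic_cohort import default_spec, simulate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]

_ALLOWED_SECTIONS = {
    "seed", "simulate", "contrasts", "balance", "boundaries", "domains",
    "loops", "fusion", "nmf", "diff", "sv",
}


@dataclass
class RunConfig:
    seed: int = 1
    simulate: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=lambda: [["SHH", "G3"], ["SHH", "G4"], ["G4", "G3"]])
    balance: dict = field(default_factory=dict)
    boundaries: dict = field(default_factory=dict)
    domains: dict = field(default_factory=dict)
    loops: dict = field(default_factory=dict)
    fusion: dict = field(default_factory=dict)
    nmf: dict = field(default_factory=lambda: {"k": 3, "n_runs": 30})
    diff: dict = field(default_factory=lambda: {"alpha": 0.05})
    sv: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_SECTIONS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _long_range_fraction(matrix, min_bp: int = 20_000) -> float:
    """Share of contact counts at genomic distance > min_bp (cis QC gate)."""
    total = 0.0
    far = 0.0
    for (i, j), v in matrix.counts.items():
        total += v
        if (j - i) * matrix.bin_size > min_bp:
            far += v
    return far / total if total else float("nan")


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage on a (simulated) cohort; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "qc": {}}
    timer: dict[str, float] = {}

    def stage(name):
        timer[name] = time.perf_counter()

    def done(name, **info):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - timer[name], 3), **info}

    stage("simulate")
    sim_kwargs = dict(config.simulate)
    spec = default_spec(seed=config.seed, **sim_kwargs)
    cohort = simulate_cohort(spec)
    write_cohort(cohort, outdir / "inputs")
    done("simulate", n_samples=len(cohort.matrices))

    meta = cohort.metadata
    sample_ids = meta["sample_id"].tolist()
    groups = meta["subgroup"].to_numpy()

    stage("balance")
    balanced = {}
    for sid in sample_ids:
        balanced[sid] = mox.balance(cohort.matrices[sid], **config.balance)
        manifest["qc"].setdefault("long_range_fraction", {})[sid] = round(
            _long_range_fraction(cohort.matrices[sid]), 4)
    done("balance")

    bins = make_bins(spec.chrom, spec.bin_size, spec.n_bins, spec.chrom_length)

    stage("boundaries")
    tracks = {sid: bnd.boundary_scores(balanced[sid], **config.boundaries)
              for sid in sample_ids}
    boundary_fm = bnd.boundary_feature_matrix(tracks)
    for sid in sample_ids:
        serialize_track(bins[:-1], tracks[sid].standardized,
                        outdir / f"{sid}.boundary_z.bedgraph")
    done("boundaries", n_positions=boundary_fm.shape[1])

    stage("compartments")
    from .synthetic_cohort import simulate_reference_track

    reference = simulate_reference_track(spec)
    eig_tracks = {}
    for sid in sample_ids:
        exp = mox.expected_by_distance(balanced[sid])
        oe = mox.observed_over_expected(balanced[sid], exp)
        pearson = mox.pearson_matrix(oe)
        eig = cmp.top_eigenvectors(pearson, k=3)
        eig = cmp.select_and_orient(eig, reference, spec.chrom, spec.bin_size)
        eig_tracks[sid] = eig.oriented
        serialize_track(bins, eig.oriented, outdir / f"{sid}.eigen.bedgraph")
    eigen_fm = np.vstack([eig_tracks[sid] for sid in sample_ids])
    done("compartments")

    stage("domains")
    domain_calls = {sid: dom.call_domains(balanced[sid], **config.domains)
                    for sid in sample_ids}
    union_d = dom.domain_union(domain_calls)
    domain_fm = dom.binary_domain_matrix(domain_calls, union_d)
    done("domains", union_size=len(union_d.entries))

    stage("loops")
    loop_calls = {}
    for sid in sample_ids:
        exp = mox.expected_by_distance(balanced[sid])
        loop_calls[sid] = lps.call_loops(balanced[sid], exp, **config.loops)
    union_l = lps.loop_union(loop_calls)
    loop_fm = lps.binary_loop_matrix(loop_calls, union_l)
    done("loops", union_size=len(union_l))

    stage("fuse")
    fcfg = integ.FusionConfig(**config.fusion)
    views = {}
    views["boundaries"] = integ.affinity(
        integ.distance_continuous(integ.filter_features(boundary_fm, fcfg)), fcfg)
    views["eigenvector"] = integ.affinity(
        integ.distance_continuous(integ.filter_features(eigen_fm, fcfg)), fcfg)
    if domain_fm.shape[1]:
        views["domains"] = integ.affinity(integ.distance_binary(domain_fm), fcfg)
    if loop_fm.shape[1]:
        views["loops"] = integ.affinity(integ.distance_binary(loop_fm), fcfg)
    net = integ.snf_fuse(list(views.values()), fcfg)
    distances = integ.fused_distance(net.fused)
    n_groups = len({g for g in groups})
    labels = integ.spectral_cluster(net.fused, min(n_groups, len(sample_ids)),
                                    seed=config.seed)
    conc, _cdist = integ.concordance_network(views, net.fused, fcfg,
                                             seed=config.seed)
    done("fuse", views=list(views))

    stage("nmf")
    nmf = integ.nmf_consensus(integ.filter_features(boundary_fm, fcfg),
                              seed=config.seed, **config.nmf)
    done("nmf")

    from sklearn.metrics import adjusted_rand_score

    report = {
        "samples": sample_ids,
        "subgroups": groups.tolist(),
        "fused_labels": labels.tolist(),
        "fused_ari_vs_subgroup": adjusted_rand_score(groups, labels),
        "nmf_labels": nmf["labels"].tolist(),
        "nmf_ari_vs_subgroup": adjusted_rand_score(groups, nmf["labels"]),
        "nmf_silhouettes": nmf["silhouettes"].tolist(),
        "concordance_with_fused": {
            name: conc[(name, "fused")] for name in views},
    }
    (outdir / "clusters.json").write_text(json.dumps(report, indent=2))

    stage("differential")
    diff_tables = {}
    for ga, gb in config.contrasts:
        if (groups == ga).sum() < 2 or (groups == gb).sum() < 2:
            continue
        results, summary = diff.differential_boundaries(
            boundary_fm, groups, ga, gb, alpha=config.diff.get("alpha", 0.05))
        diff_tables[(ga, gb)] = results
        pd.DataFrame([asdict(r) for r in results]).to_csv(
            outdir / f"diffbound_{ga}_vs_{gb}.tsv", sep="\t", index=False)
        manifest["stages"].setdefault("differential_summaries", {})[
            f"{ga}_vs_{gb}"] = summary
    done("differential")

    stage("association")
    if not cohort.counts.empty and diff_tables:
        (ga, gb) = next(iter(diff_tables))
        de = diff.de_genes(cohort.counts, groups, ga, gb,
                           positions=cohort.gene_positions)
        results = diff_tables[(ga, gb)]
        sig_bounds = [(r.position + 1) * spec.bin_size
                      for r in results if r.padj < 0.05]
        if len(sig_bounds) >= 2:
            mids = (cohort.gene_positions["start"]
                    + cohort.gene_positions["end"]).to_numpy() / 2.0
            r_vals = diff.reldist(mids, sig_bounds)
            diff.reldist_histogram(r_vals).to_csv(
                outdir / "reldist_hist.tsv", sep="\t", index=False)
        n_near, table = diff.count_de_near_differential(
            de, results, cohort.gene_positions, spec.bin_size)
        table.to_csv(outdir / "de_near_differential.tsv", sep="\t", index=False)
        manifest["stages"]["association_summary"] = {"n_de_near_differential": n_near}
    done("association")

    stage("svscan")
    sv_calls = {}
    for sid in sample_ids:
        exp = mox.expected_by_distance(balanced[sid])
        oe = mox.observed_over_expected(balanced[sid], exp)
        _cov, segs = sv.coverage_track(cohort.matrices[sid])
        sv_calls[sid] = sv.butterfly_scan(
            oe, spec.bin_size, gain_segments=segs, sample_id=sid, **config.sv)
    recurrent = sv.recurrent_svs(sv_calls)
    manifest["stages"]["sv_summary"] = {
        "n_calls": sum(len(v) for v in sv_calls.values()),
        "n_recurrent": len(recurrent),
    }
    done("svscan")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
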