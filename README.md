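# topohic

Feature extraction from binned Hi-C contact matrices — A/B compartments,
contact domains, insulation boundaries, and focal loops — followed by
multi-view sample clustering (similarity network fusion, consensus NMF),
differential-boundary statistics with boundary–expression association, and
structural-variant scanning from contact maps. A synthetic-cohort simulator
with planted ground truth makes every stage testable offline.

## Layout

| module | contents |
| --- | --- |
| `topohic.io_formats` | text formats: COO contact matrices, BED, bedGraph, BEDPE, counts TSV. All coordinates 0-based half-open; bin *i* spans `[i·bin_size, (i+1)·bin_size)` |
| `topohic.synthetic_cohort` | cohort simulator: power-law distance decay, compartment checkerboard, TADs with per-subgroup boundary strengths, focal loops, Poisson contact noise, negative-binomial expression, optional planted SVs |
| `topohic.matrix_ops` | iterative-proportional-fitting balancing, distance-decay expected model, O/E (ratio and difference), Pearson correlation matrices |
| `topohic.compartments` | eigenvector selection (components 1–3, each sign) by interval Jaccard against a reference active-chromatin track; positive = A |
| `topohic.domains` | arrowhead-style transform, corner-score domain calling, cross-sample union re-scoring |
| `topohic.boundaries` | rank-based (Mann–Whitney/Stouffer) insulation Z-scores per 50-kb boundary position, per-sample standardized |
| `topohic.loops` | donut/lower-left/stripe local expecteds, Poisson tests with BH within distance strata, union re-scoring, promoter anchor annotation |
| `topohic.integrate` | feature filtering (<5 % missing, top 40 % variance), squared-Euclidean/Jaccard distances, SNF (K=20, σ=0.3, T=16), spectral clustering, NMI concordance, consensus NMF |
| `topohic.differential_assoc` | Welch t + BH differential boundaries, log2-CPM differential expression stand-in, reldist/closest/1-Mb-window gene association |
| `topohic.sv_scan` | coverage segmentation (gain/loss/deep-deletion) and butterfly-block SV candidates with recurrence across samples |
| `topohic.pipeline`, `topohic.cli` | YAML-configured end-to-end orchestration |

## CLI

```sh
topohic simulate --outdir cohort/ --seed 1          # synthetic cohort + truth
topohic balance      --in cohort/G3_01.coo.txt --bin-size 50000 --chrom-length 25000000
topohic boundaries   --in cohort/G3_01.coo.txt --bin-size 50000 --chrom-length 25000000
topohic compartments --in ... --reference cohort/reference_active.bed
topohic domains --in ... ; topohic loops --in ... ; topohic svscan --in ...
topohic diffbound --features fm.tsv --metadata cohort/metadata.tsv --group-a SHH --group-b G3
topohic run --config run.yaml --outdir out/        # full pipeline + manifest
```

`topohic run` writes per-sample bedGraph tracks, differential tables, a
cluster report (`clusters.json`) and a manifest with per-stage timings and QC
(long-range contact fraction per sample).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: printed-percentage
checks, subgroup recovery (ARI ≥ 0.9 for both SNF/spectral and consensus
NMF on the default 7/8/13 cohort), feature-concordance ordering, boundary
score null calibration and ROC, loop caller precision/recall, compartment
orientation accuracy, balancing invariants, differential-test FDR and
sensitivity, reldist calibration, and SV breakpoint localization.

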