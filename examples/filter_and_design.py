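"""Predictor preparation: marker quality filters, the transcript
differential-expression screen, and assembly of the F/M design matrices.

Markers are dropped when more than 10% of lines are missing the call or
when the gene diversity 2p(1-p) falls below 0.2; remaining missing calls
are imputed by the within-pool band frequency.  Transcripts pass the
screen when they differ between lines (one-way F-test, BH-FDR 0.01) with
a fold change of at least 1.3 at a mean log2 intensity of at least 8.
"""

from hybridblup import (
    SimulationConfig,
    build_design,
    filter_markers,
    filter_transcripts,
    impute_missing,
    sample_transcripts,
    simulate_factorial,
)

dataset = simulate_factorial(SimulationConfig(n_transcripts=2000, seed=7))

res = filter_markers(dataset.markers)
print(f"markers: {dataset.markers.shape[1]} -> {res.matrix.shape[1]} retained "
      f"({res.n_removed_missing} failed missingness, "
      f"{res.n_removed_diversity} failed diversity)")
markers = impute_missing(res.matrix, dataset.pools)
print(f"missing entries after imputation: {int(markers.isna().sum().sum())}")

kept = filter_transcripts(dataset.expression_replicates)
print(f"transcripts passing the DE screen: {len(kept)} of "
      f"{dataset.expression.shape[1]}")
subsample = sample_transcripts(kept, k=min(1000, len(kept)), rng=7)
print(f"random subsample for prediction: {len(subsample)} transcripts")

design = build_design(dataset.hybrids, dataset.pools,
                      markers=markers, expression=dataset.expression,
                      genes=subsample)
print(f"design pair: F and M are {design.F.shape[0]} x {design.F.shape[1]} "
      f"(marker block + transcript block)")
print(f"expression columns have max 1 after per-pool normalization: "
      f"F max = {design.F[:, markers.shape[1]:].max():.3f}")
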