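# isletconn

Functional-connectivity analysis of pancreatic islet β-cell Ca²⁺ imaging,
plus pre-ranked gene-set enrichment scoring for EMT-style expression
signatures.

Glucose-stimulated β-cells within an islet synchronise their Ca²⁺
oscillations; the degree of cell-cell coordination is a readout of islet
health that degrades when β-cells dedifferentiate. This package implements
the standard trace-correlation recipe used to quantify that coordination
from fluorescence recordings, and the gene-level scoring used to ask whether
an expression ranking is enriched for epithelial or mesenchymal programmes.

## The method

Given per-ROI mean-fluorescence traces F (one column per cell, ~50 cells per
islet, imaged at 0.5 Hz):

1. **Preprocess** — each trace is smoothed with a causal trailing moving
   average (window 10 frames) and normalised to its baseline F0, giving
   dimensionless F/F0.
2. **Correlate** — the Pearson coefficient R is computed for every unordered
   cell pair (autocorrelations excluded).
3. **Test** — each pair's R gets a bootstrap p-value: frames are resampled
   with replacement (applied identically to both traces), R is recomputed per
   replicate, and p = (1 + #{replicate R ≤ 0}) / (n_boot + 1) asks whether
   the bootstrap confidence interval excludes zero. Moving-block bootstrap
   and permutation nulls are available for autocorrelated traces.
4. **Threshold** — pairs with R > 0.25 **and** p < 0.001 become edges of the
   connectivity graph, drawn as straight lines between the cells' Cartesian
   coordinates and coloured by strength: green (0.25–0.5), yellow
   (0.5–0.75), red (0.75–1.0). The companion heatmap shows the full R matrix
   on a fixed [−1, 1] scale.

A synthetic-islet simulator with planted coupling — a shared zero-mean,
unit-variance oscillation of fractional amplitude *a* on baseline f0 with
independent noise σ — provides ground truth. Two coupled cells then have the
closed-form correlation ρ = a²v / (a²v + σ²) with v = f0², which calibrates
the simulator and plants target-R networks for recovery tests.

For expression data, a ranked gene list (e.g. DESeq2 Wald statistics) is
scored against a gene set by the running-sum enrichment statistic ES (signed
maximum deviation; hits weighted by |stat|, misses by a constant), with
gene-label permutation significance, sign-matched NES and Benjamini-Hochberg
adjustment across sets.

## Worked example

`examples/03_connectivity_map.py` simulates a 20-cell islet with 8 coupled
cells planted at R = 0.6, runs the full chain, and prints:

```
edges found: 28 of 28 planted
connected pairs: 14.7% of all pairs
mean R over significant edges: 0.562
precision: 1.00  recall: 1.00
edge strength bins: {'yellow': 28}
```

All 28 planted pairs (and no others) are recovered; their mean R of 0.56
sits near the planted 0.6 and lands in the yellow strength bin.
`examples/04_enrichment.py` walks the hand-checkable 6-gene running sum
(ES = 0.75) and scores a planted 500-gene ranking:

```
    set  size       es      nes        p        q
planted    15 0.808001 2.205686 0.001754 0.003509
  decoy    14 0.316427 0.855477 0.675532 0.675532
```

The other examples cover simulation (`01`) and preprocessing (`02`); the
`isletconn` command exposes the same stages as `simulate`, `preprocess`,
`connect`, `graph` and `enrich` subcommands.

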