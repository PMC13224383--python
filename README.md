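# glacier

Spatial Granger causality for spatial transcriptomics: infer *directional*
transcription-factor→target and ligand→receptor relationships, with an
estimate of each interaction's spatial range, from a UMI count matrix and
cell coordinates.

## Who this is for

Analysts of sequencing- or imaging-based spatial transcriptomics (Visium,
Slide-SeqV2, MERFISH, ...) who have a candidate list of regulator→target
gene pairs (e.g. a CellChatDB-style ligand-receptor table or a TF-target
compendium) and want to know which pairs show directed, spatially lagged
predictive relationships in a tissue slice — and over what distance.

## The method in brief

Granger causality asks whether the past of `x` improves prediction of `y`
beyond `y`'s own past. Tissue space has no time axis, so the package builds
a *partial* order instead:

1. **Isodepth** `d(x, y)`: a smooth scalar potential over the slice along
   the direction of maximum expression variation (layer depth in layered
   tissue), learned by fitting `f(x, y) = h(d(x, y))` with `h` piecewise
   linear, under a Poisson UMI model `c_ig ~ Pois(U_i e^{h_g(d_i)})` or a
   Gaussian likelihood on reduced expression.
2. **Spatial DAG**: a k-NN graph (`k = 7`) on the coordinates, each edge
   oriented from higher to lower isodepth — acyclic by construction.
   Inverting the isodepth (`d' = max d − d`) reverses every edge and tests
   the opposite flow direction.
3. **DAG-structured autoregression**: for each target, a small network
   predicts expression at every cell from its 1..L-step graph ancestors'
   regulator expression,

       h1 = σ( Σ_ℓ M_ℓ X W1ℓ + b1 ),    M_ℓ = row-normalized (Aᵀ)^ℓ,

   with a nested group-lasso penalty over lag suffixes on the first-layer
   blocks `W1ℓ` (longer lags penalized more), trained by proximal gradient
   steps that yield exact zeros. A regulator whose weights survive across
   the valid part of a λ grid (5–95% of weights nonzero) Granger-causes the
   target; its surviving lag structure estimates the interaction's spatial
   range.

On a directed path graph the machinery reduces exactly to classical
time-series Granger causality (this is tested against an F-test oracle).

## Worked example

Generate a ground-truth benchmark (500 cells, 20 genes, 5 planted
interactions among 40 candidates), run inference, and summarize:

```bash
glacier simulate --suite easy --seed 1 --out sim/
glacier infer --data sim/counts.csv --pairs sim/pairs.tsv \
    --isodepth sim/isodepth.tsv --seed 0 --epochs 1500 \
    --lambda-min 0.001 --lambda-max 1.0 --lambda-count 12 \
    --out interactions.tsv
glacier report --table interactions.tsv
```

The top of `interactions.tsv` (score-descending):

```
regulator  target  pair_type  direction  score         lag  context
g002       g012    tf_target  forward    0.5055695384  3
g000       g010    tf_target  forward    0.4392382363  1
g001       g011    tf_target  forward    0.3454883743  2
g004       g014    tf_target  forward    0.3453496976  2
g009       g017    tf_target  forward    0.3002146529  1
g003       g013    tf_target  forward    0.2876269517  1
```

The five planted pairs in this run were g000→g010 (lag 1), g001→g011
(lag 2), g002→g012 (lag 3), g003→g013 (lag 1) and g004→g014 (lag 2): all
five rank among the top six of the forty candidates (average precision
0.97), and each reported `lag` matches the lag at which the effect was
planted. `score` is the ensembled first-layer group norm — relative
evidence for the interaction, 0 when every weight was pruned. `lag` is the
dominant surviving lag: the number of DAG steps (roughly, k-NN hops along
the isodepth axis) over which the regulator's expression predicts the
target, a proxy for the interaction's spatial range.

The same analysis runs from Python via `glacier.benchmark_suite`,
`glacier.fit_isodepth` / `glacier.attach_isodepth` and
`glacier.run_glacier`; see `docs/methods.md` for the model, training
scheme, parameter defaults and limitations.

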