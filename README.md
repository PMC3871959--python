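# sigflow

Automated, parallel signal processing and supervised classification of
windowed multichannel time series (EEG/ERP-style data).

Data samples come in four granularities — raw streams, windowed time
series, feature vectors and prediction vectors — and flow through modular
node chains (preprocessing, spatial filters, feature generation,
normalization, classification, score mapping, splitting and grid-search
meta nodes). YAML operation files expand a parameterized chain template
over the Cartesian product of parameter ranges (with optional
constraints) and over seeded repetitions; each resulting process is
independent and can run on a serial or multicore back-end with
bit-identical results. All per-process metrics are consolidated into one
`results.csv`.

## Quick start

Generate a synthetic oddball summary (rare Target / frequent Standard
stimuli with a planted spatial pattern) and run an algorithm comparison:

```sh
sigflow synth --out storage/oddball --datasets 2 --channels 8 --seed 0

cat > chain.yaml <<'EOF'
node_chain:
  - node: TimeSeriesSource
  - node: Standardization
  - node: LowpassFilter
    parameters: {cutoff_hz: 10}
  - node: Decimation
    parameters: {factor: 8}
  - node: TrainTestSplitter
    parameters: {train_fraction: 0.5}
  - node: __alg__
    parameters: {retained_channels: __channels__}
  - node: TimeDomainFeatures
  - node: FeatureNormalization
  - node: GridSearch
    parameters:
      nodes:
        - node: LinearClassifier
          parameters: {complexity: __C__}
      grid: {__C__: [0.001, 0.01, 0.1]}
      folds: 5
      metric: balanced_accuracy
  - node: PerformanceSink
EOF

cat > operation.yaml <<'EOF'
type: node_chain
input_path: storage/oddball
template: chain.yaml
parameter_ranges:
  __alg__: [XDAWN, CSP, PCA, Noop]
  __channels__: range(2, 9, 2)
constraints:
  - '__alg__ != "Noop" or __channels__ == 2'
runs: 2
EOF

sigflow launch -o operation.yaml --mcore
```

The result folder (named `<spec>_<UTC timestamp>`) contains
`results.csv` (one row per successful process, train/test metrics plus
the varied parameter columns), `specs.zip` (archived operation spec and
template for replicability), `failures.yaml`, and the per-process
folders — all zipped except the first, which is kept as an uncompressed
example.

Randomness is controlled by the run index: run `r` of every chain is
seeded from `r`, so the same `runs` value reproduces identical results.

## Library use

```python
from sigflow import parse_node_chain_yaml, run_node_chain
from sigflow.dataset_io import read_dataset

chain = parse_node_chain_yaml(open("chain.yaml").read())
result = run_node_chain(chain, read_dataset("storage/oddball/oddball_0"), run_index=0)
print(result.test_metrics.balanced_accuracy)
```

Key modules:

- `sigflow.data_model` — sample/dataset types, marker and equidistant
  stream segmentation
- `sigflow.dataset_io` — CSV/ARFF/YAML on-disk formats, summaries
- `sigflow.node_framework` — node registry, chain validation/execution
- `sigflow.processing_nodes` — the algorithm library (xDAWN, CSP, PCA,
  FIR lowpass, decimation, standardization, time-domain features,
  feature normalization, logistic linear classifier, sigmoid score
  mapping, stratified splitters, grid search)
- `sigflow.operations` — operation YAML, grid expansion, constraints,
  process creation, consolidation, merge/shuffle, operation chains
- `sigflow.backends` — serial / multicore execution
- `sigflow.evaluation` — metrics, results tables, queries
- `sigflow.synthetic` — oddball stream and Gaussian feature generators

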