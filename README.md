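# ncmsim

Unsupervised simulation of sparse signed/neutrosophic cognitive maps over
gene-regulatory concepts.  A knowledge map is an NxN relationship matrix whose
cells hold causal strengths in [-1, +1] or "I" (indeterminate).  The engine
iterates a state vector through sparse vector-matrix multiplication and Elliott
squashing (x / (1 + |x|)) until the mean squared difference between successive
states falls below a tolerance; converged values are classified by sign into
expressed / repressed calls and scored against an expected up/down panel with
an exact binomial test under a biased null (the network's positive-edge
fraction, e.g. 0.66/0.34).

## Layout

- `src/ncmsim/knowledge_map.py` — data model, CSV I/O, validation, map statistics
- `src/ncmsim/simulation_engine.py` — sparse iteration, activation, MSE
  convergence and overtraining detection
- `src/ncmsim/outcome_stats.py` — expression calls, pretest probabilities,
  exact binomial p-values (`all_success`, `point_mass`, `upper_tail`),
  validation reports
- `src/ncmsim/synthetic_fixtures.py` — random maps with prescribed shape,
  planted-attractor maps with closed-form steady states, and a hand-wired
  (openly fictional) ~40-node stem-cell toy fixture
- `src/ncmsim/cli.py` — `ncmsim` command-line harness
- `fixtures/` — the toy fixture as plain-text artifacts (map CSV, protocol
  YAMLs, expected panels)

## CLI

```sh
# map statistics (nodes, edges, mean degrees, sign bias)
ncmsim stats fixtures/toy_stemcell_map.csv

# iterate to steady state; writes state.csv, trajectory.csv, summary.json
ncmsim simulate --map fixtures/toy_stemcell_map.csv \
    --protocol fixtures/protocol_oskm.yaml --out-dir out/oskm

# simulate + score against an expected up/down panel
ncmsim validate --map fixtures/toy_stemcell_map.csv \
    --protocol fixtures/protocol_rett.yaml \
    --panel fixtures/panel_rett.csv --pretest 0.66 0.34 --out-dir out/rett

# synthetic fixtures
ncmsim generate random --n-nodes 3589 --seed 1 --out scratch/big_map.csv
ncmsim generate planted --n-nodes 10 --loop-gain 2.0 --out-dir scratch/planted
ncmsim generate toy --out-dir scratch/toy
```

Exit codes: `0` success/converged, `2` ran but did not converge, `3` input or
configuration error.

Protocol YAML keys: `on`, `off` (transient +1/-1 for iteration 1 only),
`locked_on`, `locked_off` (clamped every iteration), `activation` (`elliott`,
`logistic-symmetric`, `hyperbolic-tangent`), `tolerance` (default `0.001`),
`max_iterations` (default `1000`), `overtraining_check`.

## Notes

The toy stem-cell fixture's wiring is fictional: it demonstrates protocol
mechanics (transient reprogramming factors, a locked-off knockout node,
up/down panels) at a scale where every steady value is predictable by hand.
Nothing in this repository makes a biological claim.
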