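# quantnet

A dual map between univariate time series and weighted directed networks.

The **forward map** discretizes a series into `Q` equal-occupancy quantile
bins, makes each bin a node, and weights the arc `i -> j` with the
empirical first-order Markov transition probability between consecutive
time points.  The **inverse map** goes the other way: it row-normalizes an
arbitrary non-negative adjacency matrix, recovers a node-to-quantile
ordering by simulated-annealing seriation of a distance-to-diagonal cost,
runs a random walk on the transition matrix, and emits one value per step
drawn uniformly from the walked node's quantile bin.  Round trips through
both maps preserve autocorrelation, spectral, distributional and
topological statistics up to sampling noise, so network statistics can
characterize time series and vice versa.

## Layout

| module | contents |
| --- | --- |
| `quantnet.mapping` | quantile assignment, transition counting, row normalization, `forward_map` |
| `quantnet.inverse` | seriation cost, segment-move annealer, random walk, emission, `inverse_map` |
| `quantnet.generators` | periodic-to-random toy ensemble, Lorenz/Rossler RK4 trajectories, ring / modular / star-hub network fixtures, value shuffling |
| `quantnet.diagnostics` | ACF, periodogram, spectral slope, strengths, inverted-weight shortest paths, modularity + greedy community detection, shuffle nulls, generation comparators |
| `quantnet.io` / `quantnet.cli` | plain-text series, TSV edge lists, JSON partitions; the `quantnet` command |

## CLI

```sh
# generate a toy series, map it to a network, invert the network back
quantnet generate toy --p 0 --k 0.125 --length 64 --seed 1 --output toy.txt
quantnet map --input toy.txt --quantiles 8 --output edges.tsv --partition-out part.json
quantnet invert --network edges.tsv --length 1000 --seed 2 \
    --partition part.json --no-reorder --output second.txt

# statistics and the full two-generation round-trip experiment
quantnet stats series --input toy.txt --maxlag 50 --output report.json
quantnet roundtrip --p-values 0,0.05,1 --realizations 10 --length 10000 \
    --quantiles 50 --seed 1 --output roundtrip.json
```

Chaotic and network generators: `quantnet generate lorenz|rossler|network ...`.

## Notes

- Quantile assignment is rank-based with stable tie-breaking, so the
  forward map is exactly invariant under strictly increasing transforms
  of the values.
- Round trips reuse the first generation's bin boundaries
  (`forward_map(..., partition=...)`), keeping the node-quantile
  correspondence fixed.
- All randomness flows from explicit seeds; the inverse map splits its
  master seed into independent annealing / start / walk / emission
  streams.
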