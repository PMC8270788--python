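# hicarch

Chromosome-architecture analysis of Hi-C contact maps: per-bin domain
metrics (directionality index, insulation, diamond score, arrowhead-style
corner score), multi-caller TAD consensus with diamond-score/size/density
filtering, loop filtering and loop-domain annotation, DI-based border
clustering with DI-bias subclusters, rescaled aggregate-TAD maps and
condition ratio maps, A/B compartment scores by eigenvector reference and
matrix projection, and spike-in scale factors — exercised end to end on a
seeded synthetic generator with planted TADs, corner loops, compartment
checkerboards and border-asymmetric signal.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: brute-force
oracle equivalence for the diamond score, distance-decay expectation and
aggregate maps; formula spot checks; multi-seed parameter recovery on the
default synthetic fixture (border recovery, loop-domain sensitivity,
k-means asymmetry classes, compartment A/B agreement and switch
tracking); conservation invariants; and the knockdown-ratio /
border-asymmetry direction checks.

## Command line

```bash
# full pipeline on the default synthetic fixture (1,000 bins x 10 kb,
# 12 domains, 4 loop domains, compartment stage series at 25 kb)
hicarch run-all --seed 3 --out-dir out/

# write a synthetic contact map + bin table only
hicarch simulate --seed 3 --out-dir sim/ --asymmetric

# call domains from insulation minima on a triplet matrix
hicarch call --matrix sim/matrix.tsv --bins sim/bins.tsv --out domains.bed
```

`run-all` writes every intermediate in plain text (triplet matrix, bin
table, bedGraph tracks, BED/BEDPE calls, TSV aggregate maps, PNG
heatmaps) plus `report.json` (per-stage counts) and `manifest.json`
(config hash, seed, file list). A YAML config mirroring all CLI defaults
can be passed with `--config`; re-running the same config and seed
reproduces the report byte for byte.

## Package layout

| module | contents |
| --- | --- |
| `hicarch.matrix_core` | bin table, sparse symmetric contact matrix, triplet I/O, VC / VC_SQRT / balancing, expected-by-distance, observed/expected |
| `hicarch.synthetic_data` | seeded generator with planted domains, loops, compartments, asymmetry, signal tracks, spike-in splits |
| `hicarch.domain_metrics` | DI, insulation, diamond score, corner score |
| `hicarch.tad_consensus` | insulation caller, border merge, score/size/density filters, reciprocal-overlap comparison |
| `hicarch.loop_analysis` | loop distance/VC filters, loop-domain annotation |
| `hicarch.border_clustering` | border DI vectors, k-means classes, DI bias, equal-size subclusters, border signal profiles |
| `hicarch.aggregation` | rescaled aggregate maps, ratio maps, track PCA |
| `hicarch.compartments` | reference eigenvector, mark orientation, projection, [-1,1] normalization, switch tracking |
| `hicarch.signal_spikein` | spike-in scale factors, track scaling |
| `hicarch.pipeline_cli` | config, orchestration, CLI |

Conventions: coordinates are 0-based half-open on the bin grid; all
matrix operations are per-chromosome (cis); missing bins propagate as
entry deletion, never as zeros; every source of randomness sits behind an
explicit seed.
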