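# repkit

Hierarchical T-cell receptor (TCR) repertoire analysis as a scriptable
library and CLI. repkit consumes clonotype tables (MiXCR `exportClones`
TSV, AIRR Rearrangement TSV, or its own canonical TSV), organizes samples
through an *experiment design file* with arbitrary grouping variables, and
runs three tiers of analysis:

- **single-sample** — TRBV/TRBJ segment usage, CDR3 length spectratype
  (optionally stratified by J segment), ranked clonotype frequency
  distribution, D50, top clones;
- **pairwise** — shared / private clonotype comparison with a coefficient
  of determination over log10 frequencies, and convergent-recombination
  analysis (distinct nucleotide sequences per amino-acid clonotype);
- **multi-sample** — clonal space homeostasis with chi-square comparison,
  longitudinal clonotype tracking, similarity matrices (Jaccard, overlap
  coefficient, Morisita–Horn, Bhattacharyya) with agglomerative clustering,
  diversity indices (Shannon, clonality, inverse Simpson, Gini–Simpson,
  Chao1, D50) with seeded rarefaction, and a Mann–Whitney two-group test.

A seeded synthetic-repertoire simulator (power-law / lognormal / uniform
clonal expansion, V/J usage biases, CDR3 length spectra, programmable
convergent recombination, non-productive fractions, and longitudinal
expansion/contraction scripts) makes every statistic testable without any
external data.

## CLI

```sh
# generate a demo data set + design file
repkit simulate --out demo --n-samples 5 --n-clones 200 --depth 10000 --seed 1

# or a 5-timepoint longitudinal series (expansion at t2, contraction at t4)
repkit simulate --out demo_long --timepoints 5 --seed 1

# per-sample analyses
repkit single --design demo/design.csv --out out_single

# overlap + convergence between two samples
repkit pairwise --design demo/design.csv --out out_pair --samples sim1,sim2

# group-level analyses, grouped by a design variable
repkit multi --design demo_long/design.csv --out out_multi --group-by time_point --seed 7

# normalize any supported dialect into canonical TSV
repkit convert --design demo/design.csv --out out_canonical
```

Common flags: `--key-mode {nt,aa,nt+vj,aa+vj}` selects clonotype identity
(default `nt+vj`), `--functional/--no-functional` toggles removal of
non-productive clonotypes (default on), `--seed` fixes all randomness.
`repkit --config cfg.yaml <command> ...` pre-sets options from YAML (one
mapping per command); explicit flags override the config. Every run writes
a `manifest.json` with parameters, seed and per-file dialect detection,
and identical config + seed produce byte-identical outputs.

## Design file

CSV or TSV with mandatory columns `sample_id` and `file` (paths resolved
relative to the design file); every other column is a grouping variable.
`--group-by var1,var2` groups samples by the cross-product of observed
value combinations.

## Library use

```python
from repkit import (SimulationParams, simulate_repertoire, diversity,
                    overlap_pair, clonal_space_homeostasis)

rep = simulate_repertoire(SimulationParams(n_clones=500, depth=50_000, seed=0))
print(diversity(rep, "shannon").value)
print(clonal_space_homeostasis(rep).to_frame())
```
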