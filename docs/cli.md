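# Command-line interface

All subcommands accept `--seed`; outputs land in a run directory with fixed
names. Nodes are 0-indexed everywhere; edges are written parent→child.

## Subcommands

```
dagmcmc simulate   --nodes N --density F --arity K --concentration C
                   --samples M --interventions F --fanin F --seed S --out DIR
dagmcmc run        --data D.tsv [--mask M.tsv] --proposal 0.8,0.2
                   --burnin B --sample S --thin T --fanin F --ess E
                   --chains C --seed S --out DIR
dagmcmc exact      --data D.tsv [--mask M.tsv] --fanin F --ess E --out FILE.csv
dagmcmc diagnose   RUN_DIR [RUN_DIR ...] --out DIR
dagmcmc experiment --config exp.yaml [--seed S] --out DIR
```

`--proposal` is the mixture vector as a comma list: `0.8,0.2` means
propose a 1-step transition with probability 0.8 and a 2-step transition
with probability 0.2.

## Run directory contents (`run`, and per cell of `experiment`)

| file | content |
| --- | --- |
| `manifest.json` | config snapshot, per-chain seeds, software version, input digests, acceptance rates — sufficient to re-run bit-identically |
| `dags_<i>.txt.gz` | one edge-list string per retained state of chain i |
| `trace_<i>.csv` | step, log score |
| `edge_posteriors_<i>.csv` / `edge_posteriors.csv` | per-chain / pooled n×n matrices |
| `map_dag.tsv`, `map_dag.dot` | highest-scoring retained structure |

## Experiment YAML schema

```yaml
# one of:
data: path/to/data.tsv          # with optional  mask: path/to/mask.tsv
generator:                      # or generate synthetically
  nodes: 10
  density: 0.3                  # edge-inclusion probability
  arity: 3
  concentration: 0.5            # Dirichlet CPT concentration
  samples: 3000
  interventions: 0.3            # fraction of rows with one node clamped
  seed: 7

proposals: [[1.0], [0.8, 0.2]]  # one ensemble per mixture vector
chains: 3
burn_in: 100000
sample_size: 50000
thin: 1
fanin: 5                        # optional
ess: 1.0
seed: 0
subsample_sizes: [500, 1000, 3000]   # optional dataset-size sweep
```

The sweep writes one run directory per (proposal, dataset size) cell plus
`summary.csv` with mean pairwise SSD, best-pair SSD, MAP log score and
mean acceptance rate per cell.

## Dataset format

TSV or CSV with a header row of variable names; cells are non-negative
integer category codes. Arities are inferred as max code + 1 per column
unless given. The intervention mask is a same-shape 0/1 table (1 = the
value was set by perturbation, not observed).
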