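# structmark

Structural network biomarkers: a pipeline that infers two populations of
gene networks from two-condition expression data, computes eigenvalue- and
entropy-based graph invariants as features, classifies network class
membership with a polynomial-kernel SVM, and quantifies each invariant's
discrimination power (ndv) — alongside a conventional gene-expression
biomarker arm for comparison.

## Components

| Module | Role |
| --- | --- |
| `structmark.graph_core` | Graph type, adjacency/distance/Laplacian matrices, exact isomorphism and automorphism-orbit computation |
| `structmark.spectral` | Eleven eigenvalue descriptors (energy, Estrada index, spectral radius/gap; distance and Laplacian variants) + eigenvalue sign ratios |
| `structmark.entropy` | Ten entropy descriptors (information-functional entropies, topological information content, Balaban J, Bonchev indices, symmetry index, …) |
| `structmark.c3net` | Mutual-information estimation and conservative causal-core network inference with a pooled permutation null |
| `structmark.subgraph_extract` | GMT gene sets and vertex-induced subgraph extraction with a minimum-size filter |
| `structmark.features_classify` | Feature tables, information-gain selection, stratified CV of a grid-searched polynomial SVM, macro-averaged error measures |
| `structmark.uniqueness` | ndv (descriptor degeneracy) counts and sensitivity reports per network group |
| `structmark.synthetic_data` | Seeded generators: two-condition expression with planted modules and DE genes, gene sets, two-class graph populations |
| `structmark.cli_io` | `structmark` CLI and the end-to-end pipeline |

All distance-based quantities on disconnected graphs are computed on the
largest connected component (ties broken by smallest vertex label).
Entropies are reported in bits.

## CLI

Each stage is a subcommand; `run-all` chains them:

```sh
# synthetic inputs (expression TSVs, GMT gene sets, truth record)
structmark simulate --out sim/ --seed 1

# C3NET inference from a genes x samples TSV
structmark infer --expression sim/benign.tsv --out nets/benign --seed 1 --emit-mi

# gene-set-induced subgraphs (min-genes is mandatory)
structmark extract --graph nets/benign.edges --vertices nets/benign.vertices \
    --gene-sets sim/gene_sets.gmt --condition benign --min-genes 5 --out subs/

# descriptor table, classification, degeneracy report
structmark measure --graphs subs/ --battery eigenvalue,entropy --out features.csv
structmark classify --features features.csv --folds 10 --seed 1 --report report.json
structmark uniqueness --features features.csv --out uniqueness.csv

# everything from a YAML config
structmark run-all --config config.yaml --out run/ --seed 1
```

A minimal `config.yaml` needs only `min_genes: 5`; every other knob
(simulation parameters, estimator, alpha, permutations, SVM grid, folds,
tolerance, seeds) has a default and the effective configuration is written
next to the outputs, so any run can be regenerated byte-identically.

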