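# Example pipeline configuration (every field shown at its default).
# Load with:  geobirth run --config examples/pipeline_config.yaml
# or:         PipelineConfig.from_yaml("examples/pipeline_config.yaml")

out_dir: results            # where report CSVs and the manifest land
records: null               # records CSV path; null + simulate -> synthetic data
graph: null                 # adjacency edge list; null -> packaged DRC graph
simulate: true              # generate the default synthetic survey
n_records: 7172             # simulated sample size (survey scale)
seed: 0                     # master seed for simulation and MCMC

populations: [all, young]   # all women 15-49 and/or young women 15-24
adjusted_terms:             # classical adjusted-model term lists
  all: [province, residence, education, age_group, contraception]
  young: [province, wealth, age_group]

n_basis_all: 20             # spline basis size for the 15-49 age smooth
n_basis_young: 10           # ...and for the 15-24 smooth (shorter span)
unstructured: true          # include the exchangeable province effect u

n_iter: 12000               # Gibbs iterations per chain
burn_in: 2000
thin: 10
chains: 2                   # >= 2 enables split-Rhat reporting

report_levels: [0.80, 0.95] # map tables at 80%, OR tables at 95%
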