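# Full pipeline configuration for `lncffl run --config config.yaml`.
# Paths are relative to where the command is run; generate matching inputs
# with `lncffl simulate --out-dir fixtures --scenario paper-shaped --seed 0`.

edges: fixtures/edges.tsv            # TSV: source, target, layer[, evidence]
gene: fixtures/gene.tsv              # feature_id + one column per sample
mirna: fixtures/mirna.tsv
lncrna: fixtures/lncrna.tsv
design: fixtures/design.tsv          # sample_id, group (case/control)
genesets: fixtures/genesets.gmt      # optional, GMT
cernas: fixtures/cerna.tsv           # optional, TSV: gene, miRNA, lncRNA
drug_associations: fixtures/drugs.tsv  # optional: drug, target, target_type[, category]
out_dir: lncffl_run

permutations: 1000        # sample-label permutations (B); minimum 100
seed: 42
alpha: 0.05               # dysregulation threshold on the permutation p-value
tau: 0.3                  # |r| threshold separating "no correlation" states
log2p1: false             # apply log2(x + 1) before scoring
equal_var: true           # Student (pooled-variance) t-test; false = Welch

min_module_size: 4        # smallest reported core module
density_penalty: 2.0      # cohesiveness penalty term
merge_threshold: 0.8      # Jaccard overlap at which core modules merge
min_shared: 2             # shared molecules needed for an FFL-ceRNA merge
categories_of_interest: [hormonal, anti-inflammatory]
group_aliases: {GDM: case, NGT: control}
log_level: INFO
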