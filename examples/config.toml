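# Every tunable of the pipeline in one place; all keys optional
# (missing keys use the documented defaults).

[alignment]
match = 1.0
mismatch = -1.0
gap_open = 2.0     # magnitudes: a gap of length L costs gap_open + gap_extend*L
gap_extend = 0.5

[disease]
alpha = 0.5        # weight of gene-set Jaccard vs ontology similarity

[snf]
K = 20             # nearest neighbors in the local kernel (capped at n-1)
t = 20             # maximum diffusion iterations
tol = 1e-6         # early stop on successive fused averages

[features]
n_bins = 10
top_n = 10
kmer_ks = [2, 3, 4]
svd_rank = 5
pca_variance = 0.95
kmer_raw = false

[gbdt]
n_estimators = 60
learning_rate = 0.1
max_depth = 9
min_samples_split = 24
min_samples_leaf = 11
max_features = 9
subsample = 0.8
seed = 0

[evaluate]
threshold = 0.5
use_pca = false

[synthetic]
n_circ = 132
n_disease = 40
n_blocks = 5
seq_len = [150, 300]
n_sites = 32
go_universe = 1000
genes_universe = 500
within_block_assoc_prob = 0.13
between_block_assoc_prob = 0.001
noise_sd = 0.3
seed = 0
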