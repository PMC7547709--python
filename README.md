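# menanet

Molecular ecological network analysis of soil microbial communities.

`menanet` is a reusable Python toolkit for the analysis battery commonly used
to compare soil microbial communities between two treatments (for example a
reseeded grassland, RG, against a natural grassland, NG): alpha diversity,
correspondence-analysis ordination, permutation dissimilarity tests, and —
at its core — Random-Matrix-Theory (RMT) co-occurrence network construction
with module detection, Zi/Pi node roles, and gene-significance linkage to
environmental variables. A synthetic-data module generates OTU tables,
environment tables and FASTQ files with the statistical structure the
analyses assume, so the whole pipeline is testable without any sequencing
data.

## The methods in brief

**Diversity.** Per sample, richness *S*, Shannon–Wiener
*H* = −Σᵢ pᵢ ln pᵢ (nats) and Gini–Simpson *D* = 1 − Σᵢ pᵢ², computed on
counts rarefied to a common depth (default 1500 reads, drawn without
replacement).

**Ordination.** Correspondence analysis eigen-decomposes the chi-square
standardised abundance matrix S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; DCA removes
the arch artifact by segment-wise detrending of higher axes against axis 1
(26 segments by default); CCA constrains the site scores to linear
combinations of environmental variables by a weighted least-squares
projection inside the same decomposition, and reports per-axis and
cumulative percent of total inertia.

**Dissimilarity tests.** ANOSIM (rank statistic R), Adonis/PERMANOVA
(pseudo-F with R²) and MRPP (weighted within-group distance δ with
chance-corrected agreement A) on Bray–Curtis distances, plus a generic
Mantel test. All permutation p-values use the add-one estimator
p = (1 + #{permuted ≥ observed}) / (1 + N) and are reproducible by seed.

**RMT networks.** Counts are prevalence-filtered and log10-transformed,
pairwise Pearson correlations give a similarity matrix s = |r| (signs kept),
and the adjacency threshold is chosen automatically: scanning a grid of
thresholds, the nearest-neighbour spacing distribution (NNSD) of the
unfolded eigenvalues of the thresholded matrix shifts from GOE (Wigner
surmise, correlated noise) to Poisson (modular structure); the smallest
threshold whose NNSD is accepted as Poisson defines the network. Topology is
summarised by mean degree, average shortest-path distance, mean clustering
coefficient and modularity; nodes are classified by within-module degree
z-score (Zi ≥ 2.5 → module hub) and participation coefficient
(Pi ≥ 0.62 → connector). Gene significance GS = r² between a node's
abundance and an environmental variable is linked to node degree by a
vector-mode Mantel test.

## Worked example

Generate the packaged demo study (54 samples = 2 groups × 9 sites × 3
subplots at depth 1500, four dominant phyla at ~80% of the community,
planted co-occurrence blocks and OTU-linked environment variables), then
test the two groups:

```bash
$ menanet make-demo demo --seed 1
demo config: demo/config.yaml

$ menanet dissim demo/otu_table.tsv demo/groups.tsv --seed 1
test    statistic_name  statistic       P       R2      A
Anosim  R       0.6238515079392993      0.001
Adonis  pseudo_F        5.161459284657111       0.001   0.09029614270261492
MRPP    delta   0.5008233618233618      0.001           0.03664701692363437
```

All three tests agree that the two synthetic treatments host distinct
communities (P = 0.001, the smallest value attainable with 999
permutations); ANOSIM's R = 0.62 means between-group distances rank well
above within-group distances, and Adonis attributes R² ≈ 9% of the
distance-based variance to the grouping.

The full pipeline (QC → rarefaction → phylum bars → diversity → DCA →
dissimilarity tests → per-group RMT networks → CCA → connectivity–GS
tables, with an artifact manifest and checksums) runs from the config:

```bash
$ menanet run demo/config.yaml
wrote 25 artifacts
```

`demo/results/network_stats.tsv` then holds one row per group, e.g. for the
seed-1 demo the RG network has 138 nodes, 141 links, mean degree 2.04 and
modularity 0.85, against 148 nodes, 157 links, mean degree 2.12 and
modularity 0.81 for NG — the same table shape used to compare empirical
co-occurrence networks between treatments.

As a library:

```python
from menanet import (prepare_log_matrix, similarity_matrix,
                     rmt_threshold_scan, build_network, detect_modules,
                     topology, node_roles, read_otu_table)

table = read_otu_table("demo/otu_table.tsv")
sim = similarity_matrix(prepare_log_matrix(table, min_prevalence_fraction=0.5))
scan = rmt_threshold_scan(sim)          # automatic RMT threshold
net = build_network(sim, scan.chosen_threshold)
modules, q = detect_modules(net)
print(topology(net))                     # nodes, links, degree, paths, Q
roles = node_roles(net)                  # Zi/Pi classification per OTU
```

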