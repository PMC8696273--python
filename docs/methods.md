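# Methods

## Model and procedure

`genefc` analyses the coupling between two region-pair-level quantities: a
transcriptomic similarity and a functional connectivity strength. The
inputs are a region × gene expression matrix (one matrix for the whole
cohort — donor expression atlases are not subject-specific), per-subject
region × region functional connectivity, and a region → network atlas with
hemisphere and homolog labels. Connections are vectorized in row-major
upper-triangle order (`i < j`, 0-based) everywhere.

The pipeline has four steps:

1. **Individual-level screening.** For each subject and gene, the Pearson
   correlation between the subject's connectivity vector and the gene's
   co-expression product vector `E_ia·E_ja` across all connections, with
   two-sided p-values from the t distribution on `S − 2` degrees of
   freedom. A gene is significant in a subject below the
   Bonferroni-corrected level `α/N` (α = 0.05 over all `N` genes); genes
   significant in strictly more than 80% of subjects form the pool.
   Two-sided tests are used because anti-correlated co-expression is as
   meaningful as correlated co-expression.
2. **Coupling tensor and group-wise CP model.** The contribution tensor
   `C[a, s, h] = (FC_sh · CGE_s) · (E_ia · E_ja)` is built on the pooled
   genes. Subjects are split into four groups (randomly halving within
   each acquisition site when site labels exist), each group's tensor is
   decomposed with the semi-nonnegative CP model, and genes whose absolute
   leading-component weights exceed mean+SD in **all four** groups are the
   tensor-route genes. Cross-group agreement is reported as a mismatch
   rate (Jaccard distance of the four selections) and a correspondence
   (mean absolute Pearson correlation of the sign-aligned gene-weight
   vectors over the six group pairs); these definitions are this package's
   — the originating analysis names but does not define them.
3. **Reliable genes and gene-related connections.** A permutation test
   jointly shuffles all entries of the population-averaged gene ×
   connection contribution matrix (flatten–permute–reshape) 1000 times; a
   gene is significant only if its observed connection-averaged mean beats
   *every* null mean (P < 0.001). Reliable genes are the intersection of
   the permutation and tensor routes. Connections are selected by
   |population CEC| > mean+SD, intersected with the mean+SD selection on
   the leading component's connection weights.
4. **Network dissection.** Connections are classified intra-/inter-network
   and homologous. Network-shared genes show no one-way-ANOVA difference
   (P ≥ 0.05) of population-averaged contributions across the per-network
   groups of intra-network connections. Network-specific genes must pass
   four criteria in order: (1) mean+SD selection from a CP decomposition
   restricted to the network's intra-network connections; (2) a
   specificity index (SI) — target-network mean minus pooled
   other-networks mean of the gene's population-averaged contributions
   over intra-network connections — beating all 1000 size-preserving label
   permutations; (3) across-network ANOVA rejecting at the Bonferroni
   level 0.05/(number of criterion-2 survivors), computed dynamically;
   (4) first-ranked network mean at least twice the second plus a Welch
   two-sample t-test at P < 0.05, with the final label required to match
   the SI-significant network. Survivor counts per criterion are reported
   in a per-network table and are non-increasing by construction.

## Normalization conventions

- Expression: each gene column is z-scored across regions (population SD).
  In the default `pearson` mode each region row is then standardized
  across genes, which makes the mean-of-products CGE *exactly* the Pearson
  correlation between two regions' profiles; the literal mean-of-products
  definition and the Pearson property cannot both hold exactly, and the
  row step perturbs the column z-scores by O(1/√N). A `literal` mode keeps
  exact column z-scores instead.
- Connectivity: optional Fisher r-to-z (for raw correlation input), then
  per-subject z-scoring across connections with population SD. Whether the
  original analysis Fisher-transformed is not documented; the flag default
  follows the input type (on for raw correlations, off for the synthetic
  benchmark, whose connectivity is already on an unbounded scale).
- Population SD (divisor n) wherever a mean of products must equal a
  Pearson correlation; sample SD (n−1) in every mean+SD selection
  threshold. All averages are unweighted arithmetic means. All mean+SD and
  prevalence thresholds use strict inequality.

## The semi-nonnegative CP model

`cp_decompose_seminonneg` fits `X ≈ Σ_r scale_r · a_r ⊗ b_r ⊗ c_r` with
the individual mode `c_r ≥ 0` (subjects act as nonnegative mixture
weights; genes and connections may carry sign — the natural reading of
"semi-nonnegative" for gene/connection/individual data). Alternating least
squares with exact block updates: free modes by linear least squares on
the Gram system, the constrained mode by row-wise NNLS (only rows whose
unconstrained solution goes negative are re-solved), so the reconstruction
error is non-increasing across sweeps — asserted in tests. Five random
restarts (best final fit kept), tolerance 1e-8 on the change in relative
error, at most 500 iterations; factors are unit-normalized with magnitudes
absorbed into nonnegative component scales, components ordered by scale,
and the gene-vector sign anchored positive at its largest-magnitude entry.

**Rank.** The reference-scale analysis uses rank 10 (the `cpdecomp`
default). The synthetic benchmark plants a *single* global coupling
pattern, and its tensor is essentially (gene × connection matrix) ⊗
(subject profile): every coupling direction shares one subject profile, so
the Kruskal uniqueness condition fails for rank > 1 and ALS mixes the
dominant direction across components. Rank 1 is the identified model at
this scale and is the pipeline default; the module itself is rank-general
and rank-10 recovery is tested on identifiable planted tensors.

## Permutation null

"Shuffling gene and connection labels" is implemented as a full joint
shuffle of the population-averaged matrix entries — the only reading that
changes per-gene means (permuting row/column labels alone would not). A
`within_connection` mode (independent column shuffles, preserving
per-connection marginals) is provided. The exceed-all-nulls criterion
gives P < 1/n_perm; empirical p-values are reported as
`(1 + #{null ≥ observed}) / (n_perm + 1)` and calibration on exchangeable
nulls is verified (≈ 1/1001 significant, binomial tolerance).

## Synthetic benchmarks

The generator plants a connectivity **template**
`T_s = base + system·[same system] + intra·[same network] +
homolog·[mirror pair]`, each subject observing `T + N(0, σ_h²)` with
per-subject noise levels drawn from `σ ± spread` (individuals differ in
data quality, hence coupling strength). Homologs are interleaved
even/odd region pairs sharing a network. Planted genes mix a standardized
signal pattern `v` with unit noise, `√c·v + √(1−c)·noise`, where `c` is
the coupling effect (expression-variance share).

Three planted-gene archetypes:

- **rank-1 coupling genes** use the pattern maximizing
  `|corr(v_i·v_j, T)|` over zero-mean `v` (BFGS from the doubly-centered
  template's leading eigenvector). A single gene's co-expression product
  is rank-1 in the region pair, so this is the strongest signal a gene can
  carry; the raw leading eigenvector of a block template is near-uniform
  and its centered product barely tracks the template. This ceiling also
  motivates the default template's realism choices: heterogeneous network
  sizes and a two-system hierarchy (the largest network versus the rest),
  both properties of real parcellations, raise the attainable alignment
  from ≈0.59 to ≈0.9.
- **bilateral coupling genes** are independent hemisphere-symmetric
  patterns: their co-expression is elevated at every homologous pair, so
  the ensemble couples to homotopic connectivity equally in all networks —
  the archetype of a *network-shared* gene (with equal network sizes the
  homolog share per network is constant, so their per-network
  contributions are balanced).
- **network-specific genes** use the leading eigenvector of the template
  restricted to one network's regions, zero-padded elsewhere, so their
  contribution concentrates on that network's intra-network connections.

Benchmarks (sizes chosen to keep every run in seconds while preserving the
regimes that matter):

| benchmark | purpose | key settings |
|---|---|---|
| `default_config` | end-to-end pipeline | 90 regions (4005 connections, the reference atlas size), networks (42,24,12,12), 300 genes: 20 rank-1 (effects 0.3–0.9) + 10 network-specific, 40 subjects, noise 0.2±0.1 |
| `connectivity_config` | gene-related connection recovery | 40 regions, 4×10 networks, homolog boost 1.0 ≫ intra 0.3, 50 bilateral genes (effect 0.7) of 150; planted connections = the 20 homologous pairs |
| `dissection_config` | network-shared / network-specific recovery | 40 regions, 4×10 networks, 20 bilateral genes + 10 network-specific (effect 0.75) of 160 |

The per-gene effect gradient in the default benchmark (0.3–0.9) reflects
that real connectivity-related genes are unequally coupled; the mean+SD
selection stages specifically target the strongest, so a homogeneous pool
would make their selections pure noise. The network-specific effect of
0.75 in the dissection benchmark follows from a power computation: the
exceed-all-1000-permutations SI criterion needs ≈3.3σ of separation, which
weaker effects cannot deliver with ~45 connections per network.

Ground truth for connections is recorded as the noiseless-limit mean+SD
selection on |z(T)·z(expected CGE)|. On the homotopic benchmark this set
is crisp (the homologous pairs) and the pipeline recovers it (pooled
sensitivity ≈0.93, specificity ≈1.0 over three seeds); on the hierarchical
default benchmark the noiseless coupled set is broad (~28% of
connections) while a noisy run selects ~13%, so exact set recovery is not
a meaningful criterion there and the manifest simply reports the overlap.

**What the generator does not emulate**, hence what green tests do *not*
establish about real data: gene–gene spatial autocorrelation and
co-expression modules (background genes are iid noise — the screening
null is therefore cleaner than in real data, where a fixed shared
connectivity structure makes per-subject tests anti-conservative; the
originating procedure likewise applies no spatial-autocorrelation
correction); BOLD acquisition, preprocessing and motion artifacts
(connectivity is generated at the matrix level); site effects beyond
labels; distance-dependent connectivity; subject-specific expression.

Two further honest power limits at benchmark scale, both documented
rather than patched: the permutation route's exceed-all-nulls bar requires
a per-gene mean gap of ≈3.4σ/√S, so with a ~30-gene pool of near-clonal
planted genes only the globally strongest (often the network-specific
ones) clear it, and the reliable-gene intersection of the two routes can
be empty — at the reference scale the pool is ~1300 heterogeneous genes
and both routes sample its top; and the screening criterion's published
operating point is only reached because the benchmark's planted effects
are unambiguous.

## Numerical and edge-case choices

- Degenerate (constant-product) genes in screening are flagged and treated
  as non-significant, never fatal; constant gene columns in normalization
  raise with the gene named.
- Networks with fewer than two intra-network connections are excluded from
  group statistics with a warning; the per-network CP rank is reduced to
  the sub-tensor dimensions with a warning.
- Leading-component ties warn and keep stable order. All-zero tensors and
  NaNs raise. Constant weight or CEC vectors yield empty selections with a
  warning.
- Post-hoc network ranking uses absolute means (with a warning) when
  network means carry mixed signs; the twice-greater rule reads
  `first ≥ 2 × second`.
- `split_groups` errors below 2 subjects per group.
- Group splitting, CP restarts, permutations and SI nulls each consume
  seeds derived deterministically from the run seed; end-to-end runs are
  byte-reproducible (asserted in the acceptance suite).

## Limitations

Beyond the generator's simplifications above: the SI is a target-vs-rest
mean difference with a size-preserving permutation null — the simplest
statistic matching its stated purpose; the cell-type-derived original it
adapts is proportion-based, and a fold-ratio variant would need a
different null. Mismatch rate and correspondence are this package's
definitions. The pipeline holds expression fixed across subjects by
design; cohorts with subject-level expression would need a different
coupling tensor. Inputs are assumed complete (no missing-value handling).
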