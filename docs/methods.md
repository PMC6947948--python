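# Methods

## Model and assumptions

The unit of analysis is a *triplet*: three pairwise-interacting genes (a PPI
triangle) that can be assigned the three roles immune / inflammation /
disease, one role per gene. The working assumption is that disease-relevant
biology shows up as *coordinated* change across such triangles — either in
mean expression (differential expression of all three genes) or in
co-expression structure (the three pairwise correlations differ between
cases and controls). Both signals are summarised per triplet:

* `score_dif = P_immune · P_inflammation · P_disease`, the product of the
  three per-gene two-sided two-sample t-test p-values (pooled-variance
  Student by default, Welch behind a flag). The product is small when all
  three genes shift together; it is *not* a p-value itself and is only used
  as an ordering statistic.
* `score_pcc = |Δr₁·Δr₂·Δr₃|` with `Δr = r_case − r_ctrl` per gene pair
  (Pearson, within group). Each `Δr ∈ [−2,2]`, so `score_pcc ∈ [0,8]`;
  large values mean rewiring of all three edges.

The two orderings are merged by equally weighted average ranks (ties get
fractional average ranks), oriented so that larger final score = more
dysregulated. Ranks rather than raw values make the combination
scale-free, at the cost of cohort-relative meaning: a triplet's final
score depends on what else was scored.

### Permutation null

Significance is assessed by shuffling sample labels with group sizes
preserved, rescoring every triplet per shuffle, and computing the add-one
empirical p-value `(1 + #{permuted final ≥ observed final}) / (1 + n_perm)`
per triplet. The subtle choice is the scale on which a permuted score
becomes a *final (rank) score*. Two variants are implemented
(`null_reference` in `permutation_pvalues`):

* **observed** (default): the permuted `score_dif` / `score_pcc` are ranked
  against the observed cohort's score distributions. The question answered
  is "would a label-shuffled version of this triplet score as high on the
  real ranking?". Under a global null this is calibrated (uniform p), and
  power is not bounded by cohort size.
* **cohort**: the permuted cohort is re-ranked jointly against itself.
  Because a joint ranking always uses up the ranks 1..M, each triplet's
  permuted final score is marginally uniform whenever triplets are
  exchangeable; at most about α·M triplets can then ever reach p < α,
  which silently caps power when a sizeable fraction of the cohort is
  genuinely dysregulated (with 30 of 150 triplets planted, measured power
  drops from 1.0 to ≈0.57). It is kept because it is the natural reading
  of "permutation-based final ranking score" and useful for comparison.

The add-one convention keeps p > 0 and includes the observed labeling as
one permutation; the comparison is `≥` (ties count against significance).
Selection uses strict `perm_p < α` with no multiplicity correction — the
p-values are decision scores for network construction, not inferential
claims about individual triplets.

### Numerical choices

* t-test p-values are floored at 1e-300 so `score_dif` never underflows to
  exact 0; zero-pooled-variance rows give p = 1 (equal means) or the floor
  (unequal means).
* A constant expression vector makes Pearson correlation undefined; such
  pairs get r = 0 with a logged warning.
* All scoring is vectorised over unique genes and unique gene pairs, so the
  permutation loop costs O(n_perm · (genes + pairs) · samples).

## Core clusters

Cluster quality is cohesiveness `w_in / (w_in + w_bound + penalty·|S|)`
(unit edge weights, penalty default 2), the protein-complex objective of
the ClusterONE family. Search is a deterministic grow/shrink local search
(best single-vertex addition or removal, strict improvement, lexicographic
tie-breaks) started from every vertex in decreasing-degree order, from
every closed neighborhood, and from every connected component. The richer
seed set matters: from single-vertex seeds alone the search provably
cannot reach optima that require crossing low-cohesiveness intermediate
states (e.g. two triangles joined by a bridge), and with it the search
matched the exhaustive-subset optimum on all 300 random ≤8-node graphs
tried during development. Candidates with overlap `|A∩B|²/(|A||B|) ≥ 0.8`
are merged, then filtered to ≥3 members and induced edge density ≥ 0.5,
ranked by cohesiveness; the top 4 are reported by default. The defaults
mirror the published plugin defaults.

## Consensus classification

For each candidate group count k in 2..k_max, samples (profiles over a
cluster's genes) are subsampled at 80% for 100 rounds; k-means (10 restarts,
a fixed RNG stream per (k, round)) partitions each subsample, and the
consensus matrix accumulates co-clustered / co-sampled frequencies. The
area under the empirical CDF of the upper-triangle consensus values is
computed by trapezoid on a 201-point grid; `delta_area(2) = area(2)` and
`delta_area(k) = (area(k) − area(k−1))/area(k−1)` otherwise, and the chosen
k is the largest one with `delta_area ≥ 0.1` (threshold configurable and
reported). Final assignment cuts an average-linkage dendrogram of
(1 − consensus) at the chosen k.

A caveat worth knowing: on idealized *equal tight* blobs the delta-area
rule overshoots — at k above the true group count, which blob gets split
varies between subsamples, the consensus acquires intermediate values, and
the CDF area keeps growing by more than the threshold (measured
delta_area(3) ≈ 0.23 on two 10-SD-separated blobs). The `stable` flag
(consensus essentially binary, genuine separation present, chosen_k groups
realised) is the guard against trusting such a k. Cluster-vs-status
association uses the Pearson chi-square without continuity correction;
empty groups are dropped, and tables smaller than 2×2 raise.

## Synthetic data

`simulate_scenario` emulates exactly the structure the scoring model
assumes, with defaults set to the study conditions used throughout the
tests: 30 planted + 120 null triangles on 600 genes, ER background edge
probability 0.005, 20 cases + 20 controls, case-side mean shift 1.5 × the
within-group SD on all three planted genes, compound-symmetric pairwise
correlation +0.6 in cases versus −0.6 in controls for planted triplets,
and −0.6 in both groups for null triplets. Each triangle owns its three
genes (disjoint triples), so ground truth is unambiguous. A 3×3
compound-symmetric correlation matrix requires ρ > −1/2; requested values
below that are repaired to the nearest correlation matrix by eigenvalue
clipping, which puts the effective control correlation near −0.49 (so the
planted rewiring per pair is ≈1.09, not 1.2). Background genes draw roles
from (0.45, 0.25, 0.15) immune/inflammation/disease fractions with a 0.15
multifunction fraction to exercise the role-assignment logic; drugs target
uniformly sampled genes. Everything derives from one `SeedSequence`, so
identical seeds give byte-identical scenarios.

What the generator does *not* emulate: probe-level noise, batch effects,
heavy-tailed expression, correlated background genes, hub-biased drug
targeting, or role catalogs with annotation errors. Passing recovery tests
therefore demonstrates correctness of the machinery under the stated
generative model, not performance on microarray data.

## Design choices on genuinely open points

* Triangles, not loose "interactions": `score_pcc` needs all three pairwise
  correlations, so a triplet is defined as a full triangle.
* A multifunction gene can support several role assignments of one
  triangle; every valid assignment is emitted as its own triplet by default
  (`mode="first"` keeps one per gene set).
* Expression values are used as provided — no log transform or
  normalisation is applied implicitly.
* Probes mapping to several symbols contribute to each symbol's mean; gene
  rows with missing values are excluded from scoring with a warning.
* The degree-distribution fit regresses log10 raw frequency n(k) on
  log10 k (network-analyzer convention), requiring ≥3 distinct degrees.

## Problem sizes and runtime

Default test and acceptance runs use the study conditions above with 200
permutations; the full pytest suite finishes in well under a minute and
`scripts/acceptance.py` in a few seconds on one CPU. Larger cohorts scale
linearly in permutations and in unique genes/pairs.

## Known limitations

* Final scores are cohort-relative; adding triplets changes every rank.
* The observed-reference permutation null includes each triplet's own
  observed score in the reference scale (conservative by O(1/M)).
* The greedy cohesiveness search is exact only empirically (on small
  graphs); no optimality guarantee exists for large networks.
* The consensus delta-area rule inherits the instability described above;
  inspect `cdf_area`/`delta_area` and the `stable` flag rather than
  trusting `chosen_k` blindly.
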