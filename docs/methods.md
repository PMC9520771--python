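# Methods

## The model

`dcsp` implements a driver- and drug-aware measure of pathway activity and a
screen for pathways whose activation is specific to a single cancer type.

For a drug *D* with target genes *T*, a pathway *P*, and a directed
regulatory network, the pathway genes are split into

* **G_u** — the targets that are pathway members plus every pathway gene
  from which some target can be reached along directed edges (unbounded-depth
  transitive reachability), and
* **G_d** — pathway genes reachable *from* a target, minus G_u.

Per tumor sample the upstream expression sum S(G_u) is weighted by three
network-enrichment connectivity scores:

    PAS_u = S(G_u) · (1 + w1 + w2 + w3)
    PAS_d = S(G_d) · (1 + w1 + w2 + w3)
    PAS   = PAS_u − PAS_d

The weights are w_i = Φ(z_i), where z_i is the network enrichment analysis
(NEA) z-score of the link count between two gene sets in an undirected
functional network — (drivers ↔ targets), (drivers ↔ pathway),
(targets ↔ pathway) — standardized by a degree-preserving randomization null:

    z = (d_AF − mean_null) / sd_null

Φ is the standard normal CDF; it is the only standard "normal probability
score" reading that maps z-scores into [0, 1] with 0.5 at z = 0, matching the
intended semantics (0 ≈ no functional interaction, 1 ≈ strong interaction).
The downstream-activation variant of the score is simply −PAS.

### The specificity screen

For every (drug, pathway, cancer) triplet two statistics are computed from
the per-sample PAS values:

* **T1** — a robust one-vs-rest t statistic: Welch's unequal-variance t on
  10%-trimmed samples (a Yuen-style trimmed t; the trimming fraction is
  configurable and 0 recovers plain Welch), one-sided for overactivation of
  the target cancer against the pooled remaining cancers.
* **T2** — one-way heterogeneity of the *remaining* cancers:
  T2 = Σ_c n_c (m_c − m̄)² / s²_pooled with the sample-size-weighted grand
  mean and the pooled within-cancer variance, referred to a χ² distribution
  with (#remaining − 1) df for reporting.

A triplet is a **DCSP** when (i) the BH-adjusted one-sided p of T1 is below
0.01, (ii) its T2 lies within the first quartile of the T2 values of the
*FDR-passing* members of its family, (iii) every cancer entering the
comparison has more than 5 samples, and (iv) at least 3 cancers enter.
Cancers failing (iii) are excluded from both the rest pool of T1 and from T2
before any statistic is computed.

Two genuinely open choices are exposed as configuration:

* **Family** for multiple testing and the T2 quartile: all (drug, pathway)
  candidates of one target cancer (default) or the global triplet set.
* **Quartile ordering**: the default applies the two filters sequentially —
  the T2 quartile is computed among the candidates that already pass the FDR
  cut. The alternative (`t2_quartile_scope="family"`) takes the quartile over
  the full family before FDR filtering. The sequential reading makes the
  homogeneity filter a refinement of the significance filter; under the
  non-sequential reading the quartile condition of a genuinely specific
  triplet is a ~25% lottery against its own null family, which defeats the
  purpose of the filter whenever only a handful of triplets are real.

### Response statistics

Drug sensitivity is the area under the dose–survival curve (AUC); smaller
AUC = stronger response. For one triplet, samples with positive activation
(PAS > 0; −PAS > 0 for the downstream variant) are kept, PAS and AUC are
independently mapped to normal scores — the rank-based inverse normal
transform Φ⁻¹(r/(n+1)) with average ranks for ties — and Pearson's r is
computed. The rank-based pipeline makes r invariant to monotone rescalings
of either assay. The rediscovery rate RDR(f) is the share of the top f·m
discovery-set records (ranked by discovery r, most extreme first within the
chosen sign) whose one-sided validation p (in the discovery direction) falls
below α; with a validation set independent of PAS, RDR(f) ≈ α at every
fraction, which is the "target line" a negative control should track.

The permutation specificity test compares the PAS of one (drug, pathway)
group against the PAS of (i) other drugs on the same pathway, (ii) the same
drug on other pathways, or (iii) both different. The observed statistic is
the plain pooled-variance two-sample t — under label permutation
exchangeability makes it exact, so no robustification is needed — and the
one-sided empirical p is (1 + #{t* ≥ t_obs})/(n_perm + 1), never zero, with
floor 1/(n_perm + 1) at n_perm = 10,000 by default.

## Numerical and degenerate-case choices

* **NEA nulls.** `permute_network` uses a lazy double-edge-swap chain: two
  edges are drawn uniformly, the proposed swap is rejected in place if it
  would create a self-loop or multi-edge; this chain's stationary law is
  uniform over simple graphs with the fixed degree sequence. Each replicate
  rewires a fresh copy with 10·|E| swap attempts. `analytic` uses the
  configuration-model expectation Σ k_x k_y / (2E) over unordered eligible
  pairs with a Poisson-approximation sd of √mean; it is deterministic and is
  the default inside `pas_matrix`, where thousands of set pairs are scored.
  The analytic sum runs over *unordered* pairs so that the null counts each
  potential edge exactly once, consistent with the observed link count when
  the two sets overlap.
* **Degenerate nulls.** If sd_null = 0 (e.g. gene sets isolated in the
  network) z is defined as 0 — the weight collapses to the neutral 0.5 and
  the PAS stays computable. Gene-set members absent from the network are
  dropped before counting; an error is raised only when a pair of sets loses
  all support.
* **Partition edge cases.** Genes on a cycle through a target are assigned
  to G_u (target-side precedence). Pathway genes reachable in neither
  direction default to G_d — they cannot be argued to feed the target — with
  an `exclude` policy available. A pathway with no upstream support at all
  raises rather than silently scoring.
* **Screen degeneracies.** Zero winsorized variance in both groups yields
  T1 = 0, p = 1 for equal means; zero pooled variance with unequal means
  yields T2 = +∞, which can never pass the quartile filter.
* **Caching.** Within `pas_matrix` the three z-scores are cached across the
  keys they actually depend on — (drug, cancer), (pathway, cancer),
  (drug, pathway) — and permutation seeds are derived per key from the run
  seed via CRC32, so results are independent of evaluation order.

## The synthetic cohort generator

`simulate_cohort` emulates the structure of a pharmacogenomic screening
cohort; its defaults are the conditions used throughout the test suite:

| parameter | default | rationale |
|---|---|---|
| cancers × samples | 6 × 12 | inside the 6–64 cell-lines-per-cancer range of real screens |
| drugs × pathways | 4 × 5 | 20 candidate pairs, desk-scale |
| pathway size | 10 genes | small curated-set scale |
| expression | log-normal, log-mean ~ N(1, 0.5), log-sd 0.4 | TPM-like positive skew, gene-specific abundance |
| functional network | Erdős–Rényi p = 0.01 | sparse background; planted links added at p = 0.5 |
| AUC | 0.5 + N(0, 0.1), planted slope −0.1·standardized S(G_u) | AUC-like scale; planted cor(PAS, AUC) ≈ −0.3…−0.7 |

A planted (drug, pathway, cancer) triplet receives three coordinated
signals: the upstream half of the pathway chain is upshifted in the planted
cancer by `effect_size` within-cancer standard deviations per gene (the
theoretical log-normal sd, so the shift is exact by construction); the
functional network gains driver–target–pathway links; and the drug's AUC in
that cancer is coupled negatively to the true upstream activation.

Two generator choices matter for interpretation:

* **Shared driver pool.** All cancers share one driver-gene pool. With
  cancer-specific random driver sets the connectivity weights themselves
  differ across cancers, which rescales PAS per cancer and makes *every*
  pathway look cancer-specific — a configuration without planted signals
  would not be a null for the screen. Sharing the pool keeps cancers
  exchangeable under the null; the cost is that the simulator does not probe
  the regime where driver repertoires genuinely differ between cancers.
* **Drug placement.** Planted drugs act mid-chain (half the pathway
  upstream); background drugs act at the top of the chain (one upstream
  gene). This makes a planted expression shift specific to the planted
  (drug, pathway) pair — if every drug split a pathway at the same point,
  all drugs would inherit the same upstream signal and the planted drug
  would be statistically indistinguishable from its siblings.

What the simulator does **not** reproduce: gene–gene expression correlation,
pathway overlap, realistic network topology (scale-free degree
distributions, modules), dose–response curve shapes, batch structure, or
missingness. Passing tests therefore demonstrate the statistical properties
of the method under its own assumptions, not performance on real cohorts.

## Problem sizes in the test suite

The acceptance tests run 200 null cohorts and 100 planted replicates at the
default 6 × 12 size, 1,000-replicate null calibrations of the correlation
and 10,000-permutation specificity tests, 200-replicate rediscovery-rate
simulations, a 100-DAG partition oracle and an exhaustive enumeration of a
7-node degree class — sizes chosen so the full suite completes in about two
minutes on one CPU while every bound retains its stated Monte-Carlo meaning.

## Known limitations

* The trimmed one-sided t p-values are mildly liberal in the far tail for
  skewed expression sums at n ≈ 12 (measured ≈ 2× at p = 10⁻³ under the
  generator's null); the screen's binomial calibration bound still holds
  with an order of magnitude to spare.
* The analytic NEA null underestimates the permutation sd on very dense
  networks (Poisson approximation); use `permute_network` when link counts
  are large relative to the network.
* `expression_sum` restricts G_u to genes present in the expression matrix;
  drug targets outside the measured transcriptome contribute to the
  partition and the weights but not to S(G_u).
* The quartile filter is undefined on an empty FDR-passing family; such
  families simply produce no DCSPs.
* With very small FDR-passing families the sequential quartile rule loses
  its screening power: if the only survivors of a family share an inflated
  T2 (e.g. because a strong shift in another cancer sits in their rest
  pool), the empirical quartile of that tiny pool cannot reject them. At
  realistic candidate counts (thousands of pairs per cancer) the survivor
  pool is large enough for the quartile to be meaningful; at desk scale an
  occasional heterogeneous triplet can slip through.
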