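# Methods

## Network reconstruction

A subject's raw data is a directed integer matrix of streamline counts
(`counts[i, j]` = streamlines seeded in ROI i passing through ROI j) and a
per-seed way-total vector. Connection probability is `counts[i, j] /
waytotal[i]`; the non-directional weight is the average of the two
directions. The weakest fraction (default 0.10) of each subject's
*nonzero* undirected edges is then zeroed.

Decisions where the procedure admitted more than one reading:

- "Lowest 10% of connections" counts nonzero undirected edges per
  subject, not all n(n−1)/2 possible pairs and not an absolute weight
  cutoff: zero entries are non-connections, and a per-subject edge count
  keeps the rule comparable across subjects of different density.
- The number removed is `floor(fraction * m)`; ties on weight are broken
  by ascending (weight, smaller node id, larger node id) so thresholding
  is deterministic.
- Thresholding is applied after symmetrization (the order in which the
  reconstruction steps are naturally stated).
- Networks are never binarized; every downstream metric is weighted.

## Graph metrics

Weights are probabilities in [0, 1], so the distance of an edge is the
reciprocal of its weight (strong connection = short edge), the
convention of the standard brain-connectivity toolboxes. The metric
engine is implemented in this package (all-pairs distances by
Floyd–Warshall relaxation — with an optional numba-compiled kernel of
the identical loop — and betweenness by Brandes' algorithm with a binary
heap); `networkx` and exhaustive path enumeration serve as independent
oracles in the test suite only.

- Global efficiency averages inverse shortest-path lengths over
  unordered pairs; disconnected pairs contribute 0 rather than raising,
  so fragmenting networks (during attack) remain well defined.
- Local efficiency of node i is the global efficiency of the subgraph
  induced on i's neighbors with the original edge weights; paths through
  non-neighbors are excluded (the alternative — shortest paths through
  the full graph restricted to neighbor endpoints — is deliberately not
  used, to match the "between direct neighbors" definition). Nodes with
  degree < 2 score 0.
- Clustering is Onnela's geometric-mean form with weights normalized by
  the *network-wide* maximum; degree < 2 scores 0 by convention.
- Betweenness is unnormalized and counts unordered source–target pairs.
  Shortest-path ties split credit proportionally to path counts; equal
  distances are compared exactly (no tolerance), matching the reference
  implementations.
- Mean connectivity strength averages over nonzero edges (not over all
  possible pairs); an all-pairs variant was considered and rejected
  because strength is meant to describe retained connections.

## Robustness simulation

Forty of the 87 nodes are removed one by one in order of decreasing
nodal degree; after every deletion, global efficiency and the
clustering-coefficient mean are recomputed on the induced subnetwork of
survivors. Because "decreasing degree" can describe a fixed or a
recomputed ranking, both are implemented: `static` (default) ranks nodes
once on the intact network; `adaptive` re-ranks at every step. Degree
ties — common in dense thresholded networks — break by higher nodal
strength, then lower node id. Nodes whose degree drops below 2
contribute 0 to clustering, which keeps the trajectory defined however
far the attack proceeds (with the 40-of-87 default, at least 47 nodes
always survive). A uniformly random deletion order (`random_attack`,
replicated and seeded) provides the comparison baseline.

## Statistics

- **Global comparison.** Per metric, Shapiro–Wilk (α = 0.05) in each
  group gates the test: both normal → two-tailed Welch t (unequal
  variances; group sizes 48 vs 24 are unbalanced, so pooling is not
  assumed); otherwise Mann–Whitney U, exact when the combined n ≤ 20
  and untied, tie-corrected normal approximation otherwise. Every
  output row names the test that ran. Zero variance in both groups
  yields p = 1 with a warning.
- **Nodal comparison.** The same test per (property, node); the
  Benjamini–Hochberg step-up adjustment is applied within each property
  family (local efficiency, degree, betweenness; m = n nodes each),
  because the three properties form separate reporting blocks. A pooled
  mode is available. Uncorrected p < 0.05 is flagged separately.
- **Clinical correlations.** Pearson r per (metric, score, group) —
  Pearson because r is the reported quantity; a Spearman mode exists —
  pairwise-complete over missing scores; symptom/functioning scales
  exist only for patients. Constant vectors or n < 3 produce flagged
  rows, not errors.
- **Mixed model.** `global_efficiency ~ n_removed * group` with a
  per-subject random intercept, REML (statsmodels MixedLM); the Wald z
  test of the interaction measures whether the groups' deterioration
  slopes differ. The clustering trajectory is excluded by default: its
  U-shaped course violates the linearity the model assumes.

## Synthetic data generator

What it emulates: per-subject dense weighted connectomes with (a) a
shared anatomical block structure, (b) subject-level variation through a
single latent factor, (c) a small global patient deficit with extra
focal deficits, and (d) clinical scores correlated with the latent
factor.

- **Template.** Propensities are block-structured: homologous left/right
  pairs 0.70, same hemisphere & same region class 0.57, same hemisphere
  0.43, cross-hemisphere 0.28, times a symmetric lognormal jitter
  (sd 0.25 on the log scale) from a frozen generator that is part of
  the template definition, clipped to [0.01, 0.95]. The level is chosen
  so mean connectivity strength of reconstructed networks is ≈ 0.35 and
  nodal degrees after the 10% threshold land in the high tens on 87
  nodes — the density regime of probabilistic-tractography connectomes.
- **Subject factor.** s ~ N(1, 0.05²), truncated positive. 0.05 puts
  the between-subject coefficient of variation at 5%, small against the
  group deficit of 5% so group directions are recoverable, yet large
  against binomial sampling noise (≈ 0.7% per edge at 5000 samples), so
  subjects differ genuinely.
- **Deficits.** Patient propensities are multiplied by 0.95 globally
  and by 0.85 on rows/columns of a configurable focal region list
  (default: left caudate and accumbens, left thalamus, bilateral
  rostral anterior cingulate, bilateral superior temporal, left
  precuneus). Deficits act on propensities, not counts, so the
  reconstruction stage sees realistic sampling noise. These effect
  sizes are calibrated to make the qualitative group *directions*
  recoverable, not any published magnitudes.
- **Counts.** Independent Binomial(5000, propensity) per ordered pair —
  independent rather than multinomial because a probabilistic
  streamline can intersect several targets, so per-target counts are
  not mutually exclusive and need not sum to the way-total.
- **Clinical scores.** score = mean + slope·(s − 1) + noise, with the
  slope set from a target correlation r (slope = r·sd/σ_s) and noise sd
  = sd·√(1 − r²), so the marginal group mean/SD equal their targets
  (FSIQ raw 97.8 ± 15.5 patients / 120.1 ± 9.2 controls; CTT-1
  48.6 ± 14.4 / 54.5 ± 7.5; CTT-2 47.0 ± 13.7 / 63.8 ± 20.5; PANSS
  61.0 ± 14.7 and GAF 39.8 ± 19.3 patients only). Default link
  correlations: 0.15 (FSIQ), 0.30 (CTT-1), 0.25 (CTT-2), −0.10
  (PANSS), 0.10 (GAF) — modest positive cognition links, a weak
  negative symptom link.

What it does **not** emulate: spatial geometry and distance-dependent
connection costs, heavy-tailed weight distributions, within-subject
scan–rescan variability, site/motion artifacts, or structured
missingness in clinical scores. Passing tests therefore demonstrate
correctness and calibration of the *pipeline*, not biological validity
of any particular effect size.

## Numerical and degenerate-input choices

- Edge weight 0 ⇒ distance ∞; 1/∞ := 0 in every efficiency; isolated
  or degree-1 nodes score 0 in clustering and local efficiency.
- All-pairs distances come from Floyd–Warshall relaxation; the numba
  kernel performs the same relaxations in the same order, so results
  are bit-identical to the numpy path.
- The BH adjustment is the step-up `min_{j ≥ i} (m·p_(j)/j)` capped at
  1, validated against exhaustive cutoff checking and against
  statsmodels.
- Randomness: a single master seed feeds a `SeedSequence` hierarchy —
  one child per subject plus one for clinical noise — so cohorts are
  bit-reproducible and per-subject streams independent.
- Simulation sizes in the test suite: oracle equivalence uses 200
  random graphs of ≤ 8 nodes (exhaustive enumeration is exact there);
  type-I calibration uses 1000 null cohorts of 12 + 12 subjects;
  mixed-model coverage uses 200 replicates of 10 + 10 subjects × 20
  steps; direction recovery uses 100 full-size cohorts (48 + 24).

## Known limitations

- The 87-region atlas reconstructs the standard cortical parcellation
  plus subcortical structures; the exact membership beyond the count
  and class groupings is advisory.
- The attack simulation records only targeted (degree-ordered) and
  uniform-random deletions; strength- or betweenness-ordered attacks
  are not implemented.
- With the default synthetic effect sizes, group differences are much
  stronger than in small clinical samples (binomial sampling noise at
  5000 streamlines is tiny), so p-values from the default cohort are
  far smaller than anything a comparable imaging study would report;
  only directions and calibration properties are meaningful.
- MixedLM Wald p-values are asymptotic; no Satterthwaite/Kenward-Roger
  small-sample correction is applied.
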