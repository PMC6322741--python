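# Methods

## Problem setting

The input is a peptide × sample matrix of spectral counts for
phosphotyrosine-containing peptides, together with a list of gene symbols
flagged as tyrosine kinases (TKs). Because a kinase's activity tracks the
abundance of its phosphorylated isoform, a statistical dependency between
the phospho-state of a TK peptide and that of another peptide, measured
across a large sample compendium, is evidence of a (direct or indirect)
kinase→substrate relationship. The package infers a directed TK→substrate
network from such dependencies, then uses it to score per-sample kinase
activity and candidate synergistic kinase pairs.

## Discretization (IQD)

Spectral counts are small non-negative integers dominated by zeros, so
equal-width bins are useless and plain quantile bins split tie groups.
IQD sorts one peptide's counts (stably, by value then sample index) and
fills bins sequentially: the current bin's quota is
`remaining_points / remaining_bins`; tie groups are absorbed whole (a group
whose first member falls in the current bin joins it entirely, even if it
overshoots the quota); after each bin closes the quota is recomputed.
Consequences, all property-tested: samples with equal counts always share a
bin; all-distinct vectors get occupancies differing by at most one; a
constant vector yields a single bin; and the effective bin number is capped
by the number of distinct values (a choice the original description leaves
open — we cap rather than error). Integer arithmetic (`occupancy × bins ≥
points`) avoids floating-point quota comparisons.

## Mutual information and edge significance

On binned pairs the plug-in estimator is used:
`I(X,Y) = log N + (1/N) Σᵢⱼ kᵢⱼ log(kᵢⱼ / (kᵢ kⱼ))` (nats, 0·log 0 = 0),
clamped at 0 against float round-off. Two significance routes exist:

* **G-test (default).** `G = 2N·I` is exactly the log-likelihood-ratio
  statistic for independence and is asymptotically χ² with
  `(Mx−1)(My−1)` degrees of freedom counted over occupied bins. This
  analytic tail resolves the Bonferroni-scale thresholds (≈ 5×10⁻⁵ for a
  thousand candidate pairs) that a permutation p-value with resolution
  `1/(n_perm+1)` cannot reach at any feasible permutation count — the
  reason it is the default for network screening.
* **Permutation (`mi_pvalue`).** `p = (1 + #{I_perm ≥ I_obs})/(1 + n_perm)`,
  permuting one profile; exact and assumption-free, used for single-pair
  questions and as the null-calibration reference in tests.

Candidate edges are all (kinase peptide, other peptide) pairs — including
other phosphosites of the same gene and other kinases, so cis/trans
autophosphorylation is representable — kept at Bonferroni-corrected
α = 0.05 over the tested pairs. Kinase–kinase pairs are scored once (MI is
symmetric); the stored direction is a convention.

The bin number M is a calibration parameter. `select_bin_number` sweeps M,
infers the network restricted to a gold standard's genes, scores gene-level
precision and sensitivity against the known edges and picks the F1-best M
(smallest on ties; the trade-off rule is configurable). Without a gold
standard the default is M = 10.

## DPI pruning and bootstrap consolidation

For a signaling relay TK₁→TK₂→S the data processing inequality bounds
`I(TK₁,S) ≤ min(I(TK₁,TK₂), I(TK₂,S))`, so in every triangle of network
edges the minimum-MI edge is the candidate indirect path; it is removed
when strictly below `(1 − tolerance) × (second-smallest MI)`. The default
tolerance is 0 (strict). Removal decisions are evaluated on the input
network and applied at once. Since only kinase-anchored pairs ever carry
MI, every triangle necessarily has two regulator vertices; the scan
therefore enumerates regulator pairs and their common neighbors.

The final network is consolidated over B = 100 (default; 50 in the scaled
test runs) bootstraps of the sample columns: each bootstrap is re-discretized,
re-scored and DPI-pruned; an edge's support count s is then tested against a
Poisson model with mean = total support / distinct edges (Bonferroni over
distinct edges at 0.05). Two details:

* The Poisson filter targets sporadic edges. When most detected edges are
  reproducible the mean support approaches B and the upper tail saturates;
  an edge present in **every** bootstrap is retained regardless, since
  deterministic presence cannot be sporadic noise. Majority voting
  (s > B/2) is available as an alternative rule.
* The consolidated MI is the mean over supporting bootstraps.

Edges are annotated with the Spearman correlation of their raw count
profiles (two-sided p, uncorrected, as used for the negative-edge summary);
constant rows give an undefined correlation and are flagged (NaN) and
excluded from sign-fraction denominators. The gene-level projection keeps
the maximum MI over contributing peptide edges. Enrichment of TK–TK edges
among targets is scored by a hypergeometric upper tail over a caller-supplied
target universe; this test formulation is the package's own choice.

## pVIPER

**Signature.** For one test sample, each peptide's score is
`(x − mean(normals)) / sd(normals)` with a variance floor: zero-variance
peptides use the median of the nonzero normal sds. Cell-line and tumor
columns are unreplicated, so this one-sample standardized difference is the
nearest well-defined analogue of a per-peptide t statistic; at least two
normal-class samples are required.

**Signalons.** Per regulator, candidate substrates from the network are
kept when their Spearman correlation with the regulator is significant
after Bonferroni correction over that regulator's candidates (α = 0.05).
Negative-correlation targets are retained in the data structure but
excluded from enrichment — kinases add phosphate, so informative coupling
is positive and the enrichment is single-tail.

**Enrichment.** The signature is ranked by signed score and the ranked
profile is transformed to normal rank quantiles before weighting. This
follows master-regulator practice: raw signature scores are unbounded on
sparse counts (a spiked count over a floored sd can reach 10³–10⁴) and a
single outlier would otherwise dominate the running-sum null. The ES is a
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |rank-quantile| ×
|rho|-weight, miss decrements uniform; the signed maximum-deviation value is
returned). The null redraws size-matched random peptide sets carrying the
same weights (1000 draws by default, seeded); NES = (ES − mean)/sd of the
null and the p-value is the two-sided empirical tail. Flagged (empty-target)
results carry p = 1 instead of raising.

**Protein integration and multiplicity.** Peptide-level NES values of one
gene are combined by Stouffer's method with unit weights, `Σz/√m`; the
combined p-value is computed by applying the same combination to the
permutation null draws, which keeps it uniform under the null by
construction. Benjamini–Hochberg is applied across regulators within each
sample. Note a limitation: the permutation null assumes exchangeable
targets; sibling peptides of a multi-peptide protein are correlated, which
mildly inflates the null rejection rate (measured ≈ 6–9% at nominal 5% with
20% two-peptide proteins, 2–4% without). Calibration checks therefore run
on the exchangeable construction; shadow/pleiotropy-style corrections are
out of scope.

**Pair synergy.** For kinases A and B, the observed ES is computed on the
positive targets shared by both signalons; the null redraws equally sized
sets from the targets unique to either. A small one-sided p thus means the
shared substrates are more enriched than the kinases' private ones — the
signature of a joint dependency. Empty intersections (or pools smaller than
the shared set) give a flagged null result. The subset-resampling null is a
declared construction. A site-level classifier labels samples
`combo_sensitive` / `single_agent` / `insensitive` according to whether the
canonical pair of driver phosphosites (EGFR site 1197 with MET site 1003 by
default) jointly drives significant positive synergy, only the first site
does (with other partners), or neither.

## Drug-synergy statistics

Fractional inhibition is the working scale (converters to/from viability
are provided). Excess Over Bliss is `f_AB − (f_A + f_B − f_A f_B)`. IC50 is
log-dose linear interpolation of the first downward 0.5 crossing of the
viability curve; curves that never cross return a censoring sentinel
(`above_max` / `below_min`), never a number — interpolation was chosen over
4PL fitting as assumption-free for curves reported only through their IC50.
The combination index is `CI = d₁/D₁ + d₂/D₂` labelled strong synergy
(CI ≤ 0.8), borderline (0.8 < CI < 1; the band's upper edge at 1 is a
declared reading), or additive/antagonistic (CI ≥ 1). The Fisher exact test
for prediction-vs-outcome tables is one-sided (hypergeometric upper tail on
the concordant cell); all four margins must be positive.

## Synthetic data generator

The generator emulates a LUAD-like phosphotyrosine compendium at a scale
where full runs finish in seconds (defaults: 10 TKs, 100 substrate
proteins, 154 tumor + 46 cell-line + 50 normal samples, 10 edges per TK,
one planted synergistic pair sharing 50% of its substrates, 2 TK→TK edges,
0.5% negative edges, 20% two-peptide proteins, 60% zero cells). Mechanism:

* Per-sample kinase activity ~ N(0,1) in tumors/cell lines, N(0, 0.3²) in
  normals; TK→TK edges propagate activity with the configured coupling;
  spiked samples model targeted activation (all kinases reset to baseline
  variation, designated ones pinned `spike_magnitude` = 3 sd above baseline).
* Substrate latent = `coupling × Σ(signed parent activities) + √(1−c²)·ε`.
  Parent contributions add, so the shared substrates of two co-activated
  kinases rise above either kinase's private targets — the planted-synergy
  construction. A gene's first peptide carries the gene latent; additional
  peptides are 0.9-correlated satellites.
* Counts are negative-binomial (dispersion 4 by default) with log-rate
  `base + 2.5 × latent`, per-peptide base abundance ~ N(0, 0.8²), and the
  global intercept calibrated by bisection so the expected zero fraction
  equals `zero_inflation`. Zeros are therefore abundance-dependent
  non-detections, as in real spectral counting, not an independent dropout
  mask; `zero_inflation = 1` still yields the all-zero limit. The slope and
  dispersion were fixed once from the attenuation of latent correlation
  through the count layer (count-level Spearman ≈ 0.5 for a latent coupling
  of 0.8), which is what makes the planted structure recoverable at the
  default sample size.

What the generator does **not** emulate: peptide sequences and detectability
differences, batch structure, saturation of spectral counting at high
abundance, phosphatase regulation, and realistic kinase-network topology
beyond a bipartite layer with a few TK→TK edges. Passing recovery tests
therefore demonstrate correctness and calibration of the algorithms under
the stated generative model, not performance guarantees on real LC-MS/MS
data.

## Numerical and testing choices

Natural logarithms throughout (only relative comparisons matter). All
randomness flows through `numpy.random.default_rng` with caller-provided
seeds; derived stage seeds are arithmetic functions of the base seed, so
pipelines and the CLI manifest are byte-reproducible. Test problem sizes
(e.g. 10-seed recovery runs at the default compendium scale, 50-seed
recovery-rate checks at 300 permutations) were chosen to keep the full
suite under a minute while leaving comfortable margins on the tested
thresholds. Oracles in the test suite — a literal transcription of the
iterative binning rule, a double-sum MI estimator, exhaustive triangle
enumeration for DPI, a literal GSEA walk, and hypergeometric enumeration
for the Fisher tail — are written independently of the production code
paths they check.
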