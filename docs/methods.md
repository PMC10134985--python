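# Methods

## Data model

The packaged haplotype table (`mixstock/data/table1.csv`) holds integer
counts of 763-bp mtDNA control-region haplotypes for eleven Atlantic and
Indian-Ocean leatherback rookeries and four Southwest Atlantic foraging
samples, together with declared sample sizes (`N` row, validated against
the column sums at load), nesting-females-per-year weights (`NFpy` row),
and population roles. The seven-stock grouping
(`mixstock/data/stocks.json`) pools ACR/FLA/DR into NWCG and TRI/GUI/FWI
into SECG; the remaining rookeries are singleton stocks. The default
Southwest Atlantic mixture pools the UR, BA, and SBR foraging columns;
the small ES sample (n = 8) is carried in the table but not pooled.

Orphan filtering removes mixture individuals whose haplotype has zero
count in every baseline stock (here Dc1.7 and Dc9.1, 4 individuals,
182 retained of 186). Such haplotypes carry no origin information under
the model — their likelihood is driven entirely by the pseudocounts — and
retaining them only inflates posterior noise. The operation is idempotent
and records its removals.

## Haplotype calling

Queries are compared to the library over a left-anchored window of the
library's alignment length; a call requires a unique exact match, where
IUPAC ambiguity codes match any base in their expansion (so `R` matches
`A`; two codes match if their expansions intersect). Queries matching no
sequence are orphans, reported with the nearest haplotype and its Hamming
distance (ambiguity-aware; ties broken alphabetically). No new haplotype
names are minted — nomenclature for novel control-region variants is a
matter of external curation. A fully ambiguous query that matches several
library sequences is an error rather than an arbitrary call.

## Diversity

Nei's unbiased estimator h = n/(n−1)(1 − Σx_i²) with the large-sample
variance V(h) = 2/(n(n−1)) {2(n−2)[Σx_i³ − (Σx_i²)²] + Σx_i² − (Σx_i²)²}.
The unbiased (n/(n−1)) form is used throughout; reported values are
full-precision, with rounding left to the presentation layer. n < 2 is an
error rather than a zero. The ± value quoted alongside h is sd = V(h)^½.

## Homogeneity

Pearson's X² on the haplotype-by-population contingency table via
`scipy.stats.chi2_contingency` without continuity correction, after
dropping haplotypes absent from every selected population (they would
contribute zero to the statistic but inflate the degrees of freedom);
df = (retained haplotypes − 1)(populations − 1). The asymptotic p-value
is the default even though several expected cells fall below 5 for these
data; an optional Monte-Carlo p-value (tables resimulated under the
pooled frequencies with fixed column totals) is provided for sparse
tables and agrees with the asymptotic value on dense ones.

## Mixed-stock model

Dirichlet-multinomial finite mixture with latent origins, fitted by the
three-block Gibbs sweep described in the README. Numerical choices:

- **Baseline pseudocounts** β_{s,h} = 1/H per stock, H the union of
  baseline and mixture haplotypes, so each stock's frequency prior sums
  to 1 — the minimally informative convention of the mixed-stock
  literature.
- **Mixture prior** scaled to sum to 1 in both modes: flat α_s = 1/S,
  weighted α_s = NFpy_s / ΣNFpy. Keeping both priors at total weight 1
  makes flat and weighted runs directly comparable.
- **Initialization**: chain k starts with proportion 0.90 on stock
  k mod S and the remainder spread evenly (each of 7 stocks dominates one
  of the 7 default chains), with q at the baseline posterior mean. The
  over-dispersed starts make the Gelman-Rubin diagnostic meaningful.
- **R̂** is the classic potential scale reduction factor computed per
  stock on the kept draws of each chain (no split-half, no rank
  normalization), with the conventional 1.2 threshold; zero-variance
  (degenerate) traces define R̂ = 1. Non-convergence warns and flags the
  result rather than raising.
- **Credible intervals** are equal-tailed empirical 2.5%/97.5% quantiles
  of the pooled kept draws.
- **Degenerate likelihoods**: an individual whose haplotype has zero
  probability under every stock at the current state receives a uniform
  origin draw and the event is logged (cannot occur after orphan
  filtering, but the sampler stays defined).
- **Reproducibility**: one master `SeedSequence` spawns an independent
  child stream per chain, so runs are bit-identical for a given seed and
  chain count.

Correctness of the sampler is established two ways: a 2-stock, 2-haplotype
toy posterior is integrated by brute-force quadrature over the full
(θ, q_A, q_B) cube and the sampler mean must agree within 0.01; and on
synthetic mixtures with known proportions the 95% intervals must cover
the truth at near-nominal rates (≥ 80% over 20 replicates at n = 500).

The default configuration (7 chains × 15,000 sweeps, 10,000 burn-in,
35,000 pooled draws) mirrors standard practice for mtDNA baselines of
this size and runs in seconds. Between-seed variation of posterior means
on the packaged mixture is roughly ±1.5 percentage points, and the
credible-interval endpoints move by several points between seeds, because
the two dominant West African stocks share their major haplotype
(Dc1.1) and the sampler mixes slowly along the GAB↔GHA direction
(autocorrelation decays over hundreds of sweeps). Users comparing runs
should therefore compare intervals, not just means.

## Strandings

The 710-km coast is partitioned at cumulative 350 and 480 km into inner
estuarine, outer estuarine, and oceanic zones (half-open on the left,
closed at the far end); explicit zone labels in the input override
position-based assignment. Months map to austral meteorological seasons
(Dec–Feb Summer, Mar–May Fall, Jun–Aug Winter, Sep–Nov Spring) — the
convention adopted here since season labels are often used without
definition. Life stage splits at the 130-cm minimum nesting CCL into
small juveniles and a combined large-juvenile/adult class, with missing
CCL undetermined. Cause classification is a deterministic cascade in the
order gillnet (monofilament) → longline (hook) → trawl (ropes) →
ghost-net → vessel (severed fresh carcass), so adding lower-priority
evidence never demotes a classification; no evidence means undetermined.

Temporal structure is tested with a likelihood-ratio test of a Poisson
per-level-mean model against a common mean, on counts aggregated per
calendar year (full observed span, including zero years) or per month
(all 12). The statistic is the closed-form deviance difference
2 Σ y_l ln(y_l/ȳ) on chi-squared with levels − 1 df; this avoids
perfect-separation issues that GLM fits hit at zero-count levels and is
verified against a statsmodels Poisson GLM in the tests. It is a
stand-in for mixed-model ANOVAs sometimes used on such data: with only
aggregated counts available the Poisson log-linear LRT is the canonical
choice, but statistic values are not comparable across those model
families.

The alongshore kernel density uses Gaussian kernels with reflection at
both coast endpoints, so mass integrates to 1 over the domain (within
1e-3 by quadrature); bandwidth is Silverman's rule by default (a 30-km
kernel for degenerate single-point inputs) and is always expressed in km.

## Synthetic-data generators

`simulate_mixture` draws each individual's stock from the configured
proportions and its haplotype from that stock's frequencies (by default
the baseline's Dirichlet posterior mean, counts + 1/H — the same
smoothing the sampler uses, so recovery tests close the loop exactly).
`simulate_strandings` draws Poisson event counts per (year, month) with
seasonal rates split evenly over each season's months, positions uniform
within a zone drawn from configured weights, CCL from a truncated normal
(default mean 139.8 cm, sd 11.6 cm on [110, 170]), and a generating cause
that deposits its evidence flag. Defaults emulate the packaged study's
conditions: 25 years at ~8.9 events/year (Summer 2.9, Fall 3.6,
Winter 0.3, Spring 2.1), zone weights 0.116/0.273/0.611 (renormalized
from printed percentages totalling 99.8), ~44% of records with a measured
CCL, and 90.6% of causes undetermined. Both generators emit a truth
sidecar with every generating parameter and the realized latent counts.

What the generators do **not** emulate: carcass drift (positions are the
stranding positions, not death positions), within-season clustering or
multi-day stranding events (counts are independent Poisson), reporting
effort that varies across years, and any dependence between CCL, sex,
zone, and cause. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Known limitations

- The mixed-stock posterior is only as informative as the baseline:
  stocks sharing haplotype profiles (GAB/GHA here) trade off against each
  other, giving wide, strongly negatively correlated intervals; minor
  contributions from stocks sharing cosmopolitan haplotypes (e.g. Dc3.1)
  are mostly prior noise.
- The published chi-squared for the three foraging areas is not
  recoverable from the published count table itself (the table gives
  12.92 at df 14); the implementation reports what the stated method
  yields on the packaged counts.
- Published annual/monthly stranding LRT values require the event-level
  records, which are not publicly deposited; the count model is validated
  on synthetic series instead.
- One-to-one haplotype calling assumes equal-length, pre-aligned
  fragments; heterogeneous-length or indel-bearing sequences are out of
  scope.
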