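# Methods

This note documents the models and procedures implemented in `mirswitch`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## Data model and containers

An `ExpressionStudy` holds a log2-scale intensity matrix (features ×
samples) with a sample sheet (sample, day, replicate). The pipeline assumes
preprocessing (e.g. RMA-style summarisation) has already happened upstream;
it starts from processed log2 values. All correlation screens operate on
**day-mean profiles** — one value per time point, the arithmetic mean of
that day's replicates — because the screening statistics compare temporal
shapes, not replicate scatter. The one exception is peak calling, which by
default uses the replicate-level vector (below).

## Expression filtering, collapsing, normalisation

* **Detection floor.** A feature is expressed when its maximum day-mean
  log2 value strictly exceeds the floor (default 5). The mean, not any
  single replicate, is compared, and the boundary value is excluded; both
  choices are configurable because either convention is defensible.
* **Probe collapsing.** When a probe→feature map is supplied, the probe
  with the highest overall mean intensity represents the feature. This rule
  is deterministic and robust to single-probe dropout; nothing downstream
  depends on it beyond having one row per feature.
* **Min–Max normalisation** rescales a profile to [0, 1] for display and
  cross-feature comparison. A constant profile maps to all zeros with a
  warning rather than raising: flat features legitimately survive filtering
  and must not abort a batch run.
* **Fold changes** are differences of day means on the log2 scale against
  the day-0 (first-day) reference.

## Moderated-t differential expression

Per feature and per day-vs-day-0 contrast, the two-sample pooled variance
s² (d = nₐ + n_b − 2 df) is shrunk toward an empirical-Bayes prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)
    t   = (mean_a − mean_b) / (s̃·√(1/nₐ + 1/n_b)),   df = d + d₀

The hyperparameters (d₀, s₀²) are estimated by the method of moments on
log variances: under the scaled inverse-χ² prior, e = log s² − ψ(d/2) +
log(d/2) has variance ψ′(d/2) + ψ′(d₀/2), which identifies d₀ through a
Newton inversion of the trigamma function; the mean of e then gives s₀².
When the observed spread of log variances does not exceed the sampling
spread expected from d alone, d₀ is flagged infinite and s̃² = s₀²
(a normal reference distribution is then used). Contrasts are fitted per
day rather than through one global design matrix — equivalent for
day-vs-reference contrasts and much simpler. Benjamini–Hochberg adjustment
is applied within each contrast (via statsmodels); the DE call requires
adj-p < 10⁻⁵ **and** |log2FC| > 2, strict by default with a non-strict
option since either reading of the thresholds is plausible. A 10⁻¹² floor
on pooled variances keeps noise-free (simulated) data from producing
undefined statistics.

Calibration measured by the test suite: on pure-null data (5000 features,
3 vs 3) the mean false-discovery proportion at BH 0.05 over 200 fixed seeds
is ≈ 0.02–0.05, and planted 4-log2FC effects at noise sd 0.1 are recovered
with ~100 % sensitivity at adj-p < 10⁻³ with zero null features flagged at
10⁻⁵.

## Peak calling with one-hot templates

A switch-like miRNA is one expressed at baseline except at a single time
point. The detector correlates each miRNA's profile with every one-hot
template (1 at one day, 0 elsewhere) and calls a peak when the best Pearson
r ≥ 0.6, assigning the argmax day (earliest on ties, at most one peak day
per miRNA so per-day counts partition the calls).

**Correlation level.** With a 5-point day-mean profile the template
correlation is extremely permissive: for a completely flat miRNA whose
day means differ only by noise, max-over-days r exceeds 0.6 with
probability ≈ 0.71 — and because Pearson r is scale-invariant this does not
depend on how small the noise is. The default therefore correlates the
full replicate-level sample vector against the template expanded across
replicates (15 points at 3 replicates), which keeps the template logic but
gives the statistic enough degrees of freedom to be selective: the null
pass rate drops to ≈ 0.04 while noiseless planted peaks still score exactly
1. The bare day-mean mode is retained as `peak_level="mean"`
for comparability with analyses that used length-n_days binary vectors.
Measured on the planted-peak benchmark (200 miRNAs, 20 peaked per day,
amplitude 4, noise sd 0.3, 3 replicates): 100 % correct-day recovery,
≈ 4 % false calls among flat miRNAs.

Note that a profile need not be a literal one-hot to pass: any profile
with a sharp unique maximum (e.g. a strongly dynamic miRNA) can correlate
above 0.6 with the template at its maximum day. The templates themselves
pairwise correlate at −1/(n_days − 1).

## Kendall screening and conservation

Candidate interactions from several resources are merged by (miRNA, gene)
identity (union of sources; experimental evidence dominates predicted),
restricted to expressed features, and annotated with the tie-corrected
Kendall τ_b of the miRNA and target day-mean profiles, computed by exact
O(n²) pair enumeration — exact and instant at these profile lengths, and
rank-based so it is robust to monotone distortions. Repression candidates
have τ < −0.2.

Conservation requires a pair to be annotated in both studies with
|τ_vitro − τ_vivo| < 0.2 and τ < −0.2 in both. Two numerical points:

* τ on an n-day profile has discrete support with spacing 2/(n(n−1)/2)
  (0.2 at n = 5). Strict threshold comparisons are therefore enforced up to
  a 10⁻⁹ tolerance, so a gap of exactly 0.2 cannot slip through as
  0.1999…; without this guard the decoy false-positive rate roughly
  doubles.
* The |Δτ| filter compares values from both studies' supports, so matched
  grid lengths make the filter symmetric; distinct lengths are supported
  but change which near-threshold pairs survive.

Surviving pairs are optionally restricted to a user-supplied gene set
(e.g. a heart-development term's descendant closure, always loaded from a
file, never fetched) and aggregated per miRNA: target count, the targets
themselves, and how many are transcriptional regulators. Cross-study
identity is by shared identifiers (same species); no orthology mapping.

At the default thresholds the decoy pass probability is structural:
a null pair passes both-study τ < −0.2 with equal τ support values with
probability ≈ 0.022 on 5-day grids, which sets the precision ceiling of
the screen (≈ 0.82 with 50 planted pairs against 500 decoys; recall
≈ 0.99). Measured seed-averaged numbers are recomputed by
`scripts/acceptance.py`.

## Conditional ontology enrichment

Annotations obey the true-path rule (a term inherits its descendants'
genes; propagation is one topological pass and idempotent). Each term is
tested by the upper-tail hypergeometric P(X ≥ k) for k selected genes among
K term genes, n selected, N universe (scipy's exact tail). To avoid
cascades of significant ancestors that merely contain one enriched child,
terms are processed children-before-parents and the gene content of a
term's already-significant children (p ≤ 0.01, non-strict) is excluded
from that term's annotation set, universe and selection — for that test
only, never globally. Results are independent of which valid
children-first order is used, because conditioning depends only on the
children's (fixed) p-values. The default universe is the expressed genes
appearing in ≥ 1 propagated annotation; using the whole array instead is a
config option. No multiple-testing correction is applied across terms
(conditioned raw p-values are reported). Null calibration: with random
annotations and random selections, ≈ 0.6–1 % of term tests reach p ≤ 0.01
(the deficit from 1 % reflects the test's discreteness).

## Synthetic-data generator

The generator emulates the statistical structure the screens assume, not
array physics:

* every feature draws a constant log2 baseline from `baseline_range`
  (default 6–12, i.e. above the detection floor — the generator models the
  post-QC regime by default; widen the range to exercise the floor);
* peaked miRNAs (a per-day fraction, disjoint across days) gain
  `peak_amplitude` (default 4) at exactly one day, at the same day index in
  both studies;
* miRNAs carrying true interactions follow a dynamic profile: the levels
  0…`peak_amplitude` in a random day order, drawn per miRNA **and per
  study**. Any such profile has distinct day values, so a noiseless target
  is exactly anti-monotone (τ = −1) whatever the shape, while two distinct
  dynamic miRNAs are not systematically rank-correlated — an earlier
  shared-ramp design made decoys crossing opposite-direction ramps into
  systematic false positives, which is a property of the fixture, not of
  the screen;
* each true interaction's target day profile is its baseline minus
  `repression_beta` × (miRNA profile − its mean), applied in the member
  study or in both for conserved ("both") interactions;
* i.i.d. Gaussian noise (sd `noise_sd`, default 0.3 log2 units) is added
  per sample afterwards, so repression couples day profiles, not replicate
  noise;
* decoy interactions are random never-planted (miRNA, gene) pairs; each of
  the five resources lists each true/decoy pair independently with
  probability `resource_coverage` (default 0.6), the last resource marked
  experimental;
* the toy ontology is a single-rooted DAG whose designated term annotates
  exactly the planted heart-like gene set (all true targets plus a random
  tenth of the rest); filler terms annotate random subsets.

Day grids: in vitro defaults to days 0–16 in steps of 4; in vivo defaults
to embryonic days 9.5–13.5 — matched in length (see the conservation note)
but free config, including distinct lengths. Identical configs (including
seed) produce byte-identical fixture files.

**What the generator does not model:** batch/array effects, probe-level
structure, variance heterogeneity across intensity, correlated noise,
indirect regulation, or miRNAs targeting many genes with shared profiles.
Passing the planted-truth benchmarks therefore demonstrates that the
implementation recovers the structure it is designed to detect under clean
conditions; it does not certify performance on real arrays.

## Problem sizes and determinism

The benchmarks use the sizes stated with each measure: 200 miRNAs per seed
for peaks (20 seeds), the default 600-gene/120-miRNA pair with 50 planted
conserved pairs and 500 decoys for the chain (20 seeds), 5000 features for
DE (200 null seeds), and 100 null-ontology seeds (10⁴ term tests). Every
stage is deterministic given the config seed; the pipeline manifest records
input digests and per-stage counts so two runs can be diffed exactly
(stage outputs are byte-identical; the manifest itself embeds run paths).
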