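# Methods

## Scope and data model

The package takes methylation-array **beta values** β ∈ (0,1) (probes ×
samples) with per-sample class labels (EC = esophageal, GC = gastric
adenocarcinoma), gastric molecular subtypes (EBV, MSI, GS, CIN), and
cohort identifiers, plus a per-probe annotation table (gene, coordinates,
TSS interval, CpG-island relation, regulatory group, GO terms, 27k-array
membership).  Raw IDAT processing is out of scope: the pipeline starts at
beta values, as one does with processed GEO series.  All screening and
classification happen on **z-scored M values**; beta values are retained
only for reporting.  M = log₂(β/(1−β)) is a bijection (0,1) ↔ ℝ, and
beta values are clipped to [10⁻⁶, 1−10⁻⁶] wherever they are produced so
M stays finite.

## Normalization

- 27k filtering keeps exactly the annotation's `on_27k` probes, in the
  original matrix order, and precedes testing; the Benjamini–Hochberg
  correction therefore runs over the 27k universe only.
- Batch correction is per-probe z-scoring within each cohort (ddof = 1).
  Rows constant within a cohort map to zeros rather than NaN — degenerate
  synthetic rows must not crash the pipeline — and single-sample cohorts
  are rejected outright because their sd is undefined.
- z-scoring is per probe, not per sample: the batch effects being removed
  are probe-level cohort offsets.

## Moderated t and the variance prior

Per probe, with class sizes n₁ (GC), n₂ (EC) and d = n₁+n₂−2 residual
degrees of freedom, the pooled variance s² is shrunk toward a prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),
    t = (mean_GC − mean_EC) / (s̃·√(1/n₁ + 1/n₂)),  df = d₀ + d.

The prior (d₀, s₀²) is fitted by the method of moments on z = log s²:
e = z − ψ(d/2) + log(d/2) has variance trigamma(d/2) + trigamma(d₀/2),
so d₀ = 2·trigamma⁻¹(Var(e) − trigamma(d/2)) (Newton iteration) and
log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2).  When the observed spread of
log-variances does not exceed what d degrees of freedom already imply,
d₀ = ∞ and s₀² is the arithmetic mean of the variances (full shrinkage);
exact-zero variances are offset to 10⁻⁵ of the median before taking
logs.  A `prior_df` argument can force d₀; `prior_df = 0` recovers the
ordinary pooled two-sample t.  The test suite cross-checks the t
statistics against the limma `lmFit`/`eBayes` pipeline (agreement to
10⁻⁸) and against an independent from-scratch re-derivation (10⁻¹⁰).
One deliberate difference from limma: p-values use d₀ + d degrees of
freedom as stated, without limma's additional cap of the total df at the
pooled residual df — the difference only appears when d₀ = ∞ and is
immaterial at the filter thresholds used.

**Fold change.** A fold change for methylation is not well defined on
the beta scale; here fc = 2^|Δmean M| on the analysis scale, making the
fc > 3 filter direction-agnostic.  Pool membership uses strict
inequalities (fdr < 10⁻⁴, fc > 3), ordered by ascending fdr, ties by
descending fc then probe_id.  A `top_n` mode (most significant n probes)
is exposed as an alternative pool rule; the threshold rule is the
default.

## GO subpools

Subpools are an inverted index of the pool by GO term ("partition with
replacement": multi-term probes join every matching subpool).  The
default minimum subpool size is 31 because a 30-probe signature cannot
be drawn from fewer candidates.  GO annotation is an input table — any
annotation export with (probe, accession, label) rows works; no web
calls.

## The MSS screen

- **RGS size m = 10** (the size of a random gene set is a free
  parameter): m must be well below the subpool size for a frequency
  signal to emerge across hundreds of sets, and small m keeps the
  Fisher 2×2 tables informative.  Configurable.
- **RPS**: 25 samples per gastric subtype + 100 EC = 200 samples,
  ratio 1:1, exact stratification, sampled without replacement.
- **Dissimilar RPS selection**: the full-scale protocol generates
  1,000,000 candidates and keeps the 200 most dissimilar; maximum
  dispersion is NP-hard, so the implementation uses greedy farthest-point
  selection under Jaccard distance on sample-id sets — seed with the
  globally most distant pair, then repeatedly add the candidate whose
  minimum distance to the selection is largest.  Every tie breaks toward
  the lower candidate index, making the selection deterministic given
  candidate order.  The library default generates 10,000 candidates;
  the analysis drivers and acceptance runs use 200 → 50.
- **Per-RPS differential set D**: within the RPS's samples only, pool
  probes are ranked by |moderated t| (the same moderation machinery as
  the pool step — one definition of "differential" everywhere) and the
  top q are taken, q = min(300, ⌊pool/2⌋) by default so D never swallows
  the pool.
- **Fisher enrichment**: one-sided hypergeometric tail
  P(X ≥ |RGS ∩ D|) over the pool universe with |D| draws of |RGS|
  successes.  The exact 2×2 construction is a documented interpretation:
  the screen asks whether a random gene set is over-represented among
  the probes that separate the classes inside that patient subset.
- **Scoring and gilding**: score = 1 / mean(p) across RPSs (permutation
  invariant); RGSs are ranked by descending score, ties by rgs_id, and
  the top 50 per term are gilded.  The signature is the 30 most frequent
  probes across a term's gilded RGSs, ties at the cutoff resolved to the
  lexicographically smallest probe_id.

All sampling consumes one seeded `numpy.random.Generator` threaded
through the run in a fixed order, so runs are bit-reproducible.

## Classification

Nearest-centroid with Euclidean distance (a `correlation` option is
exposed; Euclidean is the default metric for centroid classifiers).
Leave-one-out excludes the sample, recomputes both class centroids, and
reassigns it; exact ties go to EC.  Validation cohorts are evaluated
with the same LOO protocol within the validation set (the protocol is
applied per dataset); a transfer mode (fit centroids on one set, score
another) is also provided.  Precision and recall use GC as the positive
class; zero-denominator cases are reported as undefined (`None`), which
is distinct from 0.

## TSS distances

Coordinates are 1-based, closed intervals.  The TSS is represented by
its interval midpoint, ⌊(start+end)/2⌋; a probe's distance is the
absolute bp separation from its position to that midpoint (strand
ignored — only magnitudes are of interest), and a signature's statistic
is the arithmetic mean over exactly its probes.  The annotation supplies
one TSS per probe; choosing among multiple transcripts is out of scope.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes:

- Generation happens on the M scale — per-probe class means plus
  Gaussian subtype, batch and residual noise terms — then maps back to
  beta.  Defaults: 2,000 probes, 50 planted probes with a 0.3 beta-scale
  class effect, 200 samples per class (50 per gastric subtype),
  3 cohorts, batch sd 0.4 and residual sd 0.35 on the M scale, 85% of
  probes 27k-flagged (planted probes always flagged, so the filter never
  removes the signal by construction).
- Because the logistic map is nonlinear, Gaussian M-noise biases
  realized mean beta toward 0.5; class means are pre-corrected by
  solving E[expit₂(m+ε)] = target (Gauss–Hermite quadrature + bisection)
  so the planted class-mean beta difference equals the requested effect
  size rather than drifting below it.
- Planted probes default to gastric-hypermethylated so the planted
  class-mean beta difference is +effect_size exactly;
  `planted_frac_hyper` allows mixed directions, as real signatures
  contain both.
- Subtype nuisance shifts hit a random 5% marker subset of probes per
  subtype with random sign (magnitude = the M-shift equivalent of a
  ±subtype_shift beta change at β = 0.5).  Shifting *every* probe would
  leak a systematic Jensen-bias class difference into null probes.
- Batch offsets are per (cohort, probe) Gaussians on the M scale; cohort
  assignment is stratified round-robin so each cohort contains every
  class and subtype (per-cohort z-scoring would otherwise distort the
  class signal).  Real inter-cohort batch magnitude is unknowable from
  the study design, so `batch_sd` is a free parameter.
- GO terms: each probe receives 1–3 terms from a 12-term vocabulary;
  planted probes are concentrated (probability 0.9 each) into two
  "signal" terms, so signal carries into specific GO subpools the way a
  coherent biological program would.
- Probe→TSS distances are drawn uniform on [150, 290] bp (promoter
  proximal, mean 220 bp); TSS intervals are symmetric around their
  midpoint.
- A `cohort_seed` argument redraws only the sample-level randomness
  (assignment, batch, noise), producing an independent validation cohort
  over the same probe universe and truth set.

What the generator does **not** emulate: Infinium type-I/II chemistry
bias, copy-number confounding, probe–probe correlation blocks, missing
values, or tumor-purity variation.  Passing tests therefore demonstrate
the pipeline's correctness and its recovery behaviour under idealized
Gaussian-on-M noise with batch structure, not performance on real
arrays.

## Problem sizes

The analysis drivers and acceptance runs use desk-scale parameters —
2,000 probes, 400 samples per cohort, 200 RPS candidates reduced to 50,
100 RGSs per term during discovery (500 where the default screening
parameters themselves are the quantity being exercised) — chosen so the
full pipeline runs in seconds while leaving every structural property
(pool filtering, subpool formation, dissimilarity reduction, gilding,
signature extraction) at its genuine defaults: signature size 30,
RPS size 200 with 25 per subtype, 500 RGSs per term and 50 gilded at
full-scale settings.

## Known limitations

- The greedy max–min RPS reduction is a heuristic; it attains the
  exhaustive optimum on small instances often but not always (the test
  fixture verifies a case where it does).
- The moment-based prior fit matches limma's default estimator, but not
  its robust (`robust=TRUE`) variant.
- With very small pools, q = ⌊pool/2⌋ makes Fisher p-values coarse; the
  ranking across RGSs remains informative, which is all the gilding rule
  needs.
- Signatures are reported per GO term; combining terms' signatures into
  a single panel is left to the user.
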