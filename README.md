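# methylmss

Discovery and validation of DNA-methylation signatures that distinguish
gastric (GC) from esophageal (EC) adenocarcinoma — the classification
problem posed by tumors of the gastroesophageal junction, which are
treated very differently depending on which cancer they resemble.  The
package implements the optimized Multiple Survival Screening (MSS)
resampling algorithm over methylation-array beta values, a leave-one-out
nearest-centroid classifier, and probe-to-TSS distance summaries, and it
ships a seeded synthetic-cohort generator so the complete pipeline runs
end-to-end with no external data.

## The method

Starting from a beta-value matrix B (probes × samples, β ∈ (0,1)) with
class labels, gastric molecular subtypes (EBV, MSI, GS, CIN) and cohort
identifiers:

1. **Normalization.** Probes are restricted to the 27k-array universe
   (promoter-centric probes), converted to M values,
   M = log₂(β / (1 − β)), and z-scored per probe within each cohort to
   absorb batch offsets.
2. **Differential pool.** Each probe is tested GC vs. EC with an
   empirical-Bayes moderated t: the pooled variance s² is shrunk toward
   a prior (d₀, s₀²) fitted by the method of moments on log s², giving
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) and t = Δ/(s̃·√(1/n₁ + 1/n₂)) on
   d₀ + d degrees of freedom.  Probes with Benjamini–Hochberg
   FDR < 10⁻⁴ and fold change 2^|Δ| > 3 form the pool.
3. **GO subpools.** The pool is partitioned *with replacement* into
   GO-term subpools (a probe with several terms joins each).
4. **MSS screen.** For each subpool, many random gene sets (RGS) are
   drawn.  Balanced random patient sets (RPS; 25 samples per gastric
   subtype + an equal number of EC samples, 200 total at full scale)
   are generated in bulk and reduced to the most mutually dissimilar
   subset by greedy max–min selection under Jaccard distance.  Each RGS
   is tested against each RPS with a one-sided Fisher's exact test
   (does the RGS overlap the RPS's top differentially methylated pool
   probes more than chance?); the reciprocal of an RGS's mean Fisher p
   is its enrichment score.  The top-scoring RGSs per term are
   "gilded", and the 30 probes appearing most often across them form
   the term's signature.
5. **Classification.** A sample is represented by its 30-probe
   signature vector; leave-one-out nearest-centroid assigns it to the
   class (EC/GC centroid) it is closer to.  Precision and recall are
   reported with gastric as the positive class.
6. **TSS distances.** Each signature probe's distance to the midpoint
   of its transcription start site is computed, and averaged per
   signature.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic cohort pair (2,000 probes, 50 planted class-effect probes at
beta effect size 0.3, 200 samples per class over 4 gastric subtypes and
3 batches):

```
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_pool.py
python analysis/04_screen.py --seed 1
python analysis/05_classify.py
python analysis/06_tss_distance.py
```

which prints (abridged):

```
discovery: 2000 probes x 400 samples (EC=200, GC=200, 3 cohorts)
planted probes with true class effect: 50 (effect size 0.3 on the beta scale)
discovery: 2000 probes -> 1726 after 27k filter; steps: filter_to_27k -> beta_to_m -> zscore_by_cohort
moderated t on 1726 probes (prior df d0=14.62, prior variance s0^2=0.865)
pool (FDR<1e-4, FC>3): 50 probes, 50 of 50 planted recovered
pool 50 probes; 2 GO subpools >= 31 members; 50 RPSs retained; 10000 Fisher tests
  GO:0005515: 30-probe signature, 30/30 planted
discovery  GO:0005515: precision 100.0%  recall 100.0%  (n=400)
validation GO:0005515: precision 100.0%  recall 100.0%  (n=400)
GO:0005515: mean probe-to-TSS distance 217.5 bp (range 150-285 bp)
```

Reading: the differential filter recovered every planted probe into a
50-probe pool; the MSS screen concentrated the two signal GO terms'
signatures entirely on planted probes; the 30-probe signature classifies
both the discovery cohort and an independently generated validation
cohort perfectly under leave-one-out; and the signature probes sit
~220 bp from their TSS midpoints, i.e. squarely promoter-proximal.

Equivalent library calls:

```python
from methylmss import CohortSpec, ScreenConfig, generate_cohort, discover_signatures

cohort, annotation, truth = generate_cohort(CohortSpec(seed=1))
result = discover_signatures(cohort, annotation,
                             ScreenConfig().scaled(rps_candidates=200, rps_keep=50, rgs_per_term=100),
                             seed=1)
result.signatures  # {go_term: 30-probe Signature}
```

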