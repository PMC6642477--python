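# Methods

## Model and procedure

MLPA reports, for each targeted locus, a fluorescence peak whose height
is proportional to the number of template copies, the probe's own
amplification efficiency, and a per-sample intensity scale (DNA input,
injection, detector gain). The pipeline removes the nuisance factors in
two ratio steps and reads copy number off the result.

With peak height *h(s, p)* for sample *s*, probe *p*:

* **Intra-sample**: *r(s, p) = h(s, p) / A_ref(s)*, where *A_ref(s)* is
  an aggregate of the sample's reference-probe heights. The aggregate is
  the **median** by default (robust to one aberrant reference probe;
  configurable to the mean). This cancels the per-sample scale exactly:
  multiplying a sample's whole peak vector by any c > 0 leaves every
  *r* unchanged, a property the suite tests end to end.
* **Inter-sample**: *DQ(s, p) = r(s, p) / A_samp(p)*, where *A_samp(p)*
  aggregates *r(·, p)* over designated reference samples assumed diploid
  at all targets. The aggregate is the **mean** by default (configurable
  to median). This cancels the per-probe efficiency. When no reference
  samples are designated, the cohort itself is used with a per-probe
  median — valid only when CNVs are rare at every probe — and the
  fallback warns loudly.

Under this model E[DQ] = copies/2 for autosomal targets, and for
noise-free input the equality is exact (an oracle identity the tests
pin).

### Classification

DQ intervals follow the conventional dosage-quotient bands for this
assay class: DQ = 0 homozygous deletion, (0.40, 0.65) heterozygous
deletion, (0.80, 1.20) normal, (1.30, 1.65) heterozygous duplication,
(1.75, 2.15) homozygous duplication, everything else ambiguous. All
intervals are open: every printed endpoint classifies as ambiguous. A
literal DQ = 0 is unattainable once any noise exists, so the
homozygous-deletion class accepts DQ < `hom_del_eps` (default **0.10**,
configurable); DQ in [0.10, 0.40] stays ambiguous, keeping the gap
structure of the published bands intact.

### Gene-level aggregation

A gene is deleted/duplicated if any of its exon probes is. Three cases
the band definition leaves open are resolved as explicit policy:

* same-direction mixed zygosity (HET_DEL + HOM_DEL among one gene's
  probes) → the more extreme class;
* deletion- and duplication-class probes in one gene → `discordant`,
  genotype `Unknown` (never a forced call);
* ambiguous probes are dropped when a sibling probe is called; a gene
  with only ambiguous probes is ambiguous and excluded from frequency
  denominators.

### Cohort summaries

Allele frequencies by direct counting: p_del = f(Del/Del) + f(Del/Wt)/2,
p_dup symmetric, p_wt the remainder. Denominators are *called* samples
per gene (Unknown excluded from numerator and denominator), with
exclusion counts carried alongside. Percentages are half-up rounded at
one decimal (the convention of printed survey tables); internal
arithmetic is full precision. The 14-category mutational-status taxonomy
is a pure function of the set of non-normal gene classes an individual
carries; two of the printed category definitions ("homo- and
heterozygous deletions" appearing twice, as categories 4 and 7) are
textually indistinguishable, so the classifier emits 4 and 7 is
unreachable; the four class combinations with no defined category map to
0 (unclassified) with the set recorded. The 4-group carrier partition
(deletions only / duplications only / both / none) is derived from the
same class sets; "none" coincides with category 1 by construction.

Sample size for estimating a proportion: n₀ = ⌈z²p(1−p)/e²⌉, with finite
population correction n = ⌈n₀ / (1 + (n₀−1)/N)⌉ when a population size
is given. The defaults z = 1.96, and the worked design point p = 0.03,
e = 0.03, give n = 125.

## Synthetic data

No raw capillary data are publicly deposited for pharmacogene MLPA
surveys, so the generator emulates the one property the analysis
depends on — signal proportional to copy number:

    h = base_height · (copies/2) · scale_s · ε

with `scale_s` a per-sample log-normal factor (CV `sample_scale_cv`,
default 0.10) and ε per-peak log-normal noise (CV `noise_cv`, default
0.05), both mean 1. Reference probes behave as permanent 2-copy targets.
Zero copies emit exactly zero (no additive background by default), so
the DQ = 0 class is reachable. Q-fragments are emitted at
`q_level`/`dna_quantity` of reference level (defaults 0.10 and 1.0 —
adequate DNA, passing the 0.33 QC cutoff), D-fragments and the
X-fragment at reference level, and the Y-fragment follows a simulated
per-sample sex (female fraction 0.5).

Cohorts are drawn either from per-gene (del, wt, dup) allele frequencies
with alleles paired i.i.d. (random mating), genes independent, or
directly from a diplotype-label frequency table — multinomially, or
deterministically by largest-remainder apportionment when exact integer
counts at a given n are wanted. Published percentage tables rounded at
one decimal can drift off the simplex by up to ~0.1 in a column total;
totals within 0.2 of 100 (or 0.002 of 1) are renormalized, anything
larger is rejected as a genuine violation.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: electropherogram artifacts
(stutter, pull-up, size-dependent signal decay), GC/length efficiency
trends, batch effects between runs, correlated noise across probes, and
between-gene linkage (genes are simulated independently, so joint
statistics such as double-deletion co-occurrence are not calibrated to
any real cohort).

The bundled dataset module carries the published per-gene genotype and
allele frequency tables of a 123-donor Colombian cohort typed on this
panel. Only marginals were published; per-individual joint genotypes
were not, so joint quantities (category percentages, carrier-group
fractions) are checked as structural properties (partition, sum to
100%) rather than reproduced values.

## Numerical choices

* DQ interval membership is evaluated with strict `<` on floats exactly
  as the bands are stated; no epsilon is applied at interval endpoints.
* Half-up decimal rounding (`decimal.Decimal`) for all reported
  percentages, since banker's rounding would disagree with printed
  tables at .5 boundaries.
* Zero heights propagate to DQ 0, never NaN; division is guarded at the
  aggregates only (zero reference aggregate → sample excluded
  intra-sample, probe uncallable inter-sample, each logged).
* Largest-remainder apportionment breaks remainder ties by stable sort
  order (first listed label wins), making exact-count reconstruction
  fully deterministic.
* The sample-size ceiling subtracts 1e-12 before `ceil` so that an
  analytically integral n₀ is not bumped up by float error.

## Problem sizes

The test suite and the acceptance script run simulations at 200 samples
(noise-free oracle), 300 samples (joint-statistics properties) and 500
samples (noisy recovery), sizes at which binomial sampling error is
small enough for 3-standard-error checks to be meaningful while the
whole suite stays fast (a few seconds).

## Known limitations

* Del/Dup diplotypes total two copies and are necessarily called Wt/Wt;
  the suite asserts this blindness as the expected outcome. Estimated
  deletion and duplication allele frequencies are accordingly biased
  low by a factor (1 − p_other) when both CNV alleles segregate at the
  same gene.
* Duplications of non-functional alleles cannot be distinguished from
  functional ones by dosage alone; phenotype predictions are flagged
  "copy-number-only" on every record.
* No GC/length signal correction, no multi-batch merging, no
  Hardy-Weinberg testing (extension points, intentionally absent).
* QC cutoffs (Q 0.33, D 0.33, Y 0.30) are pragmatic defaults, not
  estimates from real control-fragment distributions; they are
  configurable.
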