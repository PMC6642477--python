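# mlpacnv

Copy-number variation (CNV) profiling of pharmacogenes from MLPA probe
signals: normalization, dosage-quotient calling, per-gene genotyping, and
cohort-level allele/genotype frequency reports, with a synthetic
peak-signal generator for fully reproducible end-to-end testing.

## The problem

Whole-gene deletions and duplications in drug-metabolism genes — the
cytochrome-P450 family (*CYP2D6*, *CYP2A6*, ...) and the glutathione
S-transferases (*GSTM1*, *GSTT1*, *GSTP1*) — change enzyme dosage and with
it drug response: individuals with zero active copies are predicted poor
metabolizers, those with more than two are predicted ultrarapid
metabolizers. Multiplex Ligation-dependent Probe Amplification (MLPA)
measures relative copy number at ~40 targeted exons in a single reaction;
this package implements the downstream analysis a population CNV survey
needs, from raw per-probe peak heights to publication-style frequency
tables.

The default panel covers 40 exon regions in 11 *CYP-450* and 3 *GST*
genes (every gene ≥ 2 probes except *GSTT1*, which has a single exon-1
probe), 8 copy-number-stable reference probes, and the standard MLPA
control fragments (4 Q-, 3 D-, 1 X-, 1 Y-fragment).

## The method

For sample *s* and probe *p* with peak height *h(s, p)*:

1. **Intra-sample normalization** — relative signal
   *r(s, p) = h(s, p) / median{ h(s, q) : q ∈ reference probes }*,
   removing the per-sample intensity scale.
2. **Inter-sample normalization** — dosage quotient
   *DQ(s, p) = r(s, p) / mean{ r(t, p) : t ∈ reference samples }*,
   where reference samples are assumed diploid at every target. For an
   autosomal locus E[DQ] = copies / 2.
3. **Classification** — DQ < 0.10 → homozygous deletion (nominally
   DQ = 0); 0.40 < DQ < 0.65 → heterozygous deletion; 0.80 < DQ < 1.20 →
   normal; 1.30 < DQ < 1.65 → heterozygous duplication; 1.75 < DQ < 2.15 →
   homozygous duplication; every other value (including all interval
   endpoints) → ambiguous.
4. **Gene calls** — a deletion or duplication on any exon marks the whole
   gene; same-direction mixed zygosity resolves to the more extreme class;
   opposite directions in one gene are discordant (genotype Unknown).
5. **Cohort summaries** — genotype frequencies per gene; allele
   frequencies by direct counting, *p(del) = f(Del/Del) + f(Del/Wt)/2*
   (and symmetrically for duplications); a 14-category taxonomy of
   individuals by the combination of CNV classes they carry; a 4-group
   carrier partition (deletions only / duplications only / both / none);
   a per-gene CNV census; and the sample-size calculation
   *n = ⌈z²p(1−p)/e²⌉* with optional finite population correction.

Note the intrinsic blind spot of dosage assays: a Del/Dup individual
carries two copies in total and is indistinguishable from Wt/Wt.

## Worked example

```python
import mlpacnv as m

panel = m.default_panel()                       # 40 targets, 14 genes
freqs = tuple(
    m.AlleleFreqSpec(g, p_del={"GSTM1": 0.476}.get(g, 0.0), p_dup=0.0)
    for g in panel.genes
)
cfg = m.SimConfig(n_samples=500, freqs=freqs, noise_cv=0.05, seed=23)
truth, peaks, refs = m.simulate_run(cfg, panel)  # synthetic MLPA batch
calls = m.call_samples(peaks, panel, reference_sample_ids=refs)
af = m.allele_frequencies(m.genotype_frequencies(calls))
print(round(100 * af.loc["Deletion", "GSTM1"], 1))
```

prints `50.2` — the *GSTM1* deletion-allele frequency the pipeline
recovers from 500 noisy simulated samples whose generating frequency was
47.6%, i.e. within sampling error of the truth (binomial SE on 1000
alleles ≈ 1.6 points).

A bundled dataset (`mlpacnv.datasets`) carries the published per-gene
genotype frequencies of a 123-donor Colombian cohort typed on this
panel; reconstructing integer counts at n = 123 and summarizing them
reproduces the published allele table exactly at one decimal (e.g.
*GSTM1* deletion 47.6%, duplication 15.4%; *GSTT1* deletion 27.2%;
*CYP2D6* duplication 7.7%).

The same workflow is available from the shell:

```sh
mlpacnv simulate --n 123 --freqs freqs.yaml --seed 7 --out sim/
mlpacnv normalize --peaks sim/peaks.tsv --reference-samples REF001,REF002 --out norm/
mlpacnv call --dq norm/dq.tsv --out called/
mlpacnv summarize --calls called/calls.tsv --out report/
mlpacnv samplesize --p 0.03 --e 0.03     # -> 125
```

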