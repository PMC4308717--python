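# xconstraint

Comparative-transcriptomics analysis of **evolutionarily constrained gene
expression and splicing** between two species (think human cell lines vs
mouse tissues profiled by RNA-seq), built as a tested Python library plus a
set of numbered analysis drivers. Because the real consortium panels are
hundreds of millions of reads, every stage is exercised end-to-end on seeded
synthetic two-species panels with known ground truth that emulate the
statistical structure of such data.

## What it computes

**Dynamic range and constrained genes.** For a one-to-one orthologue with
npIDR-filtered RPKM values, the dynamic range is

&nbsp;&nbsp;&nbsp;&nbsp;DNR = log10(max RPKM) − log10(min RPKM)

over the non-zero values pooled across *all* samples of *both* species,
defined only when the gene is detected in ≥ 2 samples per species. Across
orthologues the DNR distribution is bimodal; it is decomposed into two
Gaussians by EM and genes are called **constrained** when DNR ≤ the
intersection point of the weighted component densities — i.e. their
expression varies by less than roughly two orders of magnitude across
tissues, cell types and species. Companion statistics: expression-matched
constrained/unconstrained control sets, the fraction of transcriptional
output (Σ RPKM·length) from constrained genes, a two-factor ANOVA variance
split (gene vs sample), expression breadth, cross-species correlation of
log average expression, antisense-to-total ratios, and nuclear/cytosolic
localization variability.

**Replicate reproducibility (npIDR).** Elements detected in at least one of
two replicates are binned by log signal; a bin's discordance is the fraction
of its elements seen in only one replicate, made monotone non-increasing in
signal. Values with npIDR > 0.1 are zeroed and replicates averaged per
biosample.

**Intron-centric splicing.** Per junction (D, A) and sample:
ψ5 = n(D,A)/Σ_A′ n(D,A′), ψ3 = n(D,A)/Σ_D′ n(D′,A), pooled
ψ = 2n/(den5+den3), and the completeness of splicing
θ = split/(split + boundary reads). Junctions are constitutive-high
(ψ > 0.85 in all samples of both species), constitutive-low (ψ < 0.15
everywhere) or variable; variable junctions with intermediate mean inclusion
m ∈ (0.15, 0.85) and variance ≤ 20% of the Bernoulli maximum m(1−m) are
flagged as **constrained in splicing**.

**Isoform variance decomposition (Vls/Vt).** Samples of a gene are points in
transcript-abundance space; after square-root rescaling, the variance of
their projections onto the constant-splicing ray (fixed isoform proportions)
over the total variance gives the fraction of transcript variation explained
by gene expression — 1 purely expression-driven, 0 purely splicing-driven —
with a bootstrap median to blunt outlier samples.

**Genome-wide signal conservation.** Pearson correlation of log10 mean
coverage over orthologous 100-nt bins, stratified by annotation class,
distance to the nearest gene and conservation score; strand-oriented
metagene profiles of chromatin marks ±500 nt around the TSS/TTS normalized
to the per-mark maximum; and per-orthologue mark divergence
|Δlog10 signal|.

## Worked example

```bash
python analysis/01_simulate_panels.py --seed 1 --outdir results/data
python analysis/03_expression_constraint.py --seed 1 --outdir results
```

prints (seed 1):

```
DNR defined for 4972/5000 orthologues; mixture threshold 1.364 (component means 1.07 / 3.22)
constrained: 2260 (45.5% of defined); accuracy vs generator truth 98.4%
expression-matched control sets: 1060 genes each
transcriptional output from constrained genes: 8.6% (sp1), 9.7% (sp2)
ANOVA variance fractions: gene 0.51, sample 0.0018, residual 0.48
breadth (mean samples detected): constrained 19.2 vs unconstrained 16.7
cross-species cc of log average expression: 0.99 (constrained) vs 0.95 (unconstrained)
```

Reading: of 5,000 simulated orthologues, 4,972 are detected well enough to
carry a DNR; the fitted two-Gaussian intersection lands at 1.36 between the
narrow constrained mode (≈1.1) and the wide unconstrained mode (≈3.2), and
classifying at that threshold recovers the generator's truth labels for
98.4% of genes. Constrained genes are detected in more samples (breadth
19.2 vs 16.7 of 20) and correlate more strongly across species. The other
drivers (`02` npIDR filtering, `04` splicing, `05` Vls/Vt, `06` bins and
metagene profiles) follow the same pattern and write their tables under
`results/`.

The same machinery is scriptable per step, e.g.

```bash
xconstraint psi --junctions results/data/junctions_sp1.tsv \
    --boundaries results/data/boundaries_sp1.tsv | head
xconstraint dnr --matrix1 results/expression_filtered_sp1.tsv \
    --matrix2 results/expression_filtered_sp2.tsv \
    --orthology results/data/gene_orthology.tsv --out results/dnr.tsv
```

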