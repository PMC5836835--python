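# Methods

## Model overview

`terius` treats lncRNA annotation refinement as two sequential two-class
problems, each solved by a one-dimensional class-conditional density
model and a Bayes posterior with equal priors.

**Step 1 (translation).** The statistic is a weighted relative entropy
(WRE) of a transcript's sub-codon signal. A read contributes to
sub-codon position `(t − f) mod 3`, where `t` is the spliced transcript
coordinate of its 5' end and `f` the frame under evaluation; Ribo-seq
reads sharing a 5'-end transcript position are collapsed to one before
counting. The WRE weights come from a reference profile: pooled
sub-codon distributions of Ribo-seq and RNA-seq 5' ends over all
annotated CDSs, anchored at each CDS start. The frame with the highest
WRE of the raw count proportions is the most-likely reading frame
(MLRF); the MLRF signal is then divided componentwise by a random
control (the same total re-distributed uniformly over three positions)
and renormalized before the final θ is computed. This order — select the
frame first, normalize afterwards — is deliberate: frame selection
biases the first position upward, and the control normalization removes
exactly that kind of spurious enrichment (uniform input stays uniform
under its own control).

**Step 2 (3'UTR fragments).** The statistic is θ = ln(CLIP RPM / RNA
RPM) over the transcript's exonic span, where RPM is 5'-end count ×
10⁶ / library size. Zero CLIP signal is qualitatively different from
low signal: it is encoded as a flag, and the per-class flag frequency
replaces the density likelihood in the posterior for flagged
transcripts. The density part of each class model is fitted on the
non-zero θ values only.

### Assumptions

- Translation manifests as phased footprint 5' ends; no P-site offset is
  applied, so the model works on raw 5'-end periodicity, not on inferred
  ribosomal A/P sites.
- The 5'-end base alone decides both sub-codon position and region
  membership; alignment spans are ignored everywhere for consistency.
- The association model assumes the CLIP protein's binding scales with
  transcript abundance within a class, so the RPM ratio is comparable
  across expression levels; transcripts with RNA RPM = 0 are outside its
  domain and are labelled `unclassified_unexpressed` rather than forced.
- Both scores use the natural logarithm; the base is recorded in the
  model file (`log_base=e`) so serialized models are unambiguous.

## Parameters

| parameter | default | meaning |
|---|---|---|
| RPS cutoff | 0.5 | posterior above which step 1 calls non-coding |
| UAS cutoff | 0.5 | posterior at/above which step 2 calls lncRNA (≥, so an exactly-0.5 tie is a lncRNA call) |
| priors | 0.5 / 0.5 | class priors in both posteriors |
| random-control replicates | 30 | multinomial draws averaged into the control; averaging shrinks control variance so the normalization is nearly deterministic at typical depths |
| pseudocount | 0.5 | added symmetrically to observed and control signals only when a control component is 0 |
| training expression floor | RNA RPM ≥ 0.3 | inclusion filter for association training observations; off at classification time unless configured |
| KDE hyper grid | kernels {gaussian, epanechnikov} × bandwidth rules {Silverman, Scott} × adjust {0.5, 1, 2} | searched by the inner CV folds; fully user-configurable |
| balanced cohorts | 50 replicates | negative-class subsamples (size = positive class) whose fitted densities are averaged pointwise into the final model |

Numerical choices: densities are evaluated on a 512-point grid spanning
the data ± 3 effective bandwidths, interpolated linearly, and defined as
0 outside the grid — a θ outside both class supports therefore triggers
the both-zero fallback (posterior 0.5 plus a degeneracy flag) instead of
extrapolation. WRE ties across frames break to the lowest frame index;
isoform-length ties in the training-set filters break to the
lexicographically smaller transcript id. Coordinates are 0-based
half-open internally (GTF converted on read). MLRF is decided per
transcript; 5'-end collapsing is likewise per transcript coordinate,
not genome-wide.

### Nested cross-validation

5 repetitions of stratified 2-fold outer splits; within each outer
training half, a 2-fold inner split scores every hyperparameter
combination by AUC of the class-posterior on the inner held-out half.
The outer half is scored once with the winning combination; the modal
winner across the ten outer folds becomes the final hyperparameter set.
The inner loop is 2-fold to keep the 5 × 2 structure coherent end to
end. Degenerate folds cannot arise because the splits are stratified and
training requires ≥ 10 samples per class.

### 3'UTR fragmentation

lncRNAs are processed in descending spliced length; each is paired,
without replacement, with a uniformly random 3'UTR donor still long
enough (longest-first maximizes the number of successful pairings). The
fragment start is uniform in the donor UTR's spliced coordinates and the
cut is mapped back to genomic intervals, so fragment lengths match their
lncRNA partners exactly even across introns. Ten seeded fragmentation
replicates are averaged into the association model (densities pointwise
on the union grid, zero fractions arithmetically).

## Synthetic data

The generator emulates the statistical structure the classifiers read,
not sequencing realism. Single-exon transcripts (300–1500 nt) are placed
on one contig with alternating strands; multi-exon structure is
unnecessary because both statistics act in spliced coordinates, and
single-exon fixtures keep coordinate oracles trivial. Defaults: 150
transcripts per class; coding transcripts get Poisson(100) Ribo-seq
reads with sub-codon distribution (0.6, 0.2, 0.2) in a recorded true
frame; non-coding transcripts get uniform sub-codon reads at half depth
— deep enough that their sub-codon proportions are estimates of
uniformity rather than pure sampling noise, which is the regime the
recovery benchmarks specify (≥ 50 reads per transcript for both
classes). RNA-seq is uniform Poisson(100) everywhere. CLIP is
Poisson(50 × enrichment), with enrichment 5 for 3'UTR fragments and 1
for lncRNAs, and an exactly assigned zero-signal fraction (0.40 lncRNA,
0.05 fragments): zero-truncated sampling for non-assigned transcripts
makes the realized zero fraction equal the configured one by
construction. Read length is fixed at 30 nt — irrelevant to 5'-end
counting but required for valid SAM output.

What passing on this generator does **not** show: robustness to P-site
offset drift, length-dependent coverage bias, multimapping, isoform
mixtures, or CLIP peak-shape artefacts — none of which the generator
models. It does show that the scoring formulas, the frame selection, the
zero-fraction handling, the CV machinery and the two-step routing are
implemented correctly and recover planted structure at realistic depths.

## Design choices on genuinely open points

- Overlap filters ("same strand" exon overlap) use the strictest
  reading: one shared exonic base disqualifies; intronic and antisense
  overlap do not.
- The 3'UTR is exonic sequence strictly 3' of the stop codon
  (stop-codon features are merged into the CDS on GTF read, so BED12
  thick regions and GTF agree).
- 5'-end collapsing is on for periodicity input, off for RPM: raw depth
  better reflects expression.
- The classification-time expression floor is exposed but off by
  default; only RPM = 0 is treated as out of domain.
- The zero-CLIP flag requires exactly zero reads, not a small-RPM
  threshold.

## Limitations

- The association step is RBP-agnostic: any protein with
  translation-dependent 3'UTR enrichment can stand in for UPF1, but the
  model quality is bounded by that enrichment contrast in the supplied
  CLIP data.
- Scores are per transcript; no aggregation of isoform calls to gene
  level is attempted.
- Very short transcripts (< ~100 nt of usable signal) are usually routed
  LRT and decided by step 2 alone.
- The model files store densities as grids; likelihoods outside the
  training support are 0 by design, so applying a model far outside its
  training θ range yields uninformative 0.5 posteriors (flagged).
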