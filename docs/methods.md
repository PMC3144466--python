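# Methods

This note documents the models, conventions and numerical choices behind
plugprot, and what the synthetic-data generator does and does not emulate.

## The experimental design being modeled

A vasectomized, unlabeled male is mated to a female metabolically labeled
with ¹⁵N (~95% incorporation). Proteins recovered from the mated female's
reproductive tract therefore separate by mass: peptides with
natural-abundance nitrogen are male-derived (ejaculated), peptides whose
nitrogen is ~95% ¹⁵N are female-derived. The pipeline's stages mirror the
analysis of such an experiment: spectrum-to-peptide matches are filtered
by a target-decoy FDR, proteins are inferred under a conservative
two-peptide rule, abundance is summarized by spectral counting,
ejaculated proteins are tested for functional overrepresentation, and
their evolutionary rates are compared against the genome.

## Isotope chemistry

Residue formulas, element monoisotopic masses, isotope abundances and the
natural ¹⁵N abundance (0.003663) are pinned in `plugprot/constants.py`;
the residue table is cross-checked against pyteomics in the test suite.
The m/z convention is mz = (M + z·1.00727646688)/z.

**Labeled mass shift.** The default shift is the search-engine
approximation: `incorporation` Daltons per nitrogen atom (so a
3-nitrogen peptide at 95% incorporation gains 2.85 Da). An `exact` option
applies the physical mass difference, N · incorporation · 0.9970349 Da.
The default exists for parity with how labeled-mode database searches are
configured; the simulator itself uses the exact shift, since real labeled
peptides obey physics, and the loose matching tolerance absorbs the
difference exactly as a real search engine's precursor tolerance does.
The 95% incorporation is modeled per nitrogen atom (each nitrogen is ¹⁵N
with probability equal to the incorporation), not per residue.

**Isotope envelopes.** Isotopologue distributions are aggregated by
neutron-count bin: each element contributes a binomial/multinomial
pattern over neutron shifts, with the nitrogen heavy-isotope probability
replaced by the enrichment fraction; element patterns are convolved by
binary exponentiation, and truncated convolution is exact for the
retained bins (bin k receives contributions only from bins ≤ k). Each
bin also carries the intensity-weighted mean mass offset, so envelope
centroid m/z values and envelope mean masses are first-moment-exact;
tests verify the full distribution against a naive per-atom polynomial
expansion to 1e-9 and the labeled mean-mass shift against the closed
form N·(f − f₀)·Δm.

**Envelope classification.** An observed envelope is compared to two
theoretical templates (natural abundance; labeled at the stated
enrichment) by cosine similarity, after projecting each template onto
the observed peaks' neutral masses (nearest template isotopologue within
0.35 Da, else zero). Because at high enrichment the envelope moves many
neutrons above the monoisotopic peak, mass displacement and shape both
contribute to the separation; on noisy synthetic envelopes
(multiplicative σ = 0.05, peptides with ≥5 nitrogens) accuracy exceeds
99%. Ties classify as natural — the conservative call when the
classification feeds an inclusion list, since a missed male peptide only
costs sensitivity while fragmenting a labeled peak wastes instrument
time.

## Identification conventions

- **Decoys** are per-target shuffles (same length and residue multiset).
- **FDR filtering** finds the lowest score threshold s such that
  (#decoys ≥ s)/(#targets ≥ s) ≤ the nominal FDR and accepts all target
  PSMs with score ≥ s (ties at the threshold accepted). If no threshold
  qualifies, the acceptance is empty; with no decoys present the FDR is
  undefined and the call errors.
- **"Region in the genome"** is operationalized as a gene: peptides map
  to genes by exact tryptic-peptide identity, and n_locations counts
  distinct genes. A gene is identified iff ≥2 distinct peptides map to it
  and ≥1 maps uniquely; genes failing only the uniqueness clause are
  reported separately as ambiguous.
- **Fractional counting**: each accepted PSM contributes 1/n_locations to
  every gene containing its peptide, so total counts are conserved
  exactly.
- **Induced female proteins** must (i) have a predicted secretion signal
  at P > 0.90 — a missing prediction fails this criterion conservatively —
  (ii) be absent from the unmated labeled control, and (iii) not be a
  male seminal-fluid gene.

## Quantification

NSAF_g = (c_g/L_g)/Σ_j(c_j/L_j) with counts summed over the mated
biological samples (the unmated control is excluded); per-sample NSAF is
the same formula restricted to one sample. Multi-transcript genes use the
median transcript length (even-length lists: mean of the central pair);
shortest/longest/seeded-random rules are available for sensitivity
checks. The replicate comparison applies arcsin(√NSAF) (domain-clipped to
[0,1] against floating error) before the rank-sum test.

## Statistics

- **Hypergeometric enrichment** is the upper tail P(X ≥ k) with the
  population restricted to annotated genes; the Bonferroni multiplier is
  the number of terms with ≥1 study-set annotation. Both choices are the
  usual term-for-term denominators. No ontology-graph propagation is
  performed; annotations are taken as given.
- **Wilcoxon rank-sum** reports W = #(x_i > y_j) + ½·#ties (the
  Mann–Whitney U of the first sample, as in R's `wilcox.test`). The
  two-sided p is the exact permutation null of U (doubled smaller tail)
  when min(n,m) ≤ 8 with no ties, and a tie-corrected normal
  approximation with continuity correction otherwise; a degenerate
  statistic yields p = 1.
- **Fisher's exact test** uses the two-sided point-probability rule.
- **Likelihood-ratio tests** use plain chi-square tails with df = 2 for
  M7 vs M8 and df = 1 for M8a vs M8. A 50:50 mixture null for the
  boundary test would be less conservative; plain chi-square was chosen
  and documented since nothing pins the mixture convention. Negative
  log-likelihood gaps within 1e-6 (optimizer noise) are clamped to zero
  and logged; larger ones error.
- **QC boundaries** follow the printed inequalities verbatim: remove
  aligned codons < 100, dN > 1 (dN = 1 kept), dS ≥ 0.381 (0.381 removed),
  and maximum pairwise dS strictly exceeding twice the genome median
  (exactly 2× kept).
- **Selection verdict**: all five criteria must hold (conjunction).
- **NG86 dN/dS**: synonymous/nonsynonymous sites averaged between the two
  sequences, mutations to stop codons counted as nonsynonymous,
  equal-weight pathway counting with stop-traversing orderings excluded
  (all orderings used only if every one is blocked), Jukes–Cantor
  correction. Saturated proportions (p ≥ 3/4, e.g. a single fully
  substituted site) yield an infinite distance; dS = 0 leaves ω
  undefined and such records are excluded from rate comparisons with a
  logged reason. The implementation agrees with an independent reference
  implementation to 1e-9 on random codon pairs.

## Acquisition

Inclusion windows are closed intervals mz·(1 ± 10·10⁻⁶) × rt ± 1.5 min,
one window per natural-classified, not-previously-sampled feature, no
merging (overlaps permitted) — the simplest faithful reading of the
windowing rule, and boundary behavior is pinned for tests. A precursor is
fragmented in directed mode iff it falls inside ≥1 window. The
feature-level simulator always runs replicate 1 data-dependently
(intensity-weighted selection under a capacity), then in directed mode
fills capacity from in-window features first; retention times are the
features' observed values.

## The synthetic-data generator

**Proteome.** Proteins are concatenations of globally unique "tryptic
blocks" (6–30 residues, terminal K/R, no proline after a cleavage site),
so with `family_fraction = 0` no tryptic peptide occurs in two genes —
peptide uniqueness is controlled by construction rather than by chance. A
chosen fraction of genes form paralog families of 2–3 members sharing one
inserted block, exercising multi-mapping and fractional counting. Default
sizes: 20 male genes (7 flagged as copulatory-plug proteins, emulating
the seminal-vesicle secretions plus transglutaminase), 30 female genes,
lengths 80–400 residues.

**Experiment.** The default design is the study design: 2 plug samples
× 7 technical replicates, 2 uterine samples × 5, and 1 unmated control
(1 replicate), 95% enrichment, 2% unlabeled leakage among female PSMs.
Per-gene expected spectra are log-normal (log-mean log 20, log-sd 1.0 per
biological sample), reproducing the few-genes-many-spectra skew; the plug
genes' expectations are rescaled per draw so their expected share of true
male spectra is 37%, the share printed for the seven plug proteins. Each
technical replicate observes a binomial thinning (detection probability
0.5) of the sample's Poisson totals, which makes discovery curves and the
first-replicate abundance bias emergent rather than hard-coded. True
match scores are Normal(4, 1); decoy and injected-incorrect matches draw
from the same family shifted to Normal(1.5, 1) — a modeling convenience
(nothing pins the real score distributions) chosen so decoy-FDR behavior
is analytically predictable. Decoys and incorrect target matches are each
injected at 10% of the true PSM count; the incorrect matches carry a
truth flag so the realized false-discovery proportion is measurable.
Observed masses get 3 ppm multiplicative noise, and labeled PSMs carry
the exact per-nitrogen shift. These defaults produce ~25,000 spectra per
experiment across the 25 tables, the scale of the study.

**Evolution tables.** Selected genes draw 2ΔL statistics from noncentral
chi-square distributions (noncentrality 25·effect for df 2 and 20·effect
for df 1), an extra ω class of 1.1 + effect·(0.3 + Exp(0.5)) occupying
2–12% of codons, and ≥1 FEL site; null genes draw central chi-square
statistics, ω ∈ [0.3, 1.5], class proportion < 5% and Poisson(0.05) FEL
sites. Each QC rule is violated by an independent 5% of genes, flagged in
the truth table. At effect = 2 the verdict classifier's recall exceeds
0.95 and its type-I rate is far below 0.01 by construction of criteria
1–2.

**What the generator does not emulate.** No raw spectra, chromatography,
charge-state or co-elution effects; scores are not derived from spectral
similarity; transcript-length variation, post-translational modification,
protein inference ambiguity beyond shared tryptic blocks, and real GO
topology are absent. Passing tests therefore demonstrate the correctness
and calibration of the analysis logic under the stated statistical
structure, not performance on real LC-MS/MS data.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical FASTA/TSV
outputs and identical summaries. The test suite runs the full synthetic
experiment at its default scale, 20-seed batteries for the calibration
and replicate-structure checks, 50 small experiments for the FDR
property, 1,000 genes for the type-I rate, 200 for recall, and 1,000
noisy envelopes for the classifier — sizes chosen so the entire suite
completes in well under a minute on one CPU while keeping binomial error
small relative to the asserted margins.
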