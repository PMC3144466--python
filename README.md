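# plugprot

**plugprot** re-implements, as a tested and reusable Python pipeline, the
computational analysis behind a ¹⁵N differential-labeling proteomics study
of the house-mouse ejaculate: unlabeled males are mated to females raised
on a ¹⁵N diet, so every protein recovered from the mated female's
reproductive tract can be assigned an origin by mass — unlabeled peptides
are male-derived (seminal fluid and the copulatory plug), mass-shifted
peptides are female-derived. The pipeline covers the full analysis chain:

- **Isotope chemistry** — peptide elemental composition and monoisotopic
  mass; the labeled-search mass adjustment (0.95 Da × number of nitrogen
  atoms at 95% incorporation, with the physically exact
  Δm(¹⁵N−¹⁴N) = 0.9970349 Da as an option); theoretical isotope envelopes
  at arbitrary ¹⁵N enrichment; cosine classification of observed envelopes
  as natural-abundance vs enriched.
- **Identification** — shuffled-decoy databases; per-spectrum target-decoy
  FDR filtering at 1% (lowest score threshold *s* with
  #decoys≥s / #targets≥s ≤ FDR); labeled-mode mass-window matching;
  peptide-to-gene mapping; the two-peptide / one-unique-peptide protein
  inference rule with an explicit ambiguous-gene report; fractional
  spectral counting (each spectrum contributes 1/n to each of the n genes
  sharing its peptide, conserving totals exactly).
- **Quantification** — experiment-wide NSAF
  (NSAF_g = (c_g / L_g) / Σ_j (c_j / L_j), summed over the biological
  samples; median transcript length for multi-transcript genes),
  replicate discovery curves, and the arcsin-√NSAF first-vs-later
  replicate comparison (Wilcoxon rank-sum).
- **Enrichment** — term-for-term hypergeometric overrepresentation with
  Bonferroni correction.
- **Evolution** — pairwise dN/dS quality control (≥100 aligned codons,
  dN ≤ 1, dS < 0.381; genes whose maximum pairwise dS exceeds twice the
  genome median removed), likelihood-ratio tests of the M7/M8/M8a codon
  site models, the five-criterion recurrent-positive-selection verdict
  (M8>M7 at P<0.01, M8>M8a at P<0.01, extra ω class > 1.1 occupying ≥1%
  of codons, ≥1 FEL-positive site), a Nei–Gojobori (1986) dN/dS estimator
  for synthetic data, Wilcoxon rank-sum (R's W convention) and Fisher's
  exact test.
- **Acquisition** — inclusion lists (m/z ± 10 ppm × retention time
  ± 1.5 min) built from natural-classified, not-yet-sampled MS1 features,
  and a feature-level simulation of directed vs data-dependent
  acquisition.
- **Synthetic data** — the raw MS data of the original study are not
  available, so a first-class generator emulates its structure: 2
  copulatory plugs × 7 technical replicates + 2 uterine fluids × 5 + 1
  unmated control; 95% ¹⁵N incorporation with rare unlabeled leakage;
  seven plug proteins carrying ~37% of male spectra; paralog families
  producing multi-mapping peptides; decoy and incorrect matches from a
  shifted null score distribution; plus evolutionary-rate tables with
  known selection/QC ground truth.

## Worked example

Run the whole pipeline on synthetic data:

```bash
plugprot run --seed 3 --outdir out/
# identified 50 genes from 19012 accepted PSMs (NSAF sum 1.000000000)
```

`out/summary.json` then contains (abridged):

```json
{
  "n_psms_simulated": 25757,
  "n_psms_accepted": 19012,
  "estimated_fdr": 0.00999,
  "n_genes_identified": 50,
  "nsaf_sum": 1.0000000000000002,
  "discovery_curve": [41, 46, 48, 49, 50, 50, 50],
  "replicate_nsaf_test": {"median_first": 0.1033, "median_later": 0.0629,
                          "W": 350.0, "p_value": 3.09e-05},
  "top_terms": ["GO:male_biased", "GO:0002", "GO:0004"]
}
```

Reading: 25,757 simulated spectra pass through the 1% decoy FDR filter
(19,012 accepted at a realized estimate of 0.0100); 50 genes satisfy the
two-peptide/one-unique rule; NSAF sums to exactly 1 over them; the
discovery curve saturates (the last two plug replicates add no new
genes), and genes found in the first replicate have significantly higher
transformed NSAF than later discoveries (W = 350, P ≈ 3×10⁻⁵) — the
abundance-ordering signature expected when sampling is near-complete. The
planted male-biased annotation term is recovered as the top enrichment.

Individual stages are exposed as subcommands (`simulate`, `identify`,
`quantify`, `enrich`, `evolve`, `acquire`) operating on plain TSV/FASTA
files, and the same operations are importable from `plugprot.*`.

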