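# tdbu

Integrated **top-down / bottom-up label-free proteomics** analysis:
proteoform-level quantitation, protein-level spectral counting, allelic
expression ratios from intact-mass spectra, and concordance analysis
between the two platforms.

Top-down (TD) MS measures intact proteoforms — the specific molecular
forms of a protein, with sequence variants and co-occurring PTMs — while
bottom-up (BU) MS measures tryptic peptides and infers proteins. The two
platforms see a two-state tumor comparison differently: BU detects far
more proteins, TD resolves proteoform-level changes (PTM stoichiometry,
allele-specific expression, proteolytic processing) that peptide-level
inference averages away. This package implements the statistical
pipeline for such a comparison and a synthetic-data generator emulating
a 2-state × 3 GELFrEE-replicate × 5 LC-MS-replicate × 5-fraction study
of the low-molecular-weight (< 30 kDa) proteome, so the whole analysis
is testable without instrument data.

**For whom:** proteomics methods developers and statisticians who need a
reference implementation of label-free TD quantitation and TD/BU
concordance analysis with planted ground truth.

## The statistical core

* **TD branch** — MS1 neutral masses are grouped by accurate mass
  (10 ppm) and retention time (5 min), linked to catalog proteoforms
  within 2.2 Da, and standardized within each (proteoform, fraction):
  z = (x − x̄) / s. Each proteoform is tested with a fixed-effects
  two-way ANOVA, z ~ state + fraction (each GELFrEE fraction a separate
  measure), with Benjamini–Hochberg FDR at α = 0.05; effect size is
  log2(mean₂/mean₁) of raw intensities. With one fraction and balanced
  groups the F statistic equals t² of the equal-variance t-test.
* **BU branch** — spectral counts filtered (≥ 2 unique peptides per
  protein; variant peptides need ≥ 3 counts within one run), summed per
  GELFrEE replicate, and tested with a two-sided equal-variance t-test
  on log2(count + 0.5); BH FDR at α = 0.01.
* **Allelic analysis** — a heterozygous cSNP yields two co-eluting
  proteoforms whose interleaved isotopic envelopes are unmixed by
  non-negative least squares over two averagine templates; the
  coefficient ratio estimates allele-specific expression and drives the
  genotype call.
* **Concordance** — TD proteoforms roll up to protein accessions and a
  3×3 grid over TD × BU status {DE, not DE, not detected} yields percent
  DE agreement among co-detected proteins, platform-only counts and the
  BU/TD detection ratio.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Run the full synthetic study (simulate → TD quant + BU quant →
concordance → report):

```sh
tdbu run-all --out run1 --seed 1
```

The report (`run1/report.txt`) from that exact command:

```
tdbu pipeline report
seed: 1
design: study3 (3 GELFrEE x 5 LC-MS x 5 fractions)
catalog: 278 proteoforms / 150 proteins
td_observations: 5108 rows
td mass groups: 278 (278 linked)
td tested proteoforms: 269 (77 DE)
td untestable/present-absent: 1
bu_counts: 5967 rows (78.2% peptide x run cells missing after filters)
bu tested proteins: 150 (0 DE)
concordance summary: {..., "percent_DE_agreement_among_codetected": 70, ...}
```

Reading it: with 25% of proteins planted as differentially expressed,
the TD branch flags 77 of 269 tested proteoforms at 5% FDR, while the BU
branch — three replicates per state, 78% missing cells, 1% FDR across
150 proteins — flags none: its smallest p-value (4×10⁻⁴) does not clear
the BH critical value (≈7×10⁻⁵). That asymmetry is the multiple-testing
penalty intrinsic to the design, and the 70% agreement among co-detected
proteins is then dominated by the both-not-DE cell. Per-entity outputs
land in `run1/td_results.tsv`, `run1/bu_results.tsv`,
`run1/td_volcano.tsv` and `run1/concordance.tsv`.

Individual stages are also exposed (`tdbu simulate`, `tdbu quant-td`,
`tdbu quant-bu`, `tdbu allele`, `tdbu compare`) and everything is
importable as a library (`tdbu.td.quantify_td`,
`tdbu.bu.protein_de_test`, `tdbu.allelic.estimate_allele_ratio`,
`tdbu.concordance.summarize`, ...).

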