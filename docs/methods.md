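# Methods

`tdbu` implements an integrated label-free differential-expression
analysis of a two-state tumor proteome as measured by two complementary
MS platforms: top-down (TD), which observes intact proteoforms, and
bottom-up (BU), which observes tryptic peptides and infers proteins.
Because raw instrument data are out of scope, the package ships a
synthetic-data generator that reproduces the statistical structure of
such a study, and every analysis stage is exercised end-to-end against
planted ground truth.

## Study design model

A study is a two-state factorial layout
(`types.StudyDesign`): states × GELFrEE replicates × LC-MS replicates ×
molecular-weight fractions. Two presets cover the emulated designs:

* **study3** — 2 × 3 × 5 × 5 fractions over 0–30 kDa (150 TD
  acquisitions; the BU side digests fractions together, giving
  2 × 3 × 5 = 30 runs);
* **study2** — 2 × 3 × 6, single fraction.

GELFrEE fractions are equal-width mass bins of `mw_range`; each
proteoform's home fraction is set by its intact mass, and with
probability `p_span` (default 0.3) it also elutes in one or two adjacent
fractions, reflecting the observation that intact proteins spread across
neighboring molecular-weight fractions.

## Synthetic data

**Catalog.** Proteins receive 1–4 proteoforms (default distribution
{1: 0.52, 2: 0.24, 3: 0.16, 4: 0.08}, putting roughly half of accessions
on a single proteoform as seen in intact-protein surveys): a base
sequence plus PTM forms (phospho, acetyl, hydroxyl) and N/C-terminal
proteolytic fragments. A configurable fraction of proteins carries a
heterozygous coding SNP, represented as a second allele proteoform with
a single-residue substitution (e.g. "E110V"). Monoisotopic masses are
recomputed from residues + water + modification shifts (pyteomics
residue masses) and are re-derivable to 1e-4 Da — a validated invariant.

**TD observations.** Per theoretically possible
(proteoform × state × GELFrEE × LC-MS × fraction) cell the intensity is
log-normal with coefficient of variation `intensity_cv` (default 0.25, a
typical MS1 label-free spread) around the state mean; state 2's mean is
state 1's × 2^log2FC. Neutral masses carry Gaussian error with sd 2 ppm;
retention times get a per-proteoform center plus 0.5 min jitter. Cells
are dropped completely at random at `missing_rate` (default 0.546,
matching the ~55% missing MS1 observations of the emulated study); an
alternative logistic-in-log-intensity censoring mode mimics loss near
the detection threshold, without any claim about which mechanism real
data follow (the generator cannot adjudicate that).

**BU counts.** Peptide counts per run are drawn zero-truncated
negative-binomial (dispersion 2 by default; counts are over-dispersed)
around peptide abundance × the protein's fold change. A zero count is
represented by the absence of a row — spectral-count tables never record
zeros — so the missing-cell fraction equals the per-cell drop
probability (default 0.785, the emulated study's 78.5%) exactly, which
makes the missingness rate testable against a binomial interval.
Proteins with a catalog cSNP/NSJ contribute one annotated variant
peptide.

**Envelope spectra.** Intact-mass spectra of 1–2 co-eluting proteoforms
use the averagine model: the elemental composition of an "average
residue" (C4.9384 H7.7583 N1.3577 O1.4773 S0.0417) scaled to the
proteoform mass, per-element isotope distributions (NIST abundances)
convolved by exponentiation-by-squaring, aggregate peaks re-centred on
the exact monoisotopic mass, Gaussian peak shapes with
FWHM = m/z / resolving power, proton mass 1.00728 Da. Noise is additive
Gaussian relative to the strongest signal.

What the generator does **not** emulate: chromatographic peak shapes,
MS/MS spectra, charge-state distributions, shared/degenerate peptides,
protein-inference ambiguity, batch effects, or intensity-dependent mass
error. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
performance on raw instrument data.

## TD quantitation

1. **Mass grouping** — greedy agglomeration of MS1 observations seeded
   in descending intensity (ties by ascending mass): a seed collects all
   unassigned observations within `mass_tol_ppm` (10) and `rt_tol_min`
   (5), then the intensity-weighted consensus is refined until every
   member is within tolerance of it. Deterministic for a fixed table.
2. **Linkage** — each group is linked to the nearest catalog mass within
   2.2 Da (ties: smaller error, then lexicographic id); unlinked groups
   are retained but excluded from quantitation.
3. **Standardization** — within each (proteoform, fraction) cell,
   subtract the mean of all measurements and divide by their sample sd,
   centring each cell at zero with unit sd. Cells with < 2 measurements
   or zero variance are untestable and reported in a side table.
4. **Hierarchical ANOVA** — per proteoform, a fixed-effects linear model
   `z ~ state + fraction` (optionally + GELFrEE replicate) with an
   F-test on the state term, pooling fractions so each fraction acts as
   a separate measure of the proteoform's differential expression. With
   one fraction and balanced groups this reduces exactly to the
   equal-variance two-sample t-test (F = t²), which the tests verify to
   1e-10 along with agreement with an independent two-way ANOVA fit.
5. **Effect size** — log2 of the ratio of raw state mean intensities.
   Standardized values are z-scores and carry no scale, so testing on
   standardized values with effect sizes from raw means is the only
   self-consistent combination.
6. **FDR** — Benjamini–Hochberg step-up at α = 0.05; the reported
   q-value is the monotone BH-adjusted value. Where a per-entity
   "instantaneous q" is wanted, this BH q is the package's definition (a
   local-FDR reading would be an alternative; it is not implemented).

Entities observed in only one state are reported as present/absent, with
no fold change. Minimum data for testing: ≥ 2 observations per state.

## BU quantitation

Identification filters assume PSM/protein FDR estimation happened
upstream (rows carry optional pass flags); the package enforces the
≥ 2-unique-peptides rule and the variant-peptide threshold (a SNP or
splice-junction peptide must reach 3 counts within a single LC-MS run).
Testing sums counts to the GELFrEE replicate (the biological replicate
unit; LC-MS runs are technical), then applies a two-sided t-test on
log2(total + 0.5) — pooled equal-variance by default, Welch under a
flag, and the call for borderline proteins can flip between the two.
DE calling is BH at α = 0.01. Proteins with all-zero counts in one
state are "present/absent" when the other state peaks at ≥ 3 counts in
some run, otherwise "insufficient evidence": with ~78% of cells missing,
a total absence of low counts is weak evidence of absence.

With three replicates per state, BH at 1% FDR over a few hundred
proteins demands p below ~1e-4 at the top rank; the BU branch therefore
flags few or no proteins at the default synthetic scale even when
effects are real. This is a faithful property of the design — the same
multiple-testing penalty that the two-platform comparison highlights —
not a calibration failure; the global-null simulations confirm the
branch controls its FDR.

## Allelic-ratio estimation

For a heterozygous cSNP pair, two unit-normalised averagine envelope
templates (one per allele, at the allele's theoretical m/z ladder) are
fitted to the spectrum by non-negative least squares; the alt/ref
coefficient ratio estimates the allelic expression ratio. An allele is
"detected" if it carries ≥ 5% of the summed coefficients; genotypes are
heterozygous (both detected, ratio within the 0.2–5.0 band), homozygous
(one envelope, or a ratio outside the band), or not detected. Pairs
separated by < 2 Da are flagged unresolvable rather than fitted. One
charge state is analyzed per call; multi-charge aggregation is out of
scope. At 1% noise, charge 10 and resolving power 120,000 the estimator
recovers ratios 1–10 within 10% (property-tested over seeds), and the
1:1 heterozygote recovery is a headline reproduction target.

## Concordance

TD proteoform results roll up to protein accessions: a protein is in the
DE row if ≥ 1 proteoform is DE and in the not-DE row if ≥ 1 is not —
both rows are possible for one accession. The 3×3 grid over TD × BU
status (the doubly-undetected cell is empty by construction) carries
protein and proteoform counts per cell. For disjoint protein totals the
default `de_priority` convention assigns a mixed-status protein to the
DE row only (the `both` convention counts it in each row). Summaries:
percent DE agreement = 100 × (both-DE + both-not-DE) / co-detected,
rounded to integer; detection ratio = BU total / TD total to one
decimal — the printed precisions of the emulated comparison.
Fold-change agreement on co-DE proteins uses the median of a protein's
DE proteoform log2FCs against the BU log2FC (Pearson r, r²); the median
is the package's aggregation choice where none is prescribed.

## Numerical and reproducibility choices

* One master seed per run; per-stage streams derived via
  `numpy.random.SeedSequence.spawn`. Identical seeds give byte-identical
  output bundles.
* Isotope patterns pruned at 1e-5 of the base peak; spectra sampled at
  sigma/4 grid spacing.
* BH is delegated to `statsmodels` and verified against a brute-force
  step-up enumeration; t-tests to `scipy`; NNLS to `scipy.optimize`.
* Degenerate inputs: zero-variance standardization cells are flagged,
  never raised; all-equal replicate totals yield p = 1 (or 0 under an
  exact mean shift) without calling the t routine; BH rejects p outside
  [0, 1].
* Problem sizes used by the statistical suites: global-null FDR checks
  run 1,000 entities × 20 replicate simulations per branch; parameter
  recovery uses 5 proteoforms per grid point over log2FC ∈ {−3..+3} at
  cv 0.1 and 20% missingness; heterozygote recovery averages 100 seeds.

## Known limitations

* The grouping step is greedy; pathological mass ladders could split
  differently under other seeds of equal intensity (ties are broken
  deterministically, so results are reproducible).
* The hierarchical model treats fraction as a fixed blocking factor;
  random-effects formulations are not implemented.
* Protein inference, PSM scoring, deconvolution of raw spectra to
  neutral masses, and PTM site localization are all upstream of this
  package and out of scope.
* Catalog FASTA headers print masses to 4 decimals, so a write/read
  round trip preserves masses to 1e-4 Da (all other fields exactly).
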