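# Methods

`synergyseek` implements a transcriptomics-to-pharmacology pipeline for
proposing and validating drug-combination partners in drug-resistant acute
myeloid leukemia (AML). Starting from gene-level RNA-seq counts of cell
lines treated with cytarabine (AraC), daunorubicin (DNR), their combination
and a DMSO vehicle, it (i) calls directional differential expression, (ii)
distills the changes into a *resistance* signature (unique to the
non-responding line) and a *response* signature (shared by responding
lines), (iii) queries those signatures against a perturbagen
reference-signature library with Connectivity Map-style scores to rank
candidate partners, (iv) validates combinations on dose-response matrices
by Bliss independence, and (v) associates combination synergy with binary
genomic alterations across a cell-line panel.

## Differential expression

Counts are modeled as negative binomial with a **fixed dispersion**
(default 0.16, i.e. a biological coefficient of variation of 0.4, the
conventional value for human cell-line data). No per-gene dispersion is
estimated: replicate structure in this setting is typically minimal, and a
fixed-BCV exact test is the documented fallback for that regime. The
dispersion is a configuration knob.

Library composition is normalized by TMM (trimmed mean of M-values): the
reference sample is the one whose 75th-percentile count fraction is closest
to the mean of those fractions; per sample, log2 proportion ratios (M) and
average log abundances (A) are computed over genes nonzero in both samples,
trimmed 30% from each tail of M and 5% from each tail of A (keeping the
intersection), and the factor is two to the precision-weighted mean M,
finally rescaled so factors have geometric mean 1.

For each (cell line, treatment) contrast against that line's DMSO samples,
counts are scaled to the common (geometric-mean) effective library size,
rounded, and pooled within condition; the pooled group of *n* samples has
NB shape n/dispersion. Conditional on the two-group total *t*, the split is
Beta-Binomial(t, n₁/φ, n₂/φ) (at φ=0 the conditional Binomial(t, ½)), and
the two-sided p-value sums the probabilities of all outcomes no more likely
than the observed one (minimum-likelihood method; a doubling-the-tail
variant is available behind a flag — the two differ in how ties at the
observed outcome are counted). Log2 fold changes are computed on
counts-per-million with a 0.5 CPM pseudo-count, so zero counts never
produce infinities and the sign always agrees with the normalized mean
difference. Benjamini–Hochberg adjustment is applied per contrast and genes
are called with **strict** inequalities |log2FC| > 1 and FDR < 0.05.

## Signature construction

Matching between DE sets is **direction-specific**: "the same change being
absent" means a gene up in one set is removed only by being up in another.
The resistance profile is the resistant line's single-drug up/down sets
minus the union of every sensitive line's drug and combination sets (an
optional strict mode also subtracts the resistant line's own combination
sets). The response profile is the intersection of the sensitive lines'
drug and combination sets (all four sets by default; a relaxed mode
intersects the drug condition only) minus the resistant line's drug and
combination sets. Pairwise overlap tallies report shared counts with the
union across the compared group as the 100% denominator, recorded in the
report. Over-representation uses the one-sided hypergeometric upper tail
with the DE-tested genes (not the genome) as the universe, BH-adjusted
across the collection.

## Connectivity scoring

The scoring engine follows the published Connectivity Map convention, since
the upstream service exposes only a "normalized connectivity score": a
GSEA-type weighted Kolmogorov–Smirnov enrichment score per gene set (weight
0 by default — pure KS, which keeps the statistic exactly checkable against
a brute-force running sum; weight 1 available), combined as
WTCS = (ES_up − ES_down)/2 when the two component scores disagree in sign
and 0 otherwise, then normalized within each (cell line, perturbagen type)
group by the mean |WTCS| of same-sign members (NCS). Ties in ranked
profiles are broken by ascending gene symbol.

Candidate partners must reverse the resistance profile (NCS ≤ −1) and
mimic the response profile (NCS ≥ +1) in at least one cell line; the
threshold 1.0 operationalizes "an observed transcriptional effect".
Filters: (a) targets whose knockdown and overexpression signatures score
concordantly (same sign, both beyond the threshold, against the same
query) are ambiguous and removed; (b) perturbagens concordant with both
profiles in the same direction are removed; (c) compounds are kept only
when a knockdown signature of their annotated target is sign-concordant
with them — compounds with no target annotation therefore never rank, a
deliberate strict reading of "inhibitors with similar transcriptional
effects as their target-gene counterparts were selected". Survivors are
aggregated by target class (unannotated perturbagens would form singleton
classes) and ranked by number of supporting cell lines, then |mean NCS
against the resistance profile|, then class name.

## Bliss synergy

Viability grids are anchored so the untreated cell is 100%. Fractional
inhibition y = clamp(1 − V/100, 0, 1); growth stimulation above the control
counts as zero inhibition. For each combination cell the Bliss expectation
from the two single agents is yₐ + y_b − yₐ·y_b, and the excess
(observed − expected) × 100 averaged over the grid is the Bliss score:
positive = synergistic, negative = antagonistic, exactly zero = additive.
No baseline correction or monotherapy curve smoothing is applied (raw-cell
Bliss); the ×100 scale keeps scores commensurable with published
combination-screen magnitudes. Panel-level aggregation averages member
combinations per (cell line, inhibitor class) and counts synergistic vs.
antagonistic cell lines per class.

## Genomic association

Each binary alteration with at least 3 mutant and 3 wild-type cell lines
(GDSCTools' convention) is tested by one-way fixed-effects ANOVA of synergy
on mutation status — with a binary factor this is exactly the pooled
two-sample t-test (F = t²), which is how the implementation computes it; an
optional categorical covariate switches to a two-factor OLS fit. Effect
sizes are Cohen's d on the pooled standard deviation. Multiplicity is
handled by Storey–Tibshirani q-values: π₀ is estimated on the λ grid
0.05…0.95 by a cubic least-squares smoother evaluated at λ = 0.95 and
clamped to (0, 1]; for scans with fewer than 100 p-values that estimate is
unstable (it can collapse toward zero and void FDR control), so π₀ falls
back to the conservative value 1, making the q-values exactly BH. Genes are
flagged at p < 0.001 and q < 0.25, the screening defaults of the
pharmacogenomic-scan tradition. The high/low split ranks cell lines by
score descending, labels the top ⌈n/2⌉ "higher", and breaks boundary ties
by cell-line name so output is deterministic.

## Synthetic study conditions

The generator produces data with exactly the structure the analysis
assumes, plus ground truth, so every stage is testable offline.

* **Counts.** Three cell lines (one resistant, two sensitive), four
  conditions (DMSO/AraC/DNR/COMBO), three replicates, 2,000 genes with
  lognormal (σ = 1) relative abundances and 3×10⁵ expected counts per
  sample; NB dispersion 0.16. Each drugged condition plants 300 generic DE
  genes, 79% of them inductions, with |log2FC| = 2 + Exp(0.5). The
  resistance program (60 up/30 down) is planted only in the resistant
  line's DNR condition; the response program (40 up/10 down) in every
  sensitive line's DNR and COMBO conditions. Program genes carry |log2FC|
  one unit above generic DE genes: the programs represent coherent,
  strongly-responding modules, and the response profile requires a gene to
  be recovered in four separate DE contrasts, so per-contrast recall
  compounds — the boost puts the burden of the test on the set algebra
  rather than on borderline detection power.
* **Library.** 60 compounds (2 planted reversers sharing one annotated
  target, which also gets a concordant knockdown signature; the rest
  unannotated decoys), 3 knockdown/overexpression target pairs of which one
  is planted "ambiguous" (both members concordant with the query), and 20
  decoy knockdowns plus 20 decoy overexpressions with exchangeable N(0, 1)
  scores — the genetic decoys matter because NCS normalizes within
  (cell line, perturbagen type) groups, and a group containing only planted
  signals would normalize them onto the threshold itself. Planted program
  genes are offset by ±4 in score so they rank at the profile extremes.
* **Dose matrices.** Hill-type monotherapies (maximal inhibitions ~0.6 and
  ~0.4 at the grid tops) over a 5×3 combination grid; combination viability
  is the Bliss expectation minus a planted excess (default 15 on the
  percent scale) plus N(0, 3) noise on the combination cells only, clamped
  to [0, 120]. Keeping monotherapy cells noise-free makes the planted
  excess exactly identifiable at zero noise and the noisy recovery
  unbiased; the grid and curve parameters keep expected inhibition + excess
  below 1 so clamping never truncates the signal.
* **Mutations.** 30 cell lines × 50 genes, background mutation frequencies
  uniform in [0.1, 0.4]; one planted gene at frequency 0.3 shifts synergy
  by Cohen's d = 3 on a N(0, 1) baseline.

All generators are pure functions of the single config seed; independent
stage streams are derived as `default_rng([seed, stage_index])`.

What the generator does **not** emulate: transcriptome-wide gene–gene
correlation, per-gene dispersion heterogeneity, batch effects, compositional
(library-size) artifacts beyond TMM's reach, dose-dependent transcriptional
signatures, or co-mutation structure. Passing recovery tests therefore shows
the algorithms are correct and calibrated under their own assumptions, not
that real screens will behave as cleanly.

## Numerical choices and degenerate inputs

* Exact-test tie handling uses a 1e-9 relative tolerance so symmetric
  outcomes with equal probability are always counted together; p ∈ (0, 1].
* A zero two-group total gives p = 1; a sample sharing no nonzero gene with
  the TMM reference gets factor 1 with a warning.
* An empty query∩profile intersection gives ES = 0 with a warning; WTCS of
  same-sign component scores is 0; a zero WTCS normalizes to NCS 0.
* ANOVA with zero pooled variance returns p = 1, d = 0 when means are equal
  (and p = 0 with infinite d otherwise).
* Problem sizes for the recovery experiments (3 seeds for DE/profiles, 50
  for partner ranking, 100 for dose and power, 500 for the null
  calibration) were chosen to give stable Monte-Carlo estimates at desk
  scale. The null family-wise alarm rate of the association scan sits at
  ~47 tests × 0.001 ≈ 4.7% by design of the study conditions, so its test
  compares the 500-seed count against the binomial sampling bound of a true
  5% rate rather than a point value.

## Known limitations

* The connectivity engine is a local stand-in for the online query service
  the approach was designed around: raw/NCS scores only, no touchstone
  percentile (tau), no GCTX ingestion.
* The exact test does not reproduce per-gene (qCML/tagwise) dispersion
  estimation; with real replicated data an external DE tool can be
  substituted upstream and its tables fed to the signature stage.
* Bliss scoring applies no outlier or baseline correction, so scores on
  noisy experimental matrices will differ from tools that smooth
  monotherapy curves before computing the expectation.
* Published benchmark panels (large combination screens, pan-cancer
  mutation scans) require their external datasets; the machinery is fully
  implemented but validated here on planted synthetic panels.
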