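# Methods

## The analysis model

A label-free PRM study measures, for each injection *j* and targeted
peptide *q*, the summed peak area of *q*'s monitored product ions. The
package models the expected light-peptide area as

    A_qj = exp( b_p + ln2 · s_i · β_p(g_i) + γ_p·(age_i − 70) + δ_p·sex_i + u_ip )
           · r_q · d(batch_j, t_j) · ε_qj ,

where *p* is the protein of peptide *q*, *i* the subject injected in *j*,
`b_p` the log-scale base abundance, `β_p(g)` the group effect (log2 fold
change vs control for AD or non-AD dementia), `s_i ~ N(1, σ_sev²)` a
per-subject disease-severity factor shared across proteins, `u_ip ~ N(0,
σ_bio²)` between-subject biological variation, `r_q` a peptide ionization
response, `d` a multiplicative drift factor, and `ε` multiplicative
log-normal measurement noise. Each transition receives its simplex share
`f_qt` of the peptide area (Σ_t f_qt = 1) times mean-one log-normal
transition noise, so transition sums reproduce the peptide area exactly
without noise and in expectation with it.

Two standards anchor normalization. Spiked reference peptides appear at
constant nominal amount times `d` times noise, so per-injection drift
factors are estimable as the geometric mean over reference peptides of
their median-scaled areas. GIS pool injections measure the arithmetic mean
of all biological subjects' noise-free peptide levels — exactly the
equal-aliquot pool the design prescribes — so replicate GIS injections
carry technical variance only.

The normalization cascade runs in a fixed order: (1) divide by drift
factors; (2) sum peptides into proteins (missing peptides excluded, never
zero-filled); (3) divide by the per-batch mean of the GIS injections, which
makes each protein's per-batch GIS mean exactly 1; (4) log2; (5) per
protein, OLS-residualize on age and sex over biological samples and center
to mean zero. Stages (1), (3) and (5) are (essentially) idempotent:
re-deriving factors from corrected references yields a single constant,
re-normalizing ratios changes nothing, and residualizing residuals is the
identity.

## Measurement-noise structure

Measurement noise has three components, all log-normal:

- a **per-(injection, protein) component** shared by all peptides of one
  protein in one injection (interference/matrix effects on the analyte) —
  per-protein SDs drawn log-normal(ln 0.19, 0.5);
- a **per-(injection, peptide) component** — per-peptide SDs drawn
  log-normal(ln 0.105, 0.5);
- **transition noise** (SD 0.10) within the peptide.

The shared component is what keeps protein-level CVs from collapsing under
peptide averaging, mirroring real panels where roll-up improves precision
only modestly. Reference standards get their own smaller noise (SD 0.10):
they are pure synthetic peptides, more reproducible than endogenous signal.

Drift is per-batch exponential in the within-batch injection slot,
`d = exp(a_b − r_b·t)`, with offsets `a_b ~ N(0, 0.32)` and decay rates
`r_b ~ U(0.014, 0.028)` — the simplest monotone multiplicative family
consistent with smooth within-batch signal decay. GIS injections are
interleaved at the first/middle/last slots of each batch.

### Calibration of the defaults

The reference study reports mean peptide GIS CVs of ~44% before and ~27%
after normalization. No drift magnitudes or noise variances are published,
so the defaults above were calibrated once so that the default simulation
lands near those two anchors (across seeds: pre ≈ 40–50%, mean ≈ 45%; post
≈ 26%). This calibration is a tuning choice, not ground truth. Two
downstream quantities follow from the structure rather than being anchored:
the protein-level GIS CV comes out near 19% (lower than the peptide CV
partly because per-batch GIS normalization divides each batch's 2–3 GIS
replicates by their own mean, absorbing part of their variance), and
~85–90% of proteins fall under the 30% high-precision cutoff.

## Cohort and effect defaults

The default design copies the reference cohort: 20 controls, 37 AD, 31
non-AD dementia, 10 GIS injections, 4 batches, 94 peptides on 41 proteins
(the 12 leading panel proteins carry 3 peptides, the rest 2), ages uniform
55–85, sex balanced, 67 of 88 samples on the Luminex immunoassay platform
(the remainder INNOTEST, whose absolute trait values are scaled by 1.6 to
emulate the platform offset). Twenty-five proteins spanning
neuronal/synaptic, glial/inflammation, myelin and metabolic functions carry
positive AD effects (log2FC 0.55–0.88); neurofilaments also rise in non-AD
dementia; a few targets carry small or negative effects; the rest are null.
Effect magnitudes were fixed once so that the best single-protein
classifiers land in the cross-validated AUC range the reference analysis
reports (~0.84–0.93) while most injected markers remain statistically
detectable at n = 88. The severity factor (σ_sev = 0.30) correlates the
markers within a subject, as co-regulated biomarkers are in real cohorts;
without it, the maximum over 41 independent per-protein AUCs would be
noticeably inflated relative to any single protein's true discriminability.

Immunoassay traits are generated on the log scale from loadings on the
centered protein levels — total Tau and phospho-Tau load positively on
MAPT (and weakly on SMOC1/YWHAZ/ALDOA), Aβ42 negatively — plus trait noise
(SD 0.20). Base scales (Aβ42 800, tTau 120, ptau 40) put controls above
the Aβ42/tTau = 4.6 positivity cutoff and most AD cases below it.

APOE genotyping is simulated as a separate two-channel table (areas of the
E2- and E4-specific peptides, proportional to allele copy number with a
small background when absent, at realistic genotype frequencies). The
caller uses a presence threshold (default 5× a blank-level median), so
homozygous variant genotypes collapse onto the heterozygote-with-E3 call —
a limitation of presence/absence genotyping without copy-number
calibration.

## Statistical choices

- **Differential abundance**: one-way ANOVA per protein across the three
  groups, Tukey HSD for pairwise contrasts, BH FDR across the protein
  family on the ANOVA p-values (the panel is the natural FDR family). The
  AD-marker call requires FDR q < 0.05, both Tukey contrasts involving AD
  < 0.05, and the AD mean strictly the extreme one. Two-sided, α = 0.05.
- **bicor** is implemented from its definition: observations are centered
  at the median and weighted by Tukey biweights `(1 − u²)²·1[|u| < 1]`
  with `u = (x − med)/(9·MAD)`; zero-MAD vectors fall back to mean
  centering (Pearson-style) with a warning. p-values use the Student
  transform `t = r·sqrt((n−2)/(1−r²))` on n−2 df. Trait analyses are
  restricted to the Luminex subset so absolute immunoassay values are
  comparable.
- **Logistic/ROC**: unregularized IRLS (max 100 iterations, deviance
  tolerance 1e-8) on the single protein value; complete separation is
  capped and flagged, leaving monotone scores whose ROC is still valid.
  Folds are stratified with a fixed, logged seed; out-of-fold
  probabilities are pooled into one ROC per protein (lower variance than
  averaging five fold-ROCs at n ≤ 88). The ROC uses every distinct score
  threshold with ties grouped; trapezoidal AUC equals the tie-aware
  Mann–Whitney statistic. A ratio exactly at the 4.6 cutoff is negative
  (positivity is a strict inequality).
- **Degenerate inputs**: summation returns a missing marker (never zero)
  when no transition matches; CV is undefined (NaN) for fewer than two
  replicates or non-positive mean; an injection with no reference peptide,
  a batch without GIS, and a peptide mapped to two proteins are hard
  errors; a covariate without variation is dropped with a warning.

## What the simulations do and do not show

Passing tests demonstrate that the cascade removes the drift it models,
that its invariants hold exactly, that the inferential machinery is
calibrated (type-I error, FDR, AUC identities), and that injected effects
are recovered without bias at large n. The generator does not model
retention-time drift, chromatographic interference, peak-integration
errors, missingness beyond structural absence, or library mismatch — so
simulated dotp values are near 1, unlike real assays where co-isolated
interference lowers them, and real-data CV improvements may be smaller
than the simulated ones. Problem sizes in the test suite (10,000-replicate
null calibrations, 500-per-group recovery, 1,500-per-class AUC
simulations) were chosen to keep Monte-Carlo error well below the asserted
tolerances.
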