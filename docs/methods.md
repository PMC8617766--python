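# Methods

This note documents the models and conventions behind each pipeline
stage, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the known discrepancies between
recomputed and printed values.

## Assay quantification

Percent inhibition is `(1 − signal_sample/signal_control) × 100`. The
control must be strictly positive; negative inhibition (sample signal
above control) is reported and flagged, never clamped — clamping would
hide plate problems that QC should see.

IC50 estimation defaults to a four-parameter logistic fit,
`y = bottom + (top − bottom)/(1 + (IC50/x)^h)`, by bounded nonlinear
least squares on log-concentration. Because responses are normalized to
an uninhibited control, the theoretical asymptotes are 0 and 100; an
asymptote is released as a free parameter only when its plateau was
actually sampled (minimum response ≤ 20 % for the bottom, maximum ≥ 80 %
for the top), with bounds [−5, 30] and [70, 120]. This is the standard
remedy for the non-identifiability of asymptotes on one-sided designs:
a series sampled only between 45 % and 85 % inhibition carries almost
no information about both plateaus and a fully free 4PL fit there is
unstable at 2 % plate noise. On noiseless data the fit reproduces the
generating IC50 to ≤ 1e−6 relative error for Hill slopes in [0.5, 4].
When 50 % inhibition is never bracketed the estimate is refused and
reported as `>max` or `<min`; when the 4PL fit fails, log-linear
interpolation between the two bracketing points is used and the result
is marked non-converged.

Replicate summaries use the sample (n − 1) standard deviation. A single
replicate yields SD 0 with a warning. The literal token `ND` is the
only missing-value marker in every CSV.

Calibration curves are ordinary least squares over ≥ 3 distinct
standards; quantification inverts the curve and scales by dilution
factor and sample mass to a per-g or per-100 g basis, warning when the
back-calculated concentration leaves the calibrated range. All
concentrations are µg/mL; unit conversion is the loader's job.

## Composite indices

Lower-is-better endpoints (IC50) use
`(100 − value)/(100 − least) × 100`; higher-is-better endpoints use
`value/highest × 100`. The reference set includes the per-endpoint
positive controls by default (the stated rule is "sample or positive
control"); this matters — acarbose, not a rice sample, holds both enzyme
minima. A value below the lower-better reference legitimately scores
above 100; a value above 100 would go negative and is clamped to 0 with
a warning, since a 0–100 potency index cannot be worse than "no
activity".

Composites are equally weighted means (weights configurable as any
simplex). Missing (`ND`) cells follow `nd_policy`:

* `exclude` (default) — re-average over the available parameters. For
  the white-rice panel with its non-detectable PTP1B cell this gives
  AHCI 30 against a printed 29; the alternative `zero` policy gives
  22.5. Exclude is closer to the published treatment and is the
  default; both are supported.
* `zero` — score the missing parameter 0.

Rounding is nearest-integer, half away from zero, by default; `floor`
is available because the published overall score for Karungkuruvai
(85 from component scores 94 and 77) is consistent with flooring
rather than rounding 85.5 up.

Recomputation from the printed panel reproduces the published AHCI for
Kattuyanam (96) and white rice OGRCI (5) exactly, and the overall
ranking Kattuyanam > Karungkuruvai > Chennangi ≫ white rice. Three
printed values do not reproduce under any reading of the stated
formulas and are deliberately not asserted anywhere:

* AHCI of Chennangi and Karungkuruvai recompute to 92 and 95 against
  printed 93 and 94 (a five-parameter variant including an external
  in vitro glycemic index, published separately, would plausibly close
  the gap but those inputs are not in the panel);
* OGRCI of Kattuyanam / Chennangi / Karungkuruvai recompute to
  93 / 67 / 74 against printed 96 / 70 / 77 — the reference set or the
  DPPH representation actually used for those three values is not
  recoverable from the stated rule (only the white-rice value
  reproduces).

The four-enzyme AHCI is the default; the parameter list is
configuration, so a fifth externally supplied index slots in without
code changes.

## Metabolite profiling

Internal-standard normalization divides each sample's intensities by
the geometric mean of the spiked-standard intensities in that sample —
geometric rather than arithmetic so one saturated standard cannot
dominate — and drops the standard rows. Class composition reports
integer-rounded percentages of the identification count. The
identification list and the relatively quantified matrix are separate
inputs: a compound can be identified without being quantified (the
study itself identifies 99 compounds but clusters a quantified
universe of 83).

Clustering is Ward linkage on Euclidean distances (scipy), with leaf
order from dendrogram traversal, lower-index child first. PCA
autoscales compounds (unit variance) by default — the convention of the
metabolomics platforms this emulates — with `center_only` available;
components are ordered by explained variance and signed so each
component's largest-magnitude loading is positive. Reconstruction from
all components reproduces the scaled matrix to 1e−8.

## Candidate screening

Lipinski thresholds are implemented inclusively (≤ 500 Da, logP ≤ 5,
HBD ≤ 5, HBA ≤ 10): catechin and dihydroquercetin carry exactly five
H-bond donors and are in the study's own passing list, so a strict
`< 5` reading would contradict it. BOILED-Egg ellipse coefficients
(white = high GI absorption, yolk = BBB permeation) ship as overridable
configuration with the published model's defaults; GI absorption is
"high" inside the white ellipse. The Abbott bioavailability score is
rule-based: anions score by polar surface area (≤ 75 Å² → 0.85,
≤ 150 → 0.56, else 0.11), everything else scores 0.55 with at most one
rule-of-five violation and 0.17 otherwise.

The screen's shortlist rule is Lipinski-pass ∧ GI-high ∧ bioavailability
≥ 0.55, optionally capped to the top N rule-compliant compounds by
relative abundance. The cap models the study's stated selection of its
*ten abundant* drug-like metabolites: two further compounds in the
20-compound descriptor table (mellein, sinensetin) satisfy every stated
rule, so abundance ranking is the only mechanism consistent with the
published set of ten. The packaged descriptor table is a
reconstruction: physicochemical descriptors are RDKit-computed from the
packaged SMILES (Crippen logP, topological PSA), and the abundance
column is synthetic, ordered so the ten docked compounds lead the
compliant set. Screening against it is therefore a fixture-level
regression test of the screening logic, not an external-data claim.

Docking energies are consumed, never computed. Lead selection keeps
compounds at or below the threshold (default −6 kcal/mol) on all five
targets; the packaged energy matrix yields exactly five leads
(3′-O-methylviolanone, catechin, cirsimaritin, dihydroquercetin,
isoxanthohumol), while the study's text claims seven — the two extra
compounds each miss the threshold in at least one column of the printed
matrix (isorhamnetin at −5.62 on α-amylase;
3′,4′,7-trihydroxyisoflavone at −5.27/−5.05 on α-amylase/IRS). The
strict result is reported and the discrepancy documented here rather
than papered over.

Interaction cells are parsed from the grouped
`"RES1, RES2 (bond type), …"` convention, with `Nil` meaning no
contacts. Bond-type synonyms ("H bond", "Conv. H bond",
"Conventional H bond", "C-H bond"/"Carbon H bond", …) normalize to one
closed vocabulary; unbalanced nesting as printed
(`"(halogen (fluorine bond)"`) is linearised before parsing; groups
with no pending residues are ignored. Parsing then serializing is the
identity on record sets.

## Statistics

One-way ANOVA with Tukey's HSD at α = 0.05 produces the pairwise
decision matrix; the compact-letter display uses insert-and-absorb with
a redundancy sweep, and its two contracts — groups share a letter iff
their difference is not significant, and the letter count is minimal —
are verified in tests against a brute-force clique-cover oracle for up
to six groups. Letters are assigned in ascending-mean order for
lower-is-better endpoints (so `a` marks the most potent sample) and
descending order otherwise. Because the bundled panel stores only
mean/SD/n, the pipeline's letter stage simulates replicates from
Normal(mean, SD) under the run seed before testing.

Correlations are sample Pearson coefficients over genotype means,
excluding rows missing either variable (positive controls have no
phenolic totals). Over the four genotypes the panel reproduces the
published r = 0.937 (total phenolics vs DPPH) and r = 0.953 (vs FRAP)
to three decimals.

## Synthetic data

Generators emulate the study designs at desk scale: Gaussian replicate
noise around target mean/SD cells (the study reports mean ± SD of
triplicates, so Gaussian is the minimal faithful model), dose-response
series as replicate-averaged draws around a 4PL curve truncated to the
plate band [−20, 120] (the truncation keeps QC flags exercised), and
log-normal metabolite abundances (positive, right-skewed) with
multiplicative fold-change shifts on per-group marker compounds.
Ground-truth labels are always returned; the recovery tests — IC50
within 10 % of truth in ≥ 95/100 seeded series at 2-point noise,
exact recovery of three planted genotype groups by Ward clustering at
fold change 8 — are the acceptance surface for the stochastic stages.

What the generators do **not** emulate: plate spatial effects,
heteroscedastic instrument noise, ionization suppression or any other
LC-MS matrix effect, correlated replicate errors, or kinetic enzyme
mechanisms. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated noise model, not robustness to real
instrument pathology.

Problem sizes used throughout the suite and the pipeline's profiling
stage — 7-point dose-response grids, 100-seed recovery loops,
30–40-compound matrices with 9 samples, 1000 random decision matrices —
were chosen as the smallest designs at which the recovery properties
are stable and clearly diagnostic.

## Bundled reference tables

The panel, binding-energy and interaction tables are verbatim
transcriptions (including the `ND` cell and the typographic minus
sign), each row carrying a `source` provenance tag. The metabolite
identification table is partial by necessity: compounds named in the
study text carry their real names, classes and memberships; the
remainder are synthetic placeholders (named `synthetic-…`, flagged in a
`provenance` column) allocated so that class and subclass counts and
the per-genotype identification totals (70 / 68 / 71) match the
published summary. The printed subclass counts sum to 100 while the
stated identification total is 99; the table follows the subclass
counts, and the reported class percentages (26 % phenolic acids, 9 %
other polyphenols) are identical under either denominator. Numeric
annotation fields (RT, m/z, identification score, abundances) are
seeded synthetic values.

## Known limitations

* Composite scores are point estimates; no uncertainty is propagated
  (none is published for them).
* The ADME descriptor fixture reconstructs, not reproduces, the
  original web-tool outputs; absolute descriptor values may differ from
  other logP engines, which is why the screening threshold column is
  configurable.
* The compact-letter minimality check is exhaustive only to six groups;
  beyond that the insert-and-absorb result is correct but not proven
  minimal.
* Dose-response estimation assumes control-normalized percent
  inhibition; assays on other scales must be normalized upstream.
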