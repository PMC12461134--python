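# Methods

This note documents the models and procedures implemented in
`thermadapt`, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## CAAS detection

### Definition

Given a protein alignment of one orthogroup and a partition of its
taxa into *foreground* and *background* groups (taxa may also be
`excluded`), a column is a convergent amino acid substitution (CAAS)
when the set of residues observed in the foreground taxa and the set
observed in the background taxa are both non-empty and disjoint. Gap
(`-`) and unknown (`X`) characters are treated as missing data: they
are evidence of nothing, so they are removed from the residue sets,
and a column is only called when the number of missing
foreground/background cells is at most `max_missing` (default 0).

Three strictness scenarios grade how fixed each group must be:

| scenario | constraint |
|---|---|
| 1 | both groups fixed for a single residue each |
| 2 | at least one group fixed |
| 3 | any two disjoint residue sets |

Scenario 1 ⊆ 2 ⊆ 3 by construction (property-tested). The default is
scenario 3 with `max_missing = 0` — the most inclusive disjointness
rule, but strict about data completeness. The detector is verified
column-for-column against an independently written brute-force
reference on randomized small alignments.

### Trimming

Gap-rich alignment regions are removed before scanning by a single
per-column rule: a column is dropped when its fraction of gap cells
exceeds `trim_max_gap_fraction` (default 0.2). Gap-heuristic trimmers
used in practice (e.g. TrimAl's gappyout) involve an internal slope
heuristic with no closed specification; a fixed threshold is
transparent, configurable and recorded with every run. A trimmed-to-
original column map is kept so every call is reported in both
coordinate systems (1-based in all reports, 0-based internally).

### Variability filter

Manual inspection of alignments for "highly variable regions" is
replaced by a deterministic rule so results are reproducible: every
sliding window of `var_window` columns (default 5) whose *mean* number
of distinct non-gap residues per column exceeds `var_max_distinct`
(default 3) has all of its columns masked. Masked columns stay in the
alignment (coordinates are not disturbed) but are excluded from
calling. With four taxa the defaults only mask stretches where nearly
every column shows maximal disagreement — precisely where apparent
convergence is most plausibly alignment error rather than biology.

## Substitution profiling

**Flux.** For each amino acid, C counts gain events (the residue
appears in a record's foreground set) and R loss events (it appears in
a background set); the flux is D = (C − R)/(C + R), in [−1, 1], NaN
when the residue was never involved. The background residue is treated
as the reference state — foreground residues are "created", background
residues "removed" — matching the foreground-centric definition of C
and R; no ancestral-state reconstruction is attempted. A record with
non-singleton residue sets contributes one event per *distinct*
residue, not per taxon: a convergent column is one substitution event.

**Exchange matrix.** Only singleton–singleton records (scenario-1-like
columns) have an unambiguous direction, so only they increment the
20×20 background→foreground matrix; its grand total therefore equals
the number of singleton–singleton records, and the flux table's total
gains equal total losses equal the record count when all sets are
singletons.

**Residue classes.** Fixed partition of the 20 amino acids:
hydrophilic {N,Q,S,T,Y}, hydrophobic {A,C,F,G,I,L,M,P,V,W}, negatively
charged {D,E}, positively charged {H,K,R}.

**Arg/Lys ratio.** Computed as total arginine count over total lysine
count across whole provided sequences by default (`--sites all`);
restricting to CAAS residues is available behind `--sites caas`. Zero
lysines yields NaN, not an error.

**Molecular weight.** Sum of standard average residue masses plus one
water (18.02 Da), with unknown residues reported by 1-based position.
Implemented as a small in-package table so the error contract is
explicit.

**Category summaries.** Functional categories are summarised with two
percentage columns: share within the main category and share of all
records. Denominators are the category totals and the table's own
grand total (the sum of its rows); percentages are rounded to 2
decimals in reports. Records with no annotation are tallied under
"Function unknown (S)".

## Enzyme kinetics

### From signal to rate

A 5-minute assay time series is reduced to a rate by the ordinary
least-squares slope of signal on time over the assay window, with an
optional multiplicative calibration factor. At least three points are
required; a non-positive slope is flagged non-catalytic rather than
raised, and flagged rates are excluded downstream with a warning.

### Arrhenius fit

Under k = A·exp(−Eₐ/RT) the plot of ln k against 1/T (T in kelvin,
offset +273.15) is linear with slope −Eₐ/R. The fit is a least-squares
regression on per-replicate points inside the temperature window, with
R = 8.314 J·mol⁻¹·K⁻¹ and Eₐ reported in kJ·mol⁻¹. Defaults and
rationale:

* **Window 2–20 °C.** Above the activity optimum the rate falls with
  temperature and the law no longer holds; warmer assay points are
  never auto-included, they must be requested explicitly.
* **Per-replicate fitting.** `fit_arrhenius_per_replicate` treats each
  replicate index as one individual assayed across the whole
  temperature series and returns one Eₐ per individual. Population
  comparisons then operate on n individual Eₐ values per group, which
  preserves between-individual variance; this is the default for
  comparisons.
* **Non-positive rates are excluded**, not imputed: the log transform
  is undefined and any imputation would bias the slope. If exclusion
  leaves fewer than three distinct temperatures, the fit errors.

Eₐ is invariant to the unit of rate (a global rescaling shifts only
ln A), so rates may be left in raw signal units.

### Population statistics

Welch's unequal-variance t-test is the default two-group comparison:
groups here are small (n = 5) with variances that routinely differ
severalfold, and reproducing published two-decimal p-values from
printed mean ± SD summaries requires the Welch–Satterthwaite degrees
of freedom where a pooled test does not. Tests are two-sided; no
multiple-testing correction is applied by default (a Benjamini–
Hochberg option exists behind a flag). Reported p-values are rounded
to 2 decimals, or 3 when p < 0.005, matching the mixed rendering of
published tables. Degenerate inputs (both SDs zero) are flagged and
return p = 1 (equal means) or p = 0 (unequal) instead of raising.

One-way ANOVA with Tukey's HSD covers multi-group comparisons. The
all-groups-constant degenerate case returns F = 0, p = 1 (there is no
variance to partition). Note that Tukey's adjusted p is only
guaranteed to dominate the *unadjusted* p computed from the same
pooled MSE and within-group degrees of freedom; it can fall below a
two-sample pooled t-test p for the same pair, because the latter uses
a different error estimate.

## Synthetic data

The orthogroup generator emulates the input side of the CAAS scan:
per column a uniform ancestral residue, independent per-taxon
substitution at a configurable background rate, i.i.d. per-cell gaps,
and planted convergent columns (foreground residue a, background
residue b ≠ a, drawn uniformly among ordered distinct pairs, never
gapped). It does **not** emulate phylogenetic structure, rate
heterogeneity across sites, indel blocks, alignment error, or
compositional bias — so perfect planted-truth recovery demonstrates
the correctness of the detection logic, not its behaviour on real
alignments, where trimming and the variability filter carry the load.

The kinetics generator draws replicate rates from the exact Arrhenius
law with multiplicative lognormal noise (rates stay positive) at the
assay temperatures {2, 5, 10, 15, 20, 30, 40, 50} °C, 5 replicates and
σ = 0.05 by default — the sample size of the enzyme assays it stands
in for, with a noise level giving coefficients of variation of a few
percent, typical of replicated spectrophotometric rate measurements.
Exact recovery at σ = 0 (relative error < 1e−9, r² = 1) verifies the
estimator; at σ = 0.05 the median relative Eₐ error over 100
simulations stays below 5 %. The null calibration (two populations
with identical parameters, 1000 simulations) checks that the Welch
comparison rejects at the nominal 5 % rate. Lognormal noise makes the
per-replicate log-rates exactly Gaussian, so calibration there is the
expected behaviour, not a stress test of robustness.

## Problem sizes

Default simulated collections are 20 orthogroups × 100 columns with 10
planted CAAS, and kinetics runs use 5 temperatures × 5 replicates;
recovery studies use 100 simulations and the null calibration 1000.
These sizes give stable Monte-Carlo estimates (binomial SE of the
rejection rate ≈ 0.7 percentage points) while keeping the full suite
fast.

## Known limitations

* The CAAS scan is purely set-based per column: it uses no phylogeny,
  no ancestral reconstruction, and no significance model for the
  number of detections; counts are descriptive.
* The gap-threshold trim is not a reimplementation of any published
  trimmer's heuristic; on gap-free synthetic data this is immaterial,
  on real alignments the threshold matters and is recorded per run.
* Enzyme rates are unit-agnostic; no calibration to µmol product is
  attempted, which is harmless for Eₐ (unit-invariant) but means
  activity levels are comparable only within one assay series.
* Only the Arrhenius model is offered; no optimum-temperature or
  Sharpe–Schoolfield-type models above the optimum.
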