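# Methods

This note documents the models and conventions behind `strainteract`: what
each stage computes, the defaults and why, what the synthetic generator
does and does not emulate, and the numerical choices a maintainer would
want written down.

## Genotypic classification

Pairwise ANI is a similarity, not an equivalence: A–B and B–C can both
exceed a cut-off while A–C does not. "Classification at an ANI cut-off
*t*" is therefore defined as **single linkage**: groups are the connected
components of the graph with an edge wherever ANI ≥ *t* (inclusive, so
identical genomes remain grouped at *t* = 100). Single linkage is the only
standard rule that makes the cut-off semantics well defined and produces a
nested ladder of partitions as *t* sweeps from below the minimum pairwise
value (one group) to 100% (all singletons, absent identical genomes).
Group labels are canonical — numbered by smallest member index — and
rendered as `ANI_I`, `ANI_II`, … The default sweep grid is the set of
distinct off-diagonal values plus 100, which realises every achievable
partition without arbitrary spacing. Complete linkage is not implemented;
the implementation is checked against a brute-force transitive-closure
oracle over exhaustively enumerated small matrices.

Raw FastANI output is asymmetric (query→reference). The two directions of
a pair are harmonised by **arithmetic mean**; the maximum was rejected
because it systematically inflates similarity near a cut-off. All percent
quantities stay on the 0–100 scale end to end.

Gene-family union counts (families present in at least one member of an
isolate set) quantify functional complementarity; means are reported
separately for within-group and group-spanning combinations.

## qPCR and relative fitness

Cycle thresholds convert to copies through the assay calibration
Ct = −3.804·log₁₀(copies) + 43.816 (R² = 0.9996); `ct_to_copies` is the
exact inverse of this line (round-trip relative error < 1e−9). Relative
fitness is

W = log₂(Q_final_co / Q_initial) / log₂(Q_final_mono / Q_initial),

computed on **replicate means of log₁₀ biomass** (the geometric mean of
copies; with Q defined per trial from its own Day-0 observations). The
log-scale mean matches how qPCR endpoints are normally summarised, and on
the log scale the statistic reduces to a ratio of log-growth increments, so
the log base cancels. W is invariant to jointly rescaling all three
quantities; monoculture rows are exactly 1 by construction; W < 0
(decline below inoculum) is allowed and flagged, never clamped. The final
day defaults to Day 8, configurable.

All two-sample tests are **Welch** (unequal variance) two-sided t-tests:
the replicate standard deviations of different culture conditions are
visibly unequal, and Welch costs almost nothing when they happen to be
equal. Degenerate inputs resolve by convention: two constant equal samples
give (t = 0, p = 1). The fitness–ANI association is Pearson's r with the
classical t-distribution p (n − 2 df) from a least-squares fit. No
multiple-testing correction is applied across the per-combination contrast
family by default (raw per-contrast stars are reported); BH adjustment is
available in the transcription module and can be applied to any p column.

### Cross- vs within-group contrast

Under a grouping scheme, each trial is `cross` (members span ≥ 2 groups)
or `within` (monocultures and same-group cocultures). Three trial-level
statistics are contrasted by Welch tests: final log₁₀ biomass, **log₁₀
growth gain** (final − Day 0), and relative fitness. The growth gain is
the headline detection statistic, for two reasons:

- the total inoculum (10⁶ CFU/mL) is split equally among coculture
  members, so raw final biomass is confounded with member count; the gain
  subtracts each trial's own inoculum;
- relative fitness divides by the focal's monoculture growth, so fitness
  values of trials sharing a focal isolate are correlated; gain values are
  independent across trials, which keeps the Welch test's type-I error at
  its nominal level (verified at α = 0.05 over 1000 null simulations,
  acceptance band 3–7%).

The biomass and fitness contrasts are still computed and reported. A
scheme with no cross-group trials (e.g. the one-group scheme) yields a
not-applicable contrast, not an error.

## Cross-feeding network

Relative amino-acid production R = mean(C final day)/mean(C Day 0); the
default test compares final-day and Day-0 replicate **concentrations**
(Welch); testing per-replicate ratios against 1 is available by flag. The
call partition is exhaustive and exclusive: `produced` (R > 1, p < α),
`utilised` (R < 1, p < α), else `neutral`, with α = 0.05 throughout and the
test two-sided — direction is read from the ratio, not built into the test.

An edge X → Y for amino acid *a* requires the three-gate conjunction
(production by X in Y's conditioned medium, upregulation of X's terminal
biosynthesis gene for *a* in coculture with Y, utilisation by Y in X's
medium). Consequences worth noting:

- the inferred edge set is always a subset of the production-only edge
  set (each gate only filters), so borderline cases — an amino acid
  produced but not transcriptionally supported, or produced but not
  consumed by the partner — drop out without special-casing;
- the transcription gate applies to the **producer** side only; consumer
  transporter evidence is not modelled;
- when a group is represented by more than one isolate (two independent
  coculture experiment sets), the default aggregation is strict: **all**
  representatives must pass the transcription gate (`any` is available).
  Strictness reflects requiring a cooperation to replicate across
  experiment sets.

The amino-acid vocabulary is fixed at the 18 species detected by HPLC in
the defined-medium fermentations (the 20 proteinogenic acids minus
asparagine and valine); unknown names are rejected rather than passed
through. The network is a directed multigraph keyed by (producer,
consumer, amino acid); the summary counts distinct amino acids across all
edges and per-group in/out degrees.

## Differential expression

P-values are **inputs**: the DE test that produced them is out of scope,
and this module only (optionally) BH-adjusts raw p-values — per
(isolate, condition) family — and applies the significance gate
adjusted p < 0.05 **and** |log₂FC| > 1, both strict, matching the
"adjusted p < 0.05, fold change > 2" convention. BH is the step-up
procedure with the cumulative-minimum monotonicity enforcement; it is
implemented directly (it is a one-liner on sorted values) and
cross-checked in the tests against both a literal brute-force of the
definition and `statsmodels.multipletests`. COG summaries report the mean
log₂FC and gene count per (isolate, condition, category); records without
a category pool under `unassigned`.

## Synthetic generator

The generator emits every table the pipeline reads, with planted truth, so
each stage can be validated by recovery. Defaults are the study
conditions the pipeline was designed around:

| parameter | default | meaning |
| --- | --- | --- |
| `n_isolates`, `group_sizes` | 9, (3, 5, 1) | isolates per genotypic group |
| `ani_within_range` | (99.6, 100) % | within-group pairwise ANI |
| `ani_between_range` | (98.7, 99.4) % | between-group pairwise ANI |
| `n_replicates` | 4 | biological replicates |
| `days` | 0, 2, 4, 6, 8 | sampling days |
| `log10_baseline_growth` | (0.2625, 0.2213, 0.25) /day | monoculture log₁₀ gain per day; 8-day endpoints 8.10/7.77/8.00 log₁₀ copies/mL from a 10⁶ inoculum |
| `interaction_effect` | +log₁₀ 2 on group II from either partner; −log₁₀ 1.25 on I and III | additive shift on log₁₀ final abundance |
| `growth_noise_sd` | 0.1 | Gaussian noise, log₁₀ scale |
| `production_roles` | 15 roles over 6 ordered pairs, 11 amino acids | planted cross-feeding network |
| `production_ratio` / `utilisation_ratio` | 2.0 / 0.5 | Day-8/Day-0 concentration factor for producer / consumer |
| `concentration_noise_cv` | 0.1 | lognormal CV (replicate-level variance of the chemistry is not reported anywhere authoritative; 10% is a typical HPLC replicate CV) |
| `terminal_gene_log2fc` | 3.0 | planted upregulation of producers' terminal genes |
| `background_log2fc_sd` | 0.25 | null transcriptional noise |

Design decisions:

- **Endpoint model, not kinetics.** Growth is log-linear with additive
  group-to-group effects because downstream analysis consumes endpoints
  and daily biomass only; no ODE or lag/stationary structure is modelled.
  Day-0 observations are exact (they define the inoculum); interaction
  effects and noise apply from the first post-inoculation sample, so the
  final day carries the full planted effect and, with zero noise, the
  coculture/monoculture copy ratio equals the planted multiplier exactly.
- **Effects act group-to-group**, not isolate-to-isolate, matching the
  unit of inference; distinct partner groups contribute once each.
- **Multiplicative lognormal concentration noise** (mean-one), since
  concentrations are positive and HPLC error scales with level; with zero
  CV every relative production ratio is exactly its planted factor.
- **Seed substreams.** One global seed derives independent per-table
  streams (ANI = 1, design = 2, growth = 3, chemistry/transcription = 4,
  gene families = 5), so any table regenerates bit-identically on its own.
- The coculture design samples distinct member subsets with sizes uniform
  over the requested range (default 2–3) from the enumerated subset pool;
  the focal isolate is drawn uniformly from each trial's members.
- Group representatives in the transcription tables are the first and last
  member of each group (two independent experiment sets; singletons
  contribute the same isolate twice).

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: sequence-level variation (no genomes or
reads), growth kinetics and death phases, qPCR efficiency drift or
plate effects, batch structure between the two experiment sets, amino-acid
interconversion (each amino acid is independent), transporter expression
on the consumer side, and compositional interactions among more than two
groups beyond additive effects.

## Problem sizes in validation

The recovery and calibration suites use the study-scale defaults: 95
trials (9 monocultures + 86 cocultures) per simulated dataset, 100 seeds
for detection power and network recovery, 1000 seeds for null calibration,
200 seeds for partition recovery; the classification oracle is exhaustive
over all matrices up to n = 6 on small ANI alphabets (three letters
through n = 5, two letters at n = 6) and densely sampled (4000 matrices,
four-letter alphabet) at n = 7.

## Known limitations

- Single linkage is a documented choice; at intermediate cut-offs other
  linkage rules can give different intermediate partitions.
- The three-gate conjunction inherits the per-gate false-negative rates;
  a true cooperation missing any single line of evidence is not reported.
- Welch tests on 4 replicates have limited power for small concentration
  changes; ratios near 1 will usually be called neutral.
- The CLI's `coop` subcommand needs an explicit group→isolates mapping for
  non-synthetic data (`--groups`); the default mapping matches the
  synthetic representatives only.
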