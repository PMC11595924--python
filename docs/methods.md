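# Methods

## The screening model

The pipeline analyses a completely randomised germination screen: a panel
of accessions (genotypes) germinated under a control (0% PEG-6000, dose
0), a moderate osmotic stress (7.5% PEG, dose 0.5) and a severe stress
(15% PEG, dose 1), with `r` replicate petri dishes per accession ×
treatment cell. Twelve traits are measured per dish: five morphological
(GP %, RL cm, SL cm, FW mg, DW mg) and seven biochemical (PC, SSC, TPC,
AC in µg/g FW; GPA, CAT in units/min/g FW; LP in nmol/g FW). Units are
carried as opaque labels — the pipeline never converts them. Germination
percentage is 100 × germinated / sown seeds, so it lives in [0, 100] by
construction.

All inference is fixed-effects on a balanced design:

* **One-way CRD ANOVA** (accession, or tolerance class, as the factor)
  with the usual between/within decomposition and an upper-tail F
  p-value.
* **Two-way factorial ANOVA** (accession × PEG) using balanced-design
  sums of squares; every cell must hold the same replicate count r ≥ 2,
  and unbalanced tables are rejected rather than approximated (no Type
  II/III machinery — the assay design is balanced, and silently changing
  the estimand seemed worse than asking the caller to rebalance).
* **Duncan's new multiple range test** for letter displays. For span p
  the protection level is γ_p = 1 − (1 − α)^(p−1) and the least
  significant range is LSR_p = q(p, ν, 1 − γ_p) · √(MSE/n). The
  protected stepwise rule is applied in its closed form: a pair of
  ordered means is non-significant iff some window containing both has
  range < its own LSR; letters label the maximal such windows. Unequal
  group sizes use the harmonic mean n. Ties in means are ordered stably
  by level identifier and never split a letter group. The quantile q
  comes from the studentized-range distribution (scipy), wrapped in a
  cache because a single numerical inversion costs ~0.1 s; it is
  validated against published critical-value tables in the test-suite.

### Degenerate inputs

Zero error variance yields F = +∞ with p = 0 and a `degenerate` flag
(F = nan when the effect SS also vanishes); `duncan_letters` with
MSE = 0 gives distinct letters to distinct means, flagged likewise.
p-values are kept at machine precision internally; the report layer
prints values below 1e-4 as `<0.0001` and rounds to two decimals with
round-half-even.

## Ranking and classes

Per stress scope the accession's trait value is its mean over replicates
(combined scope: the mean of its T1 and T2 means, ranked *after*
averaging — averaging the two scope ARs is not the same thing and is
deliberately not done). Rank 1 is best under the trait's orientation;
all traits are higher-is-better except LP (membrane-damage marker). The
average rank (AR) uses 11 traits by default (all but LP), so tie-free
ARs are multiples of 1/11. The STI basis is germination plus seedling
growth, the latter computed as RL + SL summed per replicate before
averaging; component STIs are averaged arithmetically, and the combined
scope takes the mean of the T1 and T2 aggregates. Final order: STI
descending for T1/T2, AR ascending for combined (tie-breaks: the other
index, then accession id — fully deterministic). Both the trait sets and
the ordering policies are configurable (`RankingConfig`, or the YAML
config accepted by the CLI).

Tolerance classes slice the final combined ordering into three
near-equal contiguous groups (64 accessions → 22/21/21): high /
moderate / low.

## Biomarker analysis

For each biochemical trait and stress treatment, class means are
compared by one-way ANOVA **on accession means** (so group SDs reflect
between-accession spread, not dish noise) with Duncan letters from the
same error term. The biomarker set is the traits significant at α
(default 0.01) under *every* stress treatment, ordered by worst-case p.
The set is monotone in α by construction.

A caveat found while validating: when the classes are themselves derived
from the ranking, traits that carry *no* tolerance signal can still come
out significant, because the combined ranking partly selects on their
genotype effects, which persist across treatments — a selection artifact
akin to winner's curse. The biomarker recovery experiments therefore
condition on the generator's planted classes; with recovered classes, at
α = 0.01 some signal-free trait entered the biomarker set in roughly one
pilot panel in ten. Interpreting class-comparison tables on real data
deserves the same caution.

## Synthetic-data generator

The generator emulates the screening design with a single latent
tolerance score per accession, `tol ∈ [0, 1]` (evenly spaced over the
panel by default, assigned in a seed-determined permutation). Expected
cell means for accession i, trait t, dose s:

* declining traits (GP, RL, SL, FW): μ_t · g_it · (1 − d_t·s·(1 − e_t·tol_i))
* accumulating traits (DW and the biochemicals): μ_t · g_it · (1 + u_t·s·(1 + e_t·tol_i))
* LP: as accumulating, but driven by sensitivity (1 + e·(1 − tol_i)) —
  the most stressed-damaged accessions are the least tolerant.

g_it is a mild lognormal genotype effect drawn independently per
accession × trait; replicate values are truncated-at-zero normal with a
constant CV; GP is a binomial germination count out of 25 seeds per
dish. DW *increases* with dose on purpose — it exercises the
orientation-override machinery, since a dose-accumulating trait can
still be higher-is-better.

Calibration: control baselines μ_t are the panel grand means of an
in-vitro tomato screen under 0% PEG (e.g. GP 90.10%, RL 8.21 cm, PC
854.45 µg/g FW), and the dose coefficients d_t, u_t are solved so that
at the mean tolerance score (0.5) the dose-1 grand mean hits the
corresponding full-stress/control ratio (e.g. GP → 80.04/90.10, PC →
2295.87/854.45). A per-trait `signal_weight` scales e_t so individual
traits' tolerance links can be silenced, which is how the biomarker
recovery experiments isolate PC/SSC/TPC.

### Default parameters and what they represent

| parameter | default | meaning |
|---|---|---|
| n_accessions / n_reps / seeds_per_dish | 64 / 5 / 25 | the screening design |
| tolerance_effect e | 1.0 | strong genotype × treatment interaction |
| genotype_sd | 0.01 | mild lognormal genotype main effect (log-scale SD) |
| noise_cv | 0.02 | replicate CV of the non-GP traits |
| tolerance_scores | evenly spaced | planted gradient for recovery tests |

The default is a deliberately *high-signal, low-noise* operating point:
the tolerance gradient dominates accession differences, so the planted
ordering is recoverable (Spearman between score and combined rank ≈
−0.998; the three top-scored accessions land in the top five combined
ranks in ≳95% of panels). Real screens are noisier — replicate CVs of
5–15% and genotype main effects rivalling the treatment effect are
common, and under such settings adjacent accessions on the planted
gradient are *not* reliably separable (with CV 8% and genotype SD 6% the
rank correlation stays below −0.95 but top-3 identification drops to
roughly a third of panels). Passing recovery tests therefore demonstrate
correctness of the machinery under the generator's idealised conditions,
not expected precision on field-quality data. The generator also omits,
by design: spatial/batch effects between dishes, trait–trait residual
correlation beyond the shared tolerance score, measurement floor/ceiling
effects other than GP's [0, 100] clamp, and any dose nonlinearity (the
dose response is linear in s between the calibrated anchors).

## Numerical choices

* Studentized-range quantiles: scipy's `studentized_range.ppf`,
  lru-cached; spot-validated against published tables at 0.95/0.99.
* SS additivity is asserted on every ANOVA table at 1e-6 relative
  (measured agreement with brute-force recomputation is ~1e-15).
* Rounding to 2 decimals (numpy round-half-even) happens only in report
  emission; ranks, ARs and STIs are exact internally.
* Ties: mid-ranks (average method) in per-trait rankings; deterministic
  id-based tie-breaks in final orderings; stable mean-then-id order in
  Duncan displays.
* Truncated-normal noise is drawn by resampling negatives (truncation
  mass ≤ 1e-6 at the default CV, so the loop is effectively free).

## Known limitations

* Only balanced two-way designs; no mixed models or unbalanced SS types.
* Duncan's test is the only multiple-comparison procedure; no
  Tukey/Scheffé alternatives.
* The only tolerance index implemented is the Fernandez STI (plus AR);
  SSI, TOL, GMP, MP, YSI would be natural extensions.
* Class construction is a rank slice; model-based clustering of
  tolerance is out of scope.
* The generator's calibration targets grand means only; it makes no
  attempt to match accession-level values or trait covariances of any
  real panel.
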