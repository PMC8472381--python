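# Methods

This note records the model behind each stage, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate.

## Spike-in absolute quantification

The qPCR model assumes both assays are read at the same fluorescence
threshold, so the initial template ratio of assays *a* and *b* is
(1+E_a)^Ct_a / (1+E_b)^Ct_b with per-cycle efficiency E (a fraction in
(0, 1.2]; values above 1.2 are rejected as artefacts) and cycle threshold
Ct. Efficiencies are inputs — estimating them from raw fluorescence
curves is out of scope. When a sample has replicate wells per assay the
pipeline averages Ct (and efficiency) before forming the ratio. The
ratio is computed in log space and raises on non-representable results
rather than overflowing.

Volume removed during the incubation for plaque titrations is corrected
with a single multiplicative factor V/(V − v_removed) on the end-point
census, not compounded per sampling event: aliquots remove cells in
proportion to volume, and per-event bookkeeping would require withdrawal
times that are not part of the data model.

The bundled worked-example qPCR table stores the end-point rows with the
assay labels swapped relative to their original presentation: only that
pairing of the (efficiency, Ct) tuples yields the measured community
*growth* (a ~783-fold excess of 16S over the spike); the as-labeled
pairing would imply a ~600-fold community collapse, contradicting every
other measurement in the dataset. The fixture documents this in its
docstring.

## Per-taxon growth

Amplicon read proportions are taken to equal 16S copy proportions (no
amplicon-length or primer-bias correction). Growth per ASV is
max(final − initial, 0): a taxon whose abundance fell is treated as a
non-grower, because death and growth within one interval cannot be
separated with two time points. Cell counts divide copies by a
genus-level 16S copies-per-genome; a missing genus falls back to 1
copy/genome with a logged warning, which deliberately *over*-estimates
cells (and hence the taxon's carbon draw) while flagging the uncertainty.
Generation-time estimates use exact log2 arithmetic with no rounding to
whole doublings. The detection limit (cells corresponding to a single
read) is reported at two significant figures, matching how such limits
are meaningfully quoted.

## Gradient fitting and labeling

A taxon's DNA mass over fraction density is modelled as a single Gaussian
A·exp(−(x−μ)²/2σ²); the fitted μ estimates its buoyant density.
Per-fraction taxon mass is the fraction's total DNA times the taxon's
read share in that fraction; fractions with zero total reads contribute
no point, while zero-share fractions contribute genuine zero points that
constrain the fit.

Numerical choices: the optimiser (Levenberg–Marquardt via trust-region
reflective, scipy `curve_fit`) is initialised at the mass-weighted mean
and standard deviation with amplitude at the observed maximum; μ is
bounded to the observed density range and σ to [1e-5, range width]. At
least 4 fractions with positive mass are required (`min_fit_points`);
otherwise the fit is refused. R² = 1 − SS_res/SS_tot is reported
unclamped — negative values honestly signal fits worse than a flat line —
and compared as-is to thresholds.

If the control-bottle fit fails or has R² < 0.8 (`min_r2`, configurable)
and a GC fraction is available, the unlabeled density falls back to the
Schildkraut relation ρ = 1.660 + 0.098·GC and the result is marked
`theoretical`. There is no analogous fallback for the labeled bottle:
the labeling level is exactly what that fit is supposed to measure, so a
failed labeled-bottle fit yields `insufficient_data` rather than a guess.

Labeling is clamp((ρ_13C − ρ_12C)/0.036, 0, 1), where 0.036 g/mL is the
density gain of fully heavy-carbon-labeled DNA. Levels below 0.25 carry
a `possibly_indirect` flag (weak shifts can arise from cross-feeding on
labeled metabolites), and the default significance rule — labeling ≥ 0.10
with labeled-bottle R² ≥ 0.8 — is an explicit, configurable choice; no
universally agreed criterion exists for calling an ASV "labeled".

Published labeling levels were evidently computed from unrounded fitted
densities (two-decimal densities cannot reproduce them exactly), so the
pipeline also accepts labeling levels directly as an input table; the
bundled worked example uses that channel.

## Carbon ledger

Defaults: 30 fg C per cell (a measured value; real quotas span roughly
20–40 fg, and the single global value is the dominant systematic
uncertainty of the budget — it is overridable), 1.49×10⁻¹⁶ g C per phage
particle, yield 0.33 (from the pure-culture feeding experiment,
`pure_culture_yield`), label purity 1.0, and an initial heavy-carbon pool
of 3.2×10⁻⁶ g. The pool default follows the published budget input even
though 2.28×10¹⁰ particles × 1.49×10⁻¹⁶ g C = 3.40×10⁻⁶ g; the two
disagree at the ~6% level in the source material and the discrepancy is
documented rather than resolved. Simulations use `phage_carbon_pool` so
truth and estimate share one self-consistent denominator. Contributions
are reported both at full precision and at integer-percent display
rounding.

## The synthetic generator

`simulate_experiment` emulates the study design: two bottles, a community
of 50 ASVs of which 9 are labeled, 12 fractions evenly spaced over
1.65–1.78 g/mL, taxon density spread σ = 0.006 g/mL, unlabeled peak
positions drawn from the GC relation on GC ~ U(0.35, 0.65), labeled-bottle
peaks shifted by 0.036 × labeling. The labeled taxa default to the real
experiment's labeling levels, initial/final read shares and copy numbers,
and the total census runs 9.78×10⁷ → 2.47×10⁸ copies. Noise layers:
mean-one log-normal on per-fraction taxon DNA (CV 0.10), multinomial read
sampling, Gaussian Ct noise (sd 0.1 cycles) on triplicate qPCR wells —
replicate wells being standard qPCR practice. Conservation is exact by
construction: noise is applied to taxon masses first and each fraction's
recorded total is their sum.

Free parameters not fixed by the emulated design were set once to
realistic values: 100,000 reads per gradient fraction (a modern
multiplexed amplicon run across 24 fraction libraries; this depth also
ensures that the wings of a σ = 0.006 g/mL peak sampled at ~0.012 g/mL
fraction spacing register nonzero counts, without which the 4-point fit
precondition would rarely be satisfiable), 4,000 reads per bulk sample
(the real samples had 3,748 and 3,578), 400 ng of DNA per gradient, and
an exponential free-phage decay to ~10⁻⁸ of the inoculum by the final
time point.

What the generator does *not* emulate — and hence what passing recovery
tests cannot show: bimodal partially-labeled subpopulations (each taxon
is one peak), compositional coupling between bottles beyond a shared
final community, PCR amplification bias and chimeras, overdispersion
beyond multinomial sampling, density-dependent fraction volumes, and any
ultracentrifugation physics. Parameter-recovery results therefore
characterise the estimator under its own assumptions, not the field
accuracy of SIP.

A geometric consequence of the emulated design worth knowing: with σ =
0.006 g/mL and ~0.012 g/mL fraction spacing, a taxon whose peak falls on
a fraction density concentrates its reads in three fractions; its
labeled-bottle fit is then (correctly) refused for having fewer than four
positive points. In simulations this affects a few percent of taxa per
seed. Control-bottle refusals are rescued by the GC fallback.

## Problem sizes in the test suite

Statistical tests run the full pipeline on 10 seeded synthetic
experiments at the defaults above (50 ASVs, 24 fraction libraries each);
the read-depth monotonicity check compares depths of 3,000 vs 30,000
reads per fraction over 3 seeds, a regime where counting noise — not the
fluorometry CV — limits accuracy; the fit-versus-grid-search equivalence
check uses 16-point instances, dense enough that the peak is constrained
by several points rather than sitting on a degenerate (μ, σ) ridge. All
sizes are the package's own choices for characterising the estimator.

## Known limitations

- The single carbon quota per cell and single yield for all taxa
  propagate directly into every contribution; both are biological
  simplifications inherited from the method.
- The Gaussian model assumes one homogeneously labeled population per
  taxon; partial labeling of a subpopulation shifts μ rather than
  splitting the peak, biasing labeling toward the population average.
- The growth clamp discards taxa with simultaneous death and growth, so
  the mass balance is a lower bound in that respect.
- GC-fallback densities carry the (unquantified here) error of the
  GC–density relation; results relying on it inherit that uncertainty.
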