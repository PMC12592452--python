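# Methods

## The mixing model

Each consumer is attributed to the three particle size-fraction sources
(small 0.7–6 µm, medium 6–53 µm, large >53 µm) through three amino-acid
tracers: δ¹⁵N of phenylalanine and lysine and δ¹³C of leucine. Source and
essential amino acids change negligibly across trophic transfers, so the
trophic discrimination factor is fixed at zero and a consumer's tracer
vector is modelled as a noisy convex combination of the source signatures.

The likelihood propagates source spread into the mixture: for proportions
`p` on the K-simplex, tracer j is Normal with mean `Σ_k p_k·m_kj` and
variance `Σ_k p_k²·s_kj² + τ_j²`. This "fixed-source, propagated-variance"
form (the MixSIR error structure) is the natural choice when every animal is
fit individually with a single observation per tracer: with J = 3 data
points there is no information to estimate a residual variance, so the
source SDs and a fixed analytical error must carry all of it. A
hierarchical option (`source_mean_uncertainty=True`) adds the `s²/n` term
for source-mean estimation uncertainty. Assumptions worth stating:

* sources are independent Gaussians per tracer (no tracer covariance within
  a fraction);
* the analytical error τ is known, not estimated — default 0.5 ‰ for both
  nitrogen and carbon tracers, typical CSIA-AA instrument precision; this is
  a package default, not a measured value;
* the prior is Dirichlet(α = 1), the flat "generalist" prior; α = 1/K is
  available for the alternative uninformative convention;
* concentration-dependence (sources contributing different amounts of
  nitrogen per unit mass) is out of scope.

### Sampler

Sampling runs in additive-log-ratio (ALR) coordinates
`y_k = log(p_k/p_K)`, where the target density picks up the Jacobian
`Σ_k log p_k`; combined with the Dirichlet prior this gives the compact
form `Σ_k α_k log p_k` for the prior-plus-Jacobian term. The proposal is a
spherical Gaussian random walk whose scalar step size is tuned by a
Robbins–Monro recursion (target acceptance 0.30, gain t^-0.6) **only during
the adaptation phase**, then frozen, preserving detailed balance for every
retained draw. The default schedule is three chains × (50,000-step
adaptation, 40,000-step burn-in, 100,000 steps thinned by 50), i.e. 2,000
retained draws per chain and 6,000 total. `MixingModelSpec.reduced()`
scales the same structure down (5,000/4,000/20,000/thin 10) for simulation
studies with many fits; the structure (adapt → burn-in → thinned retention)
is identical and the full schedule is used for the sampler-vs-quadrature
comparison.

Each chain draws from its own RNG stream derived from `(seed,
chain_index)`; all randomness is pre-generated from numpy Generators, so a
rerun under a fixed seed is byte-identical. The hot loop is a numba kernel
over those pre-generated streams. Convergence is checked with the
split-chain Gelman–Rubin statistic and effective sample size (via arviz);
R-hat > 1.05 on any component flags the result non-converged (returned,
flagged, never silently dropped).

### Quadrature oracle

`brute_force_posterior` integrates the same unnormalised posterior over a
regular grid on the simplex (default step 0.005, ~20,000 nodes for K = 3)
and returns normalised means/SDs. It shares no code path with the sampler
(vectorised numpy vs the numba kernel, no Jacobian since it works directly
on the simplex measure) and is the reference in tests: the sampler must
agree within 0.02 per component. Halving the grid step moves the oracle by
< 10⁻³, so its own discretisation error is negligible at that tolerance.

### Pooling

Because plume degradation distinguishes the medium and large fractions from
the small one, posteriors are pooled post-modelling into small (0.7–6 µm)
vs large (>6 µm = medium + large). Pooling sums **per draw**, so pooled
SDs and intervals are exact posterior functionals, not sums of summary
statistics.

## Tracer selection

1. **Missingness**: a candidate amino-acid variable is dropped if it is
   missing from ≥ 4 samples within any single size fraction (the strict
   reading; a pooled-count variant is available).
2. **Discrimination**: one-way ANOVA across the three fractions; variables
   with p ≥ α (default 0.05) are dropped. Under-replicated variables are
   treated as dropped, with a warning.
3. **Homogeneity**: within each fraction, pairwise PERMANOVA across site,
   cruise and depth levels on Euclidean distances over the selected
   tracers, Benjamini–Hochberg adjusted across the pairs of each
   fraction × factor cell. A clean report supports pooling samples across
   those factors; it does not veto the selection.

The PERMANOVA pseudo-F is computed from sums of squared distances
(`SS_total = Σ_{i<j} d²/n`, `SS_within = Σ_g Σ_{i<j∈g} d²/n_g`), which is
algebraically the Gower-centred decomposition; the permutation p-value uses
the add-one estimator `(1 + #{F* ≥ F}) / (1 + n_perm)` so p is never zero,
and small instances can be enumerated exhaustively. The distance metric
(Euclidean) and the BH adjustment are package defaults — the selection
outcome on study-like data does not depend on them, but both are
configurable and raw p-values are always reported.

## Concentration prep and contrasts

Normalised amino-acid content is
`(Σ AA nitrogen / CSIA subsample fraction) / (bulk PN / bulk subsample
fraction)` in ngN/µgPN; equal subsample fractions cancel. Outliers are
flagged by Tukey fences (1.5 × IQR beyond the quartiles) within each
sample-type × size-fraction stratum — a standard, parameter-free rule,
applied per stratum because the strata differ by an order of magnitude;
strata under 4 records are skipped. Flagged records are retained with a
flag, excluded from downstream means and ANOVA. The group contrast is a
one-way fixed-effects ANOVA of background vs pooled plume + discharge
records per size fraction (pooling mirrors the plume/discharge framing;
a three-group variant and a log-transform option exist — concentrations are
right-skewed, so the log option is the robustness check).

## Particle field (LISST)

The size grid is 32 log-spaced class centres from 1.36 to 230.14 µm (common
ratio ≈ 1.18); edges are reconstructed at geometric half-steps, giving
bandwidths 0.22–38 µm that tile the axis exactly. Processing: (1) bin to
1-db depth intervals (per-class means, bins labelled by centre); (2)
calibrate each class by subtracting its minimum over the deepest 10 db of
the binned cast — the deep cast segment is taken as particle-quiescent, so
those minima estimate the per-class instrument/background offset; flooring
at zero makes calibration idempotent; (3) aggregate classes into small
(1.25–6 µm) and large (6–250 µm) fraction volumes by bin centre (no
partial-bin splitting). Number concentrations use the spherical model
`N = V / ((π/6) d³)` with d the bin centre (1 µL = 10¹² µm³); this is
validated by internal round-trip consistency only, since whether reported
counts come from instrument firmware or a conversion is generally unknown.
PSD maxima report all tied bin centres of the window-mean distribution.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular field record:

* **Sources** — 7 samples per fraction (the study's particle sample count),
  Gaussian per tracer. The default signature matrix (‰)

  | fraction | δ¹⁵N_Phe | δ¹⁵N_Lys | δ¹³C_Leu |
  |---|---|---|---|
  | small | 2 | 4 | −26 |
  | medium | 5 | 14 | −28 |
  | large | 10 | 13 | −19 |

  with 1.0 ‰ within-fraction SD places the three pools 5–8 SD apart
  pairwise and off-collinear: δ¹⁵N rises from small to large, while the
  medium pool carries strongly elevated δ¹⁵N_Lys (heterotrophic microbial
  resynthesis of trophic-sensitive AAs during particle reworking) with the
  most depleted essential-AA δ¹³C. The off-axis medium pool keeps the
  source triangle well conditioned — a posterior-SD design calculation with
  the quadrature oracle puts the calibrated posterior SD at ≤ ~0.10 per
  component, so mixture recovery is informative. A near-collinear source
  set (medium at the small/large midpoint) would leave a posterior ridge
  with component SDs of ~0.2 no matter how the sampler performs; real
  CSIA-AA source sets can be that degenerate, in which case only the pooled
  small-vs-large contrast is well resolved.
* **Consumers** — tracer vectors drawn from exactly the model's generative
  distribution (mixture mean, propagated variance + measurement variance),
  so parameter recovery and interval calibration test the sampler, not a
  model mismatch. `mis_specified_noise_scale` inflates (or, at 0, removes)
  the generator noise relative to the model for robustness and
  planted-truth designs. The default consumer set plants the study regime:
  46 consumers in 8 groups (4 zooplankton size fractions, 4 micronekton
  taxa), 30 of 46 with pooled large-fraction truth above 0.5 (16 of the 26
  in the 1000–1500 m discharge stratum), 5 of 8 groups large-dominant.
  Planted pooled-large truths sit in 0.80–0.95 or 0.05–0.20 — at least 0.30
  from the census threshold, about four posterior-error SDs — so the census
  result is a property of the pipeline, not of boundary shrinkage. The
  census validation uses noise-free plants (consumers at their exact
  mixture expectations): with realistic tracer noise a single ~2.7σ draw
  can legitimately carry one consumer across the 0.5 line, which is a
  statement about power (covered by the recovery study), not about census
  correctness.
* **Concentrations** — lognormal with moment-matched group mean/SD
  (background 4.7 ± 2.7 / 41.1 ± 25.3 / 46.3 ± 34.7 ngN/µgPN for
  small/medium/large; plume and discharge 3.8 ± 4.4 / 1.7 ± 1.5 /
  4.2 ± 4.7), lognormal because the targets have SD ≈ mean and
  concentrations are non-negative; a zero-truncated normal is the
  alternative. Default counts: 7 background, 3 plume, 3 discharge records
  per fraction.
* **LISST casts** — 700–1500 db at 0.5-db raw sampling; every cast carries
  a per-class constant offset (0.05 µL/L) plus a small noise floor, and its
  deepest 10 m stay at baseline (the calibration segment). Plume casts add
  a lognormal-shaped PSD mode at 3.5 µm (inside the observed 2.6–4.3 µm
  band) in a Gaussian depth layer centred at the 1250 m discharge depth,
  scaled so the small/large fraction sums at the plume core hit 9.80 and
  2.18 µL/L before noise; background casts carry a broad, weak enhancement
  reaching 0.08 / 0.23 µL/L. The within-plume spatial structure is a
  modelling choice — real plumes are gradients, not Gaussian layers — so
  only core amplitudes and the mode location are treated as meaningful.
* **Traits** — guild counts hit the configured proportions exactly by
  largest-remainder rounding (zooplankton: 53% particle feeders, 20%
  gelatinous of 79 taxa; micronekton: 60 / 37.5 / 1.25 / 1.25% of 80 taxa),
  and micronekton density weights are solved so zooplanktivores carry 85%
  of density.
* **Tracer table** — the three real tracers discriminate; 12 decoy
  variables are exchangeable across fractions by construction (the same
  sample values recur in each fraction, so their between-fraction variance
  is exactly zero and the screen rejects them under any seed), and one
  decoy is missing from 4 small-fraction samples to exercise the
  missingness filter. Null behaviour of the screen (retention ≈ α) is
  tested separately with genuinely random decoys.

What the generator does **not** emulate: tracer covariance within sources,
non-Gaussian source distributions, depth- or cruise-structured source
drift, concentration differences between sources, and plume spatial
heterogeneity. Passing tests therefore show the chain is correct under its
own assumptions and calibrated at realistic noise; they do not show the
assumptions hold for any particular field dataset.

## Numerical choices

* Source SDs are floored at 0.1 ‰ (degenerate constant samples would
  otherwise collapse the likelihood).
* ALR step-size log-scale is clamped to [−15, 5] during adaptation.
* Permutation p-values use the add-one estimator; exhaustive enumeration is
  exact (no add-one).
* Depth strata are half-open `[lower, upper)` so a consumer at exactly
  1000 m is counted once.
* The census criterion uses the pooled posterior mean ≥ threshold; the
  posterior-probability variant P(p_large ≥ 0.5) is computed alongside and
  reported side by side in the summary table.
* Largest-remainder rounding breaks ties by order of descending remainder.
* Simulation sizes in the validation suite — 10 full-schedule instances for
  the sampler-vs-quadrature check, 100 consumers (reduced schedule) for
  recovery/calibration, 500 datasets × 999 permutations for PERMANOVA
  calibration, 200 replicates for ANOVA power — were chosen so each check
  resolves its tolerance with comfortable Monte-Carlo margin.

## Known limitations

* The ALR walk with a scalar step is adequate for K ≤ 4 and the posteriors
  arising here; strongly anisotropic posteriors (near-collinear sources)
  would mix slowly and should use the hierarchical/oracle routes for
  verification.
* The quadrature oracle scales as O(step^-(K-1)) and is restricted to
  K ≤ 4.
* ANOVA on untransformed concentrations is mildly anticonservative under
  the lognormal generator at small n; the log-transform option is the
  appropriate sensitivity check.
* Particle number concentrations inherit every bias of the sphere model;
  irregular mineral fragments can be off by factors.
* The trait table's density weights are a two-point construction (one
  weight for zooplanktivores, one for the rest), sufficient for the
  weighted-proportion arithmetic but not a plausible abundance
  distribution.
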