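# midmix

Quantitative analysis chain for midwater food-web ecology under deep-sea
mining discharge: from compound-specific amino-acid isotope values (CSIA-AA)
and in-situ laser-diffraction particle size distributions to the
conclusion-level statistics — **which particle size fraction forms the base
of the midwater food web, and how mining plume particles differ from natural
background particles in amino-acid content and concentration.**

The package is written for trophic ecologists and biological oceanographers
working with stable-isotope mixing models. It implements every stage as a
tested library (`src/midmix`), with numbered analysis drivers under
`analysis/` and a seeded synthetic-data generator that emulates the study
design (three particle size-fraction sources sampled 7× each; 46 consumers
in 8 zooplankton/micronekton groups; background vs plume/discharge
amino-acid concentration records; background and plume LISST casts; a
taxon→feeding-guild trait table), so the whole chain runs without any
external data.

## The model

Particles are partitioned into three size fractions — small (0.7–6 µm),
medium (6–53 µm) and large (>53 µm) — each a candidate source for the
consumers' trophic base. Three amino-acid tracers are used: δ¹⁵N of
phenylalanine and lysine (source AAs, recording the isotopic baseline) and
δ¹³C of leucine (an essential AA tracing the carbon source). These tracers
are non-fractionating during trophic transfer, so no trophic discrimination
offset is applied.

For consumer tracer vector *x* = (x₁…x_J) and source proportions
*p* = (p₁…p_K) on the simplex:

```
x_j ~ Normal( μ_j(p), σ_j(p) )
μ_j(p)  = Σ_k p_k m_kj
σ_j²(p) = Σ_k p_k² s_kj² + τ_j²
p ~ Dirichlet(α),  α = 1  (flat "generalist" prior)
```

with m_kj, s_kj the per-fraction sample mean/SD of tracer j and τ_j a fixed
analytical measurement SD (default 0.5 ‰). Each animal is fit
individually: three MCMC chains (additive-log-ratio random-walk Metropolis),
each with a 50,000-step adaptation, 40,000-step burn-in and 100,000 retained
steps thinned by 50 (2,000 draws per chain, 6,000 total). Medium and large
draws are pooled per draw into the ">6 µm" class. A deterministic
simplex-quadrature evaluation of the same posterior serves as an independent
oracle for the sampler.

Around the mixing model the package implements the full chain: response-
factor quantification and total-AA-per-PN normalization; Tukey outlier
screening and one-way ANOVA contrasts of amino-acid concentration
(background vs plume/discharge, per fraction); iterative tracer selection
(missingness filter at ≥4 missing per fraction, ANOVA discrimination screen,
pairwise PERMANOVA homogeneity checks); LISST processing (32 log-spaced size
classes from 1.36 to 230.14 µm, 1-db depth binning, deep-baseline
calibration, fraction aggregation, sphere-model volume→count conversion, PSD
maxima); and the trophic-base census with guild proportions.

## Worked example

Run the numbered drivers in order (all accept `--seed` and `--outdir`):

```
$ python analysis/02_particle_concentrations.py --seed 1
one-way ANOVA, background vs plume/discharge (normalized ngN/µgPN):
   small: F =     1.21, p = 0.2940  (n = [7, 6]) -> not distinguishable
  medium: F =    23.22, p = 0.0007  (n = [6, 6]) -> different
   large: F =    23.76, p = 0.0005  (n = [7, 6]) -> different
```

Small particles carry similar amino-acid nitrogen in plume and background,
but medium and large plume/discharge particles are strongly depleted
relative to background (generator targets 41.1 ± 25.3 vs 1.7 ± 1.5 and
46.3 ± 34.7 vs 4.2 ± 4.7 ngN/µgPN) — the plume dilutes the nutritious size
classes with nutritionally poor material.

```
$ python analysis/03_select_tracers.py --seed 1
selected tracers: d15N_Phe, d15N_Lys, d13C_Leu
rejected 12 candidates (missingness or no fraction discrimination)

$ python analysis/05_particle_field.py --seed 1
background casts (3): peak fraction volumes small = 0.10, large = 0.27 µL/L
plume casts (5): peak fraction volumes small = 9.81, large = 2.21 µL/L
plume PSD mode: 3.67 µm (range 3.67-3.67)

$ python analysis/06_foodweb_report.py --seed 1
stratum 700-1500 m: 30/46 consumers (65%) with >= 50% of trophic base from particles > 6 µm
stratum 1000-1500 m: 16/26 consumers (62%) with >= 50% of trophic base from particles > 6 µm
5 of 8 consumer groups are large-particle dominant on average
```

The plume carries two orders of magnitude more small-particle volume than
background water, with a particle size mode near 3.7 µm; the mixing model
attributes the majority of most consumers' trophic base to particles >6 µm —
exactly the size classes the plume degrades.

The same pipeline is scriptable through the `midmix` CLI
(`midmix all --seed 1 --outdir out/`) or `midmix.pipeline.run_pipeline`.

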