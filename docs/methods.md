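# Methods

## Model structure

The engine is a proportional multi-state life table (MSLT): a cohort
state-transition model in which every modelled chronic disease runs its
own independent four-state process (healthy, diseased, dead from the
disease, dead from other causes) and contributes mortality and disability
*proportionally* on top of residual all-other-cause rates. One closed
cohort is created per entry age (20–100) and sex in the base year (2015)
and followed in annual cycles until age 100. Children and adolescents are
outside the cost-effectiveness population. Transition intensities depend
on current age only (Markov property); diseases do not interact.

The causal chain per scenario is: tax → price (+15% in the base case) →
category demand via an elasticity matrix (−17.25% SSB) → stratum
energy-intake change → BMI shift → potential impact fractions (PIFs) →
adjusted incidence → disease prevalence/mortality/disability streams →
life-table DALYs, QALYs and costs. The consumption change is a one-time
sustained shift; the BMI response is the full steady-state change applied
from the first cycle (no multi-year weight trajectory).

## Key numerical choices

**Disease step.** Within a cycle the hazards (incidence i, remission r,
case fatality f, other-cause mortality m) are constant, and the state
update is the exact matrix exponential of the intensity matrix. Because m
acts equally on the two alive states it factors out as `exp(-m·t)`,
leaving a 2×2 subsystem solved by eigendecomposition; deaths are
accumulated by exact integrals of the occupancy trajectories. The update
is therefore mass-conserving to machine precision, exact for any hazard
magnitude, and vectorises over (disease × stratum) arrays — the property
the probabilistic analysis relies on for speed. A repeated-eigenvalue
branch covers the defective case (r = 0, i = f) and all-zero hazards.

**PIF integration.** Exposure distributions are lognormal (configurable
to normal), parameterised by arithmetic mean and SD; the intervention is
a location shift of the mean with SD unchanged. Relative risks are
log-linear per 5 kg/m² above a TMREL of 22.5 kg/m² (the GBD convention);
the direct SSB pathway uses the same form per 8-oz serving above zero,
with the post-tax intake distribution scaled multiplicatively by the
demand change. Integrals run over the 0.1st–99.9th percentile of the
comparator distribution and are *renormalised within those bounds*, so
the finite bounds are purely a numerical device: a flat risk function
yields exactly zero for any shift, and identical distributions yield
exactly zero in floating point (this underwrites the exact-null
guarantee). The production path splits the integral at the TMREL kink —
the flat part is evaluated through the CDF, the smooth part on 96
Gauss–Legendre nodes — and agrees with adaptive quadrature and with a
10⁵-point Riemann reference to ~1e-11. The two pathways of type-2
diabetes and ischaemic heart disease combine multiplicatively,
`i* = i·(1−PIF_bmi)·(1−PIF_direct)`; a config switch disables the direct
pathway.

**Life table.** Residual rates are defined from the comparator arm:
`m⁻ = all-cause − Σ_d m_d`, `w⁻ = pYLD − Σ_d p_d·dw_d`, so the
decomposition closes exactly (the comparator reproduces the all-cause
inputs to machine precision); negative residuals abort with the offending
age/sex cell named. Death probability uses `q = 1 − exp(−m)`
(constant-hazard-within-year; `m/(1+m/2)` available for cross-checks),
life years are trapezoidal, and the terminal age-100 interval carries an
exponential open-ended tail `L = l/m`. Disease-specific mortality is
deaths per person-year alive from the disease process; disability uses
mid-cycle prevalence. DALYs averted are the arm difference in
health-adjusted life years `Lw = L(1−w)` with no age weights and no
internal time discounting (discounting is applied once, in the economics
layer, at 1.5%/yr with t = 0 in the first model year). QALYs apply
age/sex utilities for normal weight (BMI ≤ 25), overweight (25 < BMI ≤
30) and obesity (> 30) to each arm's life years, capturing both the
utility and the survival difference.

**Cohort initialisation.** Cohorts enter disease-free; prevalence builds
along each cohort's remaining life. The alternative (initialising at
baseline prevalence) would need a consistent prevalence input the
synthetic bundle deliberately does not fabricate; with residuals defined
from the comparator run, initialisation cancels to first order in the arm
difference.

## Synthetic inputs

The generator fabricates every table the pipeline consumes, deterministic
and bit-identical under a fixed seed (manifest checksum), at the study
conditions the model targets: ~28M adults scaled by 1/1000 so a full run
takes seconds; Gompertz all-cause mortality; SSB intake ~190 (men) / 120
(women) kcal/day declining with age against ~2550/1950 kcal total; BMI
means ~26–29 with SD ~4–4.6 and a secular trend of ~0.025 kg/m²/yr; 29
chronic diseases (27 BMI-mediated plus type-2 diabetes and ischaemic
heart disease, which also carry the direct SSB pathway), each with
exponential-in-age incidence, zero remission (chronic-irreversible),
case fatality as a fixed share of all-cause mortality, disability weights
0.02–0.09 and annual per-case costs CAD$600–7500; a six-category food
demand system with SSB own-price elasticity −1.15 and small positive
cross terms (substitutes claw back ~5–15% of the SSB energy drop), plus a
US-style alternative at −1.04 with one substitution channel missing; and
obesity-related utility weights ordered normal ≥ overweight ≥ obese.
Hazard and consumption tables are generated at age-band resolution and
interpolated to single-year ages by shape-preserving monotone piecewise
cubics (PCHIP) through band midpoints — this replaces the epidemiological
smoothing software used in practice, whose internal consistency-solving
is deliberately not reproduced (hazards are generated jointly consistent
instead). Outside the first/last midpoints the end values are held
constant so interpolated rates can never leave the input band range; the
cost is that a trending curve's first/last band means are reproduced to
~5% rather than the ~2% achieved on interior bands.

Incidence scales were chosen so that the summed disease disability stays
inside the all-disease pYLD envelope at every age — a feasibility
constraint of the proportional decomposition, checked on every run.

What the generator does *not* emulate: survey microdata (no sampling
weights, no measurement error), realistic disease-specific hazard shapes
or correlations, age-varying elasticities, cohort effects in BMI beyond a
linear trend, and any between-disease comorbidity. Passing tests
therefore demonstrate the *machinery* — arithmetic, integration, state
dynamics, accounting identities, directional responses — not calibration
to any real population.

## Uncertainty

The probabilistic analysis re-samples five parameter families once per
iteration, shared across strata (systematic-error correlation): mean BMI
(normal, SD 0.15 kg/m²), relative risks (shared lognormal factor, SD 0.05
on the log), the energy-to-weight constant ρ (normal, SD 1.5, truncated
at 5), SSB intake (normal multiplier, SD 3%) and elasticities (normal
multiplier, SD 5%); normals are truncated at physical bounds. "Monte
Carlo with bootstrapping" is implemented as parametric sampling of these
named inputs. Point estimates are iteration means; 95% uncertainty
intervals are empirical 2.5/97.5 percentiles; the Monte-Carlo standard
error of the mean shrinks as 1/√n (percentile intervals do not — they
estimate parameter uncertainty, not simulation error). Both ICER
estimators are reported: the ratio of mean costs to mean QALYs (headline)
and the mean of per-iteration ratios. Failed iterations are excluded and
counted; more than 1% aborts.

Default problem sizes: 81 ages × 2 sexes × 29 diseases per run (~0.6 s);
the bundled analyses use 100–500 PSA iterations and the model default is
2000.

## Known limitations

- Stratum BMI means evolve by calendar-year trend only; an ageing cohort
  does not move along the cross-sectional age profile.
- The steady-state weight response overstates early-year BMI change
  relative to a dynamic weight model.
- Disease independence ignores comorbid disability interactions.
- Tax revenue uses post-tax consumption under the static demand response;
  no long-run demand drift, reformulation, or cross-border substitution.
- The elasticity application is linear in percentages, appropriate for
  the 10–20% price changes modelled; it is not a demand system estimate.
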