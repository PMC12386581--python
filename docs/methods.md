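# Methods

## The relaxation model

`bppfit` analyses the temperature dependence of the proton spin–lattice
relaxation time T₁ in polycrystalline organic solids, where relaxation is
driven by dipolar couplings modulated by a small number of thermally
activated internal motions (methyl/hydroxyl rotations, ring librations,
and similar).  Each motion k is described by three parameters:

- τ₀ₖ — pre-exponential correlation time, seconds;
- E_aₖ — activation energy, kJ/mol;
- ΔM₂ₖ — the part of the ¹H second moment (Gauss²) averaged out by the
  motion, which weights its relaxation contribution.

The correlation time follows the Arrhenius law τₖ(T) = τ₀ₖ·exp(E_aₖ/RT),
and the total rate is the Bloembergen–Purcell–Pound (BPP) sum

    1/T₁(T) = (2/3) γ² Σₖ ΔM₂ₖ [ τₖ/(1+ω₀²τₖ²) + 4τₖ/(1+4ω₀²τₖ²) ],

with γ the proton gyromagnetic ratio (2.6752218744×10⁴ rad s⁻¹ G⁻¹) and ω₀
the angular Larmor frequency (2π·25 MHz by default).  In these units a
tabulated parameter set (τ₀ in s, E_a in kJ/mol, ΔM₂ in G²) can be used
verbatim and the rate comes out in s⁻¹.  Contributions are additive; a
motion contributes maximally at the temperature where ω₀τₖ = 0.61579…
(the root of the derivative of the two-term spectral density), producing
the familiar T₁ minimum.

Assumptions: laboratory-frame T₁ only; isotropic BPP spectral densities;
one Arrhenius branch per motion; no cross-relaxation, Lipari–Szabo order
parameters, or distribution of correlation times.

## T₁ extraction from saturation recovery

Saturation-recovery curves follow M(t) = M₀(1 − exp(−t/T₁)).  The fit is
unweighted nonlinear least squares (Levenberg–Marquardt) started from a
plateau/63.2%-crossing heuristic, with a retry ladder (log-linear
regression start, then five seeded random perturbations).  Degenerate
inputs fail loudly: constant signals, fits with non-positive T₁, and fits
whose T₁ exceeds 50× the sampled time window (the degenerate linear regime
where only M₀/T₁ is identified).  The 1σ uncertainty of T₁ comes from the
Gauss–Newton covariance.  A Monte-Carlo calibration (1000 seeded fits, 21
uniform points over 0–10 s, T₁ = 2 s, additive noise 2% of M₀) gives a
95th-percentile relative T₁ error of ≈5.9% and 3σ coverage of 99.1%, so
the covariance-based SE is trustworthy at this noise level.

## Fitting the multi-motion model

Given a T₁(T) series and a motion count K, the package minimizes the sum
of squared **log** residuals Σᵢ[ln T₁ᵐᵒᵈ(Tᵢ) − ln T₁ᵒᵇˢ(Tᵢ)]².  Log
residuals are the natural choice because T₁ spans orders of magnitude over
80–300 K and the measurement error is multiplicative; for lognormal noise
this is the maximum-likelihood objective.  Positivity is enforced by
optimizing (log₁₀τ₀, E_a, log₁₀ΔM₂) per motion inside the box
log₁₀τ₀ ∈ [−16, −8], E_a ∈ (0, 60] kJ/mol, log₁₀ΔM₂ ∈ [−4, 1], which
brackets reported solid-state values with margin.

The objective is multimodal, so the fit runs 64 seeded Latin-hypercube
starts (drawn as a prefix of a fixed 64-point design so best-of-n SSE is
monotone in n for a given seed) through a bounded trust-region
least-squares solver (relative tolerances 10⁻¹⁰, ≤10⁴ evaluations) with an
analytic Jacobian, keeping the best converged start.  Results are
bit-reproducible for fixed (series, K, seed, n_starts, bounds).  Spot
checks on noisy series confirm that a solve started at the generating
parameters never improves on the best of 64 starts, i.e. the multistart
reaches the global optimum.

Estimated motions are displayed sorted by descending ΔM₂; identity is
never positional.  For scoring against a reference, motions are paired
greedily by nearest neighbour in (E_a, log₁₀τ₀) normalized by the joint
spread of each coordinate.

Model order K is user-specified by default.  An opt-in scan fits
K = 1..K_max and scores each with small-sample AICc on Gaussian
log-residuals (p = 3K + 1 including the variance); SSE is floored at an
RMS log-residual of 10⁻⁸ so numerically perfect fits tie and the penalty
decides, breaking ties toward smaller K.  K values whose 3K + 2 minimum
length or AICc correction the series cannot support are skipped.

Parameter uncertainty uses a parametric residual bootstrap: log-residuals
of the fit are resampled with replacement onto the fitted curve and each
replicate is refitted by a single local solve from the point estimate.
Reported is the 95% interval half-width as a percent of the estimate; τ₀
is assessed on the log₁₀ scale (half-width of log₁₀τ₀ relative to
|log₁₀τ₀|), since τ₀ is only meaningful to order of magnitude.  More than
20% failed refits marks the fit unstable.

## Synthetic data

The generator emulates the targeted acquisition: a 25 MHz spectrometer,
30 temperatures spaced uniformly in 1/T over 80–300 K (uniform spacing on
an Arrhenius plot; a uniform-in-T grid is available), and multiplicative
lognormal noise on T₁ with coefficient of variation 0.10, matching a ±10%
measurement uncertainty while preserving positivity (an additive-Gaussian
variant sits behind a flag).  Noise is i.i.d. across temperatures.
Recovery curves are generated on a 16-point logarithmic delay grid from
0.05·T₁ to 5·T₁ with additive Gaussian noise; grid density and span are
package choices, as is the 30-point temperature count (chosen so every
bundled parameter set's minima are resolved).

What the generator does **not** emulate: temperature-calibration error,
correlated drifts, FID-level artifacts, or non-exponential recovery.
Passing recovery tests therefore demonstrate statistical identifiability
under the assumed noise model, not robustness to instrumental systematics.

## Identifiability: what parameter recovery can and cannot show

The end-to-end experiment (`run_recovery_experiment`, CLI `recover`)
simulates seeded replicate series from a reference parameter set, fits
with the generating K, matches motions, and aggregates median matched
estimates.  Motions with ΔM₂ < 0.02 G² are flagged weakly weighted and
excluded from the verdict.  Three structural effects dominate the results:

1. **Extreme-narrowing degeneracy.**  A motion with ω₀τ ≪ 1 over the whole
   window (e.g. a low-barrier motion with E_a ≈ 2 kJ/mol) contributes a
   nearly temperature-flat rate proportional to ΔM₂·τ₀·exp(E_a/RT): only
   the product ΔM₂τ₀ is identifiable, never τ₀ alone — even from noiseless
   data — and if its contribution is far below the noise floor its E_a is
   lost too.  A large ΔM₂ does not rescue such a motion, so the
   ΔM₂ ≥ 0.02 G² proxy overstates identifiability in this regime.
2. **Edge-of-window minima.**  A motion whose T₁ minimum lies within
   ≈25 K of the window ceiling (e.g. at 275 K against a 300 K maximum)
   has only one flank of its dispersion sampled; its parameter estimates
   are strongly seed-dependent, with median activation-energy errors over
   some 20-replicate windows of ≈25%.
3. **Overlapping minima.**  When two well-weighted motions have minima
   ≈30 K apart, the likelihood surface at 10% noise develops a long
   correlated valley in which amplitude (ΔM₂) can rotate between the
   motions with compensating (E_a, τ₀) shifts.  The estimator remains
   essentially unbiased (20-replicate median E_a error ≈1%), but single
   replicates scatter by ±25–40% in E_a and ±0.8 in log₁₀τ₀ — which the
   bootstrap confirms: 95% half-widths of E_a around 40–60% on such
   series.  Medians over small numbers of replicates inherit much of this
   scatter.

Consequently, quantitative recovery is reliable for well-weighted motions
with interior, well-separated minima, and degrades in the three regimes
above.  These are properties of the experimental design (frequency range,
temperature window, noise level), not of the optimizer; single-frequency
T₁(T) data over a finite window simply carry limited information, which is
why multi-frequency (field-cycling) data are the standard remedy.

## Stability arithmetic

Small exact computations on tabulated data: encapsulation efficiency
100·entrapped/total (uncapped — calibration can push it above 100%);
per-sample EPR amplitude decay 100·(A₀−A₃ₘ)/A₀ with the mean taken over
irradiated samples only by default (dose-0 rows carry native signals, not
radiation-induced radicals; a toggle includes them); drug content as a
percent of a reference with first-order delta-method SD propagation for
the ratio (validated against a 10⁶-draw Monte-Carlo to within 5% for CVs
≤ 10%); and degradation-peak area as a percent of total peak area.

## Numerical choices

- exp(E_a/RT) is evaluated in log space; τ is capped at 10³ s, far beyond
  any measurable regime, to avoid overflow deep in the slow-motion limit.
- K = 0 models raise instead of returning infinite T₁.
- The T₁-minimum locator inverts the Arrhenius law at ω₀τ = 0.6157951…;
  minima outside (1 K, 10⁴ K), or unreachable because τ₀ already exceeds
  the optimal correlation time, are flagged rather than raised.
- Physical constants: γ = 2.6752218744×10⁴ rad s⁻¹ G⁻¹,
  R = 8.314462618 J mol⁻¹ K⁻¹; overridable in `SpectrometerConfig` for
  testing.

## Known limitations

- Single Larmor frequency; no joint multi-field fitting.
- No stretched-exponential or multi-component recovery models.
- The residual bootstrap understates uncertainty when the fitted curve
  absorbs part of the noise (it resamples fitted residuals, whose RMS is
  below the true noise level for flexible models).
- Greedy motion matching can mispair when a structurally unidentifiable
  motion wanders near an identifiable one in (E_a, log₁₀τ₀) space.
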