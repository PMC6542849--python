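# Methods

## The measurement model

A sub-nanometer pore through a thin membrane is treated as an electrolytic
point contact.  Its conductance in electrolyte of conductivity σ is g = σ·d
(d the geometric-mean waist diameter, in nm); a thick-membrane refinement
(`reduced_conductance`) puts the bulk path in series with the disk access
resistance 1/(4σr) at each aperture and in parallel with the counter-ion
surface term 4μ⁺|ρ_s| (equivalently σ_min·d with σ_min = 4μ⁺|ρ_s|/d).  The
thin-membrane, neutral-wall limit of the reduced model reduces exactly to
the point-contact law.

Current noise is decomposed as S_I(f) = S₁/f·(1/f) + S₀ + S₁·f.  The
carrier-correlation model treats the pore current as a sum of N
single-carrier currents with pairwise spectral correlation ξ:
Var(Σiₙ) = ⟨Δi²⟩[N + N(N−1)ξ].  Uncorrelated motion gives normalized noise
S/I² ∝ 1/I₀²; fully correlated motion gives S/I² independent of current.
The crossover current I_T, extrapolated first to zero activity (I_T0, per
pore) and then to zero threshold versus diameter (per ion), estimates the
de-hydrated ion diameter.

## Electrolyte model

Activity coefficients follow log₁₀γ = −A z²√I/(1 + B·a₀√I) + b·I with
A = 0.5085 M^−1/2 at 25 °C and the b·I term only in the Truesdell-Jones
variant.  B is used as 0.3281 Å⁻¹ M^−1/2 with a₀ converted nm→Å (the
conventional pairing that makes B·a₀ ≈ 1 M^−1/2 and reproduces accepted
NaCl coefficients, e.g. γ_TJ(0.5 M NaCl) = 0.682).  The salt-level γ uses
the cation's parameters; ionic strength is C for 1:1 salts and 3C for
MgCl₂.  Note that with the tabulated b values the TJ form exceeds 1 above
≈1.1 M for LiCl and ≈1.8 M for MgCl₂ — consistent with measured activity
data at high molality, so no cap is imposed; the working range of the
pipeline is ≤ 0.5 M.  Bulk conductivity is the ideal-dilution Kohlrausch
sum σ = F Σ|z_i|c_iμ_i (linear in C; it ignores the finite-concentration
conductivity decrement, an acceptable ~10% overestimate at 0.5 M that
cancels in every zero-intercept extrapolation).  Mobilities are from
limiting molar conductivities at 25 °C; diffusivities via the Einstein
relation.

## Steric Poisson-Boltzmann solver

The waist cross-section is solved as a 1-D radial, symmetric-electrolyte
problem: ∇²Ψ = sinh Ψ / [λ²(1 + α(cosh Ψ − 1))], Ψ = eψ/k_BT, α = 2a³n₀
(a the solvated radius, n₀ the bulk density taken at the ionic strength).
α = 0 is classical PB; α > 0 caps the counter-ion concentration at 2n₀/α
(the finite-size saturation bound, asserted in tests).  Discretization:
second-order finite differences on 2000 uniform points, the axis handled by
the polar-Laplacian limit 4(Ψ₁−Ψ₀)/h², the wall by a ghost-node flux
condition Ψ'(R) = eσ_s/(εε₀k_BT) from Gauss's law.  The damped Newton
iteration uses a tridiagonal banded solve, a 2 k_BT/e trust region on each
update, a 2-norm line search, and — if the direct solve stalls — adaptive
continuation in the wall charge (increment halves on failure).  Convergence
is declared at a sup-norm residual of 1e−8 or at the discretization
roundoff floor ~32·eps·|Ψ|/h², whichever is larger (on sub-nanometer radii
the floor exceeds 1e−8; true accuracy, established against a shooting-method
integration, is ~1e−8 in Ψ).  Physically infeasible inputs — wall charge
exceeding what maximal steric packing in the cross-section can neutralize —
correctly fail with the residual attached.

## PSD estimation and decomposition

Spectra are averaged modified periodograms (Hann window, 50% overlap), with
the segment length the smallest power of two reaching 0.1 Hz resolution;
the DC bin is dropped.  The white level S₀ is initialized as the geometric
mean ("mean logarithmic PSD") over 1–5 kHz.  The pink amplitude is the 1 Hz
intercept of a forced-slope (−1) fit with weights w(f) = f^−1/2 — one order
of magnitude of weight per two decades, so no hard high-frequency cutoff is
needed.  Numerically, the two-component split is iterated by fitting the
amplitude (and refining S₀) through the summed model log₁₀(S₁/f/f + S₀) on
a log-binned spectrum (64 bins/decade) until the intersection
f* = S₁/f / S₀ reaches a fixed point: fitting the smooth superposition
rather than two hard-cut lines removes the few-percent bias that points
near the crossover otherwise inject into the intercept.  Pink presence is
decided by a small-sample-corrected AIC comparison of the pink+white model
against a white-only model, so purely white traces report S₁/f = 0 instead
of a spurious intercept.  The dielectric term S₁ is recorded only when the
5–50 kHz band rises with frequency.  The free exponent β is an unweighted
log-log slope over 0.1–100 Hz; fits with β outside [0.5, 1.6] are flagged.

Known estimator property: periodogram averaging over m segments biases
log-PSD levels by ψ(m) − ln m (≈ −7% for m = 7).  The bias is common to
S₁/f and S₀ and multiplicative across traces, so it cancels exactly in the
threshold intersection and in every zero-crossing extrapolation; it is left
uncorrected to keep the printed estimator definitions.

## Threshold detection

In coordinates (u, v) = (log₁₀I₀², log₁₀S₁/f/I₀²) the model is a forced
slope −1 branch below threshold (S₁/f constant, intercept σ_< at 1 pA) and
a constant branch σ_> above (S₁/f ∝ I₀²).  The fit scans all contiguous
splits (≥ 2 points per branch), iterates the branch intersection to a fixed
point, and then — for noisy data — refines (σ_<, σ_>) against the smooth
superposition σ_</I₀² + σ_>, whose asymptotes are the two lines.  The hard
two-line fit ignores the 1/I₀² tail that the uncorrelated branch
contributes above threshold and underestimates I_T by up to ~10% when few
points lie far above it; exactly piecewise (noiseless) data bypasses the
refinement and is recovered exactly.  I_T = √(σ_</σ_>).  A threshold is
reported present only if the two-branch model beats both single-branch
alternatives under AICc and the intersection lies inside the measured
current range.  The standard error of I_T propagates the residual variance
of both branch levels through the intersection.

Both extrapolations are weighted least squares (statsmodels WLS):
I_T on activity (n ≥ 3 activities enforced; intercept I_T0) and I_T0 on
diameter (x-intercept d_ion, delta-method standard error), with
inverse-variance weights from the previous stage and a uniform fallback.
Activities use the Truesdell-Jones model by default.  Pores lacking three
activities with detected thresholds are dropped with a logged warning;
negative-slope extrapolations are flagged rather than silently reported.

## Synthetic data generator

The generator is the package's ground truth and encodes the study
conditions: four cations (Li⁺, Mg²⁺, Na⁺, K⁺) with planted correlation
diameters 0.13 / 0.16 / 0.22 / 0.25 nm; five waist diameters 0.35–0.97 nm
(cone half-angle 15°, 10 nm membrane); concentrations 0.125–0.5 M; eight
biases log-spaced 0.01–0.6 V; 2²⁰-sample traces at 25 kHz (41.9 s).  The
sampling rate is chosen so a single recording supports 0.1 Hz PSD
resolution with several averaged segments while spanning all fitted bands
(0.1 Hz–12.5 kHz); traces are synthesized in float32, ample for
percent-level spectral work.

Planted structure: I₀ from the point-contact law with the ideal-dilution σ;
carrier count N from the bi-conical volume occupancy; the threshold law
I_T = s·(d − d_ion)·(1 + k·a) with s = 300 pA/nm and k = 1 M⁻¹ — the
minimal form that increases with activity and diameter and vanishes at the
ion size, which is a modeling choice, not an empirical law.  The
correlation switch is a logistic in log₁₀I₀ of width 0.1 decade (a hard
switch would make change-point detection trivially easy).  Below threshold
the pink amplitude is the uncorrelated carrier sum (0.05 pA²/Hz per
carrier, placing the pink/white crossover at tens of Hz over a
5×10⁻³ pA²/Hz white floor — the regime where pink noise dominates the
0.1–100 Hz band); above threshold it rises as ξ·(I₀/I_T)² toward the fully
correlated N² limit.  Pure power-law noise is synthesized spectrally
(amplitude ∝ f^(−β/2), random phases, zero DC); correlated-carrier
ensembles use the mixture construction iₙ = i + √ξ·s(t) + √(1−ξ)·eₙ(t),
which achieves pairwise correlation exactly ξ in expectation.  Every output
is a pure function of (plan, seed); manifests embed the seed and the
planted truth columns.

What the generator does *not* emulate: amplifier roll-off and capacitive
transients (the 15 s settling expunge is therefore skipped for synthetic
traces), dielectric (S₁·f) noise, drift and 50/60 Hz pickup, ion-specific
deviations such as the divalent anomaly in σ_> versus activity, and any
mechanistic coupling between carriers — correlation is planted
statistically.  Passing end-to-end tests therefore demonstrates that the
pipeline recovers the planted empirical structure at realistic noise
levels, not that real recordings obey that structure.

## Brownian-dynamics transport stand-in

A 1-D overdamped Langevin walker on a PMF W(z) (k_BT units) tilted by qE:
z ← z + D(−W′ + qE/k_BT)dt + √(2Ddt)η, numba-compiled, with linear force
interpolation on the PMF grid.  Step-size guards require drift and
diffusive steps below 10% of the grid spacing, with the error naming a
stable dt.  Transport mode absorbs at the exits and re-injects at the entry
point (single-ion channel, one-at-a-time permeation); events carry signed
directions so a flat, field-free channel nets zero current, and a
reflecting-entry variant supports barrier-escape runs compared against the
mean-first-passage-time quadrature T = D⁻¹∫e^U∫e^−U (within a factor 1.5
across 2–6 k_BT barriers).  Equilibrium mode (reflecting ends) supports
PMF recovery by Boltzmann inversion (anchored at the free-energy minimum,
binned over the sampled range; unvisited interior bins raise an error
listing them) and diffusivity from the MSD slope.  The MSD estimator uses
MSD = 2Dt — the one-dimensional form, replacing the 6t denominator of the
three-dimensional definition — over a lag window in the linear regime.
Average current is (signed translocation count)·e/time; the instantaneous
current assigns each event e/(translocation time) over its interval, so its
time integral equals the transported charge exactly.

## Problem sizes and numerical defaults

End-to-end verification runs 4 ions × 5 diameters × 4 concentrations × 8
biases = 640 traces per seed at 2²⁰ samples each, about two minutes per ion
on one CPU; the acceptance script runs one seed, the test suite five.
Iteration budgets: 50 for both fixed-point split iterations (relative
tolerance 1e−3), 200 Newton iterations per PB solve.  Line-fit guards:
≥ 3 points for every extrapolation, ≥ 6 points spanning ≥ 1.5 decades of
current for a threshold fit.  Reported diameters carry delta-method
standard errors; with only 2–3 residual degrees of freedom in the final
fits, 95% intervals require the t-quantile (≈ 4.3 SE at n = 4), not 2 SE.

## Known limitations

- The conductance model is ideal-dilution and the activity model cation-only;
  neither matters for zero-intercept extrapolations but both limit absolute
  conductance accuracy at ≥ 0.5 M.
- The PB solver treats the waist as a circular cylinder (elliptical waists
  enter only through the geometric-mean diameter) and a symmetric 1:1
  reduction of the electrolyte; axial variation enters only through the
  resistance integral of the reduced conductance model.
- Correlated-noise sizing inherits the generator's threshold law; with
  undeposited laboratory data, planted-parameter recovery is the strongest
  claim the tests can make.
- The BD stand-in is single-ion: multi-ion congestion above threshold is
  represented statistically (ξ), not mechanistically.
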