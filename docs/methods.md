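# Methods

## Data and model

A stratified two-arm study on paired organs yields, per stratum
*j* ∈ {1, …, J} and group *i* (1 = treatment, 2 = control), two kinds of
subjects: *bilateral* subjects contribute both organs, and the count of
subjects with *t* ∈ {0, 1, 2} responding organs is `m[t, i, j]`;
*unilateral* subjects contribute one organ, counted as `n[t, i, j]` with
*t* ∈ {0, 1}. Either kind may be absent, so purely bilateral and purely
unilateral designs are special cases of the same table.

Each organ responds with probability π_ij. The two organs of one bilateral
subject are exchangeable with intraclass correlation ρ_j, shared by both
groups of a stratum but free to differ across strata. The number of
responding organs of a bilateral subject is then trinomial with

    p0 = (1 − π)(ρπ − π + 1),   p1 = 2π(1 − π)(1 − ρ),   p2 = π(ρ + π − ρπ),

and unilateral subjects are Bernoulli(π). With ρ ∈ [0, 1] all three
probabilities are non-negative for every π ∈ [0, 1]; ρ < 0 is not in the
model's domain. The treatment effect in stratum *j* is the odds ratio
θ_j = π_1j(1 − π_2j) / (π_2j(1 − π_1j)), and the hypothesis under test is
H0: θ_1 = … = θ_J.

All log-likelihoods drop the multinomial/binomial constants; only
differences of log-likelihoods are ever used, so this is exact.

## Estimation

**Unconstrained fit.** Strata are independent, and within a stratum the
profile score in π_i at fixed ρ is, after clearing denominators, a cubic in
π_i whose coefficients are polynomial in the counts and ρ. The fitter
alternates (a) the closed-form cubic root for π_1 and π_2 (trigonometric
three-real-roots solution; the interior root is selected by likelihood
value) with (b) a scalar Fisher-scoring step for ρ using the expected
information

    I(ρ) = Σ_i m_{+i} π_i(1 − π_i) [ π_i / (ρπ_i − π_i + 1) + 2/(1 − ρ)
           + (1 − π_i) / (π_i + ρ(1 − π_i)) ].

The cubic coefficients and every derivative were re-derived symbolically
from the log-likelihood and are pinned by tests against finite differences
and brute-force 1-D maximisation; the analytic score, curvature and
information expressions in `likelihood.py` are the single source of truth.

**Constrained fit.** Under H0 the control probability is eliminated via
π_2 = π_1 / (π_1(1 − θ) + θ) and Σ_j l_{j|θ}(π_1j, ρ_j, θ) is maximised by a
two-step scheme: an inner Newton–Raphson update of θ — performed on log θ,
which enforces positivity and symmetrises the curvature of the profile —
holding (π_1j, ρ_j) fixed, then per-stratum 2×2 Fisher-scoring updates of
(π_1j, ρ_j) holding θ fixed. The constrained log-likelihood is implemented
by substituting π_2(π_1, θ) into the unconstrained one, so the substitution
identity holds exactly by construction. The fitted π̃_2j are computed from
(π̃_1j, θ̃), never re-estimated, so the homogeneity constraint is exact in
the output.

**Initialisation and convergence.** ρ starts at 0.5 (a deterministic choice;
seeded random restarts are available through `FitOptions(restarts=, seed=)`
— the objective in ρ is well behaved and restarts have never changed the
optimum in testing). The constrained fit starts from the unconstrained one:
stratum means of π̂_1j and ρ̂_j, and the geometric mean of the θ̂_j clipped
to [0.01, 100] — the geometric mean (rather than an arithmetic one) keeps a
boundary-inflated θ̂_j, which can be many orders of magnitude, from poisoning
the start. Convergence requires max parameter change < 1e−8 *and*
log-likelihood change < 1e−10, with at most 500 outer iterations.

**Domain handling.** Probabilities are evaluated in [1e−10, 1 − 1e−10] and
ρ in [0, 1 − 1e−10]. Any scoring/Newton step is step-halved (up to 50
times) until it stays in the domain and does not decrease the objective, so
ascent is monotone. A coordinate-wise polish step follows the joint 2×2
update in the constrained fit: when ρ is pinned at a boundary the joint
step can shrink to nothing, and the 1-D π_1 update keeps the fit moving to
stationarity. Estimates that end on a clamp bound are reported in
`boundary_flags`. If scoring stalls, the fit falls back to bounded L-BFGS-B
on the full parameter block.

**Boundary solutions.** A group with no responses at all (the female control
group of the bundled myopia data) has its likelihood maximised at π = 0;
the fit reports the clamped value 1e−10 with a flag. The published analysis
of that dataset instead stopped its iteration at π̂ = 0.0032, which is why
several of its printed numbers (θ̂ = 236.4251, T_W = 4.3991, and — through
the likelihood value — T_LR) are stopping-rule artifacts rather than
properties of the model; this package reports the exact boundary-stable
values and emits an instability warning for Wald quantities.

## Test statistics

All three statistics are referred to the upper tail of χ² with J − 1
degrees of freedom.

* **Likelihood ratio:** T_LR = 2 Σ_j [l_j(π̂_1j, π̂_2j, ρ̂_j) −
  l_j(π̃_1j, π̃_2j, ρ̃_j)], clamped at 0.
* **Score:** at the constrained MLE the nuisance components of the score in
  α_j = (θ_j, π_1j, ρ_j) vanish (asserted in tests), so
  T_SC = Σ_j (∂l_j/∂θ_j)² [I_j⁻¹]_θθ with ∂l_j/∂θ_j obtained by the chain
  rule through π_2(π_1, θ) and I_j the expected information in the α_j
  parameterisation, I_j = Kᵀ I_{(π_1, π_2, ρ)} K with K the Jacobian of the
  reparameterisation.
* **Wald:** with δ̂ = (logit π̂_1j, logit π̂_2j, log ρ̂_j)_j and the
  (J−1)×3J contrast C whose rows encode log θ̂_j − log θ̂_{j+1},
  T_W = (Cδ̂)ᵀ (C Δ_g I_β̂⁻¹ Δ_gᵀ Cᵀ)⁻¹ (Cδ̂), Δ_g the block-diagonal
  delta-method Jacobian. T_W is invariant to the choice of full-rank
  contrast (tested). The statistic is reported, with a warning, even when
  the fit is boundary-flagged, because refusing it would hide the
  diagnostic; it is meaningless in that case.

Expected — not observed — information is used everywhere. The 3×3 stratum
information in (π_1, π_2, ρ) is assembled analytically as
`n_+/(π(1−π))` (binomial part) plus `m_+ Σ_t (∂p_t/∂a)(∂p_t/∂b)/p_t`
(multinomial part); the π_1–π_2 cross entry is zero because the groups are
independent given ρ. Tests validate every block against numerically
averaged negative Hessians over the exact category probabilities.

## Monte-Carlo studies

`simulation` draws unilateral counts as binomials and bilateral counts as
trinomials with the model's category probabilities, with π_2j implied by
the stratum odds ratio. Defaults mirror the published study conditions:
equal group sizes m = n ∈ {30, 50, 100}, π_1 ∈ {0.2, 0.3, 0.4},
ρ ∈ {0.4, 0.5, 0.6}, common θ ∈ {1, 1.2, 1.5, 2} for size, the
`THETA_PATTERNS` tables for power, nominal level 0.05, and 50,000
replicates for fixed grids / 10,000 per random setting (both reducible via
`SimSpec.reps` for desk-scale runs; the acceptance script uses 10,000).
Every replicate gets a child seed spawned from the master seed, so runs
are bit-reproducible and independent of scheduling. Replicates whose fits
fail even after the numerical fallback are excluded from the denominator
and counted, with an alarm above 0.1 % exclusions; in practice exclusions
are zero at the study conditions.

What the generator emulates is exactly the model: exchangeable organs,
correlation shared across groups within a stratum, independence across
subjects. It does not emulate features of real data such as missingness
that is informative (here, whether a subject is bilateral or unilateral is
fixed by design, not by outcome), covariate-driven heterogeneity within a
stratum, or negative within-pair correlation. Passing size/power checks
therefore validate the inferential machinery under the model, not
robustness to model misspecification.

## Numerical choices, in brief

* clamp bounds 1e−10; boundary flags when a clamp binds at exit;
* arccos argument in the cubic solution clamped within 1e−9 of [−1, 1]
  (pure rounding), error beyond;
* purely unilateral groups bypass the cubic (binomial MLE), ρ = 0 case uses
  the pooled-binomial closed form, a stratum with no bilateral subjects has
  ρ pinned at 0 and flagged as unidentified;
* statistics are clamped to 0 when within 1e−9 below 0; a larger negative
  value raises, since it indicates inconsistent fits;
* singular score information falls back to a pseudo-inverse with a warning;
  a singular Wald middle matrix raises, naming the deficient stratum.

## Known limitations

* No standard errors or confidence intervals for the estimates, and no
  exact (non-asymptotic) tests: the statistics rely on χ²_{J−1} asymptotics
  and are conservative in small samples (visible in the reduced-scale
  simulation tests).
* Wald quantities are unreliable whenever any group's estimate sits on the
  parameter boundary; the package warns rather than refuses.
* Aggregated counts only; subject-level (per-organ) records must be
  tabulated before use.
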