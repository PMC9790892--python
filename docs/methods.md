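# Methods

## Model and uncertainty elimination

The plant is a perfectly mixed aerobic CSTR with aggregated biomass X,
substrate S and dissolved-oxygen O concentrations (g/L), microbial growth
r = μ(t)·X, first-order mortality βm·X and maintenance losses ms·X, mo·X,
dilution D(t) and gas–liquid oxygen transfer kLa(t)·(Os − O).  The growth
rate μ follows a Monod law whose coefficients μmax(t), Ks(t), Ko(t) are
time-varying and only known to lie in positive bounds — the dominant source
of model uncertainty in balance models of this kind.

For analysis the uncertain kinetics is replaced by an exactly known,
time-invariant substitute μ̂ (Monod in S, in O, or the SO product), with
constants fixed at the midpoints of the coefficient bounds.  The mismatch is
eliminated into a single bounded unknown input Δ = [μ − μ̂]·ν₁ acting through
the constant field ρ = [1, −1/Ys, −1/Yo]ᵀ.  The decomposition is exact: the
affine pieces plus ρ·Δ reproduce the original right-hand side identically
(property-tested to 1e−10 at random points).  All rates are in 1/h,
concentrations in g/L.  The state lives in an invariant box Ω of strictly
positive bounds; trajectories starting inside Ω with positive bounded inputs
stay non-negative (checked numerically).

The "true" kinetics is realised as the SO product form: the time-invariant
single-variable substitutes are compared against it, which is the harder,
more realistic mismatch.  S-only and O-only true forms are available on the
`TrueKinetics` type but are not part of the nine-case grid.

## Geometric stage

For a scalar output h = ν_j the observability map stacks h, L_φ̂h, L²_φ̂h;
its Jacobian is the observability matrix.  Full rank 3 away from a
measure-zero singular set is a *sufficient* condition for local weak
observability; the report wording never claims necessity.  Implementation
choices:

* **Zero columns** are detected symbolically (`sympy.simplify` per entry);
  a coordinate absent from both the output and the substitute kinetics
  yields an identically zero column and caps the rank at 2.
* **Numeric rank** is sampled at 200 uniform points of Ω; singular values
  below 1e−8 × the largest count as zero (standard numeric-rank practice).
* **Singular-point policy:** sampled points with ν₁ < 1e−6 g/L are excluded
  and counted separately — at wash-out the kinetic coupling vanishes and the
  rank argument is void.
* **Symbolic rank** is reported as an integer when structurally conclusive
  (zero column, vanishing determinant, or nonvanishing determinant with
  unanimous sampling); otherwise the sampled evidence governs and the report
  records "point-dependent".

The matching condition L_ρh is the output-indexed component of ρ
(1, −1/Ys or −1/Yo), nonzero for every output choice, so the unknown input
has relative degree one to any measured output.

## Error system and reduction

The copy z shares structure, parameters and inputs with the original; the
error ε = ν − z obeys a 3-dimensional system driven by ν(t) (the combined
dynamics is 6-dimensional).  Imposing ε_j ≡ 0 for the measured state j:

* with uncertainty, the j-th equation is solved for δΔ = Δ − Δ′ (always
  possible since ρ has no zero component) and substituted into the rest.
  The combination "kinetic bracket + δΔ" is fixed by the measured equation,
  so the reduced differential part is *linear* in the remaining errors with
  strictly negative diagonal coefficients (they contain −u₁ or −(u₁+u₂),
  and the known inputs are strictly positive);
* without uncertainty, the j-th equation becomes an algebraic constraint.
  When it factors as ε_k times a sign-definite expression the error ε_k is
  forced to zero identically (sign decided under positivity of states,
  parameters and the copy coordinate z_k = ν_k − ε_k > 0).  For Monod
  differences the factoring is the single-fraction identity
  μ̂_S(ν₂) − μ̂_S(ν₂−ε₂) = μmax⁰·Ks⁰·ε₂ / [(Ks⁰+ν₂)(Ks⁰+ν₂−ε₂)],
  whose cross-multiplied form Ks⁰·ε₂ = 0 forces ε₂ = 0.

When the measured coordinate is the only Monod argument, substitution makes
original and copy growth rates identical automatically; no special-casing is
needed.

Note one derived detail: substituting the solved δΔ back into the substrate
equation gives the cross-term coefficient −(ms − Yo·mo/Ys) (measured-oxygen
case); the term decays with ε₁ either way, so it carries no qualitative
weight.

The closed-form error solution
γ(t) = ε₁(t₀)·exp(−∫u₁ dτ − c·(t−t₀)) applies whenever the reduced ε₁
equation is −ε₁(u₁ + c) with c a positive parameter constant (c = βm+Yo·mo
for measured oxygen, βm+Ys·ms for measured substrate, both with the matching
single-variable form).  Signal classes carry exact running integrals, so γ
is evaluated without quadrature error; numeric integration agrees with γ to
~1e−11 relative at tight solver tolerances.

## Classification rules

Labels are per state and per δΔ: observable / detectable / unobservable
(measured and n/a where applicable), derived in this order:

1. the measured state is "measured";
2. a constraint-forced error coordinate (uncertainty-free reductions) is
   observable;
3. when the geometric sufficient condition holds for the case, unmeasured
   states inherit observability — equal outputs imply equal states where the
   observability map is injective.  This inheritance is *not* applied in
   uncertainty-free wash-out sub-cases, where vanishing biomass removes the
   kinetic coupling the rank argument needs;
4. a state whose reduced ODE has a negative sign-definite diagonal and
   forcing terms driven only by already-settled errors is detectable (the
   cascade is resolved iteratively, ε₁ before ε₂/ε₃);
5. δΔ is observable under the geometric condition (matching condition plus
   state observability), detectable when its expression vanishes with the
   decaying errors.

Wash-out sub-cases (IC: ν₁(t₀)=0, so ν₁ ≡ 0; asymptotic: inputs drive
ν₁ → 0) exist only where biomass is the measured output.  The δΔ labels of
these six sub-rows are encoded as declarative conclusions and flagged
`asserted` in the reports: the IC/asymptotic distinction for δΔ is
declarative (it concerns arbitrary unknown-input pairs, not the structural
realisation), and the classifier does not re-derive it.  All other cells —
every generic row, every state cell of every sub-row — are produced by the
rules above.

A consequence worth knowing: in the generic regime, removing the
uncertainty never weakens a state's label; in wash-out sub-rows of the
SO-form biomass-output case the ordering reverses (geometry-inherited
observability with uncertainty vs. constraint-based demotion without), and
the consolidated table renders disagreeing sub-rows as a union code
("O/D").

## Synthetic scenarios

A scenario bundles parameters, true-kinetics trajectories, input signals and
a pair of initial conditions; everything derives from one integer seed
through `numpy.random.SeedSequence` spawning, so regeneration is bit-for-bit
reproducible and bundles round-trip through YAML for replay.

* Canonical parameters: Ys=0.65, Yo=0.2, Sin=5 g/L, Oin=0.5 g/L, Os=10 g/L,
  βm=0.05, ms=0.05, mo=0.02 1/h; kinetic bounds μmax∈[0.3,0.5] 1/h,
  Ks∈[0.5,1.5] g/L, Ko∈[0.1,0.3] g/L; input ceilings D̄=0.15, k̄La=6 1/h.
  Plausible magnitudes for an activated-sludge reactor; the classification
  itself is structural and does not depend on them.
* Parameters are drawn uniformly within ±20% of the canonical values; ICs
  uniformly inside Ω with a 10% margin, copy IC independent with a minimum
  per-component separation of 1e−3 g/L so convergence tests are
  non-trivial.
* Time-varying true coefficients are midpoint-plus-sinusoid with amplitude
  at most 80% of the half-width (strictly inside their bounds).  Input
  signals (constant / sinusoid / piecewise-constant) keep a floor of at
  least ~0.42 × the ceiling so the slowest error mode (rate ≈ u₁) decays
  measurably.
* Default horizon 0–50 h; **convergence verification uses 0–250 h**, chosen
  from the decay-rate bound so that u₁-rate modes fall below the 1e−5 g/L
  terminal tolerance from O(1) initial errors.  The wash-out asymptotic
  sub-case is realised by a constant dilution rate (0.6 1/h) exceeding the
  maximal growth rate.

What the generator does **not** emulate: measurement noise (the analysis is
noise-free by construction), realistic influent profiles, correlated
parameter drift, or stiff temperature/pH couplings.  Passing tests therefore
demonstrate the structural claims under smooth bounded excitation, not
robustness to real plant data.

## Numerical choices

* Integration: LSODA with rtol 1e−8 / atol 1e−11 (1e−10/1e−13 where the
  closed form is compared at 1e−6 relative); halving tolerances moves
  terminal errors by <10% (tested).
* Detectability: terminal-window (last 10% of the horizon) max |ε| < 1e−5
  g/L *and* a negative log-envelope slope (windowed running maxima), which
  avoids false passes from slow transients.  Outcomes that reach neither
  the tolerance nor a violation are flagged inconclusive, never passed.
* Constraint-forced (observable) coordinates are pinned in the reduced
  simulation and must stay below 1e−7 over the whole horizon; "not
  observable" labels are corroborated by a visibly nonzero early error
  despite equal outputs.
* Unobservable δΔ wash-out cells are recorded as outside paired-simulation
  reach: the structural realisation (μ̂′−μ̂)·ν₁ vanishes with the biomass,
  so no counterexample trajectory exists in the simulated family.
* States are clamped at zero only inside right-hand-side evaluations, to
  guard Monod denominators against solver micro-undershoot.

## Known limitations

* The single-variable substitute models (S-only, O-only) are not
  mass-consistent as *stand-alone* dynamics: without the unknown input, the
  O-form model has no substrate limitation and can leave the physical
  domain.  Uncertainty-free paired simulation is therefore meaningful on
  the SO form or over horizons where trajectories stay in Ω; the
  with-uncertainty pairing always follows the bounded true dynamics.
* Observability inheritance from the rank condition is a sufficient-side
  argument; the package never claims necessity, and the geometric stage can
  only report "point-dependent" where symbolic rank is inconclusive.
* The classifier's rules mirror the nine-case structure (single measured
  state, Monod-type kinetics); it is not a general DAE decision procedure,
  and unsupported structures raise rather than guess.
* No observer is synthesised; decomposition into observable/unobservable
  subsystems and observer gain design are out of scope.
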