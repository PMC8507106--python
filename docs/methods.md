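# Methods

This note documents the models, numerical procedures and design choices
behind the package. The package studies whether mutual antagonism between
the RhoA/ROCK contractility pathway and the eNOS/NO/cGMP relaxation
pathway can produce bistable switching, and how mechanical tension
feedback changes the answer.

## The models

### Two-node motif

The minimal double-negative motif is pure mass action:

    dA/dt = ksynthA − kdegA·A − kiB·A·B
    dB/dt = ksynthB − kdegB·B − kiA·A·B

Eliminating one variable gives a quadratic whose root product is negative,
so exactly one admissible (nonnegative) steady state exists for every
positive parameter combination — mutual antagonism with bimolecular
inhibition and linear turnover is structurally monostable. The package
verifies this numerically on a log-spaced grid (5 points per constant over
[10⁻², 10²], 5⁶ = 15 625 combinations) and against the closed-form root.
The multistart classifier is additionally run on a seeded random subsample
of the grid (tens of combinations at 10–20 starts each); running it on all
15 625 combinations is possible but adds tens of minutes of runtime for no
extra information, since the closed form covers the full grid.

### Biochemical network (11 equations, 31 reactions)

State variables: inactive RhoA (GDP-bound pool), active RhoA (GTP-bound),
Ser188-phosphorylated RhoA, active ROCK, phospho-Akt, eNOS mRNA, eNOS
protein, S1177-phosphorylated eNOS, NO, cGMP, and active PKG. A constant
HGF stimulus is a clamped input, not a state, so it never appears in the
ODE count.

The double-negative loop is closed by three arms:

* **ki1** — ROCK antagonises Akt phosphorylation (mass-action removal of
  phospho-Akt by ROCK), reducing eNOS-S1177 phosphorylation and hence NO
  output;
* **ki2** — active RhoA destabilises eNOS mRNA (mass-action), reducing
  eNOS expression;
* **k4** — PKG phosphorylates active RhoA at Ser188, returning it (via a
  phosphatase step) to the inactive pool.

Ultrasensitivity enters in exactly one place: PKG activation is a Hill
function of cGMP with half-activation constant `Kmcgmp` and cooperativity
`ncgmp`. All other kinetics are mass action or first order. Secondary
reactions (basal Akt phosphorylation, basal RhoA activation, basal NO
synthesis by unphosphorylated eNOS, second-order NO autoxidation, and a
PKG-stimulated PDE feedback on cGMP) complete the 31-reaction network.

**Provenance.** The original study's reaction-by-reaction kinetics and
parameter values live in supplementary material that is not part of the
sources bundled with this package. The network here is therefore a
*synthetic reconstruction*: topology, species list, rate-law families,
parameter naming (ki1, ki2, k1…k15, k12/kdeg4 for ROCK synthesis and
degradation, Kmcgmp in the Hill term) and the qualitative regime follow
the published description, while the numerical values were calibrated
once, in advance, using a reduced steady-state chain solver (below), and
then frozen. Absolute magnitudes are qualitative by design; the published
analysis makes the same disclaimer for its own values.

### Tension-extended network (12 equations, 35 reactions, 36 perturbable parameters)

Cytoskeletal tension is treated as a dimensionless nonnegative network
species with four couplings: generation proportional to ROCK activity
(k16), tension-dependent RhoA activation — the mechanical positive
feedback (k17) — dissipation proportional to cGMP (k18), and a basal
first-order relaxation (kdeg11). The basal relaxation term is structurally
necessary: without it tension diverges whenever cGMP approaches zero,
because the mechanical loop R → ROCK → tension → R would have unbounded
gain in the contractile state. With it, the loop gain saturates below
unity at the calibrated values and the contractile state is finite.

The Hill coefficient `ncgmp` is treated as a structural constant
(cooperativity of cGMP-dependent activation), not a rate constant, and is
excluded from robustness perturbation; this yields 32 perturbable
parameters for the biochemical model and 36 for the extended one.

## Calibration and what it does (and does not) reproduce

A reduced solver computes every fixed point of the network from a single
scalar self-consistency equation: given active RhoA `R`, all downstream
steady states follow in closed form (NO from a quadratic, cGMP from a
monotone 1-D equation), and the RhoA balance returns an implied `R_out`;
fixed points are roots of `R_out(R) − R`. This solver is independent of
the ODE-assembly path and doubles as a test oracle.

Calibration targets, applied once: (i) the biochemical model is bistable
at baseline with nanomolar NO in both states; (ii) its baseline sits close
to the fold surface, so that single-parameter perturbations of a few
percent destroy bistability for the majority of rate constants (the
brittleness of the purely biochemical switch); (iii) adding the tension
coupling at the same biochemical baseline widens the bistable interval of
both antagonism constants and makes bistability robust to 10–15%
perturbation of essentially all parameters. A mild Hill cooperativity
(ncgmp = 2.2) together with near-fold positioning realises this contrast.

Measured at the frozen values: the biochemical model's bistable interval
is ki1 ∈ [0.0095, 0.0185] and ki2 ∈ [0.0029, 0.0050] with stable-branch NO
spanning ≈ 0.3–5.6 nM across the regimes; the extended model widens these
intervals by ≈ 1.4× absolutely (≈ 2–3× on the ratio scale, the larger gain
on the weak-antagonism side where tension rescues the contractile state)
and extends the NO range to ≈ 0.1–6.9 nM. Retention counts: the
biochemical model keeps bistability for only ~8/32 parameters at ±10%,
while the extended model keeps ~26–36/36 at ±10–15% and ~17–24/36 at ±30%
(the count depends on the ensemble size used in the screen; see below).
The published study reports the same qualitative structure with somewhat
different magnitudes (NO up to tens of nM, a five-fold interval widening);
a reconstruction without the original kinetics should not be expected to
match those numbers exactly, and this one does not — the package asserts
the structural and directional properties, and reports the measured
values as computed.

## Numerical procedures

**Integration.** LSODA (stiff-capable) with a finite-difference Jacobian,
relative tolerance 1e-8, absolute tolerance 1e-10. Steady state is an
event: max-norm of the rate field below `1e-9 · (1 + |x|_inf)`, confirmed
over a trailing window (1% of the elapsed time) before the run is declared
converged; a transient lull resumes integration. The default horizon is
10⁶ model time units (the time unit is symbolic — the study is
qualitative and fixes none); the bundled analyses use 10⁵, which the
models' slowest relaxation rates (leading eigenvalues ~1e-3) comfortably
satisfy. Any state component beyond 1e12 raises a divergence signal.
Negative excursions beyond the absolute tolerance are flagged, never
clipped.

**Steady states.** Integrate-then-refine: the relaxed endpoint is polished
by Newton iteration (scipy `hybr`), accepted only if the residual max-norm
does not increase. Stability is classified from the Jacobian eigenvalues
with a ±1e-8 margin; "marginal" states are excluded from attractor counts.

**Attractor census.** Random initial states are log-uniform per species
over [10⁻², 10³] nM (five decades, bracketing every attractor of the
bundled models including the extended model's deep contractile state).
Stable endpoints are clustered at relative max-norm distance 1e-3 — far
below the ≥5-fold separations between the states of interest, far above
integrator error. The bistability screen is a conjunction: the multistart
census AND an extreme-initialization test (an all-NO-side-high and an
all-RhoA-side-high start must reach distinct stable states), so a missed
basin in either probe cannot produce a false positive. The extreme-start
vectors are synthetic stand-ins constructed from the species-side
classification, since the original extreme-start table is not bundled.

**Continuation.** Pseudo-arclength predictor–corrector: tangents from the
SVD null space of the bordered Jacobian `[J_x | F_p]`, Newton correction
on the rate field plus the arclength hyperplane constraint, adaptive steps
within [1e-5, 0.05] of the range. Branches are anchored at both range
endpoints and the second anchor is traced only if it is not already on
the first branch. Folds are detected from sign changes of the tangent's
parameter component and polished to machine precision with the bordered
fold system `[F; Jv; c·v − 1] = 0` (undamped Newton with best-iterate
tracking — fold iterations are non-monotone in the residual norm). The
bistable interval is the parameter range where ≥2 distinct stable branch
segments coexist, snapped to refined fold positions when they agree
within the continuation step. Hysteresis sweeps (quasi-static up-then-down
stepping, re-integrating from the previous endpoint) provide an
independent cross-check accurate to one step width.

**Robustness.** One parameter at a time, multiplicative perturbation by
±p%; a parameter retains bistability at p% iff both signed perturbations
pass the screen (the stricter two-sided reading; the raw signed outcomes
are stored so the one-sided convention can be recovered). Each cell's
census seed is split deterministically from one root seed. The screens in
the bundled analyses use reduced ensembles (12–24 starts per cell instead
of 100) to keep grid runtimes in minutes; because a finite ensemble can
miss a small basin, retention counts are slightly conservative (the
extreme-start conjunct anchors reachability, and cells are deterministic
given the root seed). The brittle-versus-robust contrast between the two
models is insensitive to this choice.

## What the synthetic inputs do and do not emulate

The generators reproduce the *procedures* of the study — random species
initializations over decades, percentage perturbations, log-uniform
parameter-space search — with explicit seeds. They do not emulate
biological variability (no cell-to-cell parameter distributions, no
measurement noise), and the models omit, as the study itself did,
Rho-GEF/GAP species, S-nitrosation and tyrosine nitration, p190RhoGAP
feedback, spatial effects and pulsatile stimuli. Passing tests show that
the computational claims hold for the reconstructed network under its
stated procedures; they are silent on the behaviour of real cells.

## Known limitations

* The reconstruction matches the published results qualitatively
  (bistability, S-shaped diagrams, interval widening, robustness
  contrast), not numerically (exact NO ranges, the five-fold widening, the
  specific fragile-parameter triple).
* Robustness counts depend weakly on the census ensemble size (see above).
* Equilibrium continuation handles folds only; Hopf detection and
  two-parameter continuation are out of scope, and no oscillatory régimes
  were observed at the frozen values.
* The finite-difference Jacobian limits eigenvalue accuracy near folds to
  ~1e-6 relative; the fold polisher compensates by solving the bordered
  system directly.
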