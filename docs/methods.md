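# Methods

This note documents the models, algorithms, defaults and design choices in
`photobo`, and what the synthetic experiments do and do not demonstrate.

## Search spaces and encodings

**Catalyst library.** Candidates are ordered pairs from an Ra × Rb
substituent grid (the bundled preset: 20 Ra — 7 electron-donating, 5
electron-withdrawing, 8 halogenated — × 28 Rb — 18 polyaromatic, 5
phenylamine, 5 carbazole — giving 560 molecules). Each candidate carries a
16-component descriptor vector (units: V vs SHE for IP/EA/IP*/EA*, eV for
the optical gap ΔE_S1→S0, E_C and ΔE_S1→T1 and λ, Debye for ΔD, Å for the
excited-state geometry indices, dimensionless f and S_r). Descriptors are
consumed as data; no quantum chemistry is performed. For GP fitting and
Kennard–Stone seeding the descriptors are z-scored per column over the
library; the scaler is persisted with the model. Standardization is the
default for Kennard–Stone because the descriptors mix scales spanning three
orders of magnitude; raw-value distances remain available for sensitivity
checks.

**Formulation space.** Conditions are (catalyst, ligand, Ni loading)
triples on a full grid (bundled: 18 × 25 × 10 = 4,500). The combined
distance between two conditions sums four components: |Δ electronic
feature|, Tanimoto distance between the catalysts' Morgan fingerprints
(radius 2, 2,048 bits), the same for the ligands, and |Δ loading|. Each
component is min–max normalized over the materialized space (so each lies
in [0, 1]); the normalizers are frozen at construction and travel with the
space, so distances are stable under subsetting. The electronic feature
defaults to the computed electron affinity so synthetic runs need no
measurements; a measured half-wave reduction potential can be supplied
instead via the catalyst table.

**Feasibility screen.** A candidate is thermodynamically viable when
EA* > +1.19 V vs SHE (excited catalyst oxidizes the amino-acid substrate)
and EA < −1.17 V vs SHE (reduced catalyst regenerates Ni(I)→Ni(0)). The
screen annotates; it never filters the BO candidate pool, because the
window is a necessary condition only and activity is not determined by
redox thermodynamics alone. Hard filtering is available behind an explicit
caller decision.

## Surrogates

Targets (yields in %) are standardized internally and reported back in %.
Two kernels:

* **Matérn** (ν ∈ {1/2, 3/2, 5/2}, default 5/2) on standardized
  descriptors, one shared length-scale by default, per-dimension (ARD)
  optional. ARD is used where per-feature relevance matters (e.g. before
  Shapley analysis).
* **Formulation RBF** K = α·exp(−Σ_k θ_k d_k²) over the four normalized
  component distances. θ ≥ 0 weight the channels and are tuned jointly with
  α and the noise variance.

Hyperparameters maximize the log marginal likelihood in log space
(L-BFGS-B, bounds [1e−4, 1e4], noise floored at 1e−6 because
triplicate-mean yields carry real noise), with 8 restarts from seeded
log-uniform draws; the initialization point is always evaluated, so the
returned optimum is never worse than the start. An RBF over Tanimoto
distances is not guaranteed positive semi-definite, so Cholesky
factorization escalates a diagonal jitter tenfold from 1e−10 to at most
1e−4 with a warning; beyond the cap fitting fails hard and reports the
minimum eigenvalue. Posterior σ is the latent (noise-free) standard
deviation, clipped at 0.

## Acquisition and the closed loop

Each step refits the surrogate on all observations, draws a portfolio of β
values from an exponential distribution (default portfolio 12 for the
catalyst preset, 8 for the formulation preset; scale 1.0 on the
standardized-target scale, so β ≈ 1 balances one posterior standard
deviation against one unit of predicted mean), and lets each β pick the
arg-max of μ + βσ over unobserved candidates, falling to the runner-up when
two β values agree. A selection mask models the human-in-the-loop subset
choice: accept-all (default), top-k by score, or an explicit per-step id
list replaying a historical campaign. Stopping combines max steps, a total
observation budget, optional target yield, and a no-improvement patience
(default 5 steps, matching how the historical formulation campaign was
terminated). Seeding is Kennard–Stone (deterministic max–min; initial pair
= lexicographically smallest maximal-distance pair; later ties to the
lowest index) or an explicit id list.

All randomness derives from named children of one campaign seed
(β portfolio, oracle noise, GP restarts), and the log serializes to
sorted-key JSON-lines, so identical configs give byte-identical logs. The
log enforces that no id is observed twice and exposes a non-decreasing
best-so-far trace.

## Synthetic oracle

The landscape stands in for the laboratory: latent score = Σ w_i z_i
(z-scored descriptors; default weights −1.0 on the optical gap, −0.8 on EA,
+0.6 on the D index, +0.5 on oscillator strength — signs fixed to mirror
the qualitative structure–activity findings, and enforced unless explicitly
overridden) + a rank-2 catalyst×ligand Gaussian interaction (scale 0.5) + a
concave quadratic loading response peaking at 4 mol%. The latent score is
standardized and squashed through a logistic onto [0, 100]% (slope 1.2,
shift −0.7, giving a median yield ≈ 35% and maxima ≈ 90–95%, comparable to
the dynamic range of the real campaigns). Measurements are triplicate with
Gaussian noise (default SD 3 percentage points per replicate, consistent
with triplicate experimental reporting), clamped to [0, 100]; each
observation is a pure function of (target id, seed). The generator records
its arg-max and verifies it against exhaustive evaluation.

The bundled 560-molecule descriptor table is a statistical emulation, not
chemistry: descriptors are smooth functions of latent substituent
properties plus seeded noise, and the table is constructed to reproduce the
real library's screening statistics (exactly 4 oxidation-window and 1
reduction-window failures), so count pipelines can be validated against
known values. Consequences for interpretation: passing tests demonstrate
that the optimizer, kernels, screen and explanation machinery behave
correctly on a landscape with realistic structure and noise; they do not
demonstrate chemical accuracy of any yield prediction, and the smooth
descriptor→yield link is by construction more learnable than real
structure–activity data. The replay oracle exists precisely so measured
campaigns can be re-analyzed without this caveat.

## Shapley explanation

Contributions are background-marginalized Shapley values: the value of a
coalition S is the mean model output with features in S pinned to the
instance and the rest taken from background rows (default background: all
training instances). Exact enumeration is available up to 20 features;
beyond toy sizes a seeded permutation estimator is used (it converges to
the exact values; the suite checks efficiency, dummy and symmetry axioms
and the convergence on 5-feature models). The implementation is
self-contained and defined by the axioms rather than by any particular
estimator library's conventions.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations run at the real campaign
scales — 560-candidate library, 4,500-condition space, 55- and 107-run
budgets, a 20-seed paired BO-vs-random study with a 60-run budget — which
complete in well under a minute because all heavy objects (per-entity
Tanimoto matrices, Cholesky factors) are small. Tie-breaks are always "first
index wins" (arg-max semantics, Kennard–Stone, ranking ties by canonical
feature order), degenerate inputs are defined explicitly (constant targets
→ prior mean; two empty fingerprints → distance 0; constant distance
component → normalized to 0), and tolerances in the suite reflect the
arithmetic involved (1e−12 for kernel re-derivations, 1e−8 for closed-form
GP posteriors, estimator-level bounds for sampled Shapley values).

## Known limitations

* The oracle is statistical, not mechanistic; no kinetics of the
  photoredox/Ni cycles is modeled.
* The human selection step of the historical campaigns is recorded and
  replayable but not reproduced by any model.
* No cost-aware, multi-objective or asynchronous acquisition; UCB portfolio
  only, as in the workflow this package operationalizes.
* The formulation kernel's PSD repair via jitter changes the model slightly
  when triggered; runs that hit the escalation path emit a warning.
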