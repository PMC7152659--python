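# Methods

## Catalytic-cycle model

The core object is the mass-action ODE system for the dehalogenase cycle

    E + S ⇌(k1, k−1) ES →(k2) EI →(k3) EP →(k4, k−4) E + P

with species concentrations in μM and rate constants in s⁻¹ (bimolecular
k1, k−4 in μM⁻¹ s⁻¹).  A three-step variant (no EP; ES → EI → E + P) is
provided for substrates whose intermediate and product fluorescence cannot
be distinguished.  Two conservation laws hold exactly in the model and to
1e-6·max(E₀, S₀) in the integrator: the enzyme ledger E + ES + EI + EP = E₀
and the substrate ledger S + ES + EI + EP + P = S₀ (EI and EP carry the
substrate moiety).

Assumptions: dilute well-mixed solution, no temperature or pH dependence,
no substrate inhibition or abiotic hydrolysis.  Product rebinding k−4
defaults to 0 (irreversible release); it is settable for simulation but all
closed-form derivations assume it vanishes.

Derived steady-state constants follow from King–Altman algebra of the
linear chain with irreversible post-binding steps:

* kcat = (1/k2 + 1/k3 + 1/k4)⁻¹ (three-step: drop the k4 term) — the
  turnover time is the sum of step times, so kcat is invariant under
  permutation of the post-binding rates and bounded by the slowest step;
* Km = kcat·(k−1 + k2)/(k1·k2), reducing to Ks·kcat/k2 under
  rapid-equilibrium binding (k−1 ≫ k2, binding described only by
  Ks = k−1/k1);
* rate constants known only as lower bounds ("> x" in kinetic tables) are
  treated as infinitely fast in these formulas, making the derived kcat an
  upper bound; they are never reported as point estimates and are excluded
  from rate-limiting-step assignment.

Rapid-equilibrium binding is implemented by substituting a fast explicit
pair (k1 = 10 μM⁻¹ s⁻¹, k−1 = Ks·k1) rather than a differential-algebraic
formulation.  This keeps a single solver path; for the regimes of interest
(k−1 in the 10⁵ s⁻¹ range against chemistry at ≤ 10² s⁻¹) the error is far
below the fitting noise.

## Observable models

Stopped-flow fluorescence is modelled as a per-species linear combination.
Direct excitation (500 nm): V1 = f·(S + ES + a·EI + b·(EP + P)).  The
factor b multiplies the sum EP + P — bound and free product share the
fluorophore state — rather than EP alone; a is the relative intensity of
the covalent intermediate.  Tryptophan excitation (280 nm):
V2 = f·(S + o·ES + p·EI + q·EP + r·P), where o…r are free empirical
scalars absorbing FRET efficiency and intensity changes (no functional
form is imposed on them).  An optional additive per-trace baseline models
instrument drift.  Substrates without a fluorogenic signal (DBE) are
observed through an identity observable on a chosen species, normally P.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study's experimental designs with known
ground truth, seeded so every dataset is a pure function of its arguments:

* stopped-flow traces: ODE time course → observable → additive i.i.d.
  Gaussian noise with known per-point sigma (default 1% of trace
  amplitude); the sigma column is exact, which is what makes
  sigma-normalized χ² well calibrated.  Options: 1 ms dead-time cut and
  ±10% jitter of nominal concentrations (true values recorded) to
  exercise the fitter's bounded concentration-adjustment nuisances.
* steady-state tables: v₀ = kcat·E₀·S/(Km + S) plus Gaussian noise
  (default 2% of each rate), with replicate structure.
* Markov trajectories: exact sampling from a row-stochastic matrix started
  uniformly, optionally with state-conditioned spherical-Gaussian feature
  emissions — enough structure for TICA/clustering tests, deliberately
  nothing like real MD (no solvent degrees of freedom, no metastability
  hierarchy, no anisotropic features).
* NAC geometry frames: reactive frames drawn uniformly inside the
  criterion box (distance 2.8–3.41 Å, angle 157–180°), non-reactive ones
  outside at least one criterion.

Passing recovery tests therefore demonstrates that the estimators are
unbiased and their uncertainties calibrated *when the model is correct and
sigmas are known* — not that real instrument data (drift, photobleaching,
mixing artifacts, unknown sigmas) would fit equally well.

Default study conditions used by the recovery protocols and the
acceptance script (chosen once to mirror the published designs):
single-turnover BDP traces at 2–10 μM substrate against 30 μM enzyme,
120 points over 2 s, 1% noise, refitting k2 and the signal coefficients
f, a, b with binding and the bound-only steps fixed; DBE/LinB86 steady
state at 12 log-spaced concentrations 100–20 000 μM (0.2 μM enzyme, 2%
noise, 3 replicates); BDP/LinB86 at 10 concentrations 2–130 μM.  The k4
recovery uses saturating progress curves (5–20 mM substrate, 2 μM enzyme)
where the turnover rate pins product release through kcat.

## Fitting and uncertainty

χ² = Σ((obs − model)/σ)² is minimized with Levenberg–Marquardt (lmfit's
`leastsq` engine) on the residual vector.  Positive rate parameters are
fit as log10 values, which enforces positivity and conditions the
problem; standard errors are mapped back through the Jacobian of the
transform.  Signal coefficients stay linear (baseline may be negative).
Per-trace concentration factors, when enabled, are bounded to [0.9, 1.1].
Fits are deterministic given data and start; an optional multi-start mode
(log-uniform perturbations within a factor of 3, deterministic seeds,
lowest χ² kept) guards against distant local minima and is off by default
because the base contract is a reproducible single descent.

Identifiability is reported at three levels: a singular covariance flags
undetermined standard errors; the Michaelis–Menten fitter flags a Km that
the concentration range cannot bracket (all-saturating → only kcat;
all-sub-Km → only the slope kcat/Km); and profile-χ² contours scan one
parameter over a grid, re-optimizing all others, with confidence limits
where the profile crosses χ²min/0.98.  Crossings are refined by Brent
root-finding inside the bracketing grid cell, so grid resolution does not
bias the limits.  A profile that never crosses on one side yields a
one-sided bound — the same way rate constants are printed as "> x" in
kinetic tables.  Note a property of this ratio convention: the implied
Δχ² is 0.0204·χ²min, which grows with the number of points, so its
confidence level is dataset-size dependent; on the ~240-point steady-state
datasets used in the coverage simulation it corresponds to roughly 95%
one-parameter coverage.  The threshold ratio is configurable.

Derived constants carry first-order independent-error propagation
(SE(a/b) = |a/b|·√((sa/a)² + (sb/b)²)); variant comparisons use Welch's
unequal-variances t-test with Welch–Satterthwaite degrees of freedom and
significance tiers at p < 0.05 and p < 0.01.  No multiple-testing
correction is applied (raw tiers are reported); this is configurable by
the caller.

## Markov state models

The MSM layer consumes tabular data only (distance tables, geometry
tables, discrete state sequences); parsing MD trajectory binaries is
deliberately out of scope and delegated upstream.  Featurization is a
binary contact map with a strict inequality (contact iff distance < 8 Å).
TICA solves the symmetrized generalized eigenproblem C_τ v = λ C_0 v on
mean-free features, with a logged 1e-8 ridge on C_0 when near-singular;
component signs are arbitrary.  Microstates come from scikit-learn's
MiniBatchKMeans (seeded; clusters left empty by mini-batch updates are
removed and labels compacted with a warning, so every reported cluster is
non-empty).  The default cluster count is 200, matching common practice
for protein–ligand MSMs, but synthetic tests use 2–10.

Transition matrices are estimated from sliding-window counts at a lag,
restricted to the largest strongly connected state set (dropped states
reported).  The default estimator row-normalizes the counts; a reversible
maximum-likelihood option enforces detailed balance via the standard
fixed-point iteration on symmetric edge weights.  The equilibrium
distribution is the stationary left eigenvector, verified as a fixed
point to 1e-8.  Validation: implied timescales t_i(τ) = −τ/ln λ_i(τ)
(λ ≥ 1 → ∞, λ ≤ 0 → undefined) and Chapman–Kolmogorov comparison of
T(τ)^k against T(kτ) on the common state set.  Lags are in frames;
converting a physical lag (e.g. 5 ns) requires the caller's frame
interval, since trajectory stride is acquisition metadata.

Pathway decomposition uses discrete transition-path theory: forward and
backward committors from linear solves, flux f_ij = π_i q⁻_i T_ij q⁺_j,
and attribution of the reactive flux leaving the source to the channel of
the first intermediate entered (direct source→sink flux goes to a
"direct" channel).  Every intermediate must be mapped to exactly one
channel; the decomposition is exact for parallel channels and is verified
against Monte-Carlo path counting in the tests.  NAC classification is
inclusive on all bounds: distance ≤ 3.41 Å and angle within [157°, 180°].

## Known limitations

* Closed-form kcat/Km assume irreversible post-binding steps; with
  k−4 > 0 only the ODE path is valid.
* The confidence-contour convention's coverage depends on dataset size
  (see above); for small n the intervals are anti-conservative.
* The reversible MLE uses a plain fixed-point iteration — adequate for
  the ≤ 10³-state models targeted here, not for very large sparse counts.
* Published MSM quantities for this system (tunnel flux splits,
  conformer equilibrium populations) require the original
  multi-microsecond MD trajectories and are out of scope; the MSM module
  is validated on synthetic chains with known answers instead.
* Welch comparisons take reported means/dispersions at face value; no
  account is taken of correlations between parameters fit from the same
  dataset.
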