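# halokin

Kinetic and Markov-state-model analysis of haloalkane dehalogenase
catalysis.

Haloalkane dehalogenases (here: LinB wild type and its tunnel-engineered
variants LinB32 and LinB86) hydrolyze carbon–halogen bonds through a
multi-step cycle

```
E + S  ⇌(k1, k−1)  ES  →(k2)  EI  →(k3)  EP  →(k4)  E + P
```

where k2 is the SN2 attack of the catalytic aspartate, EI the covalent
alkyl-enzyme intermediate, k3 its hydrolysis and k4 product release (a
simplified three-step scheme merges the last two steps when the data cannot
distinguish them).  `halokin` is for enzymologists and simulators who want
to

* integrate this cycle as mass-action ODEs and derive steady-state
  constants analytically — kcat = (1/k2 + 1/k3 + 1/k4)⁻¹,
  Km = kcat·(k−1 + k2)/(k1·k2) (→ Ks·kcat/k2 under rapid-equilibrium
  binding), Ks = k−1/k1, and the specificity constant kcat/Km;
* fit heterogeneous kinetic data globally — stopped-flow fluorescence
  traces via the two-channel signal models
  V1 = f·(S + ES + a·EI + b·(EP+P)) and
  V2 = f·(S + o·ES + p·EI + q·EP + r·P), plus Michaelis–Menten
  initial-rate tables — by Levenberg–Marquardt on sigma-normalized
  residuals, with covariance standard errors, profile-χ² confidence
  contours (threshold χ²min/0.98, one-sided bounds reported as "> x"),
  propagated errors for derived constants, and Welch's t-test for variant
  comparison;
* build Markov state models from featurized trajectories — binary contact
  maps (< 8 Å), TICA, MiniBatchKMeans microstates, transition-matrix
  estimation (row-normalized or reversible MLE), implied timescales,
  Chapman–Kolmogorov tests, transition-path-theory decomposition of
  binding flux among access tunnels, and near-attack-conformer
  classification (distance ≤ 3.41 Å, angle 157–180°, bounds inclusive);
* generate every input synthetically with seeded reproducibility, so the
  whole pipeline is testable end to end without instrument files or MD
  trajectories.

Units everywhere: concentrations in μM, time in s, distances in Å.

## Worked example

```python
import numpy as np
from halokin import (build_mechanism, get_reference, derived_kcat,
                     derived_km, rate_limiting_step, propagate_ratio_error)
from halokin.studies import recover_mm_dbe_linb86

ref = get_reference("DBE", "LinB32")          # published microscopic set
mech = build_mechanism("four_step", rapid_equilibrium_binding=True)
print("kcat =", round(derived_kcat(ref.rates, mech), 2), "s^-1")
print("Km   =", round(derived_km(ref.rates, mech), 0), "uM")
print("limiting:", rate_limiting_step(ref.rates, mech))

ks, se = propagate_ratio_error(90.0, 3.0, 2.4, 0.1)   # k-1/k1 for BDP/LinBwt
print("Ks   =", round(ks, 1), "+/-", round(se, 1), "uM")

fit = recover_mm_dbe_linb86(seed=7)           # synthetic steady-state refit
print("kcat_fit = %.1f +/- %.1f ; Km_fit = %.0f +/- %.0f" % (
    fit.estimates["kcat"], fit.standard_errors["kcat"],
    fit.estimates["Km"], fit.standard_errors["Km"]))
```

prints

```
kcat = 3.08 s^-1
Km   = 345.0 uM
limiting: ('k4',)
Ks   = 37.5 +/- 2.0 uM
kcat_fit = 56.1 +/- 0.3 ; Km_fit = 2324 +/- 21
```

The derived kcat of 3.08 s⁻¹ for DBE/LinB32 reproduces the published
3.1 ± 0.1; product release (k4 = 3.2 s⁻¹) is rate limiting.  The last line
is a full round trip: initial rates generated from the published DBE/LinB86
pair (kcat = 57 s⁻¹, Km = 2350 μM) with 2% noise are refit and recovered
within a couple of standard errors.

A command-line layer wraps the same functions
(`halokin simulate|fit|mm-fit|msm-build|nac-classify|report`), driven by
YAML configs; every artifact records its seed and config hash and
validates against the JSON schemas shipped in `src/halokin/schemas/`.

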