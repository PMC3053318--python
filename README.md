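# lacswitch

Stochastic kinetics of the inducible *lac* genetic switch in *Escherichia
coli*: a kinetic model of the operon calibrated from single-molecule
observables, exact stochastic simulation, closed-form gene-expression laws
and their maximum-likelihood fitting, noise/gene-regulation-function
analysis, and a scaled-down lattice reaction-diffusion module for
macromolecular crowding effects.

The package is for computational biologists studying stochastic gene
expression: it lets you simulate the switch with and without the LacY
positive-feedback loop, solve its repression subsystem exactly, and test
how well simplified analytic models (bursting, telegraph) recover kinetic
parameters from single-cell protein distributions.

## The model

The *lac* repressor dimer R2 binds the operator O and blocks transcription
of the permease LacY.  A gratuitous inducer (TMG or IPTG) binds the two
sites of the dimer independently; singly induced dimers still bind the
operator at half the bare rate (proportionality C = 1/2), doubly induced
dimers essentially not at all (C2 = 0.01), and a second inducer binding an
operator-bound repressor "knocks it off" 500× faster than spontaneous
release.  Expression is transcription from the free operator (k_ts),
translation (k_tl) vs mRNA decay (k_mdeg, mean lifetime 90 s, four
proteins per transcript), and protein dilution at the growth rate
(k_pdeg = ln2 / 55 min).  With feedback (PFB), LacY actively imports
inducer (an irreversible Michaelis–Menten step expanded to elementary
reactions) and inducer also crosses the membrane passively; without
feedback (NPF) the internal inducer concentration is clamped.

Three analytic layers sit on top:

* **Burst theory.**  With pseudo-first-order repressor binding rate
  λ(I) = λ₀ / (1 + I/K_ID), the mean observed burst size is
  B(I) = 1 + k_ts/λ(I) — exactly affine in inducer concentration — and the
  mean burst duration is 1/λ(I).  These identities calibrate k_rb, k_ts,
  K_ID and k_ro_off from measured burst-size titrations.
* **Stationary laws.**  The bursting model gives a negative-binomial /
  gamma stationary protein law with frequency *a* (bursts per protein
  lifetime) and size *b*; the two-state telegraph model's hypergeometric
  stationary PMF is evaluated exactly as a Beta-mixture of negative
  binomials.  `BurstModel` and `TwoStateModel` fit these by maximum
  likelihood with resampling confidence intervals.
* **Exact solves.**  The operator–repressor subsystem of the NPF circuit
  is a finite Markov chain (231 states for 10 dimers), solved exactly for
  occupancy, burst frequency, and first-passage lifetimes; conditional
  moment equations then give exact stationary means, variances and Fano
  factors of mRNA and protein.

The spatial module builds fast-growth (2 × 0.8 µm spherocylinder) and
slow-growth (3 × 0.4 µm, condensed nucleoid, chromosome random walk) cell
models, packs the cytoplasm with an obstacle census to 50% volume
fraction, and measures repressor rebinding after unbinding, anomalous
subdiffusion (MSD exponent α(t)), and mRNA membrane-contact localization.

## Worked example

```python
import numpy as np
from lacswitch import (LacRates, grf_curve, hill_fit,
                       operator_subsystem_solve)

rates = LacRates.defaults("TMG")

sol = operator_subsystem_solve(0.0, rates)       # zero inducer
print(f"bursts per protein lifetime: {sol.burst_frequency:.3f}")
print(f"repressed-complex lifetime:  {sol.mean_complex_lifetime:.0f} s")

grid = np.concatenate([[0.0], np.logspace(-6, np.log10(2e-3), 24)])
curve = grf_curve(rates, grid, mode="exact")     # exact moment solve
fit = hill_fit(curve)
print(f"Hill inflection: {fit.K_half * 1e6:.0f} uM, "
      f"coefficient {fit.n_hill:.2f}")
print(f"peak Fano factor: {curve.fano.max():.1f}")
```

prints

```
bursts per protein lifetime: 2.963
repressed-complex lifetime:  1587 s
Hill inflection: 317 uM, coefficient 2.17
peak Fano factor: 62.6
```

Reading: at zero inducer the operator cycles between a ~26-minute
repressed complex and ~20-second free intervals, producing about three
transcription bursts per protein lifetime.  The mean LacY level responds
sigmoidally to internal inducer with half-saturation near 310 µM and
cooperativity ≈ 2.1 (an emergent property — no cooperative binding is in
the model), and the cell-to-cell noise peaks near the switching threshold
at a Fano factor of ~60, far above the Poisson value of 1.

A command-line interface mirrors the library
(`lacswitch grf|simulate-cme|simulate-rdme|fit|calibrate|landscape|rebind|fixtures`);
every subcommand writes a `manifest.json` recording configuration and
seeds beside its outputs.

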