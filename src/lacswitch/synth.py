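"""Synthetic single-cell data generators.

Everything the pipeline consumes can be generated here without external
data: exact draws from the analytic stationary laws, inducer-titration
studies shaped like published single-molecule experiments (constant burst
frequency near 3 per protein lifetime, burst size affine in inducer), and
Brownian track fixtures for diffusion analysis.  Every generator is
seed-deterministic and records its generating truth in metadata so that
fitting code can be tested closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytic import BurstParams, TwoStateParams, twostate_pmf
from .countdist import CountDistribution


def gen_negbin_counts(a: float, b: float, n_cells: int,
                      seed: int) -> CountDistribution:
    """Exact negative-binomial protein counts (burst-model stationary law).

    Sampled as a Gamma(a, b) Poisson mixture, which is the NB(a, b)
    construction itself.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=a, scale=b, size=n_cells)
    counts = rng.poisson(lam)
    return CountDistribution(protein=counts, metadata={
        "generator": "negbin", "a": a, "b": b, "n_cells": n_cells,
        "seed": seed})


def gen_twostate_counts(params: TwoStateParams, n_cells: int, seed: int,
                        mass_tol: float = 1e-6) -> CountDistribution:
    """Exact draws from the telegraph stationary PMF by inverse CDF.

    The PMF is tabulated to a truncation chosen from its mean and spread;
    a residual tail mass above ``mass_tol`` raises.
    """
    mean = params.a * params.b
    n_max = int(mean * 6 + 30 * np.sqrt(mean * (1 + params.b)) + 100)
    pmf = twostate_pmf(np.arange(n_max + 1), params)
    deficit = 1.0 - pmf.sum()
    if deficit > mass_tol:
        raise ValueError(f"truncation mass deficit {deficit:.2e} > {mass_tol}")
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    counts = np.searchsorted(cdf, rng.random(n_cells))
    return CountDistribution(protein=counts, metadata={
        "generator": "twostate", "a": params.a, "b": params.b,
        "k_on_hat": params.k_on_hat, "k_off_hat": params.k_off_hat,
        "n_cells": n_cells, "seed": seed})


@dataclass
class BurstTitrationStudy:
    """An inducer titration of single-cell protein distributions.

    Emulates reporter-based single-molecule studies of the operon without
    feedback: burst frequency a(I) approximately constant and protein burst
    size b(I) affine in inducer concentration.
    """

    concentrations: np.ndarray          # M
    distributions: list
    true_a: np.ndarray
    true_b: np.ndarray
    seed: int
    metadata: dict = field(default_factory=dict)


#: default titration ladder (M): typical low-to-induced TMG range
DEFAULT_CONCENTRATIONS = np.array([0.0, 20e-6, 40e-6, 50e-6, 75e-6,
                                   100e-6, 200e-6])


def gen_burst_titration_study(concentrations=None, a: float = 3.0,
                              b0: float = 13.99, slope: float = 5.677e5,
                              n_cells: int = 500, noise_sd: float = 0.0,
                              seed: int = 0) -> BurstTitrationStudy:
    """Generate a burst-size titration study.

    ``b(I) = b0 + slope * I`` proteins per burst (slope in proteins per
    molar), optionally perturbed by lognormal relative noise of width
    ``noise_sd``.  The defaults are the burst line implied by the tabulated
    circuit rates: intercept 4*(1 + k_ts/lambda_0) ~ 13.99 and slope such
    that the unobservable-burst-corrected half-saturation (b0 - 4)/slope is
    17.6 uM (TMG), with frequency 3 bursts per lifetime.
    """
    if b0 <= 0 or slope <= 0:
        raise ValueError("b0 and slope must be positive")
    conc = (np.asarray(concentrations, dtype=float)
            if concentrations is not None else DEFAULT_CONCENTRATIONS.copy())
    rng = np.random.default_rng(seed)
    dists, tas, tbs = [], [], []
    for i, c in enumerate(conc):
        b = b0 + slope * c
        if noise_sd > 0:
            b *= np.exp(rng.normal(0.0, noise_sd))
        d = gen_negbin_counts(a, b, n_cells, seed=int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31))
        d.metadata.update({"inducer_conc": float(c)})
        dists.append(d)
        tas.append(a)
        tbs.append(b)
    return BurstTitrationStudy(
        concentrations=conc, distributions=dists,
        true_a=np.array(tas), true_b=np.array(tbs), seed=seed,
        metadata={"b0": b0, "slope": slope, "noise_sd": noise_sd,
                  "n_cells": n_cells})


def study_burst_table(study: BurstTitrationStudy):
    """Collapse a titration study to a per-concentration burst table using
    the generating truth (frequency, protein burst size)."""
    from .bursts import BurstTable
    return BurstTable(concentrations=study.concentrations,
                      frequencies=study.true_a,
                      protein_burst_sizes=study.true_b)


def study_fitted_burst_table(study: BurstTitrationStudy):
    """Burst table from per-condition negative-binomial fits, as an
    experimentalist would produce it from measured distributions."""
    from .bursts import BurstTable
    from .fitting import BurstModel
    freqs, sizes = [], []
    for d in study.distributions:
        fit = BurstModel(d).fit()
        freqs.append(fit.params["a"])
        sizes.append(fit.params["b"])
    return BurstTable(concentrations=study.concentrations,
                      frequencies=np.array(freqs),
                      protein_burst_sizes=np.array(sizes))


def gen_brownian_tracks(D: float, dt: float, n_steps: int, n_tracks: int,
                        seed: int) -> np.ndarray:
    """Gaussian-increment 3D tracks, shape (n_tracks, n_steps+1, 3).

    Step variance per axis is 2*D*dt; used to calibrate MSD estimators.
    """
    if D <= 0 or dt <= 0:
        raise ValueError("D and dt must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt),
                       size=(n_tracks, n_steps, 3))
    tracks = np.zeros((n_tracks, n_steps + 1, 3))
    tracks[:, 1:] = np.cumsum(steps, axis=1)
    return tracks
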