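"""Transcriptional burst theory and single-molecule calibration.

When repression is strong, expression from the operon occurs in bursts: a
repressor dissociates, RNA polymerase and the repressor pool compete for the
free operator, and the burst ends when a repressor rebinds.  With a
transcription-initiation rate k_ts and a pseudo-first-order repressor binding
rate lambda, each free-operator episode yields a geometric number of
transcripts; episodes that produce no transcript are unobservable, so the
mean observed burst size is B = 1 + k_ts / lambda.

Because a repressor dimer binds inducer at two independent sites, the free
repressor pool partitions binomially and, when a singly-induced dimer binds
the operator at half the bare rate (C = 1/2), the total binding rate is
lambda(I) = lambda_0 / (1 + I/K_ID) — so both the burst size and the burst
duration are exactly affine in inducer concentration.  This linearity is what
lets a linear fit of measured burst sizes calibrate the model's rate
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rates import AVOGADRO, LacRates


class CalibrationError(ValueError):
    """Raised when a burst table cannot constrain the rate constants."""


def p_transcribe(k_ts: float, lambda_bind: float) -> float:
    """Probability that a free operator initiates transcription before a
    repressor rebinds: k_ts / (k_ts + lambda_bind)."""
    if k_ts < 0 or lambda_bind < 0:
        raise ValueError("rates must be non-negative")
    if k_ts == 0 and lambda_bind == 0:
        raise ValueError("p_transcribe undefined when both rates are zero")
    return k_ts / (k_ts + lambda_bind)


def mean_burst_from_p(p: float) -> float:
    """Mean transcripts per observed burst, 1/(1-p).

    The per-episode transcript count is geometric with success probability p;
    conditioning on at least one transcript shifts the mean from p/(1-p)
    to 1/(1-p).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    return 1.0 / (1.0 - p)


def equilibrium_repressor_fractions(I: float, K_ID: float):
    """Fractions (f_R, f_IR, f_I2R) of free repressor dimers with 0, 1, 2
    bound inducer molecules at inducer concentration ``I``.

    Two independent sites with per-site occupancy (I/K)/(1 + I/K) give a
    binomial partition.
    """
    if I < 0:
        raise ValueError("inducer concentration must be >= 0")
    if K_ID <= 0:
        raise ValueError("K_ID must be > 0")
    x = I / K_ID
    denom = (1.0 + x) ** 2
    return (1.0 / denom, 2.0 * x / denom, x * x / denom)


def binding_rate(I: float, rates: LacRates) -> float:
    """Pseudo-first-order repressor-operator binding rate lambda(I) (s^-1).

    Sums free-dimer species weighted by their operator affinities
    (I2R2 binding is negligible in the bursting regime and excluded, as in
    the bursting Markov picture).
    """
    f_r, f_ir, _ = equilibrium_repressor_fractions(I, rates.K_ID)
    per_pair = rates.k_rb / (AVOGADRO * rates.V)
    return per_pair * rates.R_tot * (f_r + rates.C * f_ir)


def burst_size(I, rates: LacRates):
    """Mean mRNA per observed transcription burst at inducer concentration I.

    For C = 1/2 this is exactly affine:
    B(I) - 1 = (B(0) - 1) * (1 + I / K_ID).
    """
    I = np.asarray(I, dtype=float)
    lam = np.vectorize(lambda c: binding_rate(c, rates))(I)
    if np.any(lam == 0):
        raise ValueError("repressor binding rate is zero; burst size diverges")
    out = 1.0 + rates.k_ts / lam
    return float(out) if out.ndim == 0 else out


def burst_duration(I, rates: LacRates):
    """Mean free-operator interval 1/lambda(I) in seconds."""
    I = np.asarray(I, dtype=float)
    lam = np.vectorize(lambda c: binding_rate(c, rates))(I)
    if np.any(lam == 0):
        raise ValueError("repressor binding rate is zero; duration diverges")
    out = 1.0 / lam
    return float(out) if out.ndim == 0 else out


@dataclass
class BurstTable:
    """Per-concentration burst observables, as inferred from single-cell
    protein distributions (gamma-fit frequency a and protein burst size)."""

    concentrations: np.ndarray   # M
    frequencies: np.ndarray      # bursts per protein lifetime
    protein_burst_sizes: np.ndarray  # proteins per burst (= 4 x mRNA size)


def calibrate_from_single_molecule(
    table: BurstTable,
    base_rates: LacRates | None = None,
    reference_concentration: float = 200e-6,
    target_duration_fraction: float = 0.05,
    target_duration: float | None = None,
) -> LacRates:
    """Recover (K_ID, k_rb, k_ts, k_ro_off) from burst-size observations.

    The calibration chain:

    1. a linear least-squares fit of protein burst size vs inducer
       concentration yields intercept c and slope s; with n_p proteins per
       mRNA the inducer half-saturation is ``K_ID = (c - n_p) / s`` (the n_p
       offset is the unobservable-burst correction, times n_p);
    2. ``k_rb`` is set so the mean burst duration at the reference
       concentration equals ``target_duration`` (default: 5% of the protein
       lifetime, the longest duration for which burst-frequency inference
       from stationary distributions remains reliable);
    3. ``k_ts`` follows from the fitted intercept and k_rb;
    4. ``k_ro_off`` is the mean observed burst frequency divided by the
       protein lifetime.

    Returns a new :class:`LacRates` with those four rates replaced and the
    free-repressor on-rates rescaled to realize the fitted K_ID.
    """
    if base_rates is None:
        base_rates = LacRates.defaults("TMG")
    conc = np.asarray(table.concentrations, dtype=float)
    sizes = np.asarray(table.protein_burst_sizes, dtype=float)
    if conc.size < 2:
        raise CalibrationError("need at least two concentrations")

    slope, intercept = np.polyfit(conc, sizes, 1)
    n_p = base_rates.proteins_per_mrna
    span = conc.max() - conc.min()
    if slope <= 0 or slope * span <= 1e-6 * abs(intercept):
        raise CalibrationError("non-positive burst-size slope; no inducer "
                               "dependence to calibrate from")
    if intercept <= n_p:
        raise CalibrationError(
            "intercept must exceed the proteins-per-mRNA offset")
    K_ID = (intercept - n_p) / slope

    tau_p = base_rates.tau_p
    if target_duration is None:
        target_duration = target_duration_fraction * tau_p
    # burst_duration(I_ref) = (N_A V / (k_rb R_tot)) * (1 + I_ref/K_ID)
    k_rb = (AVOGADRO * base_rates.V * (1.0 + reference_concentration / K_ID)
            / (base_rates.R_tot * target_duration))
    lambda0 = k_rb * base_rates.R_tot / (AVOGADRO * base_rates.V)
    k_ts = (intercept / n_p - 1.0) * lambda0
    a_mean = float(np.mean(table.frequencies))
    k_ro_off = a_mean / tau_p

    # realize the fitted K_ID by scaling the free-repressor on-rates,
    # keeping the tabulated off-rates and the 2:1 statistical factors
    on_1 = 2.0 * base_rates.inducer_off_free_1 / K_ID
    return replace(
        base_rates,
        k_rb=k_rb, k_ts=k_ts, k_ro_off=k_ro_off, k_iro_off=k_ro_off,
        inducer_on_free_1=on_1, inducer_on_free_2=on_1 / 2.0,
    )
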