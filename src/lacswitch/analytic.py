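"""Closed-form and exactly solvable references for the lac switch.

Three layers:

* steady-state protein laws of the simplified gene-expression models — the
  bursting (negative-binomial / gamma) law and the two-state telegraph law,
  whose stationary PMF is hypergeometric.  The telegraph PMF is evaluated
  through the Euler-integral (Beta-mixture) representation

      P(n) = E_t[ NB(n; alpha, t*b) ],   t ~ Beta(beta, kon+koff-beta),

  where alpha >= beta are the roots of x^2 - (a+kon+koff)x + a*kon = 0.
  A fixed Gauss-Jacobi rule integrates this exactly in the polynomial sense
  and is stable for arbitrarily large counts — no cancellation, no
  hypergeometric recurrences.

* the exact stationary distribution of the operator-repressor subsystem of
  the full lac model (operator state x composition of the free dimer pool),
  a finite Markov chain solved by dense linear algebra, with first-passage
  statistics for complex lifetimes and free intervals;

* exact stationary moments of mRNA and protein driven by that subsystem.
  Because subsystem transitions do not depend on transcript or protein
  counts, the conditional-moment equations close exactly and reduce to five
  linear solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.special import gammaln, logsumexp

from .rates import AVOGADRO, LacRates


# --------------------------------------------------------------------- #
# burst model
# --------------------------------------------------------------------- #

@dataclass
class BurstParams:
    """Burst frequency a (per mean protein lifetime) and size b (proteins)."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("burst parameters must be positive")


def negbin_logpmf(n, params: BurstParams):
    n = np.asarray(n, dtype=float)
    a, b = params.a, params.b
    return (gammaln(a + n) - gammaln(n + 1) - gammaln(a)
            + n * np.log(b / (1.0 + b)) - a * np.log1p(b))


def negbin_pmf(n, params: BurstParams):
    """Stationary protein PMF of the bursting model (negative binomial)."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.exp(negbin_logpmf(n_arr, params))
    return float(out) if np.ndim(n) == 0 else out


def gamma_pdf(x, params: BurstParams):
    """Continuous-count analogue of the bursting law (Gamma density)."""
    a, b = params.a, params.b
    x = np.asarray(x, dtype=float)
    out = np.exp((a - 1.0) * np.log(x) - x / b - a * np.log(b) - gammaln(a))
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------- #
# two-state (telegraph) model
# --------------------------------------------------------------------- #

@dataclass
class TwoStateParams:
    """Telegraph-model parameters in units of the mean protein lifetime.

    a: burst (transcription) rate while active; b: mean proteins per burst;
    k_on_hat: activation rate; k_off_hat: inactivation rate.
    """

    a: float
    b: float
    k_on_hat: float
    k_off_hat: float

    def __post_init__(self):
        if min(self.a, self.b, self.k_on_hat, self.k_off_hat) <= 0:
            raise ValueError("all two-state parameters must be positive")

    @property
    def roots(self):
        """alpha >= beta with alpha+beta = a+kon+koff, alpha*beta = a*kon."""
        s = self.k_on_hat + self.k_off_hat
        disc = np.sqrt((self.a + s) ** 2 - 4.0 * self.a * self.k_on_hat)
        return 0.5 * ((self.a + s) + disc), 0.5 * ((self.a + s) - disc)


def twostate_logpmf(n, params: TwoStateParams, nodes: int = 200):
    """Log stationary protein PMF of the telegraph model."""
    a, b = params.a, params.b
    s = params.k_on_hat + params.k_off_hat
    alpha, beta = params.roots
    # Beta(beta, s - beta) mixture of NB(alpha, t*b); Gauss-Jacobi nodes on
    # weight (1-x)^(s-beta-1) (1+x)^(beta-1), t = (x+1)/2
    x, w = special.roots_jacobi(nodes, s - beta - 1.0, beta - 1.0)
    t = 0.5 * (x + 1.0)
    logw = np.log(w) - (s - 1.0) * np.log(2.0) - special.betaln(beta, s - beta)
    n = np.atleast_1d(np.asarray(n, dtype=float))[:, None]
    tb = t[None, :] * b
    log_nb = (gammaln(alpha + n) - gammaln(n + 1) - gammaln(alpha)
              + n * np.log(tb / (1.0 + tb)) - alpha * np.log1p(tb))
    return logsumexp(log_nb + logw[None, :], axis=1)


def twostate_pmf(n, params: TwoStateParams, nodes: int = 200):
    """Stationary protein PMF of the two-state model, normalized."""
    n_arr = np.atleast_1d(n)
    if np.any(n_arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.exp(twostate_logpmf(n_arr, params, nodes=nodes))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("two-state PMF evaluation failed")
    return float(out[0]) if np.ndim(n) == 0 else out


def twostate_mean(params: TwoStateParams) -> float:
    return (params.a * params.b * params.k_on_hat
            / (params.k_on_hat + params.k_off_hat))


def twostate_cme_oracle(params: TwoStateParams, n_max: int):
    """Brute-force stationary PMF from a truncated master-equation solve.

    Independent of the hypergeometric evaluation path; used to validate it.
    The reduced model: gene toggles on/off; while on, protein bursts arrive
    at rate a with geometric sizes of mean b; proteins decay at rate one.
    """
    a, b = params.a, params.b
    kon, koff = params.k_on_hat, params.k_off_hat
    q = 1.0 / (1.0 + b)
    p = b / (1.0 + b)
    size = 2 * (n_max + 1)
    A = np.zeros((size, size))
    idx = lambda g, n: g * (n_max + 1) + n

    def rate(i, j, r):
        A[j, i] += r
        A[i, i] -= r

    for n in range(n_max + 1):
        rate(idx(0, n), idx(1, n), kon)
        rate(idx(1, n), idx(0, n), koff)
        for g in (0, 1):
            if n > 0:
                rate(idx(g, n), idx(g, n - 1), float(n))
        for j in range(1, n_max - n + 1):
            rate(idx(1, n), idx(1, n + j), a * q * p ** j)
    M = np.vstack([A, np.ones(size)])
    rhs = np.zeros(size + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return pi[:n_max + 1] + pi[n_max + 1:]


# --------------------------------------------------------------------- #
# operator-repressor subsystem of the full model
# --------------------------------------------------------------------- #

_OP_FREE = 0  # operator states: 0=O, 1=RO, 2=IRO, 3=I2RO


def _subsystem_states(r_tot: int):
    states = []
    for op in range(4):
        free = r_tot if op == _OP_FREE else r_tot - 1
        for n_ir in range(free + 1):
            for n_i2 in range(free + 1 - n_ir):
                states.append((op, n_ir, n_i2))
    return states


def _subsystem_generator(I: float, rates: LacRates):
    """Generator matrix Q (Q[i,j] = rate i->j) of the joint chain over
    operator state x free-dimer composition at clamped inducer conc I."""
    r_tot = rates.R_tot
    states = _subsystem_states(r_tot)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    conv = 1.0 / (AVOGADRO * rates.V)

    def add(s_from, s_to, rate):
        if rate > 0.0 and s_to in index:
            i, j = index[s_from], index[s_to]
            Q[i, j] += rate
            Q[i, i] -= rate

    for (op, n_ir, n_i2) in states:
        free = r_tot if op == _OP_FREE else r_tot - 1
        n_r = free - n_ir - n_i2
        s = (op, n_ir, n_i2)
        # inducer exchange on free dimers
        add(s, (op, n_ir + 1, n_i2), rates.inducer_on_free_1 * I * n_r)
        add(s, (op, n_ir - 1, n_i2), rates.inducer_off_free_1 * n_ir)
        add(s, (op, n_ir - 1, n_i2 + 1), rates.inducer_on_free_2 * I * n_ir)
        add(s, (op, n_ir + 1, n_i2 - 1), rates.inducer_off_free_2 * n_i2)
        if op == _OP_FREE:
            add(s, (1, n_ir, n_i2), rates.k_rb * conv * n_r)
            add(s, (2, n_ir - 1, n_i2), rates.k_irb * conv * n_ir)
            add(s, (3, n_ir, n_i2 - 1), rates.k_i2rb * conv * n_i2)
        elif op == 1:
            add(s, (0, n_ir, n_i2), rates.k_ro_off)
            add(s, (2, n_ir, n_i2), rates.inducer_on_cplx_1 * I)
        elif op == 2:
            add(s, (0, n_ir + 1, n_i2), rates.k_iro_off)
            add(s, (1, n_ir, n_i2), rates.inducer_off_cplx_1)
            add(s, (3, n_ir, n_i2), rates.inducer_on_cplx_2 * I)
        else:
            add(s, (0, n_ir, n_i2 + 1), rates.k_i2ro_off)
            add(s, (2, n_ir, n_i2), rates.inducer_off_cplx_2)
    return states, Q


def _stationary(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    M = np.vstack([Q.T, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, residual, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
    if rank < n:
        raise np.linalg.LinAlgError(
            "singular subsystem generator (disconnected chain)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class OperatorSubsystemSolution:
    """Exact stationary description of operator occupancy and dimer pool."""

    states: list
    probabilities: np.ndarray
    f_active: float
    mean_complex_lifetime: float   # s, repressed episode (any bound state)
    mean_free_interval: float      # s, free-operator episode
    burst_frequency: float         # repressor releases per protein lifetime
    inducer_conc: float


def operator_subsystem_solve(I: float, rates: LacRates
                             ) -> OperatorSubsystemSolution:
    """Solve the operator-repressor subsystem exactly at clamped inducer I.

    Valid for the no-positive-feedback variant, where intracellular inducer
    is an external control parameter and the subsystem is autonomous.
    """
    if I < 0:
        raise ValueError("inducer concentration must be >= 0")
    states, Q = _subsystem_generator(I, rates)
    pi = _stationary(Q)
    free = np.array([s[0] == _OP_FREE for s in states])
    f_active = float(pi[free].sum())

    release_rate = np.array(
        [{0: 0.0, 1: rates.k_ro_off, 2: rates.k_iro_off,
          3: rates.k_i2ro_off}[s[0]] for s in states])
    release_flux = float((pi * release_rate).sum())
    burst_freq = release_flux * rates.tau_p

    # first-passage mean times, entered with stationary switching flux
    mean_bound = _mean_episode(Q, states, pi, bound=True)
    mean_free = _mean_episode(Q, states, pi, bound=False)
    return OperatorSubsystemSolution(
        states=states, probabilities=pi, f_active=f_active,
        mean_complex_lifetime=mean_bound, mean_free_interval=mean_free,
        burst_frequency=burst_freq, inducer_conc=I)


def _mean_episode(Q, states, pi, bound: bool) -> float:
    """Mean dwell time of the operator in the bound (or free) set of states,
    averaged over stationary entries into that set."""
    in_set = np.array([(s[0] != _OP_FREE) == bound for s in states])
    idx_in = np.nonzero(in_set)[0]
    idx_out = np.nonzero(~in_set)[0]
    # entry distribution: stationary flux from outside into each inside state
    flux = pi[idx_out] @ Q[np.ix_(idx_out, idx_in)]
    total = flux.sum()
    if total <= 0:
        return np.inf
    entry = flux / total
    # expected absorption time of the chain restricted to the set
    Q_in = Q[np.ix_(idx_in, idx_in)]
    tau = np.linalg.solve(Q_in, -np.ones(idx_in.size))
    return float(entry @ tau)


# --------------------------------------------------------------------- #
# exact stationary moments of mRNA and protein
# --------------------------------------------------------------------- #

@dataclass
class StationaryMoments:
    mean_mrna: float
    var_mrna: float
    mean_protein: float
    var_protein: float
    cov_mrna_protein: float
    fano_mrna: float
    fano_protein: float
    f_active: float
    inducer_conc: float


def stationary_moments(I: float, rates: LacRates,
                       variant: str = "NPF") -> StationaryMoments:
    """Exact first and second stationary moments of mRNA and LacY.

    Only the no-positive-feedback variant is supported: with inducer
    clamped, the operator subsystem evolves independently of transcript and
    protein counts, so conditional moments close exactly.
    """
    if variant != "NPF":
        raise ValueError("exact moments require the NPF variant "
                         "(autonomous operator subsystem)")
    states, Q = _subsystem_generator(I, rates)
    pi = _stationary(Q)
    act = np.array([1.0 if s[0] == _OP_FREE else 0.0 for s in states])
    n = len(states)
    QT = Q.T
    eye = np.eye(n)
    k_ts, k_tl = rates.k_ts, rates.k_tl
    k_m, k_p = rates.k_mdeg, rates.k_pdeg

    birth = k_ts * act * pi
    M = np.linalg.solve(QT - k_m * eye, -birth)
    Y = np.linalg.solve(QT - k_p * eye, -k_tl * M)
    M2 = np.linalg.solve(QT - 2 * k_m * eye,
                         -(k_ts * act * (2 * M + pi) + k_m * M))
    MY = np.linalg.solve(QT - (k_m + k_p) * eye,
                         -(k_ts * act * Y + k_tl * M2))
    Y2 = np.linalg.solve(QT - 2 * k_p * eye,
                         -(k_tl * (2 * MY + M) + k_p * Y))

    mean_m, mean_y = float(M.sum()), float(Y.sum())
    # raw second factorial-style accumulators are E[m^2], E[mY], E[Y^2]
    em2, emy, ey2 = float(M2.sum()), float(MY.sum()), float(Y2.sum())
    var_m = em2 - mean_m ** 2
    var_y = ey2 - mean_y ** 2
    cov = emy - mean_m * mean_y
    return StationaryMoments(
        mean_mrna=mean_m, var_mrna=var_m, mean_protein=mean_y,
        var_protein=var_y, cov_mrna_protein=cov,
        fano_mrna=var_m / mean_m if mean_m > 0 else np.nan,
        fano_protein=var_y / mean_y if mean_y > 0 else np.nan,
        f_active=float((act * pi).sum()), inducer_conc=I)
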