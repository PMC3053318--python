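"""Maximum-likelihood fitting of single-cell count distributions.

Two model classes in the statsmodels mold: construct a model from data,
call ``fit()`` and get a results object carrying point estimates, the
negative log-likelihood, convergence diagnostics, resampling confidence
intervals and a ``summary()`` table.

``BurstModel``
    Negative-binomial stationary law of the bursting picture, parameters
    (a, b) = (burst frequency per protein lifetime, proteins per burst).

``TwoStateModel``
    Telegraph stationary law with parameters (a, b, k_on_hat, k_off_hat).
    Fitting all four parameters freely is ill-conditioned, so the fit runs
    in two stages: (a, b) are first estimated by a negative-binomial fit to
    a fully induced reference distribution (the telegraph law reduces to a
    negative binomial when the gene is always active), then the switching
    rates are fitted with (a, b) allowed to move only +/-5%.  The
    higher-likelihood of the constrained and reference-free fits is
    returned.

Optimization is downhill simplex in log-parameter space (positivity for
free), with multi-starts around moment-based initial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .analytic import (BurstParams, TwoStateParams, negbin_logpmf,
                       twostate_logpmf)
from .countdist import CountDistribution

_SIMPLEX_OPTS = dict(xatol=1e-6, fatol=1e-8, maxiter=2000)


def _as_counts(data) -> np.ndarray:
    if isinstance(data, CountDistribution):
        return data.protein
    return np.asarray(data, dtype=np.int64)


# --------------------------------------------------------------------- #
# results
# --------------------------------------------------------------------- #

@dataclass
class FitResults:
    """Point estimates and diagnostics of one maximum-likelihood fit."""

    model_kind: str
    params: dict
    nll: float
    converged: bool
    n_cells: int
    ci: dict = field(default_factory=dict)   # name -> (lo, hi, level)
    metadata: dict = field(default_factory=dict)

    def __getattr__(self, name):
        params = object.__getattribute__(self, "params")
        if name in params:
            return params[name]
        raise AttributeError(name)

    def summary(self) -> str:
        lines = [
            f"{self.model_kind} maximum-likelihood fit",
            "=" * 46,
            f"{'n cells':<18}{self.n_cells}",
            f"{'neg. log-lik.':<18}{self.nll:.4f}",
            f"{'converged':<18}{self.converged}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'95% CI':>20}",
        ]
        for name, value in self.params.items():
            if name in self.ci:
                lo, hi, _ = self.ci[name]
                ci_txt = f"[{lo:.4g}, {hi:.4g}]"
            else:
                ci_txt = "-"
            lines.append(f"{name:<12}{value:>12.4g}{ci_txt:>20}")
        return "\n".join(lines)

    def to_record(self) -> dict:
        return {
            "model": self.model_kind,
            "params": self.params,
            "nll": self.nll,
            "converged": self.converged,
            "n_cells": self.n_cells,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "metadata": self.metadata,
        }


# --------------------------------------------------------------------- #
# burst (negative-binomial) model
# --------------------------------------------------------------------- #

class BurstModel:
    """Negative-binomial model of stationary protein counts."""

    param_names = ("a", "b")

    def __init__(self, data):
        self.counts = _as_counts(data)
        if self.counts.size < 10:
            raise ValueError("need at least 10 cells to fit")
        if np.all(self.counts == self.counts[0]):
            raise ValueError("degenerate data: all counts identical")
        self.data = data if isinstance(data, CountDistribution) else None
        self._unique, self._weights = np.unique(self.counts,
                                                return_counts=True)

    def _nll(self, log_theta) -> float:
        a, b = np.exp(log_theta)
        try:
            lp = negbin_logpmf(self._unique, BurstParams(a, b))
        except (ValueError, FloatingPointError):
            return np.inf
        return -float((self._weights * lp).sum())

    def _moment_start(self):
        m = self.counts.mean()
        v = self.counts.var()
        b0 = max(v / max(m, 1e-9) - 1.0, 1e-3)
        a0 = max(m / b0, 1e-3)
        return np.log([a0, b0])

    def fit(self, n_starts: int = 5, seed: int = 0) -> FitResults:
        rng = np.random.default_rng(seed)
        x0 = self._moment_start()
        best = None
        for k in range(n_starts):
            start = x0 if k == 0 else x0 + rng.normal(0, 0.5, size=2)
            res = minimize(self._nll, start, method="Nelder-Mead",
                           options=_SIMPLEX_OPTS)
            if best is None or res.fun < best.fun:
                best = res
        a, b = np.exp(best.x)
        meta = dict(self.data.metadata) if self.data else {}
        return FitResults(model_kind="burst",
                          params={"a": float(a), "b": float(b)},
                          nll=float(best.fun), converged=bool(best.success),
                          n_cells=self.counts.size, metadata=meta)


def fit_burst(data) -> FitResults:
    """Convenience wrapper: fit the bursting law to a count distribution."""
    return BurstModel(data).fit()


# --------------------------------------------------------------------- #
# two-state model
# --------------------------------------------------------------------- #

class TwoStateModel:
    """Telegraph model of stationary protein counts.

    ``induced_reference`` supplies counts from a (near-)fully induced
    condition; the first fitting stage estimates (a, b) from it.  If it is
    omitted the data themselves serve as the reference, which is only
    appropriate for nearly always-active genes.

    The likelihood is evaluated on the unique observed counts, weighted by
    multiplicity, which keeps each simplex iteration cheap on large cell
    ensembles.
    """

    param_names = ("a", "b", "k_on_hat", "k_off_hat")

    def __init__(self, data, induced_reference=None, ab_band: float = 0.05,
                 reference_ab: tuple | None = None):
        self.counts = _as_counts(data)
        if self.counts.size < 10:
            raise ValueError("need at least 10 cells to fit")
        self.reference = (_as_counts(induced_reference)
                          if induced_reference is not None else self.counts)
        self.ab_band = ab_band
        self.reference_ab = reference_ab  # precomputed stage-1 (a, b)
        self.data = data if isinstance(data, CountDistribution) else None
        self._unique, self._weights = np.unique(self.counts,
                                                return_counts=True)

    #: log-parameter box keeping the optimizer off degenerate ridges
    #: (a -> inf, b -> 0 approaches a Poisson mixture of equal likelihood)
    _LOG_BOUNDS = (np.log(1e-3), np.log(1e4))

    def _nll(self, theta_log, a_fixed=None, b_fixed=None) -> float:
        lo, hi = self._LOG_BOUNDS
        if np.any(theta_log < lo) or np.any(theta_log > hi):
            return np.inf
        try:
            if a_fixed is None:
                a, b, kon, koff = np.exp(theta_log)
            else:
                kon, koff = np.exp(theta_log)
                a, b = a_fixed, b_fixed
            lp = twostate_logpmf(self._unique,
                                 TwoStateParams(a, b, kon, koff),
                                 nodes=128)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return np.inf
        nll = -float((self._weights * lp).sum())
        return nll if np.isfinite(nll) else np.inf

    def fit(self, n_starts: int = 3, seed: int = 0,
            compare_all_free: bool = False) -> FitResults:
        """Two-stage constrained maximum-likelihood fit.

        With ``compare_all_free`` an unconstrained four-parameter fit is
        also run and the higher-likelihood result returned.  It is off by
        default: the unconstrained likelihood has a weak-identifiability
        ridge (burst rate to infinity, burst size to zero at fixed product
        — the Poisson-mixture corner of the telegraph law) along which the
        likelihood gain is negligible but the parameters lose their
        burst interpretation; the two-stage constraint exists to keep fits
        off that ridge.
        """
        rng = np.random.default_rng(seed)
        # stage 1: negative-binomial fit to the induced reference
        if self.reference_ab is not None:
            a1, b1 = self.reference_ab
        else:
            stage1 = BurstModel(self.reference).fit()
            a1, b1 = stage1.params["a"], stage1.params["b"]

        # stage 2a: switching rates only, (a, b) pinned to stage 1
        starts = [(1.0, 1.0), (5.0, 0.5), (0.5, 5.0)]
        best2a = None
        for k, (k0, k1) in enumerate(starts[:max(1, n_starts)]):
            s = np.log([k0, k1])
            if k > 0:
                s = s + rng.normal(0, 0.3, 2)
            res = minimize(self._nll, s, args=(a1, b1),
                           method="Nelder-Mead", options=_SIMPLEX_OPTS)
            if best2a is None or res.fun < best2a.fun:
                best2a = res

        # stage 2b: let (a, b) move inside the +/- band around stage 1
        lo = np.log1p(-self.ab_band)
        hi = np.log1p(self.ab_band)

        def nll_banded(x):
            da, db, lkon, lkoff = x
            if not (lo <= da <= hi and lo <= db <= hi):
                return np.inf
            return self._nll(np.array([lkon, lkoff]),
                             a_fixed=a1 * np.exp(da),
                             b_fixed=b1 * np.exp(db))

        best_x = np.concatenate([[0.0, 0.0], best2a.x])
        best_fun, best_ok = best2a.fun, best2a.success
        best = minimize(nll_banded, best_x, method="Nelder-Mead",
                        options=_SIMPLEX_OPTS)
        if best.fun <= best2a.fun:
            best_x, best_fun, best_ok = best.x, best.fun, best.success
        da, db, lkon, lkoff = best_x
        params = {
            "a": float(a1 * np.exp(np.clip(da, lo, hi))),
            "b": float(b1 * np.exp(np.clip(db, lo, hi))),
            "k_on_hat": float(np.exp(lkon)),
            "k_off_hat": float(np.exp(lkoff)),
        }
        kind = "two-state"
        nll = float(best_fun)

        if compare_all_free:
            x0 = np.log([params["a"], params["b"], params["k_on_hat"],
                         params["k_off_hat"]])
            free = minimize(self._nll, x0, method="Nelder-Mead",
                            options=_SIMPLEX_OPTS)
            if free.fun < nll - 1e-6:
                a, b, kon, koff = np.exp(free.x)
                params = {"a": float(a), "b": float(b),
                          "k_on_hat": float(kon), "k_off_hat": float(koff)}
                nll = float(free.fun)
                kind = "two-state(all-free)"
                best_ok = free.success
        meta = dict(self.data.metadata) if self.data else {}
        return FitResults(model_kind=kind, params=params, nll=nll,
                          converged=bool(best_ok),
                          n_cells=self.counts.size, metadata=meta)


def fit_twostate(data, induced_reference) -> FitResults:
    """Two-stage constrained telegraph fit (see :class:`TwoStateModel`)."""
    return TwoStateModel(data, induced_reference=induced_reference).fit()


# --------------------------------------------------------------------- #
# resampling confidence intervals
# --------------------------------------------------------------------- #

def resample_ci(data, model_factory, subset_size: int,
                n_resamples: int = 1000, level: float = 0.95,
                seed: int = 0, max_failures: float = 0.2,
                fit_kwargs: dict | None = None):
    """Subsampling confidence intervals for fitted parameters.

    Draws ``n_resamples`` random subsets of ``subset_size`` cells (without
    replacement within each subset), refits with ``model_factory(counts)``,
    and returns per-parameter central-``level`` quantile bands as
    ``{name: (lo, hi, level)}``.
    """
    counts = _as_counts(data)
    if subset_size > counts.size:
        raise ValueError("subset_size exceeds the number of cells")
    rng = np.random.default_rng(seed)
    fit_kwargs = {"n_starts": 1} if fit_kwargs is None else fit_kwargs
    estimates = []
    failures = 0
    for _ in range(n_resamples):
        sub = rng.choice(counts, size=subset_size, replace=False)
        try:
            fit = model_factory(sub).fit(**fit_kwargs)
            estimates.append([fit.params[p] for p in sorted(fit.params)])
            names = sorted(fit.params)
        except Exception:
            failures += 1
    if failures > max_failures * n_resamples:
        raise RuntimeError(
            f"{failures}/{n_resamples} resample fits failed")
    est = np.array(estimates)
    alpha = (1.0 - level) / 2.0
    out = {}
    for j, name in enumerate(names):
        col = est[:, j][~np.isnan(est[:, j])]  # +/-inf are legitimate limits
        if col.size == 0:
            out[name] = (np.nan, np.nan, level)
            continue
        lo, hi = np.quantile(col, [alpha, 1.0 - alpha])
        out[name] = (float(lo), float(hi), level)
    return out
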