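"""Quick-look plots for curves, fits and landscapes.

Matplotlib is imported lazily so headless pipelines that never plot do
not pay for a backend.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_grf(curve, fit=None, ax=None):
    """Mean LacY vs inducer concentration, with an optional Hill overlay."""
    ax = _axes(ax)
    conc = curve.concentrations * 1e6
    ax.plot(conc, curve.mean, "o", label="model")
    if fit is not None:
        grid = np.logspace(np.log10(max(conc[conc > 0].min(), 1e-2)),
                           np.log10(conc.max()), 200)
        I = grid * 1e-6
        y = fit.y_min + (fit.y_max - fit.y_min) * I ** fit.n_hill / (
            fit.K_half ** fit.n_hill + I ** fit.n_hill)
        ax.plot(grid, y, "-", label=(f"Hill: K={fit.K_half * 1e6:.0f} uM, "
                                     f"n={fit.n_hill:.2f}"))
    ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel("inducer (uM)")
    ax.set_ylabel("mean LacY per cell")
    ax.legend()
    return ax


def plot_fano(curve, ax=None):
    """Fano factor of the stationary LacY distribution vs inducer."""
    ax = _axes(ax)
    ax.plot(curve.concentrations * 1e6, curve.fano, "o-")
    ax.axhline(1.0, ls=":", color="gray", lw=1)
    ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel("inducer (uM)")
    ax.set_ylabel("Fano factor (var/mean)")
    return ax


def plot_count_fit(data, fit, ax=None, bins=60):
    """Histogram of per-cell counts with the fitted stationary law."""
    from .analytic import (BurstParams, TwoStateParams, negbin_pmf,
                           twostate_pmf)
    ax = _axes(ax)
    counts = data.protein if hasattr(data, "protein") else np.asarray(data)
    ax.hist(counts, bins=bins, density=True, alpha=0.5, label="cells")
    n = np.arange(0, counts.max() + 1)
    if fit.model_kind.startswith("two-state") and np.isfinite(
            fit.params.get("k_on_hat", np.inf)):
        pmf = twostate_pmf(n, TwoStateParams(
            fit.params["a"], fit.params["b"], fit.params["k_on_hat"],
            fit.params["k_off_hat"]))
    else:
        pmf = negbin_pmf(n, BurstParams(fit.params["a"], fit.params["b"]))
    ax.plot(n, pmf, "-", label=fit.model_kind)
    ax.set_xlabel("protein count")
    ax.set_ylabel("probability")
    ax.legend()
    return ax


def plot_landscape(landscape, ax=None):
    """-ln P over the (protein, mRNA) plane."""
    ax = _axes(ax)
    im = ax.pcolormesh(landscape.protein_edges, landscape.mrna_edges,
                       landscape.neg_log_p, shading="auto",
                       cmap="viridis_r")
    ax.figure.colorbar(im, ax=ax, label=r"$-\ln P$")
    ax.set_xlabel("protein count")
    ax.set_ylabel("mRNA count")
    return ax
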