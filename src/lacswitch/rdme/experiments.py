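"""Crowding, rebinding, and localization experiments on the lattice.

These use dedicated single-particle walkers (rather than the count-grid
RDME sweep) because they need individual trajectories: repressor rebinding
statistics after unbinding, mean-squared-displacement/anomalous-exponent
analysis in a crowded volume, and mRNA membrane-contact dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..rates import AVOGADRO, LacRates
from .geometry import (CellGeometry, ObstacleSpec, fast_growth_obstacles,
                       place_obstacles)
from .lattice import (Lattice, SITE_CYTOPLASM, SITE_MEMBRANE, SITE_NUCLEOID,
                      SITE_OBSTACLE, SITE_OPERATOR, discretize)


# --------------------------------------------------------------------- #
# MSD analysis
# --------------------------------------------------------------------- #

def msd_analysis(tracks: np.ndarray, dt: float, n_lags: int = 40,
                 min_tracks: int = 100):
    """Time-resolved apparent diffusion and anomalous exponent.

    ``tracks``: (n_tracks, n_steps+1, 3) positions in um (or nm —
    D_obs comes out in those units squared per second).  Returns a dict
    with log-spaced lag times, MSD, ``D_obs(t) = MSD/(6 t)`` and the local
    log-log slope ``alpha(t)``.
    """
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[0] < min_tracks:
        raise ValueError(f"need at least {min_tracks} tracks")
    n_steps = tracks.shape[1] - 1
    lags = np.unique(np.round(np.logspace(
        0, np.log10(n_steps), n_lags)).astype(int))
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        disp = tracks[:, lag:, :] - tracks[:, :-lag or None, :]
        # time-and-ensemble average
        msd[i] = np.mean(np.sum(disp ** 2, axis=2))
    t = lags * dt
    d_obs = msd / (6.0 * t)
    log_t = np.log(t)
    log_m = np.log(msd)
    # local log-log slope by windowed least squares (smoother than a
    # two-point gradient at long lags where few displacements remain)
    half = 2
    alpha = np.empty(lags.size)
    for i in range(lags.size):
        sl = slice(max(0, i - half), min(lags.size, i + half + 1))
        A = np.vstack([log_t[sl], np.ones(log_t[sl].size)]).T
        alpha[i] = np.linalg.lstsq(A, log_m[sl], rcond=None)[0][0]
    return {"t": t, "msd": msd, "D_obs": d_obs, "alpha": alpha}


# --------------------------------------------------------------------- #
# repressor rebinding after unbinding
# --------------------------------------------------------------------- #

@dataclass
class RebindResult:
    packing_fraction: float
    n_trajectories: int
    n_rebinds: int
    n_escapes: int
    escape_times: np.ndarray
    rebind_probability: float
    msd: dict | None = None
    metadata: dict = field(default_factory=dict)


@njit(cache=True)
def _rebind_walker(blocked, start, center, escape_r2, p_move, p_react,
                   max_steps, seed):
    """Walk one repressor from ``start``; returns (outcome, steps).

    outcome 1 = rebind at the operator (center) site, 0 = escaped past the
    escape radius, -1 = step budget exhausted.
    """
    np.random.seed(seed)
    nx, ny, nz = blocked.shape
    x, y, z = start[0], start[1], start[2]
    cx, cy, cz = center[0], center[1], center[2]
    for step in range(max_steps):
        if x == cx and y == cy and z == cz:
            if np.random.random() < p_react:
                return 1, step
        u = np.random.random()
        if u < p_move:
            d = int(u / p_move * 6.0)
            tx, ty, tz = x, y, z
            if d == 0:
                tx += 1
            elif d == 1:
                tx -= 1
            elif d == 2:
                ty += 1
            elif d == 3:
                ty -= 1
            elif d == 4:
                tz += 1
            else:
                tz -= 1
            if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz \
                    and not blocked[tx, ty, tz]:
                x, y, z = tx, ty, tz
        dx, dy, dz = x - cx, y - cy, z - cz
        if dx * dx + dy * dy + dz * dz >= escape_r2:
            return 0, step
    return -1, max_steps


@njit(cache=True)
def _crowded_tracks(blocked, starts, p_move, n_steps, n_tracks, seed):
    """Periodic-boundary single-particle tracks in a crowded box (nm)."""
    np.random.seed(seed)
    nx, ny, nz = blocked.shape
    out = np.zeros((n_tracks, n_steps + 1, 3))
    for k in range(n_tracks):
        x, y, z = starts[k, 0], starts[k, 1], starts[k, 2]
        ux, uy, uz = 0, 0, 0  # unwrapped offsets in lattice units
        out[k, 0, 0] = 0.0
        for step in range(1, n_steps + 1):
            u = np.random.random()
            if u < p_move:
                d = int(u / p_move * 6.0)
                sx, sy, sz = 0, 0, 0
                if d == 0:
                    sx = 1
                elif d == 1:
                    sx = -1
                elif d == 2:
                    sy = 1
                elif d == 3:
                    sy = -1
                elif d == 4:
                    sz = 1
                else:
                    sz = -1
                tx = (x + sx) % nx
                ty = (y + sy) % ny
                tz = (z + sz) % nz
                if not blocked[tx, ty, tz]:
                    x, y, z = tx, ty, tz
                    ux += sx
                    uy += sy
                    uz += sz
            out[k, step, 0] = ux
            out[k, step, 1] = uy
            out[k, step, 2] = uz
    return out


def _crowded_box(box_nm: float, spacing: float, packing: float,
                 spec: ObstacleSpec | None, seed: int) -> np.ndarray:
    """Boolean blocked-site mask for a cubic crowded volume.

    Obstacles are excluded from a one-lattice-spacing ball around the
    central operator site: the repressor was bound there an instant
    earlier, so the site and its immediate neighborhood are sterically
    open by construction.
    """
    n = int(round(box_nm / spacing))
    blocked = np.zeros((n, n, n), dtype=np.bool_)
    if packing <= 0:
        return blocked
    if spec is None:
        spec = fast_growth_obstacles()
    vol = box_nm ** 3
    sub = spec.scaled_to_volume(vol, packing=packing)
    lo = np.zeros(3)
    hi = np.full(3, box_nm)
    center_nm = np.full(3, box_nm / 2.0)
    dummy = CellGeometry(shape="box", length=box_nm, diameter=box_nm,
                         operator_position=center_nm)
    centers, radii, _ = place_obstacles(
        dummy, sub, seed=seed, region=(lo, hi),
        keep_clear=(center_nm, 2.0 * spacing))
    # mark lattice sites whose center lies inside any obstacle sphere,
    # sphere by sphere over its bounding sub-box
    for c, r in zip(centers, radii):
        i0 = np.maximum(((c - r) / spacing - 0.5).astype(int), 0)
        i1 = np.minimum(((c + r) / spacing + 0.5).astype(int) + 1, n)
        axes = [((np.arange(i0[d], i1[d]) + 0.5) * spacing - c[d]) ** 2
                for d in range(3)]
        d2 = (axes[0][:, None, None] + axes[1][None, :, None]
              + axes[2][None, None, :])
        blocked[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    mid = n // 2
    blocked[mid, mid, mid] = False
    return blocked


def rebind_experiment(packing_fraction: float, n_traj: int = 5000,
                      spacing: float = 2.0, dt: float = 5e-9,
                      escape_radius: float = 64.0, box_nm: float = 160.0,
                      D_free: float = 1.0, k_rb: float = 2.43e6,
                      seed: int = 0, msd_tracks: int = 200,
                      msd_steps: int = 20000) -> RebindResult:
    """Repressor rebinding versus escape after an unbinding event.

    Each trajectory starts one lattice site from the operator (the
    just-unbound configuration) and runs until the repressor either reacts
    at the operator site (rate ``k_rb`` converted to the mesoscopic
    per-visit rate) or crosses ``escape_radius`` into bulk.  Control runs
    without the operator reaction provide D_obs(t) and alpha(t).

    ``D_free`` is the repressor diffusion coefficient in um^2/s.
    """
    if not 0.0 <= packing_fraction <= 0.55:
        raise ValueError("packing fraction must lie in [0, 0.55]")
    blocked = _crowded_box(box_nm, spacing, packing_fraction, None, seed)
    n = blocked.shape[0]
    mid = n // 2
    center = np.array([mid, mid, mid], dtype=np.int64)
    start = center + np.array([1, 0, 0])
    p_move = min(1.0, 6.0 * D_free * dt / (spacing * 1e-3) ** 2)
    v_site = spacing ** 3 * 1e-24
    k_site = k_rb / (AVOGADRO * v_site)          # per second at the site
    p_react = min(1.0, k_site * dt)
    escape_r2 = (escape_radius / spacing) ** 2

    seeds = np.random.SeedSequence(seed).generate_state(n_traj + 1)
    n_rebind = 0
    escapes = []
    max_steps = 200_000_000
    for i in range(n_traj):
        outcome, steps = _rebind_walker(
            blocked, start, center, escape_r2, p_move, p_react,
            max_steps, int(seeds[i] % 2 ** 31))
        if outcome == 1:
            n_rebind += 1
        elif outcome == 0:
            escapes.append(steps * dt)
    msd = None
    if msd_tracks > 0:
        # controls start at random free sites so the MSD reflects the
        # percolating void space, not one particular pocket
        rng = np.random.default_rng(seeds[-1])
        free = np.argwhere(~blocked)
        starts = free[rng.integers(0, free.shape[0], msd_tracks)]
        tracks = _crowded_tracks(blocked, starts.astype(np.int64), p_move,
                                 msd_steps, msd_tracks,
                                 int(seeds[-1] % 2 ** 31))
        msd = msd_analysis(tracks * spacing * 1e-3, dt,
                           min_tracks=min(100, msd_tracks))
    return RebindResult(
        packing_fraction=packing_fraction, n_trajectories=n_traj,
        n_rebinds=n_rebind, n_escapes=len(escapes),
        escape_times=np.array(escapes),
        rebind_probability=n_rebind / n_traj, msd=msd,
        metadata={"spacing_nm": spacing, "dt_s": dt, "box_nm": box_nm,
                  "escape_radius_nm": escape_radius, "D_free": D_free,
                  "seed": seed})


# --------------------------------------------------------------------- #
# mRNA localization
# --------------------------------------------------------------------- #

@njit(cache=True)
def _walk_to_membrane(site_type, start, p_move, allow_nucleoid, max_steps,
                      seed):
    """Walk from start until the particle stands on a membrane site."""
    np.random.seed(seed)
    nx, ny, nz = site_type.shape
    x, y, z = start[0], start[1], start[2]
    for _ in range(max_steps):
        if site_type[x, y, z] == SITE_MEMBRANE:
            return x, y, z
        u = np.random.random()
        if u < p_move:
            d = int(u / p_move * 6.0)
            tx, ty, tz = x, y, z
            if d == 0:
                tx += 1
            elif d == 1:
                tx -= 1
            elif d == 2:
                ty += 1
            elif d == 3:
                ty -= 1
            elif d == 4:
                tz += 1
            else:
                tz -= 1
            if tx < 0 or tx >= nx or ty < 0 or ty >= ny \
                    or tz < 0 or tz >= nz:
                continue
            st = site_type[tx, ty, tz]
            if st == SITE_OBSTACLE or st == 0:   # obstacle / extracellular
                continue
            if st == SITE_NUCLEOID and not allow_nucleoid:
                continue
            x, y, z = tx, ty, tz
    return -1, -1, -1


def mrna_localization_experiment(geometry: CellGeometry, n_mrna: int = 200,
                                 spacing: float = 32.0, D_mrna: float = 0.1,
                                 seed: int = 0) -> np.ndarray:
    """First membrane-contact positions of transcripts released at the
    operator.

    Transcripts diffuse at ``D_mrna`` um^2/s through the cytoplasm — barred
    from the condensed nucleoid when the geometry has one — until they
    first stand on a membrane site.  Returns axial (long-axis) contact
    coordinates in nm, cell-centered.  With ``D_mrna = 0`` every contact is
    the membrane site nearest the operator.
    """
    lat = discretize(geometry, spacing=spacing, dt=1.0)
    site = lat.site_type
    origin = np.array(lat.metadata["origin_nm"])
    start = np.array(lat.operator_site, dtype=np.int64)
    allow_nucleoid = geometry.nucleoid is None
    if D_mrna > 0:
        dt = (spacing * 1e-3) ** 2 / (6.0 * D_mrna)  # p_move = 1
        p_move = 1.0
        max_steps = 20_000_000
    else:
        # deterministic fall to the nearest membrane site
        mem = np.argwhere(site == SITE_MEMBRANE)
        d2 = np.sum((mem - start) ** 2, axis=1)
        nearest = mem[np.argmin(d2)]
        xs = np.full(n_mrna, (nearest[0] + 0.5) * spacing + origin[0])
        return xs
    seeds = np.random.SeedSequence(seed).generate_state(n_mrna)
    xs = np.empty(n_mrna)
    for i in range(n_mrna):
        x, y, z = _walk_to_membrane(site, start, p_move, allow_nucleoid,
                                    max_steps, int(seeds[i] % 2 ** 31))
        if x < 0:
            raise RuntimeError("transcript failed to reach the membrane")
        xs[i] = (x + 0.5) * spacing + origin[0]
    return xs
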