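"""Typed-site voxel lattice and the multiparticle reaction-diffusion step.

Space is discretized into cubic voxels of uniform spacing, each carrying a
site type (extracellular, membrane, cytoplasm, nucleoid, obstacle,
operator).  Particles live as per-species count grids.  Each time step
alternates a multiparticle diffusion sweep (every particle attempts a move
to one of six neighbors with probability ``6 D dt / spacing^2`` total;
moves into forbidden or full sites are rejected) and a per-site reaction
sweep with site-type-restricted stochastic rates.  The scheme emulates the
observable behavior of lattice-microbe style RDME operators: exact in the
well-stirred fast-diffusion limit and diffusion-limited otherwise.

The lattice Courant-like bound ``D <= spacing^2 / (6 dt)`` is enforced for
every (species, site type) pair before a run starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..rates import AVOGADRO
from .geometry import CellGeometry

SITE_EXTRACELLULAR = 0
SITE_MEMBRANE = 1
SITE_CYTOPLASM = 2
SITE_NUCLEOID = 3
SITE_OBSTACLE = 4
SITE_OPERATOR = 5

_SITE_NAMES = {0: "extracellular", 1: "membrane", 2: "cytoplasm",
               3: "nucleoid", 4: "obstacle", 5: "operator"}


class LatticeError(RuntimeError):
    pass


@dataclass
class LatticeReaction:
    """Site-restricted stochastic reaction on the lattice.

    ``order`` 1: A -> products at rate k (s^-1).
    ``order`` 2: A + B -> products; k is molar and converted to the
    per-site mesoscopic rate k/(N_A * V_site) applied to co-occupants.
    ``sites``: allowed site types (None = anywhere the reactants sit).
    """

    name: str
    reactants: tuple
    products: tuple
    rate: float
    order: int
    sites: tuple | None = None


@dataclass
class Lattice:
    spacing: float                  # nm
    dt: float                       # s
    site_type: np.ndarray           # (nx, ny, nz) uint8
    species: list
    diffusion: dict                 # (species, site_type) -> D in um^2/s
    reactions: list = field(default_factory=list)
    capacity: int = 8
    operator_site: tuple | None = None
    counts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.site_type.shape

    @property
    def site_volume_liters(self) -> float:
        return self.spacing ** 3 * 1e-24  # nm^3 -> L

    def zero_counts(self):
        for s in self.species:
            self.counts[s] = np.zeros(self.shape, dtype=np.int32)

    def place(self, species: str, index: tuple, n: int = 1):
        if species not in self.counts:
            self.zero_counts()
        self.counts[species][index] += n

    def total(self, species: str) -> int:
        return int(self.counts[species].sum())

    def max_diffusion(self) -> float:
        """Largest representable diffusion coefficient (um^2/s)."""
        return (self.spacing * 1e-3) ** 2 / (6.0 * self.dt)

    def check_courant(self):
        cap = self.max_diffusion()
        for (sp, st), d in self.diffusion.items():
            if d > cap * (1 + 1e-12):
                raise LatticeError(
                    f"D={d} um^2/s for {sp} on {_SITE_NAMES.get(st)} exceeds "
                    f"the lattice bound {cap:.4g} um^2/s "
                    f"(spacing {self.spacing} nm, dt {self.dt} s)")


def _site_volume_liters(spacing_nm: float) -> float:
    return spacing_nm ** 3 * 1e-24


# --------------------------------------------------------------------- #
# discretization
# --------------------------------------------------------------------- #

def discretize(geometry: CellGeometry, obstacles=None, spacing: float = 16.0,
               dt: float = 50e-6, species=(), diffusion=None,
               capacity: int = 8, pad: int = 2,
               subsample: int = 2) -> Lattice:
    """Coarse-grain a continuous cell model onto a voxel lattice.

    Per-voxel type by a majority volume-overlap rule (estimated on a
    ``subsample^3`` sub-grid per voxel): obstacle > nucleoid > cytoplasm,
    with a one-voxel membrane shell where inside meets outside.  The
    operator maps to exactly one site; an obstacle landing on it is
    evicted (the caller's obstacle list is not modified).
    """
    if spacing not in (2.0, 4.0, 8.0, 16.0, 32.0):
        raise ValueError("supported spacings: 2, 4, 8, 16, 32 nm")
    r = geometry.radius
    half = geometry.length / 2.0
    lo = np.array([-half, -r, -r]) - pad * spacing
    n_vox = np.ceil((np.array([half, r, r]) * 2 + 2 * pad * spacing)
                    / spacing).astype(int)
    # sub-voxel sample offsets
    offs = (np.arange(subsample) + 0.5) / subsample
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    sub = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])

    ix = np.arange(n_vox[0])
    iy = np.arange(n_vox[1])
    iz = np.arange(n_vox[2])
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    corners = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * spacing
    corners += lo

    inside_votes = np.zeros(corners.shape[0], dtype=np.int32)
    nucleoid_votes = np.zeros_like(inside_votes)
    for s in sub:
        pts = corners + s * spacing
        inside_votes += geometry.contains(pts).astype(np.int32)
        nucleoid_votes += geometry.in_nucleoid(pts).astype(np.int32)
    n_sub = sub.shape[0]
    inside = (inside_votes * 2 > n_sub).reshape(n_vox)
    nucleoid = (nucleoid_votes * 2 > n_sub).reshape(n_vox)

    site = np.full(n_vox, SITE_EXTRACELLULAR, dtype=np.uint8)
    site[inside] = SITE_CYTOPLASM
    site[inside & nucleoid] = SITE_NUCLEOID
    # membrane: inside voxels adjacent to an outside voxel
    shell = np.zeros(n_vox, dtype=bool)
    for ax in range(3):
        for d in (-1, 1):
            shifted = np.roll(~inside, d, axis=ax)
            # roll wraps; edges of the padded box are outside anyway
            shell |= inside & shifted
    site[shell] = SITE_MEMBRANE

    op_idx = tuple(((geometry.operator_position - lo) // spacing).astype(int))

    if obstacles is not None:
        centers, radii = obstacles[0], obstacles[1]
        vox = ((centers - lo) // spacing).astype(int)
        frac_covered = np.clip(radii / spacing, 0.0, None)
        for (v, rr) in zip(vox, radii):
            v = tuple(np.clip(v, 0, n_vox - 1))
            if v == op_idx:
                continue  # operator site stays reactive
            if site[v] in (SITE_CYTOPLASM, SITE_NUCLEOID):
                # majority rule: mark obstacle when the sphere covers most
                # of the voxel, or accumulate sub-voxel spheres
                if (4.0 / 3.0) * np.pi * rr ** 3 >= 0.5 * spacing ** 3:
                    site[v] = SITE_OBSTACLE
        # sub-voxel spheres: aggregate volume per voxel
        small = (4.0 / 3.0) * np.pi * radii ** 3 < 0.5 * spacing ** 3
        if np.any(small):
            acc = np.zeros(n_vox)
            np.add.at(acc, tuple(vox[small].T),
                      (4.0 / 3.0) * np.pi * radii[small] ** 3)
            fill = acc >= 0.5 * spacing ** 3
            fill &= (site == SITE_CYTOPLASM) | (site == SITE_NUCLEOID)
            fill[op_idx] = False
            site[fill] = SITE_OBSTACLE

    if site[op_idx] in (SITE_EXTRACELLULAR, SITE_MEMBRANE):
        raise LatticeError("operator voxel fell outside the cytoplasm")
    site[op_idx] = SITE_OPERATOR

    lat = Lattice(spacing=spacing, dt=dt, site_type=site,
                  species=list(species), diffusion=dict(diffusion or {}),
                  capacity=capacity, operator_site=op_idx,
                  metadata={"origin_nm": lo.tolist(),
                            "phenotype": geometry.metadata.get("phenotype")})
    lat.zero_counts()
    return lat


# --------------------------------------------------------------------- #
# stepping kernels
# --------------------------------------------------------------------- #

@njit(cache=True)
def _diffuse_species(counts, occupancy, site_type, allowed, p_move, capacity,
                     seed):
    """One diffusion sweep for one species (in place).

    ``allowed``: bool per site type; ``p_move``: per-site-type total move
    probability (split over six neighbors).  Blocked moves are rejected.
    """
    np.random.seed(seed)
    nx, ny, nz = counts.shape
    moved = np.zeros_like(counts)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                n = counts[x, y, z]
                if n == 0:
                    continue
                st = site_type[x, y, z]
                p = p_move[st]
                if p <= 0.0:
                    continue
                for _ in range(n):
                    u = np.random.random()
                    if u >= p:
                        continue
                    d = int(u / p * 6.0)
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
                    tst = site_type[tx, ty, tz]
                    if not allowed[tst]:
                        continue
                    if occupancy[tx, ty, tz] >= capacity:
                        continue
                    counts[x, y, z] -= 1
                    moved[tx, ty, tz] += 1
                    occupancy[x, y, z] -= 1
                    occupancy[tx, ty, tz] += 1
    counts += moved


@njit(cache=True)
def _first_order(counts_a, site_type, site_ok, p_react, seed):
    """Number of A->... events per site this step (binomial thinning)."""
    np.random.seed(seed)
    nx, ny, nz = counts_a.shape
    events = np.zeros_like(counts_a)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                n = counts_a[x, y, z]
                if n == 0 or not site_ok[site_type[x, y, z]]:
                    continue
                k = 0
                for _ in range(n):
                    if np.random.random() < p_react:
                        k += 1
                events[x, y, z] = k
    return events


@njit(cache=True)
def _second_order(counts_a, counts_b, same, site_type, site_ok, p_pair, seed):
    np.random.seed(seed)
    nx, ny, nz = counts_a.shape
    events = np.zeros_like(counts_a)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not site_ok[site_type[x, y, z]]:
                    continue
                na = counts_a[x, y, z]
                nb = counts_b[x, y, z]
                if same:
                    pairs = na * (na - 1) // 2
                else:
                    pairs = na * nb
                if pairs == 0:
                    continue
                p = p_pair * pairs
                if p > 1.0:
                    p = 1.0
                if np.random.random() < p:
                    events[x, y, z] = 1
    return events


def rdme_run(lattice: Lattice, t_end: float, seed: int,
             sample_interval: float | None = None,
             record_species=None):
    """Advance the lattice to ``t_end``, sampling total copy numbers.

    Returns (times, {species: totals}).  The lattice counts are evolved in
    place, so the final spatial state remains available on the lattice.
    """
    lattice.check_courant()
    n_steps = int(round(t_end / lattice.dt))
    if sample_interval is None:
        sample_every = max(1, n_steps // 200)
    else:
        sample_every = max(1, int(round(sample_interval / lattice.dt)))
    record_species = list(record_species or lattice.species)

    cap_d = lattice.max_diffusion()
    n_types = 6
    allowed = {}
    p_move = {}
    for sp in lattice.species:
        al = np.zeros(n_types, dtype=np.bool_)
        pm = np.zeros(n_types)
        for st in range(n_types):
            d = lattice.diffusion.get((sp, st), 0.0)
            if d > 0:
                al[st] = True
                pm[st] = d / cap_d  # total move prob = 6 D dt / spacing^2
        # species may sit on (but not move within) reactive sites
        for st in range(n_types):
            if lattice.diffusion.get((sp, st), None) == 0.0:
                al[st] = True
        allowed[sp] = al
        p_move[sp] = np.clip(pm, 0.0, 1.0)

    site_v = _site_volume_liters(lattice.spacing)
    rng = np.random.default_rng(seed)

    def occupancy():
        occ = np.zeros(lattice.shape, dtype=np.int32)
        for sp in lattice.species:
            occ += lattice.counts[sp]
        return occ

    occ = occupancy()
    times = [0.0]
    totals = {sp: [lattice.total(sp)] for sp in record_species}
    for step in range(1, n_steps + 1):
        for sp in lattice.species:
            if np.any(p_move[sp] > 0):
                _diffuse_species(lattice.counts[sp], occ, lattice.site_type,
                                 allowed[sp], p_move[sp], lattice.capacity,
                                 int(rng.integers(2 ** 31)))
        for rx in lattice.reactions:
            ok = np.zeros(n_types, dtype=np.bool_)
            if rx.sites is None:
                ok[:] = True
            else:
                for st in rx.sites:
                    ok[st] = True
            if rx.order == 1:
                p = rx.rate * lattice.dt
                ev = _first_order(lattice.counts[rx.reactants[0]],
                                  lattice.site_type, ok, p,
                                  int(rng.integers(2 ** 31)))
            else:
                a, b = rx.reactants
                same = a == b
                k_meso = rx.rate / (AVOGADRO * site_v)
                ev = _second_order(lattice.counts[a], lattice.counts[b],
                                   same, lattice.site_type, ok,
                                   k_meso * lattice.dt,
                                   int(rng.integers(2 ** 31)))
            if not np.any(ev):
                continue
            for sp in rx.reactants:
                lattice.counts[sp] -= ev
                occ -= ev
            for sp in rx.products:
                lattice.counts[sp] += ev
                occ += ev
            for sp in lattice.species:
                if np.any(lattice.counts[sp] < 0):
                    raise LatticeError(
                        f"negative count of {sp} after {rx.name}")
        if step % sample_every == 0 or step == n_steps:
            times.append(step * lattice.dt)
            for sp in record_species:
                totals[sp].append(lattice.total(sp))
    return np.array(times), {sp: np.array(v) for sp, v in totals.items()}
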