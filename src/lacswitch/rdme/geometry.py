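"""Cell geometries, intracellular obstacles, and the chromosome walk.

Two phenotypes are modeled.  Fast-growth cells are ideal spherocylinders
(2 um long, 0.8 um diameter) with a diffuse chromosome and the operator at
the cell center.  Slow-growth cells are thin elongated cylinders
(3 x 0.4 um) with a condensed central nucleoid that excludes ribosomes, a
chromosome laid down as a persistence-length random walk, and the operator
sitting on the nucleoid surface ~32 nm from the membrane near a pole.  The
slow-growth builder generates one pole third statistically, mirrors it to
the opposite pole, and density-samples the middle third — emulating how a
cell model is assembled from a partial tomographic reconstruction.

All coordinates are in nanometers, with the x axis along the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class ObstacleClass:
    radius: float       # nm
    mass: float         # kDa
    count: int
    volume_fraction: float


@dataclass
class ObstacleSpec:
    """Macromolecular obstacle census of the cytoplasm (counts per cell)."""

    classes: list
    target_packing: float = 0.5

    def total_fraction(self) -> float:
        return sum(c.volume_fraction for c in self.classes)

    def scaled_to_volume(self, volume_nm3: float,
                         packing: float | None = None) -> "ObstacleSpec":
        """Rescale class counts to a different (sub)volume, preserving the
        per-class volume-fraction proportions; optionally rescale the
        overall packing fraction."""
        base = self.total_fraction()
        target = self.target_packing if packing is None else packing
        classes = []
        for c in self.classes:
            frac = c.volume_fraction / base * target
            vol = 4.0 / 3.0 * np.pi * c.radius ** 3
            n = int(round(frac * volume_nm3 / vol))
            classes.append(ObstacleClass(c.radius, c.mass, n, frac))
        return ObstacleSpec(classes=classes, target_packing=target)


#: in-vivo obstacle census, fast-growth phenotype (radius nm, mass kDa,
#: count, % volume)
_FAST_TABLE = [
    (10.4, 2700, 35005, 17.8),
    (5.2, 346, 290908, 18.6),
    (4.3, 186, 18610, 0.7),
    (4.1, 162, 9907, 0.3),
    (4.0, 156, 59862, 1.7),
    (3.8, 133, 50261, 1.2),
    (3.5, 107, 47365, 0.9),
    (3.4, 91, 140212, 2.5),
    (3.0, 67, 162894, 2.0),
    (2.7, 46, 226358, 2.0),
    (2.3, 29, 321118, 1.8),
    (1.7, 11, 163939, 0.4),
]

#: slow-growth census (smaller cell; DNA handled separately by the
#: chromosome walk)
_SLOW_TABLE = [
    (10.4, 2700, 3021, 5.7),
    (5.2, 346, 96992, 25.5),
    (4.3, 186, 6205, 1.2),
    (4.1, 162, 3303, 0.4),
    (4.0, 156, 19959, 2.4),
    (3.8, 133, 16758, 1.8),
    (3.5, 107, 15792, 1.3),
    (3.4, 91, 46748, 3.6),
    (3.0, 67, 54311, 2.8),
    (2.7, 46, 75470, 2.7),
    (2.3, 29, 107064, 2.3),
    (1.7, 11, 54659, 0.6),
]


def fast_growth_obstacles() -> ObstacleSpec:
    return ObstacleSpec([ObstacleClass(r, m, n, v / 100.0)
                         for r, m, n, v in _FAST_TABLE])


def slow_growth_obstacles() -> ObstacleSpec:
    return ObstacleSpec([ObstacleClass(r, m, n, v / 100.0)
                         for r, m, n, v in _SLOW_TABLE])


# --------------------------------------------------------------------- #
# geometries
# --------------------------------------------------------------------- #

@dataclass
class CellGeometry:
    """Continuous cell description prior to lattice discretization."""

    shape: str                      # "spherocylinder" | "slow_growth"
    length: float                   # nm, overall
    diameter: float                 # nm
    operator_position: np.ndarray   # nm
    ribosome_positions: np.ndarray | None = None    # (n, 3) nm
    nucleoid: dict | None = None    # {"x_min","x_max","radius"} nm
    metadata: dict = field(default_factory=dict)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the membrane surface."""
        p = np.atleast_2d(points)
        r = self.radius
        half_cyl = self.length / 2.0 - r
        x = np.clip(p[:, 0], -half_cyl, half_cyl)
        d2 = (p[:, 0] - x) ** 2 + p[:, 1] ** 2 + p[:, 2] ** 2
        return d2 <= r ** 2

    def in_nucleoid(self, points: np.ndarray) -> np.ndarray:
        if self.nucleoid is None:
            return np.zeros(np.atleast_2d(points).shape[0], dtype=bool)
        p = np.atleast_2d(points)
        n = self.nucleoid
        rad2 = p[:, 1] ** 2 + p[:, 2] ** 2
        return ((p[:, 0] >= n["x_min"]) & (p[:, 0] <= n["x_max"])
                & (rad2 <= n["radius"] ** 2))

    def volume(self) -> float:
        """Enclosed volume in nm^3 (spherocylinder closed form)."""
        r = self.radius
        l_cyl = self.length - 2.0 * r
        return np.pi * r ** 2 * l_cyl + 4.0 / 3.0 * np.pi * r ** 3


def build_fast_growth_geometry(length: float = 2000.0,
                               diameter: float = 800.0) -> CellGeometry:
    """Ideal fast-growth spherocylinder; operator at the geometric center,
    chromosome diffuse (no nucleoid region)."""
    return CellGeometry(shape="spherocylinder", length=length,
                        diameter=diameter,
                        operator_position=np.zeros(3),
                        metadata={"phenotype": "fast_growth"})


def build_slow_growth_geometry(length: float = 3000.0,
                               diameter: float = 400.0,
                               nucleoid_radius: float = 120.0,
                               nucleoid_span: float = 2000.0,
                               n_ribosomes: int = 3021,
                               operator_membrane_gap: float = 32.0,
                               seed: int = 0) -> CellGeometry:
    """Synthetic slow-growth cell emulating tomogram-derived statistics.

    Ribosomes for the pole third are drawn uniformly in the
    nucleoid-excluded cytoplasm, mirrored across the midplane to form the
    opposite pole, and the middle third is sampled at the same density.
    The operator sits on the nucleoid boundary ``operator_membrane_gap``
    from the membrane near one pole.
    """
    rng = np.random.default_rng(seed)
    r = diameter / 2.0
    half = length / 2.0
    nucleoid = {"x_min": -nucleoid_span / 2.0, "x_max": nucleoid_span / 2.0,
                "radius": nucleoid_radius}
    geom = CellGeometry(shape="slow_growth", length=length, diameter=diameter,
                        operator_position=np.zeros(3), nucleoid=nucleoid,
                        metadata={"phenotype": "slow_growth", "seed": seed})

    third = length / 3.0
    n_pole = n_ribosomes // 3
    n_mid = n_ribosomes - 2 * n_pole

    def sample_region(n, x_lo, x_hi):
        out = np.empty((0, 3))
        while out.shape[0] < n:
            cand = np.column_stack([
                rng.uniform(x_lo, x_hi, 4 * n),
                rng.uniform(-r, r, 4 * n),
                rng.uniform(-r, r, 4 * n)])
            ok = geom.contains(cand) & ~geom.in_nucleoid(cand)
            out = np.vstack([out, cand[ok]])
        return out[:n]

    pole = sample_region(n_pole, -half, -half + third)
    mirrored = pole.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    middle = sample_region(n_mid, -half + third, -half + third + third)
    geom.ribosome_positions = np.vstack([pole, middle, mirrored])

    # operator: on the nucleoid surface, near the membrane, toward a pole
    x_op = nucleoid["x_min"] + 0.05 * nucleoid_span
    geom.operator_position = np.array([x_op, r - operator_membrane_gap, 0.0])
    # keep it on/inside the nucleoid radially if the nucleoid is narrow
    if r - operator_membrane_gap > nucleoid_radius:
        geom.operator_position = np.array(
            [nucleoid["x_min"], 0.0, 0.0])
    return geom


# --------------------------------------------------------------------- #
# chromosome random walk
# --------------------------------------------------------------------- #

def nucleoid_random_walk(geometry: CellGeometry, n_segments: int = 31000,
                         segment_length: float = 50.0,
                         angle_max: float = 90.0, unwind: int = 10,
                         seed: int = 0, max_retries: int = 200000
                         ) -> np.ndarray:
    """Persistence-length random walk confined to the nucleoid region.

    Segments of ``segment_length`` nm are added end-to-end with the angle
    between successive segments bounded by ``angle_max`` degrees.  When the
    walk exits the region it is unwound ``unwind`` steps and restarted with
    a fresh direction.  Returns segment midpoints, shape (n_segments, 3).

    Raises RuntimeError when placement exceeds ``max_retries`` restarts.
    """
    if geometry.nucleoid is None:
        raise ValueError("geometry has no nucleoid region")
    rng = np.random.default_rng(seed)
    cos_max = np.cos(np.radians(angle_max))
    nuc = geometry.nucleoid
    center = np.array([0.5 * (nuc["x_min"] + nuc["x_max"]), 0.0, 0.0])

    def inside(p):
        return bool(geometry.in_nucleoid(p[None, :])[0])

    def random_unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def constrained_dir(prev):
        # uniform on the spherical cap within angle_max of prev
        while True:
            v = random_unit()
            if np.dot(v, prev) >= cos_max:
                return v

    points = [center]
    dirs = []
    restarts = 0
    fresh_path = True   # after a restart the next direction is unconstrained
    while len(points) - 1 < n_segments:
        placed = False
        for _ in range(30):   # direction proposals before unwinding
            if fresh_path or not dirs:
                d = random_unit()
            else:
                d = constrained_dir(dirs[-1])
            nxt = points[-1] + d * segment_length
            if inside(nxt):
                points.append(nxt)
                dirs.append(d)
                fresh_path = False
                placed = True
                break
        if not placed:
            restarts += 1
            if restarts > max_retries:
                raise RuntimeError(
                    f"chromosome walk failed after {restarts} restarts "
                    f"({len(points) - 1}/{n_segments} segments placed)")
            k = min(unwind, len(points) - 1)
            del points[len(points) - k:]
            del dirs[len(dirs) - k:]
            fresh_path = True
    pts = np.array(points)
    return 0.5 * (pts[:-1] + pts[1:])


# --------------------------------------------------------------------- #
# obstacle packing
# --------------------------------------------------------------------- #

@njit(cache=True)
def _try_pack(centers, radii, n_placed, cand, cand_r, grid_head, grid_next,
              nx, ny, nz, cell, origin):
    """Insert cand into the packing if it overlaps nothing; returns 1 on
    success.  Uniform-grid neighbor search keyed on the largest radius."""
    ix = int((cand[0] - origin[0]) / cell)
    iy = int((cand[1] - origin[1]) / cell)
    iz = int((cand[2] - origin[2]) / cell)
    for dx in range(-1, 2):
        jx = ix + dx
        if jx < 0 or jx >= nx:
            continue
        for dy in range(-1, 2):
            jy = iy + dy
            if jy < 0 or jy >= ny:
                continue
            for dz in range(-1, 2):
                jz = iz + dz
                if jz < 0 or jz >= nz:
                    continue
                k = grid_head[(jx * ny + jy) * nz + jz]
                while k >= 0:
                    dxx = centers[k, 0] - cand[0]
                    dyy = centers[k, 1] - cand[1]
                    dzz = centers[k, 2] - cand[2]
                    rr = radii[k] + cand_r
                    if dxx * dxx + dyy * dyy + dzz * dzz < rr * rr:
                        return 0
                    k = grid_next[k]
    centers[n_placed, 0] = cand[0]
    centers[n_placed, 1] = cand[1]
    centers[n_placed, 2] = cand[2]
    radii[n_placed] = cand_r
    cell_idx = (ix * ny + iy) * nz + iz
    grid_next[n_placed] = grid_head[cell_idx]
    grid_head[cell_idx] = n_placed
    return 1


def place_obstacles(geometry: CellGeometry, spec: ObstacleSpec, seed: int = 0,
                    include_ribosomes_from_geometry: bool = False,
                    region=None, max_attempts_per: int = 2000,
                    tolerance: float = 0.01, keep_clear=None):
    """Random sequential addition of non-overlapping obstacle spheres.

    Classes are placed largest-first (small spheres fill interstitials).
    In slow-growth cells, ribosome positions may come from the geometry
    (tomogram-style placement) while the remaining classes are placed at
    random, including inside free space of the nucleoid region.

    ``keep_clear``: optional ``(point, radius)`` sphere (same units) from
    which obstacle surfaces are excluded, used to keep reactive sites
    sterically accessible.

    Returns (centers (n,3), radii (n,), class_index (n,)).  Raises
    RuntimeError when the achieved total volume fraction misses the spec
    total by more than ``tolerance`` (absolute).
    """
    rng = np.random.default_rng(seed)
    if region is None:
        r = geometry.radius
        half = geometry.length / 2.0
        lo = np.array([-half, -r, -r])
        hi = np.array([half, r, r])
        region_volume = geometry.volume()

        def in_region(p):
            return geometry.contains(p)
    else:
        lo, hi = np.asarray(region[0], float), np.asarray(region[1], float)
        region_volume = float(np.prod(hi - lo))

        def in_region(p):
            return np.all((p >= lo) & (p <= hi), axis=1)

    order = np.argsort([-c.radius for c in spec.classes])
    classes = [spec.classes[i] for i in order]
    n_total = sum(c.count for c in classes)

    pre = 0
    pre_centers = np.empty((0, 3))
    pre_radii = np.empty(0)
    if include_ribosomes_from_geometry:
        if geometry.ribosome_positions is None:
            raise ValueError("geometry carries no ribosome positions")
        rib_r = max(c.radius for c in spec.classes)
        pre_centers = geometry.ribosome_positions
        pre_radii = np.full(pre_centers.shape[0], rib_r)
        pre = pre_centers.shape[0]
        classes = [c for c in classes if c.radius != rib_r]
        n_total = pre + sum(c.count for c in classes)

    centers = np.zeros((n_total, 3))
    radii = np.zeros(n_total)
    class_idx = np.zeros(n_total, dtype=np.int64)
    max_r = max(c.radius for c in spec.classes)
    cell = 2.0 * max_r + 1e-9
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / cell)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / cell)))
    nz = max(1, int(np.ceil((hi[2] - lo[2]) / cell)))
    grid_head = np.full(nx * ny * nz, -1, dtype=np.int64)
    grid_next = np.full(n_total, -1, dtype=np.int64)

    n_placed = 0
    for i in range(pre):
        # tomogram ribosomes are trusted positions; insert unconditionally
        _force_insert(centers, radii, n_placed, pre_centers[i], pre_radii[i],
                      grid_head, grid_next, nx, ny, nz, cell, lo)
        class_idx[n_placed] = 0
        n_placed += 1

    for ci, cls in enumerate(classes):
        for _ in range(cls.count):
            placed = False
            for _ in range(max_attempts_per):
                cand = rng.uniform(lo, hi)
                # sphere fully usable if its center is in-region
                if not in_region(cand[None, :])[0]:
                    continue
                if keep_clear is not None:
                    point, clear_r = keep_clear
                    if (np.linalg.norm(cand - point)
                            < clear_r + cls.radius):
                        continue
                if _try_pack(centers, radii, n_placed, cand, cls.radius,
                             grid_head, grid_next, nx, ny, nz, cell, lo):
                    class_idx[n_placed] = ci + (1 if pre else 0)
                    n_placed += 1
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"packing infeasible for class r={cls.radius} nm after "
                    f"{max_attempts_per} attempts per sphere")
    centers = centers[:n_placed]
    radii = radii[:n_placed]
    achieved = (4.0 / 3.0 * np.pi * radii ** 3).sum() / region_volume
    if abs(achieved - spec.total_fraction()) > tolerance:
        raise RuntimeError(
            f"achieved packing {achieved:.3f} misses spec "
            f"{spec.total_fraction():.3f} by more than {tolerance}")
    return centers, radii, class_idx[:n_placed]


@njit(cache=True)
def _force_insert(centers, radii, n_placed, cand, cand_r, grid_head,
                  grid_next, nx, ny, nz, cell, origin):
    ix = min(max(int((cand[0] - origin[0]) / cell), 0), nx - 1)
    iy = min(max(int((cand[1] - origin[1]) / cell), 0), ny - 1)
    iz = min(max(int((cand[2] - origin[2]) / cell), 0), nz - 1)
    centers[n_placed, 0] = cand[0]
    centers[n_placed, 1] = cand[1]
    centers[n_placed, 2] = cand[2]
    radii[n_placed] = cand_r
    cell_idx = (ix * ny + iy) * nz + iz
    grid_next[n_placed] = grid_head[cell_idx]
    grid_head[cell_idx] = n_placed
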