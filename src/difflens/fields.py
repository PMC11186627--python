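"""Position-dependent diffusivity fields and hard-disc granule packings.

Units are micrometres for lengths and μm²/s for diffusivities throughout.
A field maps any point of a rectangular simulation region to a strictly
positive local diffusivity; evaluation is deterministic and side-effect
free.  The granule geometry models low-diffusive cytoplasmic patches as
non-overlapping discs of common radius packed to a requested area density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "HEX_PACKING_LIMIT",
    "FieldError",
    "OutOfBoundsError",
    "PackingError",
    "Region",
    "DiffusivityField",
    "UniformField",
    "StepField",
    "GradientField",
    "GaussianWell1D",
    "GranulePacking",
    "GranuleField",
    "make_step_field",
    "make_gradient_field",
    "make_gaussian_well_field",
    "pack_granules",
    "diffusivity_at",
    "nearest_neighbor_distances",
]

#: Densest packing of equal discs in the plane (hexagonal lattice).
HEX_PACKING_LIMIT = math.pi / (2.0 * math.sqrt(3.0))


class FieldError(ValueError):
    """Invalid field or region parameters."""


class OutOfBoundsError(ValueError):
    """A query point lies outside the simulation region."""


class PackingError(RuntimeError):
    """The requested granule packing cannot be realised."""


@dataclass(frozen=True)
class Region:
    """Rectangular simulation region ``[0, width] × [0, height]``.

    The default 1.0 × 0.45 μm matches the aspect ratio of an *E. coli*
    cell, the geometry used for the confined-diffusion and FRAP studies.
    """

    width: float = 1.0
    height: float = 0.45

    def __post_init__(self) -> None:
        if not (self.width > 0.0 and self.height > 0.0):
            raise FieldError("region dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside the closed region."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= 0.0)
            & (p[:, 0] <= self.width)
            & (p[:, 1] >= 0.0)
            & (p[:, 1] <= self.height)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` positions uniformly over the region, shape (n, 2)."""
        pts = rng.uniform(0.0, 1.0, size=(n, 2))
        pts[:, 0] *= self.width
        pts[:, 1] *= self.height
        return pts


class DiffusivityField:
    """Base class: maps points (n, 2) to local diffusivities (n,)."""

    kind = "base"

    def __init__(self, region: Region):
        self.region = region

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def max_diffusivity(self) -> float:
        raise NotImplementedError

    @property
    def bulk_diffusivity(self) -> float:
        """Diffusivity of the bulk/background phase (defaults to max)."""
        return self.max_diffusivity


class UniformField(DiffusivityField):
    kind = "uniform"

    def __init__(self, diffusivity: float, region: Region | None = None):
        super().__init__(region or Region())
        if not (diffusivity > 0.0 and math.isfinite(diffusivity)):
            raise FieldError("diffusivity must be positive and finite")
        self.diffusivity = float(diffusivity)

    def evaluate(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.full(points.shape[0], self.diffusivity)

    @property
    def max_diffusivity(self):
        return self.diffusivity


class StepField(DiffusivityField):
    """Sharp two-level profile: ``d_low`` inside an x-interval, ``d_high`` outside."""

    kind = "step"

    def __init__(self, d_low, d_high, low_zone, region: Region | None = None):
        super().__init__(region or Region())
        if not (d_low > 0.0 and d_high > 0.0):
            raise FieldError("step diffusivities must be positive")
        x0, x1 = float(low_zone[0]), float(low_zone[1])
        if not (0.0 <= x0 < x1 <= self.region.width):
            raise FieldError(
                f"low zone [{x0}, {x1}] must be a proper interval inside "
                f"[0, {self.region.width}]"
            )
        self.d_low = float(d_low)
        self.d_high = float(d_high)
        self.low_zone = (x0, x1)

    def evaluate(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        x = points[:, 0]
        inside = (x >= self.low_zone[0]) & (x <= self.low_zone[1])
        return np.where(inside, self.d_low, self.d_high)

    @property
    def max_diffusivity(self):
        return max(self.d_low, self.d_high)


class GradientField(DiffusivityField):
    """Linear diffusivity ramp along the long (x) axis, d_min at x=0."""

    kind = "gradient"

    def __init__(self, d_min, d_max, region: Region | None = None):
        super().__init__(region or Region())
        if not 0.0 < d_min <= d_max:
            raise FieldError("require 0 < d_min <= d_max")
        self.d_min = float(d_min)
        self.d_max = float(d_max)

    def evaluate(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        frac = np.clip(points[:, 0] / self.region.width, 0.0, 1.0)
        return self.d_min + (self.d_max - self.d_min) * frac

    @property
    def max_diffusivity(self):
        return self.d_max


class GaussianWell1D:
    """1D diffusivity profile D(x) = D_bulk − depth·exp(−(x−center)²/(2 width²)).

    Used by the grid (Fokker–Planck) solvers; dimensionless/arbitrary units.
    """

    kind = "gaussian_well"

    def __init__(self, d_bulk: float, well_depth: float, center: float, width: float):
        if d_bulk <= 0.0:
            raise FieldError("bulk diffusivity must be positive")
        if well_depth < 0.0 or well_depth >= d_bulk:
            raise FieldError(
                "well depth must satisfy 0 <= depth < D_bulk so the "
                "minimum diffusivity stays positive"
            )
        if width <= 0.0:
            raise FieldError("well width must be positive")
        self.d_bulk = float(d_bulk)
        self.well_depth = float(well_depth)
        self.center = float(center)
        self.width = float(width)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.d_bulk - self.well_depth * np.exp(
            -((x - self.center) ** 2) / (2.0 * self.width**2)
        )


@dataclass(frozen=True)
class GranulePacking:
    """Non-overlapping equal discs inside a region.

    ``mu_o`` is the bulk diffusivity outside discs; inside any disc the
    diffusivity is ``mu_ratio * mu_o``.  Disc membership is closed: a
    point exactly on a boundary counts as interior.
    """

    centers: np.ndarray  # (n, 2)
    radius: float
    mu_ratio: float
    mu_o: float
    region: Region
    requested_density: float

    @property
    def n_granules(self) -> int:
        return int(self.centers.shape[0])

    @property
    def achieved_density(self) -> float:
        return self.n_granules * math.pi * self.radius**2 / self.region.area

    def min_pair_distance(self) -> float:
        """Exact minimum over all pairs of center distances (inf if < 2 discs)."""
        if self.n_granules < 2:
            return math.inf
        d = np.linalg.norm(
            self.centers[:, None, :] - self.centers[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def validate(self, density_tol: float = 0.02) -> None:
        """Check non-overlap, containment and achieved density.

        The density tolerance is widened to half a disc's area fraction
        when discs are so large that the achievable density is coarsely
        quantized (e.g. r = 0.1 μm in the default region).
        """
        if self.n_granules == 0:
            return
        if self.min_pair_distance() < 2.0 * self.radius - 1e-12:
            raise PackingError("granule discs overlap")
        c, r = self.centers, self.radius
        if (
            (c[:, 0] < r - 1e-12).any()
            or (c[:, 0] > self.region.width - r + 1e-12).any()
            or (c[:, 1] < r - 1e-12).any()
            or (c[:, 1] > self.region.height - r + 1e-12).any()
        ):
            raise PackingError("granule disc extends outside the region")
        quantum = math.pi * r**2 / self.region.area
        tol = max(density_tol, 0.55 * quantum)
        if abs(self.achieved_density - self.requested_density) > tol:
            raise PackingError(
                f"achieved density {self.achieved_density:.4f} differs from "
                f"requested {self.requested_density:.4f} by more than {tol:.4f}"
            )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_center": self.centers[:, 0],
                "y_center": self.centers[:, 1],
                "radius": np.full(self.n_granules, self.radius),
            }
        )

    def save_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        mu_ratio: float,
        mu_o: float,
        region: Region,
        requested_density: float | None = None,
    ) -> "GranulePacking":
        centers = table[["x_center", "y_center"]].to_numpy(dtype=float)
        radius = float(table["radius"].iloc[0]) if len(table) else 0.0
        pk = cls(
            centers=centers,
            radius=radius,
            mu_ratio=mu_ratio,
            mu_o=mu_o,
            region=region,
            requested_density=(
                requested_density
                if requested_density is not None
                else len(table) * math.pi * radius**2 / region.area
            ),
        )
        return pk

    @classmethod
    def load_csv(cls, path, mu_ratio, mu_o, region, requested_density=None):
        return cls.from_table(
            pd.read_csv(path), mu_ratio, mu_o, region, requested_density
        )


class _DiscGrid:
    """Uniform-grid membership lookup for non-overlapping equal discs.

    Each grid cell stores the (few) discs whose area can reach any
    point of that cell; membership is then a vectorized minimum over a
    fixed-width candidate table.  Much faster than a KD-tree when the
    same static geometry is queried every epoch.
    """

    def __init__(self, centers: np.ndarray, radius: float, region: Region):
        self.radius = radius
        self.cell = max(2.0 * radius, 1e-9)
        self.nx = max(1, int(math.ceil(region.width / self.cell)))
        self.ny = max(1, int(math.ceil(region.height / self.cell)))
        buckets: dict[int, list[int]] = {}
        for i, (cx, cy) in enumerate(centers):
            x0 = max(0, int((cx - radius) / self.cell))
            x1 = min(self.nx - 1, int((cx + radius) / self.cell))
            y0 = max(0, int((cy - radius) / self.cell))
            y1 = min(self.ny - 1, int((cy + radius) / self.cell))
            for gx in range(x0, x1 + 1):
                for gy in range(y0, y1 + 1):
                    buckets.setdefault(gx * self.ny + gy, []).append(i)
        kmax = max((len(v) for v in buckets.values()), default=1)
        n_cells = self.nx * self.ny
        # dummy candidate: a far-away center that can never match
        table = np.vstack([centers, [[1e12, 1e12]]])
        self._cand = np.full((n_cells, kmax), len(centers), dtype=np.intp)
        for cell_id, idxs in buckets.items():
            self._cand[cell_id, : len(idxs)] = idxs
        self._cand_xy = table[self._cand]  # (n_cells, kmax, 2)

    def inside(self, points: np.ndarray) -> np.ndarray:
        gx = np.clip((points[:, 0] / self.cell).astype(np.intp), 0, self.nx - 1)
        gy = np.clip((points[:, 1] / self.cell).astype(np.intp), 0, self.ny - 1)
        cand = self._cand_xy[gx * self.ny + gy]  # (n, kmax, 2)
        d2 = np.square(cand[:, :, 0] - points[:, 0, None]) + np.square(
            cand[:, :, 1] - points[:, 1, None]
        )
        # closed-disc convention, with a relative float tolerance so a
        # point at distance exactly r counts as interior
        return d2.min(axis=1) <= self.radius**2 * (1.0 + 1e-9)


class GranuleField(DiffusivityField):
    """Diffusivity field induced by a granule packing.

    Returns ``mu_ratio * mu_o`` inside any disc (closed discs) and
    ``mu_o`` in the bulk.
    """

    kind = "granules"

    def __init__(self, packing: GranulePacking):
        super().__init__(packing.region)
        if packing.mu_o <= 0.0 or packing.mu_ratio <= 0.0:
            raise FieldError("granule diffusivities must be positive")
        self.packing = packing
        self._grid = (
            _DiscGrid(packing.centers, packing.radius, packing.region)
            if packing.n_granules > 0
            else None
        )

    def evaluate(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        mu_o = self.packing.mu_o
        if self._grid is None:
            return np.full(points.shape[0], mu_o)
        inside = self._grid.inside(points)
        return np.where(inside, self.packing.mu_ratio * mu_o, mu_o)

    def inside_any_granule(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._grid is None:
            return np.zeros(points.shape[0], dtype=bool)
        return self._grid.inside(points)

    @property
    def max_diffusivity(self):
        return self.packing.mu_o * max(1.0, self.packing.mu_ratio)

    @property
    def bulk_diffusivity(self):
        return self.packing.mu_o

    def area_weighted_mean_diffusivity(self) -> float:
        """φ·μi + (1−φ)·μo; the homogenized-control diffusivity."""
        phi = self.packing.achieved_density
        mu_i = self.packing.mu_ratio * self.packing.mu_o
        return phi * mu_i + (1.0 - phi) * self.packing.mu_o


def make_step_field(d_low, d_high, low_zone, region=None) -> StepField:
    """Two-level field: ``d_low`` for x in ``low_zone``, ``d_high`` elsewhere."""
    return StepField(d_low, d_high, low_zone, region)


def make_gradient_field(d_min, d_max, region=None) -> GradientField:
    """Linear gradient from ``d_min`` (x=0) to ``d_max`` (x=width)."""
    return GradientField(d_min, d_max, region)


def make_gaussian_well_field(d_bulk, well_depth, center, width) -> GaussianWell1D:
    """1D Gaussian well in the diffusivity, for the grid solvers."""
    return GaussianWell1D(d_bulk, well_depth, center, width)


def diffusivity_at(field: DiffusivityField, point) -> float:
    """Local diffusivity at one point; raises if outside the region."""
    p = np.asarray(point, dtype=float).reshape(1, 2)
    if not field.region.contains(p)[0]:
        raise OutOfBoundsError(f"point {tuple(p[0])} outside region")
    return float(field.evaluate(p)[0])


def nearest_neighbor_distances(centers: np.ndarray) -> np.ndarray:
    """Per-disc nearest-neighbor center distance (order diagnostic)."""
    if centers.shape[0] < 2:
        return np.array([])
    tree = cKDTree(centers)
    dist, _ = tree.query(centers, k=2)
    return dist[:, 1]


def _hex_lattice_sites(region: Region, r: float) -> np.ndarray:
    """Sites of a touching hexagonal disc lattice fully inside the region."""
    dy = math.sqrt(3.0) * r
    sites = []
    y = r
    row = 0
    while y <= region.height - r + 1e-12:
        x0 = r + (r if row % 2 else 0.0)
        x = x0
        while x <= region.width - r + 1e-12:
            sites.append((x, y))
            x += 2.0 * r
        y += dy
        row += 1
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def _jitter_lattice(
    centers: np.ndarray,
    r: float,
    region: Region,
    rng: np.random.Generator,
    sweeps: int,
    scale: float,
) -> np.ndarray:
    """Randomly displace discs to break lattice order, preserving invariants.

    Per sweep, each disc gets one proposed displacement drawn uniformly
    from a disc of radius ``scale * r``; accepted only if the disc stays
    inside the region and overlaps no other disc.  The KD-tree used for
    neighbor candidates is rebuilt each sweep; since any disc moves at
    most ``scale·r`` per sweep, querying with a ``3·scale·r`` margin is a
    conservative superset of possible conflicts.
    """
    centers = centers.copy()
    n = centers.shape[0]
    if n == 0:
        return centers
    lo_x, hi_x = r, region.width - r
    lo_y, hi_y = r, region.height - r
    max_step = scale * r
    query_r = 2.0 * r + 3.0 * max_step
    for _ in range(sweeps):
        tree = cKDTree(centers)
        # propose all displacements for this sweep at once
        u = rng.uniform(0.0, 1.0, size=n)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        rad = max_step * np.sqrt(u)
        disp = np.column_stack((rad * np.cos(theta), rad * np.sin(theta)))
        neighbor_lists = tree.query_ball_point(centers, query_r)
        for i in range(n):
            cand = centers[i] + disp[i]
            if not (lo_x <= cand[0] <= hi_x and lo_y <= cand[1] <= hi_y):
                continue
            nb = [j for j in neighbor_lists[i] if j != i]
            if nb:
                d2 = np.sum((centers[nb] - cand) ** 2, axis=1)
                if d2.min() < (2.0 * r) ** 2:
                    continue
            centers[i] = cand
    return centers


def pack_granules(
    region: Region,
    r: float,
    phi: float,
    mu_ratio: float = 0.05,
    mu_o: float = 5.0,
    rng: np.random.Generator | None = None,
    *,
    max_attempts: int = 1_000_000,
    lattice_threshold: float = 0.6,
    jitter_sweeps: int = 100,
    jitter_scale: float = 0.1,
) -> GranulePacking:
    """Pack non-overlapping discs of radius ``r`` to area density ``phi``.

    Below ``lattice_threshold`` discs are placed by random sequential
    adsorption (uniform candidate centers, rejecting overlaps and wall
    violations).  At or above it — where rejection sampling saturates —
    discs start on a hexagonal close-packed lattice and are jittered by
    small random displacements to reduce local ordering.
    """
    if rng is None:
        rng = np.random.default_rng(1)
    if r <= 0.0:
        raise FieldError("granule radius must be positive")
    if mu_ratio <= 0.0 or mu_o <= 0.0:
        raise FieldError("granule diffusivities must be positive")
    if phi < 0.0:
        raise FieldError("packing density must be non-negative")
    if phi >= HEX_PACKING_LIMIT:
        raise PackingError(
            f"requested density {phi} exceeds the hexagonal close-packing "
            f"limit {HEX_PACKING_LIMIT:.4f} for equal discs"
        )
    if phi > 0.0 and 2.0 * r > min(region.width, region.height):
        raise FieldError("granule diameter exceeds the smallest region dimension")
    disc_area = math.pi * r**2
    n_target = int(round(phi * region.area / disc_area))

    if n_target == 0:
        centers = np.empty((0, 2))
    elif phi < lattice_threshold:
        centers = np.empty((n_target, 2))
        count = 0
        attempts = 0
        lo = np.array([r, r])
        span = np.array([region.width - 2.0 * r, region.height - 2.0 * r])
        if (span < 0).any():
            raise FieldError("granule diameter exceeds the smallest region dimension")
        min_d2 = (2.0 * r) ** 2
        while count < n_target:
            if attempts >= max_attempts:
                raise PackingError(
                    f"rejection sampling saturated after {max_attempts} "
                    f"attempts at {count}/{n_target} discs (phi={phi})"
                )
            cand = lo + rng.uniform(0.0, 1.0, size=2) * span
            attempts += 1
            if count:
                d2 = np.sum((centers[:count] - cand) ** 2, axis=1)
                if d2.min() < min_d2:
                    continue
            centers[count] = cand
            count += 1
    else:
        sites = _hex_lattice_sites(region, r)
        if sites.shape[0] < n_target:
            raise PackingError(
                f"only {sites.shape[0]} lattice sites fit for r={r}; "
                f"cannot reach phi={phi}"
            )
        idx = rng.choice(sites.shape[0], size=n_target, replace=False)
        centers = _jitter_lattice(
            sites[idx], r, region, rng, jitter_sweeps, jitter_scale
        )

    packing = GranulePacking(
        centers=centers,
        radius=r,
        mu_ratio=mu_ratio,
        mu_o=mu_o,
        region=region,
        requested_density=phi,
    )
    packing.validate()
    return packing
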