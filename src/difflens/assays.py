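"""In silico microrheology, FRAP, dwell-time and density assays.

These operate on trajectory stores from the walk engine (or run their
own small simulations, for FRAP) and quantify how inhomogeneous
diffusivity reshapes apparent transport: the fitted diffusion
coefficient and saturation MSD (microrheology), the recovery half-time
after photobleaching a circular ROI (mesoscale dynamics), the dwell
time of particles inside low-diffusive granules, and neighbor-count
local densities used for the clustering analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import StepRule, TrajectoryStore, advance, count_neighbors
from .fields import DiffusivityField, GranulePacking, Region, UniformField

__all__ = [
    "MSDCurve",
    "RecoveryCurve",
    "DwellStatistics",
    "AssayError",
    "EmptyROIError",
    "compute_msd",
    "fit_diffusion_coefficient",
    "saturation_msd",
    "simulate_frap",
    "frap_replicates",
    "uniform_reference_levels",
    "mean_dwell_time",
    "local_density",
    "concentration_profile",
    "ks_distance_to_steady_state",
    "uniformity_pvalue",
]


class AssayError(RuntimeError):
    """An assay precondition failed (e.g. unsaturated MSD curve)."""


class EmptyROIError(AssayError):
    """No particles inside the ROI at bleach time."""


# --------------------------------------------------------------------------
# microrheology


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement versus lag time.

    The MSD at each lag is the ensemble average over particles of the
    squared displacement from each particle's initial position; SEM is
    over particles.
    """

    lags: np.ndarray  # s
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm²
    n_trajectories: int


def compute_msd(store: TrajectoryStore, max_lag: float | None = None) -> MSDCurve:
    """Ensemble-averaged MSD from a snapshot store.

    Lags are the store's frame times relative to the first frame.  SEM
    per lag is the standard deviation of squared displacements across
    particles divided by sqrt(N).
    """
    times = store.times - store.times[0]
    if max_lag is not None:
        if max_lag > times[-1] + 1e-12:
            raise AssayError(
                f"max_lag {max_lag} exceeds run duration {times[-1]:.6g}"
            )
        keep = times <= max_lag + 1e-12
        times = times[keep]
        frames = store.positions[keep]
    else:
        frames = store.positions
    disp = frames - frames[0]
    sq = np.einsum("fnd,fnd->fn", disp, disp)
    n = sq.shape[1]
    return MSDCurve(
        lags=times,
        msd=sq.mean(axis=1),
        sem=sq.std(axis=1, ddof=1) / math.sqrt(n),
        n_trajectories=n,
    )


def fit_diffusion_coefficient(curve: MSDCurve, fit_window: tuple) -> float:
    """Least-squares slope of MSD vs lag over the window, divided by 4.

    The window must lie in the pre-saturation linear regime and contain
    at least three points.
    """
    lo, hi = fit_window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 3:
        raise AssayError("fit window contains fewer than 3 points")
    slope = np.polyfit(curve.lags[mask], curve.msd[mask], 1)[0]
    return float(slope) / 4.0


def saturation_msd(
    curve: MSDCurve, tail_fraction: float = 0.25, slope_tol: float = 0.05
) -> float:
    """Mean MSD over the trailing ``tail_fraction`` of lags.

    The curve must be saturated: the relative MSD change across the
    tail (fitted slope × tail span over tail mean) must be below
    ``slope_tol``, otherwise a diagnostic error is raised.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    n = len(curve.lags)
    start = max(0, int(math.floor(n * (1.0 - tail_fraction))))
    lags, msd = curve.lags[start:], curve.msd[start:]
    if len(lags) < 3:
        raise AssayError("tail contains fewer than 3 points")
    slope = np.polyfit(lags, msd, 1)[0]
    mean = msd.mean()
    rel_change = abs(slope) * (lags[-1] - lags[0]) / mean
    if rel_change > slope_tol:
        raise AssayError(
            f"MSD curve not saturated: tail still changes by "
            f"{rel_change:.3f} relative (> {slope_tol})"
        )
    return float(mean)


# --------------------------------------------------------------------------
# FRAP


@dataclass
class RecoveryCurve:
    """Unbleached-particle count in a circular ROI after photobleaching.

    ``normalized`` is the count divided by the steady-state unbleached
    ROI count of a matched uniform-diffusivity reference; ``t_half`` is
    the first time the (lightly smoothed) normalized recovery reaches
    0.5, or None with ``censored=True`` if never reached.
    """

    times: np.ndarray  # s since bleach
    unbleached: np.ndarray
    normalized: np.ndarray
    t_half: float | None
    censored: bool
    roi_center: tuple
    roi_radius: float
    reference_level: float
    n_bleached: int


def _roi_mask(positions: np.ndarray, center, radius: float) -> np.ndarray:
    d2 = (positions[:, 0] - center[0]) ** 2 + (positions[:, 1] - center[1]) ** 2
    return d2 <= radius**2


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(y)]


def t_half_from_curve(
    times: np.ndarray, normalized: np.ndarray, smooth_window: int = 5
):
    """First crossing of 0.5 on the smoothed curve; (t_half, censored)."""
    sm = _moving_average(normalized, smooth_window)
    idx = np.nonzero(sm >= 0.5)[0]
    if idx.size == 0:
        return None, True
    return float(times[idx[0]]), False


def _check_roi(region: Region, center, radius: float) -> None:
    if not (
        radius > 0.0
        and radius <= center[0] <= region.width - radius
        and radius <= center[1] <= region.height - radius
    ):
        raise AssayError("ROI must lie fully inside the region")


def _recover(
    pos0: np.ndarray,
    bleached: np.ndarray,
    field: DiffusivityField,
    rule: StepRule,
    epochs: int,
    roi_center,
    roi_radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts of unbleached particles in the ROI at each epoch since bleach."""
    pos = pos0.copy()
    unb = ~bleached
    counts = np.empty(epochs + 1)
    counts[0] = np.count_nonzero(_roi_mask(pos[unb], roi_center, roi_radius))
    for e in range(1, epochs + 1):
        pos = advance(pos, field, rule, rng)
        counts[e] = np.count_nonzero(_roi_mask(pos[unb], roi_center, roi_radius))
    return counts


def simulate_frap(
    field: DiffusivityField,
    roi_center,
    roi_radius: float = 0.2,
    *,
    n_particles: int = 100_000,
    dt: float = 5e-5,
    burn_in: int = 5_000,
    recovery_epochs: int = 5_000,
    seed: int = 1,
    reference_level: float | None = None,
    smooth_window: int = 5,
) -> RecoveryCurve:
    """One photobleaching experiment on ``field``.

    Particles are initialized uniformly, equilibrated for ``burn_in``
    epochs, then every particle inside the ROI is instantaneously and
    permanently assigned the bleached label (bleached particles keep
    diffusing).  The unbleached count in the ROI is recorded each epoch.
    If ``reference_level`` is not given, a matched uniform-diffusivity
    run at the field's bulk diffusivity provides the steady-state
    normalization (the standardized background).
    """
    curves = frap_replicates(
        field,
        [tuple(roi_center)],
        roi_radius,
        n_particles=n_particles,
        dt=dt,
        burn_in=burn_in,
        recovery_epochs=recovery_epochs,
        seed=seed,
        reference_levels=None if reference_level is None else [reference_level],
        smooth_window=smooth_window,
    )
    return curves[0]


def frap_replicates(
    field: DiffusivityField,
    roi_centers,
    roi_radius: float = 0.2,
    *,
    n_particles: int = 100_000,
    dt: float = 5e-5,
    burn_in: int = 5_000,
    recovery_epochs: int = 5_000,
    seed: int = 1,
    reference_levels=None,
    smooth_window: int = 5,
) -> list[RecoveryCurve]:
    """FRAP replicates sharing one burn-in: each ROI is bleached in its
    own independent recovery continuation of the equilibrated state, so
    replicate bleach events never interact."""
    region = field.region
    for c in roi_centers:
        _check_roi(region, c, roi_radius)
    rule = StepRule(dt=dt)
    ss = np.random.SeedSequence(seed)
    seqs = ss.spawn(1 + len(roi_centers))
    rng = np.random.default_rng(seqs[0])
    pos = region.sample_uniform(n_particles, rng)
    for _ in range(burn_in):
        pos = advance(pos, field, rule, rng)

    if reference_levels is None:
        reference_levels = uniform_reference_levels(
            region,
            field.bulk_diffusivity,
            roi_centers,
            roi_radius,
            n_particles=n_particles,
            dt=dt,
            burn_in=burn_in,
            recovery_epochs=recovery_epochs,
            seed=seed,
        )

    curves = []
    times = np.arange(recovery_epochs + 1) * dt
    for i, center in enumerate(roi_centers):
        bleached = _roi_mask(pos, center, roi_radius)
        n_bleached = int(bleached.sum())
        if n_bleached == 0:
            raise EmptyROIError(f"ROI at {center} empty at bleach time")
        counts = _recover(
            pos,
            bleached,
            field,
            rule,
            recovery_epochs,
            center,
            roi_radius,
            np.random.default_rng(seqs[1 + i]),
        )
        ref = float(reference_levels[i])
        normalized = counts / ref
        t_half, censored = t_half_from_curve(times, normalized, smooth_window)
        curves.append(
            RecoveryCurve(
                times=times,
                unbleached=counts,
                normalized=normalized,
                t_half=t_half,
                censored=censored,
                roi_center=tuple(center),
                roi_radius=roi_radius,
                reference_level=ref,
                n_bleached=n_bleached,
            )
        )
    return curves


def uniform_reference_levels(
    region: Region,
    diffusivity: float,
    roi_centers,
    roi_radius: float,
    *,
    n_particles: int,
    dt: float,
    burn_in: int,
    recovery_epochs: int,
    seed: int,
    plateau_fraction: float = 0.25,
):
    """Steady-state unbleached ROI counts from a uniform-diffusivity run.

    Runs the same bleach protocol on a uniform field at the bulk
    diffusivity and returns, per ROI, the mean unbleached count over
    the trailing ``plateau_fraction`` of the recovery — the
    standardized normalization background.
    """
    field = UniformField(diffusivity, region)
    rule = StepRule(dt=dt)
    ss = np.random.SeedSequence((seed, 0xB0B))  # independent of the main run
    seqs = ss.spawn(1 + len(roi_centers))
    rng = np.random.default_rng(seqs[0])
    pos = region.sample_uniform(n_particles, rng)
    for _ in range(burn_in):
        pos = advance(pos, field, rule, rng)
    levels = []
    tail = max(1, int(round(recovery_epochs * plateau_fraction)))
    for i, center in enumerate(roi_centers):
        bleached = _roi_mask(pos, center, roi_radius)
        counts = _recover(
            pos,
            bleached,
            field,
            rule,
            recovery_epochs,
            center,
            roi_radius,
            np.random.default_rng(seqs[1 + i]),
        )
        levels.append(float(counts[-tail:].mean()))
    return levels


# --------------------------------------------------------------------------
# dwell times


@dataclass
class DwellStatistics:
    """Mean dwell time of particles inside low-diffusive granules.

    A dwell episode is a maximal run of consecutive recorded frames
    with the particle inside any disc; an episode of k frames counts
    k × (frame spacing) seconds, and the total observation time is
    n_frames × (frame spacing), so a particle resident for a whole run
    has normalized fraction exactly 1.  ``normalized_fraction`` is the
    mean episode duration divided by that total.  When the packing has
    no granules the statistics are absent (None), not zero.
    """

    mean_dwell: float | None  # s
    normalized_fraction: float | None
    n_episodes: int
    total_duration: float  # s, observation time


def mean_dwell_time(store: TrajectoryStore, packing: GranulePacking) -> DwellStatistics:
    """Average duration of granule-residency episodes over all particles.

    The store should hold densely sampled paths (dwell episodes shorter
    than the snapshot interval are invisible).  Episode durations count
    frames × frame spacing; episodes touching either end of the run are
    included at their observed (censored) length.
    """
    f = store.n_frames
    frame_dt = (
        float(np.diff(store.epochs).mean()) * store.dt if f > 1 else store.dt
    )
    duration = f * frame_dt
    if packing.n_granules == 0:
        return DwellStatistics(
            mean_dwell=None,
            normalized_fraction=None,
            n_episodes=0,
            total_duration=duration,
        )
    # same closed-disc membership test as the diffusivity field
    from .fields import _DiscGrid

    grid = _DiscGrid(packing.centers, packing.radius, packing.region)
    n = store.positions.shape[1]
    inside = np.empty((f, n), dtype=bool)
    for i in range(f):
        inside[i] = grid.inside(store.positions[i])

    # pad with False rows so episodes never bridge particles when flattened
    padded = np.zeros((f + 2, n), dtype=bool)
    padded[1:-1] = inside
    flat = padded.T.ravel()  # particle-major
    d = np.diff(flat.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    durations = (ends - starts) * frame_dt
    if durations.size == 0:
        return DwellStatistics(
            mean_dwell=0.0,
            normalized_fraction=0.0,
            n_episodes=0,
            total_duration=duration,
        )
    mean_dwell = float(durations.mean())
    return DwellStatistics(
        mean_dwell=mean_dwell,
        normalized_fraction=mean_dwell / duration if duration > 0 else None,
        n_episodes=int(durations.size),
        total_duration=duration,
    )


# --------------------------------------------------------------------------
# density and clustering metrics


def local_density(
    positions: np.ndarray, cutoff: float, baseline_ensembles
) -> np.ndarray:
    """Per-particle neighbor counts normalized to the initialization mean.

    ``baseline_ensembles`` is a list of position arrays representing
    uniform initializations; the normalization constant is the mean
    neighbor count (same cutoff) over all of them.
    """
    counts = count_neighbors(positions, cutoff).astype(float)
    base = [count_neighbors(b, cutoff).mean() for b in baseline_ensembles]
    baseline = float(np.mean(base))
    if baseline <= 0.0:
        raise AssayError("baseline ensembles have zero mean neighbor count")
    return counts / baseline


@dataclass
class ConcentrationProfile:
    bin_centers: np.ndarray
    density: np.ndarray  # unit-mass histogram
    closed_form: np.ndarray | None  # Itô steady state on the same bins
    counts: np.ndarray


def concentration_profile(
    store: TrajectoryStore,
    n_bins: int = 20,
    axis: int = 0,
    field: DiffusivityField | None = None,
    tail_fraction: float = 0.25,
) -> ConcentrationProfile:
    """Axis histogram of steady-state positions with the Itô closed form.

    Pools the trailing ``tail_fraction`` of snapshots for statistics.
    The overlay evaluates c ∝ 1/D on the bin centers (α = 0), normalized
    on the same bins; the store should already be at steady state.
    """
    f = store.n_frames
    start = max(0, f - max(1, int(round(f * tail_fraction))))
    coords = store.positions[start:, :, axis].ravel()
    length = store.region.width if axis == 0 else store.region.height
    counts, edges = np.histogram(coords, bins=n_bins, range=(0.0, length))
    widths = np.diff(edges)
    centers = 0.5 * (edges[1:] + edges[:-1])
    expected = coords.size / n_bins
    if expected < 10:
        warnings.warn(
            f"fewer than 10 expected samples per bin ({expected:.1f}); "
            "profile will be noisy",
            stacklevel=2,
        )
    density = counts / counts.sum() / widths
    closed = None
    if field is not None:
        mid = store.region.height / 2.0 if axis == 0 else store.region.width / 2.0
        pts = np.column_stack(
            (centers, np.full_like(centers, mid))
            if axis == 0
            else (np.full_like(centers, mid), centers)
        )
        D = field.evaluate(pts)
        closed = 1.0 / D
        closed = closed / (closed * widths).sum()
    return ConcentrationProfile(
        bin_centers=centers, density=density, closed_form=closed, counts=counts
    )


def ks_distance_to_steady_state(
    store: TrajectoryStore,
    field: DiffusivityField,
    alpha: float = 0.0,
    axis: int = 0,
    tail_fraction: float = 0.25,
    grid_points: int = 2048,
) -> float:
    """Kolmogorov–Smirnov distance of pooled tail positions to c ∝ D^(α−1)."""
    f = store.n_frames
    start = max(0, f - max(1, int(round(f * tail_fraction))))
    samples = np.sort(store.positions[start:, :, axis].ravel())
    length = store.region.width if axis == 0 else store.region.height
    xs = np.linspace(0.0, length, grid_points)
    mid = store.region.height / 2.0 if axis == 0 else store.region.width / 2.0
    pts = np.column_stack(
        (xs, np.full_like(xs, mid)) if axis == 0 else (np.full_like(xs, mid), xs)
    )
    c = field.evaluate(pts) ** (alpha - 1.0)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(xs))))
    cdf /= cdf[-1]
    theory = np.interp(samples, xs, cdf)
    n = samples.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.maximum(emp_hi - theory, theory - emp_lo).max())


def uniformity_pvalue(
    positions: np.ndarray, region: Region, n_bins: int = 10, axis: int = 0
) -> float:
    """χ² p-value for uniformity of positions along one axis."""
    length = region.width if axis == 0 else region.height
    counts, _ = np.histogram(positions[:, axis], bins=n_bins, range=(0.0, length))
    return float(stats.chisquare(counts).pvalue)
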