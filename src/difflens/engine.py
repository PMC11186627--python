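"""Itô-convention random-walk engine.

Particles take independent per-axis displacements drawn from U(−S, S),
with the step-size limit S set by the diffusivity at the particle's
*present* position (non-anticipatory / Itô stepping).  The mapping is
S = sqrt(6·D·dt), chosen so that a uniform step of variance S²/3 per
axis reproduces per-axis MSD 2·D·dt — the nominal diffusivity is then
recovered as an emergent property of the trajectories.  Walls reflect
by the mirror-image rule.  An optional neighbor-sensing interaction
rescales S to S_eff = S·exp(−k·n), an effective attraction.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fields import DiffusivityField, Region

__all__ = [
    "StepRule",
    "InteractionRule",
    "TrajectoryStore",
    "step_limit_from_D",
    "reflect",
    "advance",
    "count_neighbors",
    "advance_interacting",
    "run_simulation",
]


def step_limit_from_D(D, dt: float):
    """Step-size limit S = sqrt(6·D·dt) for per-axis steps U(−S, S).

    The uniform distribution on (−S, S) has variance S²/3; requiring
    per-axis variance 2·D·dt per step yields S² = 6·D·dt, so the 2D
    ensemble MSD grows as 4·D·t for free diffusion.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    D = np.asarray(D, dtype=float)
    if (D < 0.0).any():
        raise ValueError("diffusivity must be non-negative")
    S = np.sqrt(6.0 * D * dt)
    return float(S) if S.ndim == 0 else S


def reflect(points, region: Region) -> np.ndarray:
    """Fold positions back into the region by repeated mirror images.

    Implemented in closed form via the period-2L triangle wave, which is
    exactly the mirror rule (x′ = −x below 0, x′ = 2L − x above L)
    applied until the point is interior.  Interior points are unchanged.
    """
    p = np.array(points, dtype=float, copy=True)
    scalar_point = p.ndim == 1
    p = np.atleast_2d(p)
    for axis, L in ((0, region.width), (1, region.height)):
        x = np.mod(p[:, axis], 2.0 * L)
        p[:, axis] = np.where(x > L, 2.0 * L - x, x)
    return p[0] if scalar_point else p


@dataclass(frozen=True)
class StepRule:
    """Timestep of the walk; the D→S mapping is step_limit_from_D."""

    dt: float = 5e-5  # 50 μs

    def __post_init__(self):
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")

    def step_limit(self, D):
        return step_limit_from_D(D, self.dt)


@dataclass(frozen=True)
class InteractionRule:
    """Neighbor-sensing attraction: S_eff = S·exp(−k·n).

    ``n`` counts other particles within Euclidean distance ≤ cutoff
    (closed ball), evaluated synchronously at the start of each epoch.
    """

    k: float
    cutoff: float

    def __post_init__(self):
        if self.k < 0.0:
            raise ValueError("interaction strength k must be >= 0")
        if self.cutoff <= 0.0:
            raise ValueError("neighbor cutoff must be positive")

    def suppression(self, n_neighbors) -> np.ndarray:
        return np.exp(-self.k * np.asarray(n_neighbors, dtype=float))


def advance(
    positions: np.ndarray,
    field: DiffusivityField,
    rule: StepRule,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Itô step for every particle; returns new positions.

    Consumes exactly one (N, 2) uniform block from ``rng`` per call
    (particle-major order), so runs are reproducible draw-for-draw.
    """
    D = field.evaluate(positions)
    S = np.sqrt(6.0 * D * rule.dt)
    disp = rng.uniform(-1.0, 1.0, size=positions.shape) * S[:, None]
    return reflect(positions + disp, field.region)


def count_neighbors(positions: np.ndarray, cutoff: float, index: int | None = None):
    """Number of OTHER particles within ``cutoff`` (closed ball).

    Returns the full count vector, or a single count if ``index`` given.
    """
    if cutoff <= 0.0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(positions)
    counts = tree.query_ball_point(positions, cutoff, return_length=True) - 1
    if index is not None:
        return int(counts[index])
    return counts


def advance_interacting(
    positions: np.ndarray,
    field: DiffusivityField,
    rule: StepRule,
    interaction: InteractionRule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Itô step with neighbor-sensing step suppression.

    Neighbor counts are computed once from the epoch-start configuration
    for all particles (synchronous update), then each particle's step
    limit is rescaled by exp(−k·n).  With k = 0 this consumes the same
    rng draws as :func:`advance` and yields identical trajectories.
    """
    D = field.evaluate(positions)
    S = np.sqrt(6.0 * D * rule.dt)
    if interaction.k > 0.0:
        n = count_neighbors(positions, interaction.cutoff)
        S = S * np.exp(-interaction.k * n)
    disp = rng.uniform(-1.0, 1.0, size=positions.shape) * S[:, None]
    return reflect(positions + disp, field.region)


@dataclass
class TrajectoryStore:
    """Time-indexed snapshots of an ensemble plus run provenance.

    ``positions`` has shape (n_frames, n_particles, 2); ``epochs`` holds
    the epoch index of each frame.  Identical config + seed give
    bit-identical stores.
    """

    epochs: np.ndarray
    positions: np.ndarray
    dt: float
    seed: int
    region: Region
    config_fingerprint: str = ""
    labels: np.ndarray | None = None  # e.g. bleach flags, (n_particles,)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_particles(self) -> int:
        return int(self.positions.shape[1])

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.epochs * self.dt

    @property
    def duration(self) -> float:
        return float(self.epochs[-1] * self.dt)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(
            path,
            epochs=self.epochs,
            positions=self.positions,
            labels=(
                self.labels
                if self.labels is not None
                else np.zeros(self.n_particles, dtype=bool)
            ),
        )
        sidecar = {
            "dt": self.dt,
            "seed": self.seed,
            "region": {"width": self.region.width, "height": self.region.height},
            "config_fingerprint": self.config_fingerprint,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrajectoryStore":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(
            epochs=data["epochs"],
            positions=data["positions"],
            dt=meta["dt"],
            seed=meta["seed"],
            region=Region(**meta["region"]),
            config_fingerprint=meta.get("config_fingerprint", ""),
            labels=data["labels"],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (epoch, particle_id, x, y) table."""
        f, n, _ = self.positions.shape
        return pd.DataFrame(
            {
                "epoch": np.repeat(self.epochs, n),
                "particle_id": np.tile(np.arange(n), f),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
            }
        )


def run_simulation(config) -> TrajectoryStore:
    """Run a configured simulation and record snapshots.

    ``config`` is a :class:`difflens.config.RunConfig`.  Particles are
    initialized uniformly at random over the full region (granule
    interiors included).  The seed is split into two independent
    streams: one for granule-packing construction, one for dynamics;
    the dynamics stream is consumed as one (N, 2) uniform block per
    epoch after the initial (N, 2) placement block.
    """
    config.validate()
    ss = np.random.SeedSequence(config.run.seed)
    pack_seq, dyn_seq = ss.spawn(2)
    field = config.build_field(np.random.default_rng(pack_seq))
    rng = np.random.default_rng(dyn_seq)

    region = field.region
    n = config.particles.n
    rule = StepRule(dt=config.particles.dt)
    interaction = config.interaction_rule(field)

    pos = region.sample_uniform(n, rng)
    epochs = config.run.epochs
    interval = config.run.snapshot_interval
    frames = [pos.copy()]
    frame_epochs = [0]
    for e in range(1, epochs + 1):
        if interaction is not None:
            pos = advance_interacting(pos, field, rule, interaction, rng)
        else:
            pos = advance(pos, field, rule, rng)
        if e % interval == 0 or e == epochs:
            frames.append(pos.copy())
            frame_epochs.append(e)

    return TrajectoryStore(
        epochs=np.asarray(frame_epochs),
        positions=np.stack(frames),
        dt=rule.dt,
        seed=config.run.seed,
        region=region,
        config_fingerprint=config.fingerprint(),
    )
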