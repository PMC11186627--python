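"""Run configuration: strict YAML schema, validation, defaults.

A config has sections ``region``, ``field``, ``particles``,
``interactions`` (optional) and ``run``.  Unknown keys are rejected
with their dotted path; all physical quantities must be positive.  An
empty document resolves to the all-defaults run: uniform field at
5 μm²/s in a 1 × 0.45 μm region, 10⁴ particles, dt = 50 μs, 10⁴
epochs, seed 1.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field as _dcfield

import numpy as np
import yaml

from .engine import InteractionRule, step_limit_from_D
from .fields import (
    FieldError,
    GranuleField,
    Region,
    StepField,
    GradientField,
    UniformField,
    pack_granules,
)

__all__ = ["ConfigError", "RunConfig", "parse_and_validate"]


class ConfigError(ValueError):
    """Schema or consistency violation, reported with the key path."""


_FIELD_KEYS = {
    "uniform": {"D"},
    "step": {"D_low", "D_high", "zone"},
    "gradient": {"D_min", "D_max"},
    "granules": {"r", "phi", "mu_ratio", "mu_o", "jitter_sweeps"},
}


@dataclass
class FieldSpec:
    kind: str = "uniform"
    D: float = 5.0
    D_low: float = 1.25
    D_high: float = 5.0
    zone: tuple | None = None  # default: left 25% of the long axis
    D_min: float = 1.25
    D_max: float = 5.0
    r: float = 0.01
    phi: float = 0.6
    mu_ratio: float = 0.05
    mu_o: float = 5.0
    jitter_sweeps: int = 100


@dataclass
class ParticleSpec:
    n: int = 10_000
    dt: float = 5e-5


@dataclass
class InteractionSpec:
    k: float = 0.0
    cutoff: float | None = None  # default 2.5 × S(max diffusivity)


@dataclass
class RunSpec:
    epochs: int = 10_000
    snapshot_interval: int = 100
    seed: int = 1


@dataclass
class RunConfig:
    region: Region = _dcfield(default_factory=Region)
    field: FieldSpec = _dcfield(default_factory=FieldSpec)
    particles: ParticleSpec = _dcfield(default_factory=ParticleSpec)
    interactions: InteractionSpec | None = None
    run: RunSpec = _dcfield(default_factory=RunSpec)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.particles.n <= 0:
            raise ConfigError("particles.n must be positive")
        if self.particles.dt <= 0:
            raise ConfigError("particles.dt must be positive")
        if self.run.epochs <= 0:
            raise ConfigError("run.epochs must be positive")
        if self.run.snapshot_interval <= 0:
            raise ConfigError("run.snapshot_interval must be positive")
        if int(self.run.seed) != self.run.seed:
            raise ConfigError("run.seed must be an integer")
        field = self.build_field(np.random.default_rng(0), _validate_only=True)
        s_max = step_limit_from_D(field.max_diffusivity, self.particles.dt)
        if s_max > min(self.region.width, self.region.height):
            raise ConfigError(
                f"step limit {s_max:.4g} μm exceeds the smallest region "
                "dimension; reduce particles.dt or the diffusivity"
            )
        if self.interactions is not None:
            if self.interactions.k < 0:
                raise ConfigError("interactions.k must be >= 0")
            if (
                self.interactions.cutoff is not None
                and self.interactions.cutoff <= 0
            ):
                raise ConfigError("interactions.cutoff must be positive")

    # -- construction ------------------------------------------------------

    def build_field(self, rng=None, _validate_only: bool = False):
        f = self.field
        try:
            if f.kind == "uniform":
                return UniformField(f.D, self.region)
            if f.kind == "step":
                zone = f.zone or (0.0, 0.25 * self.region.width)
                return StepField(f.D_low, f.D_high, zone, self.region)
            if f.kind == "gradient":
                return GradientField(f.D_min, f.D_max, self.region)
            if f.kind == "granules":
                if _validate_only:
                    # cheap surrogate with the same extreme diffusivities
                    return UniformField(
                        max(f.mu_o, f.mu_o * f.mu_ratio), self.region
                    )
                packing = pack_granules(
                    self.region,
                    f.r,
                    f.phi,
                    f.mu_ratio,
                    f.mu_o,
                    rng if rng is not None else np.random.default_rng(1),
                    jitter_sweeps=f.jitter_sweeps,
                )
                return GranuleField(packing)
        except FieldError as err:
            raise ConfigError(f"field: {err}") from err
        raise ConfigError(f"field.kind: unknown kind {f.kind!r}")

    def interaction_rule(self, field) -> InteractionRule | None:
        if self.interactions is None or self.interactions.k == 0.0:
            return None
        cutoff = self.interactions.cutoff
        if cutoff is None:
            cutoff = 2.5 * step_limit_from_D(
                field.max_diffusivity, self.particles.dt
            )
        return InteractionRule(k=self.interactions.k, cutoff=cutoff)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "region": {"width": self.region.width, "height": self.region.height},
            "field": _active_field_dict(self.field),
            "particles": asdict(self.particles),
            "run": asdict(self.run),
        }
        if self.interactions is not None:
            d["interactions"] = asdict(self.interactions)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _active_field_dict(f: FieldSpec) -> dict:
    out = {"kind": f.kind}
    for key in _FIELD_KEYS.get(f.kind, ()):
        val = getattr(f, key)
        if val is not None:
            out[key] = list(val) if isinstance(val, tuple) else val
    return out


def _require_mapping(obj, path: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping")
    return obj


def _check_keys(d: dict, allowed, path: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _positive(d: dict, key: str, path: str, default):
    val = d.get(key, default)
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise ConfigError(f"{path}.{key}: expected a number")
    if val <= 0:
        raise ConfigError(f"{path}.{key}: must be positive, got {val}")
    return val


def parse_and_validate(text: str) -> RunConfig:
    """Parse a YAML config document into a validated :class:`RunConfig`.

    An empty document yields the all-defaults config.  Schema
    violations report the offending dotted key path.
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"invalid YAML: {err}") from err
    raw = _require_mapping(raw, "<root>")
    _check_keys(raw, {"region", "field", "particles", "interactions", "run"}, "<root>")

    reg = _require_mapping(raw.get("region"), "region")
    _check_keys(reg, {"width", "height"}, "region")
    region = Region(
        width=_positive(reg, "width", "region", 1.0),
        height=_positive(reg, "height", "region", 0.45),
    )

    fld = _require_mapping(raw.get("field"), "field")
    kind = fld.get("kind", "uniform")
    if kind not in _FIELD_KEYS:
        raise ConfigError(
            f"field.kind: unknown kind {kind!r}; allowed {sorted(_FIELD_KEYS)}"
        )
    _check_keys(fld, _FIELD_KEYS[kind] | {"kind"}, "field")
    fspec = FieldSpec(kind=kind)
    for key in _FIELD_KEYS[kind]:
        if key in fld:
            if key == "zone":
                zone = fld["zone"]
                if (
                    not isinstance(zone, (list, tuple))
                    or len(zone) != 2
                    or not all(isinstance(v, (int, float)) for v in zone)
                ):
                    raise ConfigError("field.zone: expected [x0, x1]")
                fspec.zone = (float(zone[0]), float(zone[1]))
            elif key == "jitter_sweeps":
                js = fld[key]
                if not isinstance(js, int) or js < 0:
                    raise ConfigError("field.jitter_sweeps: expected int >= 0")
                fspec.jitter_sweeps = js
            elif key == "phi":
                phi = fld[key]
                if not isinstance(phi, (int, float)) or phi < 0:
                    raise ConfigError("field.phi: must be >= 0")
                fspec.phi = float(phi)
            else:
                setattr(fspec, key, _positive(fld, key, "field", getattr(fspec, key)))

    par = _require_mapping(raw.get("particles"), "particles")
    _check_keys(par, {"n", "dt"}, "particles")
    n = par.get("n", 10_000)
    if not isinstance(n, int) or n <= 0:
        raise ConfigError("particles.n: expected a positive integer")
    particles = ParticleSpec(n=n, dt=_positive(par, "dt", "particles", 5e-5))

    interactions = None
    if "interactions" in raw and raw["interactions"] is not None:
        inter = _require_mapping(raw["interactions"], "interactions")
        _check_keys(inter, {"k", "cutoff"}, "interactions")
        k = inter.get("k", 0.0)
        if not isinstance(k, (int, float)) or k < 0:
            raise ConfigError("interactions.k: must be >= 0")
        cutoff = inter.get("cutoff")
        if cutoff is not None and (
            not isinstance(cutoff, (int, float)) or cutoff <= 0
        ):
            raise ConfigError("interactions.cutoff: must be positive")
        interactions = InteractionSpec(k=float(k), cutoff=cutoff)

    run = _require_mapping(raw.get("run"), "run")
    _check_keys(run, {"epochs", "snapshot_interval", "seed"}, "run")
    for key, default in (("epochs", 10_000), ("snapshot_interval", 100), ("seed", 1)):
        val = run.get(key, default)
        if not isinstance(val, int) or isinstance(val, bool) or (
            val <= 0 and key != "seed"
        ):
            raise ConfigError(f"run.{key}: expected a positive integer")
    runspec = RunSpec(
        epochs=run.get("epochs", 10_000),
        snapshot_interval=run.get("snapshot_interval", 100),
        seed=run.get("seed", 1),
    )

    cfg = RunConfig(
        region=region,
        field=fspec,
        particles=particles,
        interactions=interactions,
        run=runspec,
    )
    cfg.validate()
    return cfg
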