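"""Random-walk engine: stepping, reflection, interactions, orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difflens.config import (
    FieldSpec,
    InteractionSpec,
    ParticleSpec,
    RunConfig,
    RunSpec,
)
from difflens.engine import (
    InteractionRule,
    StepRule,
    advance,
    advance_interacting,
    count_neighbors,
    reflect,
    run_simulation,
    step_limit_from_D,
)
from difflens.fields import Region, UniformField


class TestStepLimit:
    def test_zero_diffusivity_gives_zero_step(self):
        assert step_limit_from_D(0.0, 5e-5) == 0.0

    def test_reference_value(self):
        # D = 5 μm²/s, dt = 50 μs → S = sqrt(6·5·5e-5) ≈ 0.0387 μm
        assert step_limit_from_D(5.0, 5e-5) == pytest.approx(
            np.sqrt(6 * 5 * 5e-5)
        )

    def test_sqrt_scaling(self):
        # quartering D halves S
        assert step_limit_from_D(1.0, 5e-5) == pytest.approx(
            2 * step_limit_from_D(0.25, 5e-5)
        )

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            step_limit_from_D(-1.0, 5e-5)


class TestReflect:
    def test_interior_unchanged(self):
        r = Region(1.0, 0.45)
        p = np.array([[0.3, 0.2]])
        assert np.array_equal(reflect(p, r), p)

    def test_mirror_below_zero(self):
        r = Region(1.0, 0.45)
        assert reflect(np.array([-0.01, 0.2]), r) == pytest.approx([0.01, 0.2])

    def test_mirror_above_wall(self):
        r = Region(1.0, 0.45)
        assert reflect(np.array([1.2, 0.2]), r) == pytest.approx([0.8, 0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(-5.0, 5.0),
        y=st.floats(-5.0, 5.0),
    )
    def test_always_lands_inside(self, x, y):
        r = Region(1.0, 0.45)
        out = reflect(np.array([x, y]), r)
        assert 0.0 <= out[0] <= r.width and 0.0 <= out[1] <= r.height


class TestAdvance:
    def test_free_diffusion_msd_slope(self):
        # ensemble MSD after m steps of free diffusion is 4·D·m·dt
        region = Region(50.0, 50.0)
        f = UniformField(5.0, region)
        rule = StepRule(dt=5e-5)
        rng = np.random.default_rng(1)
        pos0 = region.sample_uniform(20_000, rng)
        pos = pos0.copy()
        m = 50
        for _ in range(m):
            pos = advance(pos, f, rule, rng)
        msd = np.mean(np.sum((pos - pos0) ** 2, axis=1))
        assert msd == pytest.approx(4 * 5.0 * m * 5e-5, rel=0.03)

    def test_containment(self):
        region = Region(1.0, 0.45)
        f = UniformField(5.0, region)
        rule = StepRule(dt=5e-5)
        rng = np.random.default_rng(2)
        pos = region.sample_uniform(500, rng)
        for _ in range(200):
            pos = advance(pos, f, rule, rng)
            assert region.contains(pos).all()


class TestNeighbors:
    def test_single_particle_has_none(self):
        assert count_neighbors(np.array([[0.5, 0.2]]), 0.1, index=0) == 0

    def test_closed_ball_at_exact_cutoff(self):
        pos = np.array([[0.0, 0.0], [0.1, 0.0]])
        assert count_neighbors(pos, 0.1, index=0) == 1
        assert count_neighbors(pos, 0.1, index=1) == 1

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 1, (100, 2))
        cutoff = 0.15
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        brute = (d <= cutoff).sum(axis=1)
        assert np.array_equal(count_neighbors(pos, cutoff), brute)


class TestInteractions:
    def test_suppression_formula(self):
        rule = InteractionRule(k=0.1, cutoff=0.1)
        assert rule.suppression(10) == pytest.approx(np.exp(-1.0))

    def test_k_zero_identical_to_noninteracting(self):
        region = Region(1.0, 0.45)
        f = UniformField(5.0, region)
        rule = StepRule(dt=5e-5)
        inter = InteractionRule(k=0.0, cutoff=0.1)
        pos = region.sample_uniform(200, np.random.default_rng(4))
        a = advance(pos, f, rule, np.random.default_rng(7))
        b = advance_interacting(pos, f, rule, inter, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_mean_step_nonincreasing_in_k(self):
        # mean S_eff decreases with interaction strength at fixed config
        region = Region(1.0, 0.45)
        pos = region.sample_uniform(300, np.random.default_rng(5))
        S = step_limit_from_D(5.0, 5e-5)
        means = []
        for k in (0.0, 0.05, 0.2):
            n = count_neighbors(pos, 0.1)
            means.append(np.mean(S * np.exp(-k * n)))
        assert means[0] >= means[1] >= means[2]
        assert means[2] < means[0]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            InteractionRule(k=-1.0, cutoff=0.1)
        with pytest.raises(ValueError):
            InteractionRule(k=0.1, cutoff=0.0)


class TestRunSimulation:
    def test_seed_reproducibility_bit_identical(self):
        cfg = RunConfig(
            particles=ParticleSpec(n=100, dt=5e-5),
            run=RunSpec(epochs=200, snapshot_interval=50, seed=1),
        )
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert a.config_fingerprint == b.config_fingerprint

    def test_different_seeds_differ(self):
        mk = lambda s: RunConfig(
            particles=ParticleSpec(n=100, dt=5e-5),
            run=RunSpec(epochs=50, snapshot_interval=50, seed=s),
        )
        a, b = run_simulation(mk(1)), run_simulation(mk(2))
        assert not np.array_equal(a.positions, b.positions)

    def test_snapshot_interval_equal_to_epochs_gives_two_frames(self):
        cfg = RunConfig(
            particles=ParticleSpec(n=50, dt=5e-5),
            run=RunSpec(epochs=100, snapshot_interval=100, seed=1),
        )
        store = run_simulation(cfg)
        assert store.n_frames == 2
        assert list(store.epochs) == [0, 100]

    def test_particle_conservation_and_containment(self):
        cfg = RunConfig(
            field=FieldSpec(kind="step", D_low=1.0, D_high=5.0),
            particles=ParticleSpec(n=300, dt=5e-5),
            run=RunSpec(epochs=500, snapshot_interval=100, seed=3),
        )
        store = run_simulation(cfg)
        assert store.positions.shape[1] == 300
        for frame in store.positions:
            assert cfg.region.contains(frame).all()

    def test_interacting_run_conserves_particles(self):
        cfg = RunConfig(
            field=FieldSpec(kind="gradient", D_min=0.5, D_max=5.0),
            particles=ParticleSpec(n=200, dt=5e-5),
            interactions=InteractionSpec(k=0.04),
            run=RunSpec(epochs=300, snapshot_interval=100, seed=1),
        )
        store = run_simulation(cfg)
        assert store.positions.shape[1] == 200

    def test_store_round_trip(self, tmp_path):
        cfg = RunConfig(
            particles=ParticleSpec(n=50, dt=5e-5),
            run=RunSpec(epochs=100, snapshot_interval=50, seed=1),
        )
        store = run_simulation(cfg)
        path = tmp_path / "run.npz"
        store.save(path)
        from difflens.engine import TrajectoryStore

        back = TrajectoryStore.load(path)
        assert np.array_equal(back.positions, store.positions)
        assert back.seed == store.seed
        assert back.dt == store.dt
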