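"""Microrheology, FRAP, dwell-time and density assays."""

import numpy as np
import pytest

from difflens.assays import (
    AssayError,
    EmptyROIError,
    MSDCurve,
    compute_msd,
    concentration_profile,
    fit_diffusion_coefficient,
    local_density,
    mean_dwell_time,
    saturation_msd,
    simulate_frap,
    t_half_from_curve,
    uniformity_pvalue,
)
from difflens.config import FieldSpec, ParticleSpec, RunConfig, RunSpec
from difflens.engine import TrajectoryStore, run_simulation
from difflens.fields import (
    GranuleField,
    GranulePacking,
    Region,
    UniformField,
    pack_granules,
)


def _store_from_positions(positions, dt=5e-5, region=None):
    f = positions.shape[0]
    return TrajectoryStore(
        epochs=np.arange(f),
        positions=positions,
        dt=dt,
        seed=0,
        region=region or Region(),
    )


class TestMSD:
    def test_immobile_particles_zero_msd(self):
        pos = np.tile(np.array([[[0.5, 0.2]]]), (10, 7, 1))
        curve = compute_msd(_store_from_positions(pos))
        assert np.allclose(curve.msd, 0.0)
        assert curve.msd[0] == 0.0

    def test_max_lag_beyond_run_rejected(self):
        pos = np.zeros((5, 3, 2))
        with pytest.raises(AssayError):
            compute_msd(_store_from_positions(pos), max_lag=1.0)

    def test_exact_line_recovers_D_to_machine_precision(self):
        lags = np.linspace(0, 0.1, 50)
        curve = MSDCurve(
            lags=lags, msd=4 * 3.2 * lags, sem=np.zeros_like(lags),
            n_trajectories=1,
        )
        assert fit_diffusion_coefficient(curve, (0, 0.1)) == pytest.approx(
            3.2, rel=1e-12
        )

    def test_fit_needs_three_points(self):
        lags = np.linspace(0, 0.1, 50)
        curve = MSDCurve(lags, 4 * lags, np.zeros_like(lags), 1)
        with pytest.raises(AssayError):
            fit_diffusion_coefficient(curve, (0, 0.001))

    def test_saturation_requires_flat_tail(self):
        lags = np.linspace(0, 1, 100)
        rising = MSDCurve(lags, lags.copy(), np.zeros_like(lags), 1)
        with pytest.raises(AssayError):
            saturation_msd(rising)
        flat = MSDCurve(lags, np.full_like(lags, 0.2), np.zeros_like(lags), 1)
        assert saturation_msd(flat) == pytest.approx(0.2)

    def test_confined_saturation_matches_box_variance(self):
        # saturation MSD in a box = (Lx² + Ly²)/6, independent of D
        cfg = RunConfig(
            field=FieldSpec(kind="uniform", D=5.0),
            particles=ParticleSpec(n=3000, dt=5e-5),
            run=RunSpec(epochs=4000, snapshot_interval=40, seed=7),
        )
        curve = compute_msd(run_simulation(cfg))
        expected = (1.0**2 + 0.45**2) / 6.0
        assert saturation_msd(curve) == pytest.approx(expected, rel=0.05)


class TestFRAP:
    def test_t_half_first_crossing(self):
        t = np.linspace(0, 1, 101)
        norm = np.clip(2 * t, 0, 1)
        t_half, censored = t_half_from_curve(t, norm, smooth_window=1)
        assert not censored
        assert t_half == pytest.approx(0.25, abs=0.02)

    def test_non_recovering_curve_censored(self):
        t = np.linspace(0, 1, 50)
        t_half, censored = t_half_from_curve(t, np.full_like(t, 0.1))
        assert censored and t_half is None

    def test_roi_must_be_inside_region(self):
        f = UniformField(5.0, Region())
        with pytest.raises(AssayError):
            simulate_frap(f, (0.05, 0.225), 0.2, n_particles=100,
                          burn_in=1, recovery_epochs=1, seed=1)

    def test_empty_roi_raises(self):
        f = UniformField(5.0, Region(10.0, 10.0))
        with pytest.raises(EmptyROIError):
            simulate_frap(f, (5.0, 5.0), 0.2, n_particles=3,
                          burn_in=0, recovery_epochs=1, seed=5,
                          reference_level=1.0)

    def test_uniform_recovery_reaches_plateau_near_one(self):
        f = UniformField(5.0, Region())
        curve = simulate_frap(
            f, (0.5, 0.225), 0.2, n_particles=20_000, burn_in=200,
            recovery_epochs=1500, seed=1,
        )
        assert not curve.censored
        assert curve.normalized[-200:].mean() == pytest.approx(1.0, abs=0.1)
        assert curve.n_bleached > 0

    def test_doubling_diffusivity_halves_t_half(self):
        # homogeneous recovery is a pure Brownian timescale rescaling
        halves = []
        for D in (2.0, 4.0):
            vals = []
            for seed in (1, 2, 3):
                c = simulate_frap(
                    UniformField(D, Region()), (0.5, 0.225), 0.2,
                    n_particles=20_000, burn_in=100, recovery_epochs=2500,
                    seed=seed,
                )
                vals.append(c.t_half)
            halves.append(np.mean(vals))
        assert halves[0] / halves[1] == pytest.approx(2.0, rel=0.35)


class TestDwell:
    def _packing(self):
        region = Region()
        return GranulePacking(
            np.array([[0.5, 0.225]]), 0.05, 0.05, 5.0, region, 0.0
        )

    def test_particle_inside_for_entire_run(self):
        pk = self._packing()
        pos = np.tile(np.array([[[0.5, 0.225]]]), (11, 1, 1))
        store = _store_from_positions(pos)
        stats = mean_dwell_time(store, pk)
        assert stats.normalized_fraction == pytest.approx(1.0)
        assert stats.n_episodes == 1

    def test_no_granules_reports_absent_not_zero(self):
        pk = GranulePacking(
            np.empty((0, 2)), 0.01, 0.05, 5.0, Region(), 0.0
        )
        pos = np.zeros((5, 3, 2)) + 0.2
        stats = mean_dwell_time(_store_from_positions(pos), pk)
        assert stats.mean_dwell is None
        assert stats.normalized_fraction is None
        assert stats.n_episodes == 0

    def test_episode_segmentation(self):
        # one particle: in, out, in-in → two episodes, mean 1.5 frames
        pk = self._packing()
        inside, outside = [0.5, 0.225], [0.1, 0.1]
        pos = np.array([[inside], [outside], [inside], [inside]])
        store = _store_from_positions(pos, dt=1.0)
        stats = mean_dwell_time(store, pk)
        assert stats.n_episodes == 2
        assert stats.mean_dwell == pytest.approx(1.5)

    def test_geometry_only_baseline_at_unity_ratio(self):
        # μi/μo = 1: dwell equals a uniform-field control with the same
        # labels — dynamics cannot distinguish the phases
        region = Region()
        pk = pack_granules(region, 0.05, 0.2, mu_ratio=1.0,
                           rng=np.random.default_rng(8))
        cfg = RunConfig(
            field=FieldSpec(kind="uniform", D=5.0),
            particles=ParticleSpec(n=500, dt=5e-5),
            run=RunSpec(epochs=500, snapshot_interval=1, seed=9),
        )
        store = run_simulation(cfg)
        a = mean_dwell_time(store, pk)
        gcfg = RunConfig(
            field=FieldSpec(kind="granules", r=0.05, phi=0.2, mu_ratio=1.0),
            particles=ParticleSpec(n=500, dt=5e-5),
            run=RunSpec(epochs=500, snapshot_interval=1, seed=9),
        )
        # same seed → same packing stream → same dynamics when μ-ratio=1
        gstore = run_simulation(gcfg)
        gfield = gcfg.build_field(
            np.random.default_rng(np.random.SeedSequence(9).spawn(2)[0])
        )
        b = mean_dwell_time(gstore, gfield.packing)
        assert a.n_episodes > 0 and b.n_episodes > 0
        assert b.mean_dwell == pytest.approx(a.mean_dwell, rel=0.5)

    def test_dwell_increases_as_interior_diffusivity_drops(self):
        region = Region()
        means = []
        for mu in (1.0, 0.1):
            pk = pack_granules(region, 0.05, 0.2, mu_ratio=mu,
                               rng=np.random.default_rng(4))
            field = GranuleField(pk)
            from difflens.engine import StepRule, advance

            rng = np.random.default_rng(11)
            pos = region.sample_uniform(2000, rng)
            frames = [pos.copy()]
            rule = StepRule(5e-5)
            for _ in range(400):
                pos = advance(pos, field, rule, rng)
                frames.append(pos.copy())
            store = _store_from_positions(np.stack(frames))
            means.append(mean_dwell_time(store, pk).mean_dwell)
        assert means[1] > means[0]


class TestDensity:
    def test_uniform_ensemble_normalizes_to_one(self):
        rng = np.random.default_rng(0)
        region = Region(3.0, 3.0)
        pos = region.sample_uniform(2000, rng)
        base = [region.sample_uniform(2000, rng) for _ in range(3)]
        dens = local_density(pos, 0.15, base)
        assert dens.mean() == pytest.approx(1.0, rel=0.1)

    def test_matches_bruteforce_counts(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 1, (200, 2))
        cutoff = 0.1
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        brute = (d <= cutoff).sum(axis=1).astype(float)
        base = [pos]
        dens = local_density(pos, cutoff, base)
        assert np.allclose(dens, brute / brute.mean())

    def test_chi2_uniformity_helper(self):
        rng = np.random.default_rng(2)
        region = Region()
        pos = region.sample_uniform(10_000, rng)
        assert uniformity_pvalue(pos, region) > 0.01
        clumped = pos.copy()
        clumped[:, 0] *= 0.3
        assert uniformity_pvalue(clumped, region) < 1e-6


class TestConcentrationProfile:
    def test_uniform_field_flat_profile(self):
        cfg = RunConfig(
            particles=ParticleSpec(n=5000, dt=5e-5),
            run=RunSpec(epochs=1000, snapshot_interval=100, seed=1),
        )
        store = run_simulation(cfg)
        prof = concentration_profile(store, n_bins=10)
        assert prof.density.std() / prof.density.mean() < 0.1

    def test_step_profile_matches_inverse_diffusivity(self):
        cfg = RunConfig(
            field=FieldSpec(kind="step", D_low=1.25, D_high=5.0),
            particles=ParticleSpec(n=5000, dt=5e-5),
            run=RunSpec(epochs=6000, snapshot_interval=100, seed=1),
        )
        store = run_simulation(cfg)
        field = cfg.build_field()
        prof = concentration_profile(store, n_bins=20, field=field)
        low = prof.density[prof.bin_centers <= 0.2].mean()
        high = prof.density[prof.bin_centers >= 0.35].mean()
        assert low / high == pytest.approx(4.0, rel=0.15)
        # overlay integrates to unit mass on the same bins
        widths = np.diff(np.linspace(0, 1, 21))
        assert (prof.closed_form * widths).sum() == pytest.approx(1.0)

    def test_sparse_store_warns(self):
        pos = np.zeros((2, 20, 2)) + 0.2
        store = _store_from_positions(pos)
        with pytest.warns(UserWarning):
            concentration_profile(store, n_bins=20)
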