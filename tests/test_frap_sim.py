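"""Unit and property tests of the Monte Carlo simulation core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frapmc.frap_sim import (
    BOUND1,
    BOUND2,
    FREE,
    AcquisitionProtocol,
    BleachProfile,
    CoarseTimestepError,
    InvalidParameterError,
    MobilityParams,
    NucleusGeometry,
    SimState,
    apply_bleach,
    calibrate_dose,
    equilibrium_rates,
    init_particles,
    measure_roi,
    simulate_frap,
    step_diffusion,
    step_kinetics,
)


class TestMobilityParams:
    def test_free_fraction_complements_bound(self, tel_params):
        assert tel_params.free_fraction == pytest.approx(0.23)
        assert sum(tel_params.fractions) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"D": -1.0},
            {"D": 3.0, "f1": 0.5, "f2": 0.6},  # fractions exceed 1
            {"D": 3.0, "f1": -0.1},
            {"D": 3.0, "f1": 0.2, "T1": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            MobilityParams(**kwargs)

    def test_canonical_orders_residence_times(self):
        p = MobilityParams(D=3.0, f1=0.2, T1=50.0, f2=0.3, T2=1.0).canonical()
        assert p.T1 <= p.T2
        assert (p.f1, p.T1, p.f2, p.T2) == (0.3, 1.0, 0.2, 50.0)


class TestEquilibriumRates:
    def test_tel_preset_probabilities(self, tel_params):
        # closed-form first-order probabilities at dt = 1 ms
        probs = equilibrium_rates(tel_params, dt=0.001)
        assert probs.p_off1 == pytest.approx(0.001 / 0.63, rel=1e-9)
        assert probs.p_off2 == pytest.approx(0.001 / 59.0, rel=1e-9)
        assert probs.p_on1 == pytest.approx((0.57 / 0.23) * 0.001 / 0.63, rel=1e-9)
        assert probs.p_on2 == pytest.approx((0.20 / 0.23) * 0.001 / 59.0, rel=1e-9)

    def test_no_binding_without_bound_fractions(self):
        probs = equilibrium_rates(MobilityParams(D=5.0), dt=0.001)
        assert probs.p_on1 == 0.0 and probs.p_on2 == 0.0

    def test_coarse_timestep_rejected(self, tel_params):
        with pytest.raises(CoarseTimestepError):
            equilibrium_rates(tel_params, dt=0.3)  # > T1/10

    def test_placeholder_residence_ignored_when_fraction_zero(self):
        # T1 = 0.1 would demand dt <= 0.01, but f1 = 0 makes it inactive
        p = MobilityParams(D=3.0, f1=0.0, T1=0.1, f2=0.2, T2=10.0)
        probs = equilibrium_rates(p, dt=0.02)
        assert probs.p_on1 == 0.0

    def test_stationary_occupancy_of_markov_chain(self, tel_params, geometry):
        # long-run occupancies of the pure exchange chain must equal
        # (f0, f1, f2); multinomial 3-sigma oracle
        n = 30_000
        state = init_particles(geometry, tel_params, n, seed=7)
        probs = equilibrium_rates(tel_params, dt=0.01)
        for _ in range(2000):
            step_kinetics(state, probs)
        for code, f in ((FREE, 0.23), (BOUND1, 0.57), (BOUND2, 0.20)):
            count = int(np.sum(state.kinetic_state == code))
            sigma = np.sqrt(n * f * (1 - f))
            assert abs(count - n * f) < 3 * sigma

    def test_mean_bound_dwell_matches_residence_time(self, geometry):
        # geometric dwell oracle: mean consecutive dwell in bound1 = T1/dt
        params = MobilityParams(D=1.0, f1=0.4, T1=0.05, f2=0.0, T2=1.0)
        dt = 0.002
        n = 1500
        state = init_particles(geometry, params, n, seed=11)
        probs = equilibrium_rates(params, dt)
        was = state.kinetic_state == BOUND1
        run = np.zeros(n)
        started = np.zeros(n, dtype=bool)  # dwell began inside the observation
        dwells = []
        # horizon long enough that right-censoring bias << the 3-sigma band
        for _ in range(12_000):
            step_kinetics(state, probs)
            now = state.kinetic_state == BOUND1
            exited = was & ~now
            dwells.extend(run[exited & started])
            run[exited] = 0
            started[now & ~was] = True
            started[exited] = False
            run[now] += 1
            was = now
        dwells = np.asarray(dwells)
        expected = params.T1 / dt  # 25 substeps
        sem = dwells.std() / np.sqrt(dwells.size)
        assert abs(dwells.mean() - expected) < 3 * sem


class TestInitParticles:
    def test_all_inside_and_fluorescent(self, geometry, tel_params):
        state = init_particles(geometry, tel_params, 20_000, seed=1)
        assert geometry.contains(state.positions).all()
        assert state.fluorescent.all()

    def test_state_counts_binomial(self, geometry, tel_params):
        n = 100_000
        state = init_particles(geometry, tel_params, n, seed=2)
        count = int(np.sum(state.kinetic_state == BOUND2))
        sigma = np.sqrt(n * 0.20 * 0.80)
        assert abs(count - 0.20 * n) < 3 * sigma

    def test_all_free_when_no_bound_fraction(self, geometry):
        state = init_particles(geometry, MobilityParams(D=5.0), 5000, seed=3)
        assert (state.kinetic_state == FREE).all()

    def test_seed_reproducibility(self, geometry, tel_params):
        s1 = init_particles(geometry, tel_params, 1000, seed=9)
        s2 = init_particles(geometry, tel_params, 1000, seed=9)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.kinetic_state, s2.kinetic_state)

    def test_rejects_empty_ensemble(self, geometry, tel_params):
        with pytest.raises(InvalidParameterError):
            init_particles(geometry, tel_params, 0, seed=1)


class TestStepDiffusion:
    def test_zero_diffusion_is_identity(self, geometry, tel_params):
        state = init_particles(geometry, tel_params, 1000, seed=4)
        before = state.positions.copy()
        step_diffusion(state, D=0.0, dt=0.001, geometry=geometry)
        np.testing.assert_array_equal(state.positions, before)

    def test_bound_particles_do_not_move(self, geometry):
        params = MobilityParams(D=10.0, f1=0.3, T1=1.0, f2=0.3, T2=10.0)
        state = init_particles(geometry, params, 5000, seed=5)
        bound = state.kinetic_state != FREE
        before = state.positions[bound].copy()
        step_diffusion(state, D=10.0, dt=0.001, geometry=geometry)
        np.testing.assert_array_equal(state.positions[bound], before)

    def test_msd_matches_free_diffusion(self):
        # far from any boundary the MSD after k steps is 6*D*k*dt (3-sigma)
        big = NucleusGeometry(100.0, 100.0, 100.0)
        D, dt, k, n = 1.0, 0.001, 500, 4000
        state = init_particles(big, MobilityParams(D=D), n, seed=6)
        start = state.positions.copy()
        for _ in range(k):
            step_diffusion(state, D, dt, big)
        sq = ((state.positions - start) ** 2).sum(axis=1)
        expected = 6 * D * k * dt
        sem = sq.std() / np.sqrt(n)
        assert abs(sq.mean() - expected) < 3 * sem

    @settings(max_examples=15, deadline=None)
    @given(
        a=st.floats(1.0, 8.0),
        c=st.floats(0.5, 3.0),
        D=st.floats(0.1, 25.0),
        seed=st.integers(0, 2**20),
    )
    def test_reflection_preserves_containment(self, a, c, D, seed):
        geom = NucleusGeometry(a, a / 2 + 0.5, c)
        state = init_particles(geom, MobilityParams(D=D), 300, seed=seed)
        for _ in range(50):
            step_diffusion(state, D, 0.001, geom)
        assert geom.contains(state.positions).all()


class TestMeasureRoi:
    def test_counts_match_slab_volume_fraction(self, geometry):
        # numerical-integration oracle for the slab/ellipsoid overlap
        from scipy.integrate import quad

        protocol = AcquisitionProtocol()
        n = 200_000
        state = init_particles(geometry, MobilityParams(D=1.0), n, seed=8)
        count = measure_roi(state, protocol)
        a = geometry.semi_axis_x
        w = protocol.roi_width
        num, _ = quad(lambda x: 1 - (x / a) ** 2, -w / 2, w / 2)
        den, _ = quad(lambda x: 1 - (x / a) ** 2, -a, a)
        frac = num / den
        sigma = np.sqrt(n * frac * (1 - frac))
        assert abs(count - n * frac) < 3 * sigma

    def test_bleached_particles_not_counted(self, geometry):
        state = init_particles(geometry, MobilityParams(D=1.0), 1000, seed=9)
        state.fluorescent[:] = False
        assert measure_roi(state, AcquisitionProtocol()) == 0


class TestApplyBleach:
    def test_zero_dose_bleaches_nothing(self, geometry, tel_params):
        protocol = AcquisitionProtocol(sim_substep=0.007)
        state = init_particles(geometry, tel_params, 2000, seed=10)
        apply_bleach(state, BleachProfile(dose=0.0), protocol, geometry, tel_params)
        assert state.fluorescent.all()

    def test_survival_probability_outside_strip(self, geometry):
        # at 3 lateral sigmas outside the edge, dose 2:
        # p_bleach = 1 - exp(-2 * exp(-4.5)) per iteration
        profile = BleachProfile(dose=2.0, lateral_sigma=0.2)
        protocol = AcquisitionProtocol(bleach_iterations=1, sim_substep=0.021)
        params = MobilityParams(D=0.0)  # frozen positions
        n = 40_000
        state = init_particles(geometry, params, n, seed=11)
        x = protocol.roi_width / 2 + 3 * profile.lateral_sigma
        state.positions[:, 0] = x
        apply_bleach(state, profile, protocol, geometry, params)
        p_expected = 1.0 - np.exp(-2.0 * np.exp(-4.5))
        bleached = n - int(state.fluorescent.sum())
        sigma = np.sqrt(n * p_expected * (1 - p_expected))
        assert abs(bleached - n * p_expected) < 3 * sigma


class TestSimulateFrap:
    def test_conservation_without_bleach(self, geometry, tel_params, short_protocol):
        curve = simulate_frap(
            geometry, tel_params, short_protocol, BleachProfile(dose=0.0),
            n_particles=3000, seed=12,
        )
        assert curve.replicate_meta["final_unbleached_fraction"] == 1.0

    def test_stationarity_without_bleach(self, geometry, tel_params, profile):
        # no-bleach ROI trace has zero trend (slope consistent with 0)
        protocol = AcquisitionProtocol(
            n_scans=400, n_prebleach=399, sim_substep=0.007
        )
        curve = simulate_frap(
            geometry, tel_params, protocol, BleachProfile(dose=0.0),
            n_particles=8000, seed=13,
        )
        t, y = curve.time, curve.intensity
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        se = resid.std(ddof=2) / (t.std() * np.sqrt(len(t)))
        assert abs(slope) < 3 * se

    def test_prebleach_average_is_one(self, geometry, tel_params, short_protocol, profile):
        curve = simulate_frap(
            geometry, tel_params, short_protocol, profile, n_particles=3000, seed=14
        )
        pre = curve.intensity[: short_protocol.n_prebleach]
        assert pre.mean() == pytest.approx(1.0)
        assert (curve.intensity >= 0).all()

    def test_full_mixing_recovers_unbleached_fraction(self, geometry, profile):
        # conservation oracle: with no binding and fast diffusion the
        # plateau equals the unbleached-pool fraction counted directly
        protocol = AcquisitionProtocol(
            n_scans=400, n_prebleach=50, sim_substep=0.003
        )
        curve = simulate_frap(
            geometry, MobilityParams(D=25.0), protocol, profile,
            n_particles=30_000, seed=15,
        )
        plateau = curve.intensity[-80:].mean()
        unbleached = curve.replicate_meta["final_unbleached_fraction"]
        assert plateau == pytest.approx(unbleached, abs=0.03)

    def test_locked_pool_pins_curve_to_floor(self, geometry, profile):
        # 90% immobile beyond the window: recovery stays near the
        # bleach-depth floor plus the small mobile component
        params = MobilityParams(D=3.0, f1=0.45, T1=300.0, f2=0.45, T2=300.0)
        protocol = AcquisitionProtocol(sim_substep=0.007)
        curve = simulate_frap(
            geometry, params, protocol, profile, n_particles=10_000, seed=16
        )
        depth = curve.intensity[protocol.n_prebleach]
        plateau = curve.intensity[-100:].mean()
        # the mobile 10% can at most refill its own share of the dip
        assert plateau < depth + 0.15
        assert plateau < 0.35

    def test_final_level_monotone_in_long_bound_fraction(self, geometry, profile):
        # at fixed D and bleach, more long-term binding means less recovery
        protocol = AcquisitionProtocol(
            n_scans=500, n_prebleach=50, sim_substep=0.007
        )
        plateaus = []
        for f2 in (0.0, 0.3, 0.6):
            params = MobilityParams(D=3.0, f2=f2, T2=300.0)
            curve = simulate_frap(
                geometry, params, protocol, profile, n_particles=8000, seed=17
            )
            plateaus.append(curve.intensity[-80:].mean())
        assert plateaus[0] > plateaus[1] > plateaus[2]

    def test_identical_seed_identical_curve(self, geometry, tel_params, short_protocol, profile):
        c1 = simulate_frap(
            geometry, tel_params, short_protocol, profile, n_particles=2000, seed=18
        )
        c2 = simulate_frap(
            geometry, tel_params, short_protocol, profile, n_particles=2000, seed=18
        )
        np.testing.assert_array_equal(c1.intensity, c2.intensity)
        c3 = simulate_frap(
            geometry, tel_params, short_protocol, profile, n_particles=2000, seed=19
        )
        assert not np.array_equal(c1.intensity, c3.intensity)

    def test_fast_and_reference_engines_agree(self, geometry, tel_params, short_protocol, profile):
        # the compiled kernel and the public-op composition are
        # statistically equivalent realizations of the same model
        fast = simulate_frap(
            geometry, tel_params, short_protocol, profile,
            n_particles=4000, n_replicates=2, seed=20, engine="fast",
        )
        ref = simulate_frap(
            geometry, tel_params, short_protocol, profile,
            n_particles=4000, n_replicates=2, seed=20, engine="reference",
        )
        post = slice(short_protocol.n_prebleach, None)
        assert fast.intensity[post].mean() == pytest.approx(
            ref.intensity[post].mean(), abs=0.04
        )
        assert fast.intensity[post][-30:].mean() == pytest.approx(
            ref.intensity[post][-30:].mean(), abs=0.05
        )

    def test_roi_axis_permutation_consistent(self, tel_params, profile):
        # simulating along y in a permuted nucleus matches the x-axis run
        protocol_x = AcquisitionProtocol(
            n_scans=150, n_prebleach=30, sim_substep=0.007, roi_axis="x"
        )
        protocol_y = AcquisitionProtocol(
            n_scans=150, n_prebleach=30, sim_substep=0.007, roi_axis="y"
        )
        gx = NucleusGeometry(6.0, 4.0, 2.5)
        gy = NucleusGeometry(4.0, 6.0, 2.5)
        cx = simulate_frap(gx, tel_params, protocol_x, profile, 3000, seed=21)
        cy = simulate_frap(gy, tel_params, protocol_y, profile, 3000, seed=21)
        post = slice(30, None)
        assert cx.intensity[post].mean() == pytest.approx(
            cy.intensity[post].mean(), abs=0.04
        )


def test_calibrate_dose_reaches_requested_depth(geometry, profile):
    protocol = AcquisitionProtocol(
        n_scans=120, n_prebleach=100, sim_substep=0.007
    )
    dose = calibrate_dose(
        0.3, geometry, protocol, profile, D=3.0, n_particles=5000, seed=22
    )
    from dataclasses import replace

    curve = simulate_frap(
        geometry, MobilityParams(D=3.0), protocol, replace(profile, dose=dose),
        n_particles=10_000, seed=23,
    )
    assert curve.intensity[protocol.n_prebleach] == pytest.approx(0.3, abs=0.05)


def test_protocol_validation():
    with pytest.raises(InvalidParameterError):
        AcquisitionProtocol(n_prebleach=1000)  # not < n_scans
    with pytest.raises(InvalidParameterError):
        AcquisitionProtocol(sim_substep=0.004)  # not a divisor of 21 ms
    with pytest.raises(InvalidParameterError):
        AcquisitionProtocol(roi_axis="w")
    times = AcquisitionProtocol().scan_times()
    assert times.size == 1000
    # bleach gap: 3 scan intervals inserted after scan 100
    assert times[100] - times[99] == pytest.approx(4 * 0.021)
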