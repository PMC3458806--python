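"""Particle-based Monte Carlo simulation of strip-FRAP in an ellipsoidal nucleus.

The model: fluorescently tagged molecules move by free diffusion
(coefficient ``D``) inside an ellipsoidal nucleus and exchange between a
free state and two immobile bound states. Bound class ``i`` holds a
fraction ``f_i`` of molecules at equilibrium and releases with rate
``1/T_i`` (``T_i`` is the mean residence time). A narrow strip spanning
the nucleus is photobleached with a short multi-iteration pulse and the
fluorescence in that strip is read out at every scan; the normalized
recovery curve encodes ``D``, the bound fractions, and the residence
times.

Simulation is first-order in time: each scan interval is divided into
substeps, and within a substep free molecules take Gaussian steps
(per-axis variance ``2 D dt``, specular reflection at the nuclear
envelope) while binding/release events occur with the per-substep
probabilities returned by :func:`equilibrium_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

import numpy as np

from . import _kernels

__all__ = [
    "NucleusGeometry",
    "MobilityParams",
    "AcquisitionProtocol",
    "BleachProfile",
    "SimState",
    "SimulatedCurve",
    "TransitionProbs",
    "InvalidParameterError",
    "CoarseTimestepError",
    "FREE",
    "BOUND1",
    "BOUND2",
    "equilibrium_rates",
    "init_particles",
    "step_diffusion",
    "step_kinetics",
    "apply_bleach",
    "measure_roi",
    "roi_volume_fraction",
    "simulate_frap",
    "calibrate_dose",
]

# kinetic state codes
FREE, BOUND1, BOUND2 = 0, 1, 2

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class InvalidParameterError(ValueError):
    """A kinetic or geometric parameter violates its constraints."""


class CoarseTimestepError(ValueError):
    """The simulation substep is too coarse for the requested kinetics."""


@dataclass(frozen=True)
class NucleusGeometry:
    """Ellipsoidal nucleus, semi-axes in micrometres, centred at the origin."""

    semi_axis_x: float = 6.0
    semi_axis_y: float = 4.0
    semi_axis_z: float = 2.5

    def __post_init__(self) -> None:
        if min(self.semi_axis_x, self.semi_axis_y, self.semi_axis_z) <= 0:
            raise InvalidParameterError("all semi-axes must be strictly positive")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return (self.semi_axis_x, self.semi_axis_y, self.semi_axis_z)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Elementwise ellipsoid inclusion test for an (n, 3) array."""
        p = np.atleast_2d(positions)
        a, b, c = self.semi_axes
        return (p[:, 0] / a) ** 2 + (p[:, 1] / b) ** 2 + (p[:, 2] / c) ** 2 <= 1.0

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class MobilityParams:
    """Five-parameter mobility model: diffusion plus two bound classes.

    Parameters
    ----------
    D : float
        Diffusion coefficient of the free state, µm²/s.
    f1, f2 : float
        Equilibrium fractions in the short- and long-residence bound
        classes. The free fraction is ``1 - f1 - f2`` and must be
        positive.
    T1, T2 : float
        Mean residence times of the two bound classes, seconds
        (reciprocal of the release rate k_off).
    """

    D: float
    f1: float = 0.0
    T1: float = 1.0
    f2: float = 0.0
    T2: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise InvalidParameterError(f"D must be non-negative, got {self.D}")
        if self.f1 < 0 or self.f2 < 0:
            raise InvalidParameterError("bound fractions must be non-negative")
        if self.f1 + self.f2 >= 1.0:
            raise InvalidParameterError(
                f"f1 + f2 = {self.f1 + self.f2:.3f} leaves no free fraction"
            )
        if self.T1 <= 0 or self.T2 <= 0:
            raise InvalidParameterError("residence times must be positive")

    @property
    def free_fraction(self) -> float:
        return 1.0 - self.f1 - self.f2

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(free, bound1, bound2) equilibrium occupancies."""
        return (self.free_fraction, self.f1, self.f2)

    def canonical(self) -> "MobilityParams":
        """Order the bound classes so that T1 <= T2 (resolves label switching)."""
        if self.f1 > 0 and self.f2 > 0 and self.T1 > self.T2:
            return replace(self, f1=self.f2, T1=self.T2, f2=self.f1, T2=self.T1)
        return self


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan timing, bleach scheduling and ROI geometry of the strip-FRAP assay.

    Defaults follow the acquisition used throughout: 1000 scans of 21 ms,
    a 3-iteration bleach pulse after scan 100, and a strip ROI 10 pixels
    of 80 nm wide (0.8 µm) spanning the nucleus.
    """

    n_scans: int = 1000
    scan_interval: float = 0.021
    n_prebleach: int = 100
    bleach_iterations: int = 3
    roi_width: float = 0.8
    roi_axis: Literal["x", "y", "z"] = "x"
    sim_substep: float = 0.001

    def __post_init__(self) -> None:
        if self.n_prebleach >= self.n_scans:
            raise InvalidParameterError("n_prebleach must be < n_scans")
        if min(self.scan_interval, self.roi_width, self.sim_substep) <= 0:
            raise InvalidParameterError("all time/length quantities must be positive")
        if self.roi_axis not in _AXIS_INDEX:
            raise InvalidParameterError(f"unknown roi_axis {self.roi_axis!r}")
        if self.sim_substep > self.scan_interval:
            raise InvalidParameterError("sim_substep must not exceed scan_interval")
        ratio = self.scan_interval / self.sim_substep
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidParameterError(
                "scan_interval must be an integer multiple of sim_substep"
            )

    @property
    def substeps_per_scan(self) -> int:
        return round(self.scan_interval / self.sim_substep)

    @property
    def roi_axis_index(self) -> int:
        return _AXIS_INDEX[self.roi_axis]

    def scan_times(self) -> np.ndarray:
        """Elapsed time (s) at each measurement, bleach-pulse gap included.

        Scans are timestamped at the end of their scan interval; the
        bleach pulse inserts ``bleach_iterations`` extra intervals
        between scans ``n_prebleach`` and ``n_prebleach + 1``.
        """
        idx = np.arange(1, self.n_scans + 1, dtype=float)
        idx[self.n_prebleach:] += self.bleach_iterations
        return idx * self.scan_interval

    @property
    def postbleach_window(self) -> float:
        """Duration (s) of the observation window after the bleach pulse."""
        t = self.scan_times()
        return float(t[-1] - t[self.n_prebleach - 1])


@dataclass(frozen=True)
class BleachProfile:
    """Laser intensity profile of the strip bleach pulse.

    Flat-top inside the strip with Gaussian lateral shoulders: the
    relative intensity is 1 within the strip and
    ``exp(-d²/(2·lateral_sigma²))`` at signed distance ``d`` outside the
    strip edge, uniform along the strip length and depth. A fluorophore
    at relative intensity I survives one bleach iteration with
    probability ``exp(-dose * I)``.
    """

    dose: float = 1.2
    lateral_sigma: float = 0.15
    axial_uniform: bool = True

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidParameterError("dose must be non-negative")
        if self.lateral_sigma <= 0:
            raise InvalidParameterError("lateral_sigma must be positive")

    def relative_intensity(self, coord: np.ndarray, roi_width: float) -> np.ndarray:
        """Relative beam intensity at ROI-axis coordinate(s) ``coord``."""
        d = np.abs(np.asarray(coord, dtype=float)) - roi_width / 2.0
        out = np.exp(-np.clip(d, 0.0, None) ** 2 / (2.0 * self.lateral_sigma**2))
        return out


@dataclass
class SimState:
    """Mutable particle ensemble state.

    ``kinetic_state`` holds the codes FREE (0), BOUND1 (1), BOUND2 (2).
    """

    positions: np.ndarray
    kinetic_state: np.ndarray
    fluorescent: np.ndarray
    rng: np.random.Generator

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return SimState(
            positions=self.positions.copy(),
            kinetic_state=self.kinetic_state.copy(),
            fluorescent=self.fluorescent.copy(),
            rng=rng,
        )


@dataclass(frozen=True)
class SimulatedCurve:
    """A normalized FRAP curve produced by the simulator."""

    time: np.ndarray
    intensity: np.ndarray
    params: MobilityParams
    replicate_meta: dict = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.time.size


class TransitionProbs(NamedTuple):
    p_on1: float
    p_off1: float
    p_on2: float
    p_off2: float


def equilibrium_rates(params: MobilityParams, dt: float) -> TransitionProbs:
    """Per-substep transition probabilities of the 3-state exchange chain.

    The release probability of bound class i is ``dt / T_i`` and the
    binding probability from the free state is ``(f_i / f0) * dt / T_i``,
    the detailed-balance closure whose stationary distribution is
    ``(f0, f1, f2)`` with mean bound dwell times ``T_i``.

    Raises
    ------
    CoarseTimestepError
        If ``dt`` exceeds one tenth of the shortest active residence
        time, where first-order probabilities stop being valid.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if params.f1 + params.f2 >= 1.0:
        raise InvalidParameterError("f1 + f2 must be < 1")
    active_T = [T for f, T in ((params.f1, params.T1), (params.f2, params.T2)) if f > 0]
    if active_T and dt > min(active_T) / 10.0:
        raise CoarseTimestepError(
            f"dt={dt} too coarse for residence time {min(active_T)} s "
            "(need dt <= T/10)"
        )
    f0 = params.free_fraction
    p_off1 = dt / params.T1
    p_off2 = dt / params.T2
    p_on1 = (params.f1 / f0) * p_off1 if params.f1 > 0 else 0.0
    p_on2 = (params.f2 / f0) * p_off2 if params.f2 > 0 else 0.0
    if p_on1 + p_on2 >= 1.0:
        raise CoarseTimestepError("combined binding probability >= 1; reduce dt")
    return TransitionProbs(p_on1, p_off1, p_on2, p_off2)


def _sample_uniform_ellipsoid(
    rng: np.random.Generator, geometry: NucleusGeometry, n: int
) -> np.ndarray:
    """Uniform points in the ellipsoid by rejection from the bounding box."""
    axes = np.asarray(geometry.semi_axes)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 128)
        cand = rng.uniform(-1.0, 1.0, size=(m, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        take = cand[keep][: n - filled]
        out[filled : filled + take.shape[0]] = take * axes
        filled += take.shape[0]
    return out


def init_particles(
    geometry: NucleusGeometry,
    params: MobilityParams,
    n_particles: int,
    seed: int | np.random.Generator,
) -> SimState:
    """Equilibrium initial state: uniform positions, stationary kinetic states.

    All particles start fluorescent. An identical seed reproduces the
    state exactly.
    """
    if n_particles < 1:
        raise InvalidParameterError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    positions = _sample_uniform_ellipsoid(rng, geometry, n_particles)
    states = rng.choice(
        np.array([FREE, BOUND1, BOUND2], dtype=np.int8),
        size=n_particles,
        p=params.fractions,
    ).astype(np.int8)
    return SimState(
        positions=positions,
        kinetic_state=states,
        fluorescent=np.ones(n_particles, dtype=bool),
        rng=rng,
    )


def step_diffusion(
    state: SimState, D: float, dt: float, geometry: NucleusGeometry
) -> SimState:
    """One diffusion substep: free particles take reflected Gaussian steps.

    Bound particles do not move. The state is updated in place and
    returned.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if D > 0:
        mobile = state.kinetic_state == FREE
        disp = state.rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(state.n_particles, 3))
        a, b, c = geometry.semi_axes
        _kernels.apply_displacements(state.positions, disp, mobile, a, b, c)
    return state


def step_kinetics(state: SimState, probs: TransitionProbs) -> SimState:
    """One kinetics substep: Bernoulli binding/release transitions.

    Free particles bind to class 1 with probability ``p_on1`` and to
    class 2 with probability ``p_on2`` (mutually exclusive); bound
    particles release with their class's ``p_off``. Fluorescence flags
    are untouched. In place, returned.
    """
    if probs.p_on1 + probs.p_on2 >= 1.0:
        raise CoarseTimestepError("p_on1 + p_on2 >= 1: substep too coarse")
    u = state.rng.random(state.n_particles)
    ks = state.kinetic_state
    free = ks == FREE
    to_b1 = free & (u < probs.p_on1)
    to_b2 = free & ~to_b1 & (u < probs.p_on1 + probs.p_on2)
    rel1 = (ks == BOUND1) & (u < probs.p_off1)
    rel2 = (ks == BOUND2) & (u < probs.p_off2)
    ks[to_b1] = BOUND1
    ks[to_b2] = BOUND2
    ks[rel1 | rel2] = FREE
    return state


def apply_bleach(
    state: SimState,
    profile: BleachProfile,
    protocol: AcquisitionProtocol,
    geometry: NucleusGeometry,
    params: MobilityParams,
) -> SimState:
    """Execute the multi-iteration bleach pulse.

    Each iteration stochastically bleaches fluorophores according to the
    beam profile, then one scan interval of diffusion and exchange
    elapses (the iterations are successive scanner passes), so mobile
    molecules exchange into the beam and deepen the bleached pool.
    Bleached molecules keep diffusing and binding.
    """
    probs = equilibrium_rates(params, protocol.sim_substep)
    axis = protocol.roi_axis_index
    for _ in range(protocol.bleach_iterations):
        inten = profile.relative_intensity(state.positions[:, axis], protocol.roi_width)
        survive = state.rng.random(state.n_particles) < np.exp(-profile.dose * inten)
        state.fluorescent &= survive
        for _ in range(protocol.substeps_per_scan):
            step_diffusion(state, params.D, protocol.sim_substep, geometry)
            step_kinetics(state, probs)
    return state


def roi_volume_fraction(
    geometry: NucleusGeometry, protocol: AcquisitionProtocol
) -> float:
    """Analytic fraction of the nucleus volume inside the strip ROI."""
    a = geometry.semi_axes[protocol.roi_axis_index]
    h = min(protocol.roi_width / 2.0, a)
    r = h / a
    return 1.5 * r - 0.5 * r**3


def measure_roi(state: SimState, protocol: AcquisitionProtocol) -> int:
    """Number of fluorescent particles inside the strip ROI."""
    axis = protocol.roi_axis_index
    half = protocol.roi_width / 2.0
    inside = np.abs(state.positions[:, axis]) <= half
    return int(np.count_nonzero(inside & state.fluorescent))


def _validate_sim_config(
    geometry: NucleusGeometry, protocol: AcquisitionProtocol
) -> None:
    semi = geometry.semi_axes[protocol.roi_axis_index]
    if protocol.roi_width >= 2.0 * semi:
        raise InvalidParameterError(
            "roi_width must be smaller than the nucleus along the ROI axis"
        )


def _kernel_geometry(
    geometry: NucleusGeometry, protocol: AcquisitionProtocol
) -> tuple[tuple[float, float, float], list[int]]:
    """Semi-axes and column order with the ROI axis first (kernel convention)."""
    axis = protocol.roi_axis_index
    order = [axis] + [i for i in range(3) if i != axis]
    axes = geometry.semi_axes
    return (axes[order[0]], axes[order[1]], axes[order[2]]), order


def _simulate_replicate_fast(
    geometry: NucleusGeometry,
    params: MobilityParams,
    protocol: AcquisitionProtocol,
    profile: BleachProfile,
    n_particles: int,
    child: np.random.SeedSequence,
) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(child)
    state = init_particles(geometry, params, n_particles, rng)
    probs = equilibrium_rates(params, protocol.sim_substep)
    # initial dwell countdowns drawn from the stationary process
    countdown = np.full(n_particles, _kernels._NEVER, dtype=np.int64)
    p_on = probs.p_on1 + probs.p_on2
    free = state.kinetic_state == FREE
    if p_on > 0:
        countdown[free] = rng.geometric(p_on, size=int(free.sum()))
    b1 = state.kinetic_state == BOUND1
    b2 = state.kinetic_state == BOUND2
    if b1.any():
        countdown[b1] = rng.geometric(probs.p_off1, size=int(b1.sum()))
    if b2.any():
        countdown[b2] = rng.geometric(probs.p_off2, size=int(b2.sum()))

    (a, b, c), order = _kernel_geometry(geometry, protocol)
    pos = np.ascontiguousarray(state.positions[:, order])
    kernel_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    _kernels.seed_rng(kernel_seed)
    sigma_step = math.sqrt(2.0 * params.D * protocol.sim_substep)
    nsub = protocol.substeps_per_scan
    half_w = protocol.roi_width / 2.0
    # continuous fluorescence weights: bleaching is applied in expectation
    # (Rao-Blackwellized over survival outcomes), same mean, less variance
    fluor = np.ones(n_particles, dtype=np.float32)
    ks = state.kinetic_state
    counts = np.empty(protocol.n_scans)
    # unit normal increments are pre-drawn in bulk (numpy's ziggurat
    # sampler, far faster than per-element draws in the kernel), sized to
    # the current free-particle count; the kernel falls back to its own
    # RNG if the free count fluctuates past the margin
    empty = np.empty((0, 3), dtype=np.float32)
    if sigma_step > 0.0:
        block = max(1, int(1.5e7) // max(1, 3 * nsub * n_particles))
    else:
        block = 64

    def advance_scans(out: np.ndarray) -> None:
        done = 0
        while done < out.size:
            nb = min(block, out.size - done)
            if sigma_step > 0.0:
                n_free = int(np.count_nonzero(ks == FREE))
                m = int(1.08 * n_free * nsub * nb) + 2048
                normals = rng.standard_normal((m, 3), dtype=np.float32)
            else:
                normals = empty
            _kernels.advance_block(
                pos, ks, countdown, fluor, normals, nsub, a, b, c, sigma_step,
                probs.p_on1, probs.p_on2, probs.p_off1, probs.p_off2,
                half_w, out[done : done + nb],
            )
            done += nb

    advance_scans(counts[: protocol.n_prebleach])
    gap = np.empty(1)
    for _ in range(protocol.bleach_iterations):
        _kernels.bleach_round_weighted(
            pos, fluor, profile.dose, half_w, profile.lateral_sigma
        )
        advance_scans(gap)
    advance_scans(counts[protocol.n_prebleach :])
    return counts, float(fluor.mean())


def _simulate_replicate_reference(
    geometry: NucleusGeometry,
    params: MobilityParams,
    protocol: AcquisitionProtocol,
    profile: BleachProfile,
    n_particles: int,
    child: np.random.SeedSequence,
) -> tuple[np.ndarray, float]:
    """Pure-numpy composition of the public operations (slow, for cross-checks)."""
    rng = np.random.default_rng(child)
    state = init_particles(geometry, params, n_particles, rng)
    probs = equilibrium_rates(params, protocol.sim_substep)
    counts = np.empty(protocol.n_scans)

    def advance_one_scan() -> None:
        for _ in range(protocol.substeps_per_scan):
            step_diffusion(state, params.D, protocol.sim_substep, geometry)
            step_kinetics(state, probs)

    for scan in range(protocol.n_scans):
        if scan == protocol.n_prebleach:
            apply_bleach(state, profile, protocol, geometry, params)
        advance_one_scan()
        counts[scan] = measure_roi(state, protocol)
    return counts, float(state.fluorescent.mean())


def simulate_frap(
    geometry: NucleusGeometry,
    params: MobilityParams,
    protocol: AcquisitionProtocol,
    profile: BleachProfile,
    n_particles: int = 20_000,
    n_replicates: int = 1,
    seed: int = 0,
    engine: Literal["fast", "reference"] = "fast",
    normalize: Literal["prebleach", "expected"] = "prebleach",
) -> SimulatedCurve:
    """Simulate a full strip-FRAP experiment and return the normalized curve.

    Runs ``n_replicates`` independent replicates of ``n_particles``
    particles through the scan/bleach/scan schedule, sums the ROI counts
    and normalizes by the mean pre-bleach level. Replicate seeds are
    spawned deterministically from ``seed``; an identical
    (seed, configuration) pair reproduces the curve exactly.

    The ``fast`` engine runs a compiled kernel; ``reference`` composes
    the public single-step operations in Python (statistically
    equivalent, used for validation).

    ``normalize="expected"`` divides by the analytic equilibrium ROI
    occupancy instead of the realized pre-bleach mean. The pre-bleach
    level is then 1 only in expectation, but the curve carries no
    normalization sampling error — preferable for reference-library
    curves compared across thousands of nodes.
    """
    if n_particles < 1 or n_replicates < 1:
        raise InvalidParameterError("n_particles and n_replicates must be >= 1")
    _validate_sim_config(geometry, protocol)
    run_one = (
        _simulate_replicate_fast if engine == "fast" else _simulate_replicate_reference
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    total = np.zeros(protocol.n_scans)
    unbleached = 0.0
    for child in children:
        counts, frac = run_one(geometry, params, protocol, profile, n_particles, child)
        total += counts
        unbleached += frac
    prebleach_mean = total[: protocol.n_prebleach].mean()
    if prebleach_mean <= 0:
        raise InvalidParameterError(
            "no particles ever observed in the ROI; increase n_particles"
        )
    if normalize == "expected":
        scale = n_replicates * n_particles * roi_volume_fraction(geometry, protocol)
    else:
        scale = prebleach_mean
    intensity = total / scale
    meta = {
        "n_particles": n_particles,
        "n_replicates": n_replicates,
        "seed": seed,
        "engine": engine,
        "final_unbleached_fraction": unbleached / n_replicates,
        "prebleach_counts": float(prebleach_mean),
        "normalize": normalize,
    }
    return SimulatedCurve(
        time=protocol.scan_times(),
        intensity=intensity,
        params=params,
        replicate_meta=meta,
    )


def calibrate_dose(
    target_depth: float,
    geometry: NucleusGeometry,
    protocol: AcquisitionProtocol,
    profile: BleachProfile,
    D: float = 20.0,
    n_particles: int = 20_000,
    seed: int = 0,
    n_iter: int = 10,
) -> float:
    """Bisection for the per-iteration dose reaching a requested bleach depth.

    ``target_depth`` is the normalized intensity at the first post-bleach
    scan for a freely diffusing pool with coefficient ``D``. Returns the
    calibrated dose; the supplied profile's lateral shape is kept.
    """
    if not 0.0 < target_depth < 1.0:
        raise InvalidParameterError("target_depth must be in (0, 1)")
    params = MobilityParams(D=D)
    lo, hi = 0.0, 20.0
    # only the first post-bleach scan is needed per probe
    short = replace(protocol, n_scans=protocol.n_prebleach + 1)

    def depth(dose: float) -> float:
        p = replace(profile, dose=dose)
        curve = simulate_frap(
            geometry, params, short, p, n_particles=n_particles, seed=seed
        )
        return float(curve.intensity[short.n_prebleach])

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if depth(mid) > target_depth:
            lo = mid  # too shallow, increase dose
        else:
            hi = mid
    return 0.5 * (lo + hi)
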