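"""Forward simulation of hyperpolarized ¹³C acquisitions.

Two generators live here:

* :func:`simulate_hp_dynamics` — a unidirectional two-site exchange model of
  the pyruvate → lactate conversion sampled by an RF pulse train (variable
  flip angles for pyruvate, constant 90° for lactate), producing the dynamic
  signal curves an EPI readout would record.
* :func:`simulate_diffusion_signal` — mono-exponential diffusion decay
  S(b) = S₀·exp(−b·ADC), optionally Rician-corrupted and expanded to a
  voxel grid.

The kinetic model is deliberately minimal: hyperpolarized magnetization
arrives as a rectangular venous bolus, pyruvate converts to lactate at an
apparent first-order rate kPL (no back-flux — only forward conversion is
quantified downstream), and both pools relax longitudinally at R1 ≈ 1/25 s⁻¹.
Each excitation reads M_z·sin θ and leaves M_z·cos θ behind; the
non-renewable hyperpolarized magnetization is the reason variable flip
angles are used for pyruvate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from hpcmri.dynamics import DynamicSeries

# Default b-value sets (s/mm²), in acquisition order.  The ¹³C set is
# interleaved (600, 1500, 1000) to distribute the hyperpolarized signal
# decay across diffusion weightings.
B_VALUES_H1 = (25.0, 180.0, 323.0, 508.0)
B_VALUES_C13 = (50.0, 300.0, 600.0, 1500.0, 1000.0, 2000.0)

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-12


@dataclass(frozen=True)
class ExchangeParams:
    """Ground-truth kinetic state of the two-pool pyruvate/lactate system.

    Parameters
    ----------
    kpl : float
        Apparent pyruvate→lactate conversion rate (1/s).
    r1p, r1l : float
        Longitudinal relaxation rates of pyruvate and lactate (1/s).
        Default 1/25 s⁻¹, a typical [1-¹³C]pyruvate T₁ at high field.
    input_start : float
        Bolus start time (s) on the injection clock.
    input_duration : float
        Bolus duration (s); the tail-vein injection takes 12–14 s, so the
        default is the mid-range 13 s.
    input_amplitude : float
        Magnetization inflow rate during the bolus (arbitrary units/s).
    p0, l0 : float
        Initial longitudinal magnetization of each pool (for impulse-input
        experiments; default 0).
    """

    kpl: float = 0.02
    r1p: float = 1.0 / 25.0
    r1l: float = 1.0 / 25.0
    input_start: float = 0.0
    input_duration: float = 13.0
    input_amplitude: float = 1.0
    p0: float = 0.0
    l0: float = 0.0

    def __post_init__(self) -> None:
        if self.kpl < 0:
            raise ValueError(f"kpl must be >= 0, got {self.kpl}")
        if self.r1p < 0 or self.r1l < 0:
            raise ValueError("relaxation rates must be >= 0")
        if self.input_duration <= 0:
            raise ValueError("input_duration must be > 0")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Per-time-point excitation schedule for a two-metabolite dynamic scan.

    ``flips_pyr`` and ``flips_lac`` are flip angles in degrees, one per time
    point.  ``t_start`` is the time of the first acquisition relative to the
    start of the injection (default 6 s); subsequent acquisitions follow
    every ``tr`` seconds (default 3 s, 20 time points).
    """

    n_timepoints: int = 20
    tr: float = 3.0
    flips_pyr: tuple[float, ...] = ()
    flips_lac: tuple[float, ...] = ()
    t_start: float = 6.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        for name, flips in (("flips_pyr", self.flips_pyr), ("flips_lac", self.flips_lac)):
            if len(flips) != self.n_timepoints:
                raise ValueError(
                    f"{name} has {len(flips)} angles, expected {self.n_timepoints}"
                )
            arr = np.asarray(flips, dtype=float)
            if np.any(arr <= 0) or np.any(arr > 90):
                raise ValueError(f"{name} angles must lie in (0, 90] degrees")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times (s) on the injection clock."""
        return self.t_start + self.tr * np.arange(self.n_timepoints)


@dataclass(frozen=True)
class DiffusionPhantomSpec:
    """Specification of a mono-exponential diffusion decay phantom."""

    adc_true: float
    s0: float = 1.0
    b_values: tuple[float, ...] = B_VALUES_C13
    noise_sigma: float = 0.0
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.adc_true < 0:
            raise ValueError("adc_true must be >= 0")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or np.unique(b).size < 2:
            raise ValueError("need at least 2 distinct b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_vfa_schedule(
    n_timepoints: int = 20,
    scheme: str = "constant_signal",
    custom_angles: list[float] | None = None,
    tr: float = 3.0,
    t_start: float = 6.0,
) -> AcquisitionSchedule:
    """Build the dynamic-scan flip-angle schedule.

    The default ``constant_signal`` scheme for pyruvate is the classic
    arctan progression θₙ = arctan(1/√(N−n)) (n = 1..N), which spends the
    hyperpolarized magnetization so that, absent relaxation and inflow,
    every excitation reads the same transverse signal; the final pulse is
    90° and dumps the remaining magnetization.  Lactate is always excited
    at a constant 90° so that each time point reads the lactate newly
    formed during the preceding TR.

    Parameters
    ----------
    scheme : {"constant_signal", "custom"}
        ``custom`` requires ``custom_angles`` (degrees, length
        ``n_timepoints``) for the pyruvate channel.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if scheme == "constant_signal":
        if custom_angles is not None:
            raise ValueError("custom_angles only valid with scheme='custom'")
        n = np.arange(1, n_timepoints + 1)
        remaining = np.sqrt((n_timepoints - n).astype(float))
        flips = np.full(n_timepoints, 90.0)  # arctan(1/0): final pulse dumps all
        nz = remaining > 0
        flips[nz] = np.degrees(np.arctan(1.0 / remaining[nz]))
        flips_pyr = tuple(float(a) for a in flips)
    elif scheme == "custom":
        if custom_angles is None:
            raise ValueError("scheme='custom' requires custom_angles")
        if len(custom_angles) != n_timepoints:
            raise ValueError(
                f"custom_angles has length {len(custom_angles)}, expected {n_timepoints}"
            )
        flips_pyr = tuple(float(a) for a in custom_angles)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    flips_lac = tuple(90.0 for _ in range(n_timepoints))
    return AcquisitionSchedule(
        n_timepoints=n_timepoints,
        tr=tr,
        flips_pyr=flips_pyr,
        flips_lac=flips_lac,
        t_start=t_start,
    )


def _rhs(t: float, y: np.ndarray, params: ExchangeParams) -> list[float]:
    p, l = y
    inflow = (
        params.input_amplitude
        if params.input_start <= t < params.input_start + params.input_duration
        else 0.0
    )
    dp = inflow - (params.kpl + params.r1p) * p
    dl = params.kpl * p - params.r1l * l
    return [dp, dl]


def _integrate(
    params: ExchangeParams,
    t0: float,
    t1: float,
    y0: np.ndarray,
    t_eval: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Integrate the exchange ODE over [t0, t1], splitting at bolus edges.

    Returns the state at t1 and, if requested, the states at ``t_eval``.
    """
    edges = [params.input_start, params.input_start + params.input_duration]
    breaks = sorted({t0, t1, *[e for e in edges if t0 < e < t1]})
    y = np.asarray(y0, dtype=float)
    evals = [] if t_eval is not None else None
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = None
        if t_eval is not None:
            inside = t_eval[(t_eval >= a) & (t_eval < b)]
            seg_eval = np.sort(np.unique(np.concatenate([inside, [b]])))
        sol = solve_ivp(
            _rhs,
            (a, b),
            y,
            args=(params,),
            method="RK45",
            rtol=_ODE_RTOL,
            atol=_ODE_ATOL,
            t_eval=seg_eval,
            dense_output=t_eval is not None,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1].copy()
        if t_eval is not None:
            inside = t_eval[(t_eval >= a) & (t_eval < b)]
            if inside.size:
                evals.append(sol.sol(inside))
    if t_eval is not None:
        # points exactly at t1
        at_end = t_eval[t_eval >= breaks[-1]]
        if at_end.size:
            evals.append(np.tile(y[:, None], (1, at_end.size)))
        out = np.concatenate(evals, axis=1) if evals else np.empty((2, 0))
        return y, out
    return y, None


def rf_free_trajectory(
    params: ExchangeParams, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pyruvate/lactate M_z at ``times`` with no RF sampling (ground truth)."""
    times = np.asarray(times, dtype=float)
    t_end = float(times.max()) if times.size else 0.0
    y0 = np.array([params.p0, params.l0])
    _, traj = _integrate(params, 0.0, max(t_end, 1e-12), y0, t_eval=times)
    return traj[0], traj[1]


def simulate_hp_dynamics(
    params: ExchangeParams,
    schedule: AcquisitionSchedule,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> DynamicSeries:
    """Simulate a dynamic HP ¹³C pyruvate/lactate acquisition.

    The two-pool magnetization evolves continuously between excitations;
    at each acquisition time the recorded signal per metabolite is
    M_z·sin θ and the longitudinal pool is reduced to M_z·cos θ
    (instantaneous RF).  With the constant-90° lactate schedule each time
    point therefore reads the lactate formed since the previous pulse.

    Returns a :class:`~hpcmri.dynamics.DynamicSeries` carrying the raw
    (uncorrected) signals plus the RF-free ground-truth trajectories
    (``mz_free_pyr`` / ``mz_free_lac``) at the acquisition times for
    validation of the flip-angle correction.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    times = schedule.times
    flips_p = np.radians(np.asarray(schedule.flips_pyr, dtype=float))
    flips_l = np.radians(np.asarray(schedule.flips_lac, dtype=float))

    y = np.array([params.p0, params.l0])
    t_prev = 0.0
    sig_pyr = np.empty(schedule.n_timepoints)
    sig_lac = np.empty(schedule.n_timepoints)
    for i, t in enumerate(times):
        if t > t_prev:
            y, _ = _integrate(params, t_prev, float(t), y)
        sig_pyr[i] = y[0] * math.sin(flips_p[i])
        sig_lac[i] = y[1] * math.sin(flips_l[i])
        y = y * np.array([math.cos(flips_p[i]), math.cos(flips_l[i])])
        t_prev = float(t)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sig_pyr = _rician(sig_pyr, noise_sigma, rng)
        sig_lac = _rician(sig_lac, noise_sigma, rng)

    free_p, free_l = rf_free_trajectory(params, times)
    return DynamicSeries(
        times=times,
        sig_pyr=sig_pyr,
        sig_lac=sig_lac,
        schedule=schedule,
        corrected=False,
        mz_free_pyr=free_p,
        mz_free_lac=free_l,
    )


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI (Rician) corruption of a real-valued signal."""
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_diffusion_signal(
    spec: DiffusionPhantomSpec,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize mono-exponential diffusion-weighted signals.

    Returns a vector of length ``len(b_values)`` (in the acquisition order
    of ``spec.b_values``), or a stack of shape ``(n_b, *grid_shape)`` when
    ``spec.grid_shape`` is set.  Noise, if any, is Rician with scale
    ``spec.noise_sigma``.
    """
    b = np.asarray(spec.b_values, dtype=float)
    signal = spec.s0 * np.exp(-b * spec.adc_true)
    if spec.grid_shape is not None:
        signal = np.broadcast_to(
            signal[:, None, None], (b.size, *spec.grid_shape)
        ).copy()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = _rician(signal, spec.noise_sigma, rng)
    return signal
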