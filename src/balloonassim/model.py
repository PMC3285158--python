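"""Hemodynamic Balloon model: dynamics, BOLD observation, forward simulation.

The model couples a flow-inducing signal s to normalized blood inflow f,
venous volume v and deoxyhemoglobin content q:

    ds/dt = eps*u(t) - s/tau_s - (f - 1)/tau_f
    df/dt = s
    dv/dt = (f - v**(1/alpha)) / tau_0
    dq/dt = (f*E(f, E0)/E0 - v**(1/alpha) * q/v) / tau_0

with the oxygen extraction fraction E(f, E0) = 1 - (1 - E0)**(1/f).  All
hemodynamic variables are normalized to 1 at rest; the resting state is
(s, f, v, q) = (0, 1, 1, 1).  The BOLD signal change is read out through the
static nonlinear observation

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

whose default coefficients k1 = 7*E0, k2 = 2, k3 = 2*E0 - 0.2 are the usual
1.5 T calibration; they are configurable for other field strengths.  V0 is
the resting blood volume fraction of the voxel/region and simply scales the
observation — which is why it trades off against the neuronal efficacy eps
and cannot be estimated jointly with it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels

__all__ = [
    "HemodynamicParams",
    "HemodynamicState",
    "StimulusTrain",
    "BalloonTrajectory",
    "BoldSimulation",
    "DEFAULT_PARAMS",
    "neural_input",
    "oxygen_extraction",
    "bold_coefficients_1p5T",
    "bold_observation",
    "hemodynamic_derivatives",
    "integrate_balloon",
    "simulate_bold",
]


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model parameters.

    epsilon : neuronal efficacy (response of s per unit input, 1/s)
    tau_s   : signal decay time constant (s)
    tau_f   : feedback autoregulation time constant (s)
    tau_0   : mean venous transit time (s)
    E0      : resting oxygen extraction fraction, in (0, 1)
    alpha   : vessel stiffness exponent, in (0, 1); fixed, never estimated
    V0      : resting blood volume fraction, in (0, 1); supplied externally
    """

    epsilon: float = 0.54
    tau_s: float = 1.54
    tau_f: float = 2.46
    tau_0: float = 0.98
    E0: float = 0.34
    alpha: float = 0.2
    V0: float = 0.02

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        for name in ("tau_s", "tau_f", "tau_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("E0", "alpha", "V0"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {val}")

    def with_v0(self, v0: float) -> "HemodynamicParams":
        return replace(self, V0=float(v0))


DEFAULT_PARAMS = HemodynamicParams()


@dataclass(frozen=True)
class HemodynamicState:
    """Hidden physiological state (normalized; rest = (0, 1, 1, 1))."""

    s: float = 0.0
    f: float = 1.0
    v: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0 or self.v <= 0 or self.q <= 0:
            raise ValueError("f, v, q must be strictly positive")

    @classmethod
    def rest(cls) -> "HemodynamicState":
        return cls()

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.f, self.v, self.q], dtype=float)


@dataclass(frozen=True)
class StimulusTrain:
    """Boxcar (squarewave) stimulus: blocks of constant amplitude on a rest baseline.

    Blocks are half-open intervals [onset, onset + duration); input is 0
    outside all blocks.  ``sampling_dt`` is the nominal observation interval
    (the fMRI TR) used when deriving sample grids from the train.
    """

    onsets: tuple = ()
    durations: tuple = ()
    amplitude: float = 1.0
    sampling_dt: float = 2.0

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets)
        durations = tuple(float(d) for d in self.durations)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if len(onsets) != len(durations):
            raise ValueError("onsets and durations must have equal length")
        if any(d <= 0 for d in durations):
            raise ValueError("durations must be strictly positive")
        if list(onsets) != sorted(onsets):
            raise ValueError("onsets must be sorted ascending")
        for (o1, d1), o2 in zip(zip(onsets, durations), onsets[1:]):
            if o1 + d1 > o2:
                raise ValueError("blocks must not overlap")
        if self.sampling_dt <= 0:
            raise ValueError("sampling_dt must be positive")

    @property
    def end_time(self) -> float:
        if not self.onsets:
            return 0.0
        return self.onsets[-1] + self.durations[-1]

    def value(self, t: float) -> float:
        return float(self.values(np.asarray([t]))[0])

    def values(self, times: np.ndarray) -> np.ndarray:
        """Vectorized boxcar evaluation (half-open block intervals)."""
        times = np.asarray(times, dtype=float)
        out = np.zeros_like(times)
        for onset, dur in zip(self.onsets, self.durations):
            out[(times >= onset) & (times < onset + dur)] = self.amplitude
        return out

    def to_dict(self) -> dict:
        return {
            "onsets": list(self.onsets),
            "durations": list(self.durations),
            "amplitude": self.amplitude,
            "sampling_dt": self.sampling_dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusTrain":
        return cls(
            onsets=tuple(d["onsets"]),
            durations=tuple(d["durations"]),
            amplitude=float(d["amplitude"]),
            sampling_dt=float(d["sampling_dt"]),
        )


def neural_input(stimulus: StimulusTrain, t: float) -> float:
    """Boxcar input level at time t (amplitude inside a block, else 0)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return stimulus.value(t)


def oxygen_extraction(f, E0):
    """Instantaneous oxygen extraction fraction E(f, E0) = 1 - (1 - E0)**(1/f).

    Equals E0 at resting inflow f = 1; extraction falls toward 0 as inflow
    grows (flow outpaces uptake) and rises toward 1 as inflow vanishes.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("inflow f must be strictly positive")
    if not 0.0 < float(E0) < 1.0:
        raise ValueError("E0 must lie in (0, 1)")
    # E(1, E0) = E0 exactly; the general expression suffers float
    # cancellation at f = 1, which would break the resting fixed point
    out = np.where(f == 1.0, E0, 1.0 - (1.0 - E0) ** (1.0 / f))
    return out if out.ndim else float(out)


def bold_coefficients_1p5T(E0: float) -> tuple:
    """Observation coefficients (k1, k2, k3) for a 1.5 T magnet."""
    return (7.0 * E0, 2.0, 2.0 * E0 - 0.2)


def bold_observation(v, q, E0: float, V0: float, coefficients=None):
    """BOLD fractional signal change from venous volume v and dHb content q.

    Linear in V0 with zero signal at rest (v = q = 1).  ``coefficients``
    overrides the default 1.5 T (k1, k2, k3).
    """
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be strictly positive")
    if not 0.0 < V0 < 1.0:
        raise ValueError("V0 must lie in (0, 1)")
    k1, k2, k3 = coefficients if coefficients is not None else bold_coefficients_1p5T(E0)
    out = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return out if out.ndim else float(out)


def hemodynamic_derivatives(state, params: HemodynamicParams, u: float) -> np.ndarray:
    """Time derivatives (ds, df, dv, dq) of the Balloon system at one point."""
    if isinstance(state, HemodynamicState):
        s, f, v, q = state.s, state.f, state.v, state.q
    else:
        s, f, v, q = (float(x) for x in state)
    if f <= 0 or v <= 0 or q <= 0:
        raise ValueError("f, v, q must be strictly positive")
    E = oxygen_extraction(f, params.E0)
    outflow = v ** (1.0 / params.alpha)
    ds = params.epsilon * u - s / params.tau_s - (f - 1.0) / params.tau_f
    df = s
    dv = (f - outflow) / params.tau_0
    dq = (f * E / params.E0 - outflow * q / v) / params.tau_0
    return np.array([ds, df, dv, dq])


@dataclass
class BalloonTrajectory:
    """Dense state trajectory from fixed-step integration."""

    times: np.ndarray          # (n+1,) internal grid
    states: np.ndarray         # (n+1, 4) columns s, f, v, q
    clamp_count: int = 0

    def sample(self, sample_times) -> np.ndarray:
        """Linearly interpolate the trajectory at the requested times."""
        sample_times = np.asarray(sample_times, dtype=float)
        out = np.empty((sample_times.size, 4))
        for j in range(4):
            out[:, j] = np.interp(sample_times, self.times, self.states[:, j])
        return out


class IntegrationError(RuntimeError):
    pass


def integrate_balloon(
    params: HemodynamicParams,
    stimulus: StimulusTrain,
    t_span: tuple,
    dt_internal: float = 0.01,
    initial_state: HemodynamicState | None = None,
) -> BalloonTrajectory:
    """Integrate the Balloon ODEs with fixed-step RK4 from rest (by default).

    Deterministic given its inputs.  Raises IntegrationError, reporting the
    first offending time, if the state leaves the valid domain (non-finite).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must have positive length")
    if dt_internal <= 0 or dt_internal > stimulus.sampling_dt:
        raise ValueError("dt_internal must be in (0, sampling_dt]")
    n = int(round((t1 - t0) / dt_internal))
    times = t0 + dt_internal * np.arange(n + 1)
    u_seq = stimulus.values(times[:-1])
    x0 = (initial_state or HemodynamicState.rest()).as_array()
    states, clamps = _kernels.integrate_balloon_traj(
        x0, params.epsilon, params.tau_s, params.tau_f, params.tau_0,
        params.E0, 1.0 / params.alpha, u_seq, dt_internal)
    if not np.all(np.isfinite(states)):
        bad = int(np.argwhere(~np.isfinite(states).all(axis=1))[0, 0])
        raise IntegrationError(
            f"state left the valid domain at t = {times[bad]:.3f} s")
    return BalloonTrajectory(times=times, states=states, clamp_count=int(clamps))


@dataclass
class BoldSimulation:
    """Noisy + noiseless BOLD series sampled from a Balloon trajectory."""

    times: np.ndarray
    bold_noiseless: np.ndarray
    bold_noisy: np.ndarray
    states: np.ndarray          # (n, 4) states at the sample times
    params: HemodynamicParams
    noise_sd: float
    seed: int | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times,
            "bold_noiseless": self.bold_noiseless,
            "bold_noisy": self.bold_noisy,
        })


def simulate_bold(
    params: HemodynamicParams,
    stimulus: StimulusTrain,
    sample_times,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt_internal: float = 0.01,
    coefficients=None,
) -> BoldSimulation:
    """Forward-simulate a BOLD time series with additive i.i.d. Gaussian noise."""
    sample_times = np.asarray(sample_times, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_end = max(float(sample_times[-1]), stimulus.end_time)
    traj = integrate_balloon(params, stimulus, (0.0, t_end), dt_internal)
    states = traj.sample(sample_times)
    noiseless = bold_observation(states[:, 2], states[:, 3], params.E0,
                                 params.V0, coefficients)
    noiseless = np.asarray(noiseless, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = noiseless + rng.normal(0.0, noise_sd, size=noiseless.shape) \
        if noise_sd > 0 else noiseless.copy()
    return BoldSimulation(times=sample_times, bold_noiseless=noiseless,
                          bold_noisy=noisy, states=states, params=params,
                          noise_sd=noise_sd, seed=seed)
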