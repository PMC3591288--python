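"""Neural rate dynamics with fixed connections.

The activity x_i of each of N rate neurons lies in [-1, 1] and follows

    dx_i/dt = S( sum_j J_ij x_j + gamma * eta_i ) - x_i,

with S(u) = tanh(gain * u) a saturating odd sigmoid, J the (zero-diagonal)
connection matrix and eta a ±1 input pattern applied at constant strength
gamma.  gamma = 0 gives the *spontaneous* dynamics, gamma > 0 the *evoked*
dynamics.  The neural time constant is 1, so all times are in units of it.

Integration is fixed-step explicit Euler.  Because |S| <= 1 the Euler map
x -> (1-dt) x + dt S(u) keeps the state inside [-1, 1] exactly for any
dt <= 1; no clamping is applied, and a confinement assertion trips on
integrator misuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_GAIN",
    "DynamicsParams",
    "Trajectory",
    "OverlapSeries",
    "IntegrationError",
    "sigmoid",
    "sigmoid_prime",
    "neural_field",
    "simulate",
    "simulate_mean_states",
    "overlap",
    "overlap_series",
]

#: default gain of the sigmoid S(u) = tanh(gain * u).  A gain of 2 makes the
#: origin of the spontaneous dynamics unstable for the connection strengths
#: produced by learning, which is what sustains chaotic spontaneous activity.
DEFAULT_GAIN = 2.0


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class DynamicsParams:
    """Integration and measurement parameters for recall-time dynamics.

    Parameters
    ----------
    gamma_recall:
        Input strength at recall/analysis time; 0 means spontaneous activity.
    dt:
        Euler step, in units of the neural time constant (must be < 1).
    t_transient:
        Initial stretch discarded before any time average.
    t_measure:
        Length of the measurement window after the transient.
    record_stride:
        A state sample is recorded every ``record_stride`` steps.
    gain:
        Sigmoid gain of S(u) = tanh(gain * u).
    """

    gamma_recall: float = 0.0
    dt: float = 0.01
    t_transient: float = 100.0
    t_measure: float = 400.0
    record_stride: int = 10
    gain: float = DEFAULT_GAIN

    def __post_init__(self):
        if not 0 < self.dt < 1:
            raise ValueError("dt must lie in (0, 1)")
        if self.t_transient < 0 or self.t_measure <= 0:
            raise ValueError("t_transient >= 0 and t_measure > 0 required")
        if self.record_stride < 1:
            raise ValueError("record_stride must be a positive integer")
        if self.gamma_recall < 0:
            raise ValueError("gamma_recall must be non-negative")

    def with_gamma(self, gamma: float) -> "DynamicsParams":
        return replace(self, gamma_recall=gamma)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled activity states, times in neural time units."""

    times: np.ndarray  # (T,)
    states: np.ndarray  # (T, N)

    def __post_init__(self):
        if self.times.shape[0] != self.states.shape[0]:
            raise ValueError("times and states must have equal length")


@dataclass(frozen=True)
class OverlapSeries:
    """Overlap of a trajectory with one reference pattern over time."""

    times: np.ndarray
    values: np.ndarray
    reference: str = ""

    def __post_init__(self):
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")


def sigmoid(u: np.ndarray, gain: float = DEFAULT_GAIN) -> np.ndarray:
    return np.tanh(gain * u)


def sigmoid_prime(u: np.ndarray, gain: float = DEFAULT_GAIN) -> np.ndarray:
    t = np.tanh(gain * u)
    return gain * (1.0 - t * t)


def _check_shapes(x, J, eta, gamma):
    x = np.asarray(x, dtype=float)
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1] or J.shape[0] != x.shape[-1 if x.ndim == 1 else 0]:
        raise ValueError("J must be square and match x")
    if gamma > 0:
        if eta is None:
            raise ValueError("eta required when gamma > 0")
        eta = np.asarray(eta, dtype=float)
        if eta.shape[0] != J.shape[0]:
            raise ValueError("eta must match x")
    return x, J, eta


def neural_field(
    x: np.ndarray,
    J: np.ndarray,
    eta: np.ndarray | None = None,
    gamma: float = 0.0,
    gain: float = DEFAULT_GAIN,
) -> np.ndarray:
    """Right-hand side dx/dt = S(J x + gamma eta) - x."""
    x, J, eta = _check_shapes(x, J, eta, gamma)
    u = J @ x
    if gamma > 0:
        u = u + gamma * eta
    return sigmoid(u, gain) - x


def simulate(
    x0: np.ndarray,
    J: np.ndarray,
    eta: np.ndarray | None = None,
    params: DynamicsParams = DynamicsParams(),
) -> Trajectory:
    """Integrate the neural dynamics with fixed connections.

    Records a sample every ``params.record_stride`` Euler steps over
    ``t_transient + t_measure`` time units (the transient is *included* in
    the returned trajectory; measurement code discards it).  Deterministic
    given its inputs.
    """
    x0, J, eta = _check_shapes(x0, J, eta, params.gamma_recall)
    if np.any(np.abs(x0) > 1):
        raise ValueError("x0 entries must lie in [-1, 1]")
    gamma, dt, gain = params.gamma_recall, params.dt, params.gain
    drive = gamma * eta if gamma > 0 else 0.0
    n_steps = int(round((params.t_transient + params.t_measure) / dt))
    stride = params.record_stride
    x = x0.copy()
    times = [0.0]
    states = [x.copy()]
    for step in range(1, n_steps + 1):
        x = x + dt * (np.tanh(gain * (J @ x + drive)) - x)
        if step % stride == 0:
            if not np.all(np.isfinite(x)):
                raise IntegrationError(f"non-finite state at step {step}")
            assert np.all(np.abs(x) <= 1 + 1e-12), "state escaped [-1,1]"
            times.append(step * dt)
            states.append(x.copy())
    return Trajectory(times=np.array(times), states=np.array(states))


def simulate_mean_states(
    X0: np.ndarray,
    J: np.ndarray,
    H: np.ndarray | None,
    params: DynamicsParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched integration returning final and time-averaged states.

    ``X0`` is (N, B): B trajectories integrated in lockstep, column b under
    the constant input column ``H[:, b]`` (``H`` may be None when
    gamma_recall is 0).  Returns ``(X_final, X_mean)`` where ``X_mean``
    averages the state over every step with t >= t_transient.  Because the
    overlap is linear in the state, the time-averaged overlap with any
    pattern p is ``p @ X_mean / N``; this is the workhorse behind the
    ensemble recall measurements.
    """
    X = np.array(X0, dtype=float)
    gamma, dt, gain = params.gamma_recall, params.dt, params.gain
    drive = gamma * H if (gamma > 0 and H is not None) else 0.0
    if gamma > 0 and H is None:
        raise ValueError("H required when gamma_recall > 0")
    n_tr = int(round(params.t_transient / dt))
    n_me = int(round(params.t_measure / dt))
    for _ in range(n_tr):
        X = X + dt * (np.tanh(gain * (J @ X + drive)) - X)
    acc = np.zeros_like(X)
    for step in range(n_me):
        X = X + dt * (np.tanh(gain * (J @ X + drive)) - X)
        acc += X
    if not np.all(np.isfinite(X)):
        raise IntegrationError("non-finite state during batched integration")
    return X, acc / n_me


def overlap(x: np.ndarray, p: np.ndarray) -> float:
    """Normalized inner product m = p^T x / N, in [-1, 1] for x in [-1,1]^N."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("x and p must have equal shape")
    return float(p @ x / x.shape[0])


def overlap_series(traj: Trajectory, p: np.ndarray, reference: str = "") -> OverlapSeries:
    """Overlap of every recorded state with pattern ``p``."""
    p = np.asarray(p, dtype=float)
    if p.shape[0] != traj.states.shape[1]:
        raise ValueError("pattern length must match trajectory states")
    values = traj.states @ p / p.shape[0]
    return OverlapSeries(times=traj.times, values=values, reference=reference)
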