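"""Bifurcation scans and Lyapunov spectra of the recall dynamics.

Recall in this model is a change of flow structure: as the input strength
gamma is raised from 0, the chaotic spontaneous attractor deforms through
a sequence of bifurcations until (for a recallable mapping) a fixed point
matching the target appears.  Two instruments expose this:

* a bifurcation diagram collecting the local maxima of the target-overlap
  time series at each gamma on a grid, and
* the Lyapunov spectrum of the dynamics, whose count of positive
  exponents tracks the collapse from a high-dimensional chaotic attractor
  to a low-dimensional or fixed-point one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DEFAULT_GAIN, DynamicsParams, OverlapSeries, sigmoid_prime
from .learning import TrainedNetwork
from .patterns import SeedBundle

__all__ = [
    "BifurcationDiagram",
    "LyapunovSpectrum",
    "local_maxima",
    "bifurcation_scan",
    "jacobian",
    "lyapunov_spectrum",
]

#: a post-transient overlap range below this labels the attractor a fixed point
FIXED_POINT_TOL = 1e-4

#: exponents above this count as positive
POSITIVE_TOL = 1e-3


def local_maxima(series: OverlapSeries, t_transient: float = 0.0) -> np.ndarray:
    """Values at strict interior local maxima of the post-transient series.

    A constant series yields the single constant value (a fixed point has
    one "maximum").
    """
    mask = series.times >= t_transient
    v = series.values[mask]
    if v.shape[0] < 3:
        raise ValueError("need at least 3 post-transient samples")
    if np.ptp(v) == 0:
        return np.array([v[0]])
    inner = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    out = v[1:-1][inner]
    if out.size == 0:
        # monotone stretch relaxing onto a fixed point: report the endpoint
        return np.array([v[-1]])
    return out


@dataclass(frozen=True)
class BifurcationDiagram:
    """Per-gamma local-maxima sets of the target/input overlap series."""

    gamma_grid: np.ndarray
    target_maxima: list  # list of 1-d arrays, one per gamma
    input_maxima: list
    fixed_point: np.ndarray  # bool per gamma
    mu: int


def bifurcation_scan(
    net: TrainedNetwork,
    mu: int,
    gamma_grid,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
    n_restarts: int = 3,
) -> BifurcationDiagram:
    """Scan the evoked dynamics of mapping age ``mu`` over input strengths.

    At each gamma (ascending) the dynamics run from the continuation state
    (final state of the previous gamma) plus ``n_restarts`` independent
    random initial states, to expose coexisting attractors.  Local maxima
    of the overlap with the target and with the input are collected over
    the post-transient window; the point is labelled a fixed point when
    every run's post-transient target overlap has range below
    ``FIXED_POINT_TOL``.
    """
    gamma_grid = np.sort(np.asarray(gamma_grid, dtype=float))
    if gamma_grid.size == 0:
        raise ValueError("gamma grid must be non-empty")
    if isinstance(seeds, SeedBundle):
        rng = seeds.rng("analysis")
    elif isinstance(seeds, np.random.Generator):
        rng = seeds
    elif seeds is None:
        rng = net.seeds.rng("analysis")
    else:
        rng = np.random.default_rng(seeds)
    N = net.n_neurons
    mapping = net.mapping_set.by_age(mu)
    xi = mapping.target.astype(float)
    eta = mapping.input.astype(float)
    dt, gain, stride = dyn.dt, dyn.gain, dyn.record_stride
    n_tr = int(round(dyn.t_transient / dt))
    n_me = int(round(dyn.t_measure / dt))
    B = 1 + n_restarts
    cont = rng.uniform(-1, 1, size=N)
    t_max_list, i_max_list, fp_flags = [], [], []
    for gamma in gamma_grid:
        X = np.column_stack(
            [cont] + [rng.uniform(-1, 1, size=N) for _ in range(n_restarts)]
        )
        drive = gamma * eta[:, None]
        for _ in range(n_tr):
            X = X + dt * (np.tanh(gain * (net.J @ X + drive)) - X)
        mt = np.empty((n_me // stride + 1, B))
        mi = np.empty_like(mt)
        times = np.empty(mt.shape[0])
        r = 0
        for step in range(n_me):
            X = X + dt * (np.tanh(gain * (net.J @ X + drive)) - X)
            if step % stride == 0:
                mt[r] = xi @ X / N
                mi[r] = eta @ X / N
                times[r] = step * dt
                r += 1
        mt, mi, times = mt[:r], mi[:r], times[:r]
        tm, im = [], []
        fp = True
        for b in range(B):
            s_t = OverlapSeries(times=times, values=mt[:, b])
            s_i = OverlapSeries(times=times, values=mi[:, b])
            tm.append(local_maxima(s_t))
            im.append(local_maxima(s_i))
            if np.ptp(mt[:, b]) >= FIXED_POINT_TOL:
                fp = False
        t_max_list.append(np.concatenate(tm))
        i_max_list.append(np.concatenate(im))
        fp_flags.append(fp)
        cont = X[:, 0]
    return BifurcationDiagram(
        gamma_grid=gamma_grid,
        target_maxima=t_max_list,
        input_maxima=i_max_list,
        fixed_point=np.array(fp_flags),
        mu=mu,
    )


def jacobian(
    x: np.ndarray,
    J: np.ndarray,
    eta: np.ndarray | None = None,
    gamma: float = 0.0,
    gain: float = DEFAULT_GAIN,
) -> np.ndarray:
    """Linearization M_ij = S'(u_i) J_ij - delta_ij of the rate dynamics."""
    x = np.asarray(x, dtype=float)
    J = np.asarray(J, dtype=float)
    if J.shape != (x.shape[0], x.shape[0]):
        raise ValueError("J must be square and match x")
    u = J @ x
    if gamma > 0:
        if eta is None:
            raise ValueError("eta required when gamma > 0")
        u = u + gamma * np.asarray(eta, dtype=float)
    M = sigmoid_prime(u, gain)[:, None] * J
    M[np.diag_indices_from(M)] -= 1.0
    return M


@dataclass(frozen=True)
class LyapunovSpectrum:
    """Leading Lyapunov exponents, sorted descending, in 1/time units."""

    exponents: np.ndarray
    n_positive: int
    diagnostic: float  # max drift between last-half and full-run estimates
    converged: bool


def lyapunov_spectrum(
    J: np.ndarray,
    eta: np.ndarray | None = None,
    gamma: float = 0.0,
    k: int = 20,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
    x0: np.ndarray | None = None,
    t_transient: float = 200.0,
    t_accum: float = 2000.0,
    ortho_every: int = 10,
    diag_tol: float = 0.05,
) -> LyapunovSpectrum:
    """Leading ``k`` Lyapunov exponents by tangent propagation with QR
    reorthonormalization along the trajectory.

    The tangent frame is propagated with the same Euler map as the state
    and re-orthonormalized every ``ortho_every`` steps; exponents are the
    time-averaged log diagonal of the R factors after the transient.  The
    diagnostic is the largest difference between the exponents estimated
    from the last half of the run and from the whole run; exceeding
    ``diag_tol`` clears the ``converged`` flag (no exception).
    """
    J = np.asarray(J, dtype=float)
    N = J.shape[0]
    if not 1 <= k <= N:
        raise ValueError("k must lie in 1..N")
    rng = (
        seeds
        if isinstance(seeds, np.random.Generator)
        else np.random.default_rng(seeds)
    )
    dt, gain = dyn.dt, dyn.gain
    x = rng.uniform(-1, 1, size=N) if x0 is None else np.asarray(x0, dtype=float).copy()
    drive = gamma * np.asarray(eta, dtype=float) if gamma > 0 else 0.0
    if gamma > 0 and eta is None:
        raise ValueError("eta required when gamma > 0")
    Q, _ = np.linalg.qr(rng.standard_normal((N, k)))
    n_tr = int(round(t_transient / dt))
    n_ac = int(round(t_accum / dt))

    def step_once(x, Q):
        u = J @ x + drive
        sp = sigmoid_prime(u, gain)
        x_new = x + dt * (np.tanh(gain * u) - x)
        Q_new = Q + dt * (sp[:, None] * (J @ Q) - Q)
        return x_new, Q_new

    for s in range(n_tr):
        x, Q = step_once(x, Q)
        if (s + 1) % ortho_every == 0:
            Q, _ = np.linalg.qr(Q)
    log_sum = np.zeros(k)
    half_sum = np.zeros(k)
    half_at = n_ac // 2
    elapsed = 0
    for s in range(n_ac):
        x, Q = step_once(x, Q)
        if (s + 1) % ortho_every == 0 or s == n_ac - 1:
            Q, R = np.linalg.qr(Q)
            d = np.abs(np.diag(R))
            d[d == 0] = np.finfo(float).tiny
            log_sum += np.log(d)
            if s >= half_at:
                half_sum += np.log(d)
            elapsed = s + 1
    t_total = elapsed * dt
    t_half = (n_ac - half_at) * dt
    lam = np.sort(log_sum / t_total)[::-1]
    lam_half = np.sort(half_sum / t_half)[::-1]
    diagnostic = float(np.max(np.abs(lam - lam_half)))
    return LyapunovSpectrum(
        exponents=lam,
        n_positive=int(np.sum(lam > POSITIVE_TOL)),
        diagnostic=diagnostic,
        converged=bool(diagnostic <= diag_tol),
    )
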