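"""Measurement apparatus: recall, memory capacity, spontaneous statistics,
connection-matrix projections and power-law decay fits.

All mapping indices here are *ages*: age mu = 1 is the mapping learned
last, mu = 2 the one learned one step earlier, and so on.  The central
quantities are

* the time-averaged overlap m̄ of the evoked activity with a pattern,
  further averaged over random initial states;
* the recall criterion: target mu is recalled when m̄ with the target
  exceeds m̄ with every competitor (other targets, all inputs, random
  probe patterns), all measured under input mu;
* D_mu = m̄(target mu) - m̄(input mu), both under input mu; the capacity
  C is the largest age mu with D_mu' > theta for every mu' <= mu;
* the standard deviation over time of the spontaneous overlap with each
  target, quantifying how closely the input-free activity approaches it;
* the projections c_ab = a^T J b / N of the connection matrix onto
  pattern pairs, which diagnose the learned structure (Mattis-like vs.
  input/output-correlation based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams, OverlapSeries, simulate, simulate_mean_states
from .learning import TrainedNetwork
from .patterns import Mapping, ProbeSet, SeedBundle, generate_probe_set, initial_state

__all__ = [
    "RecallResult",
    "CapacityResult",
    "SpontaneousStats",
    "ProjectionQuad",
    "DecayFit",
    "time_stats",
    "mean_overlap_profile",
    "recall_trial",
    "overlap_difference",
    "capacity",
    "spontaneous_stats",
    "project",
    "matrix_quad",
    "quad_vs_age",
    "fit_decay_exponent",
]

#: default threshold theta of the capacity definition; any small positive
#: value gives essentially the same capacity.
DEFAULT_THETA = 0.01

#: default number of random initial states the recall average runs over.
DEFAULT_N_INITS = 5

#: default number of recent mappings analyzed (out of the 40 learned).
DEFAULT_ANALYSIS_WINDOW = 30


# ---------------------------------------------------------------------------
# basic time statistics


def time_stats(series: OverlapSeries, t_transient: float = 0.0) -> tuple[float, float]:
    """Mean and population SD of a series over samples with t >= t_transient."""
    mask = series.times >= t_transient
    if not np.any(mask):
        raise ValueError("no samples beyond t_transient")
    vals = series.values[mask]
    return float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# recall and capacity


def _resolve_rng(net: TrainedNetwork, seeds) -> np.random.Generator:
    if seeds is None:
        return net.seeds.rng("recall_x0")
    if isinstance(seeds, np.random.Generator):
        return seeds
    if isinstance(seeds, SeedBundle):
        return seeds.rng("recall_x0")
    return np.random.default_rng(seeds)


def mean_overlap_profile(
    net: TrainedNetwork,
    ages,
    gamma_r: float,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time- and initial-state-averaged overlaps for several ages at once.

    For each age mu in ``ages`` the evoked dynamics run under input mu at
    strength ``gamma_r`` from ``n_inits`` random initial states.  Returns
    ``(m_target, m_input, mean_states)`` where the first two are arrays
    over ``ages`` and ``mean_states`` has shape (len(ages), n_inits, N)
    holding each trajectory's time-averaged state (the overlap with any
    pattern being linear in it).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=int))
    rng = _resolve_rng(net, seeds)
    N = net.n_neurons
    etas = np.stack([net.mapping_set.by_age(int(a)).input for a in ages]).astype(float)
    xis = np.stack([net.mapping_set.by_age(int(a)).target for a in ages]).astype(float)
    B = len(ages) * n_inits
    H = np.repeat(etas, n_inits, axis=0).T  # (N, B)
    X0 = rng.uniform(-1.0, 1.0, size=(N, B))
    dyn_g = dyn.with_gamma(gamma_r)
    _, X_mean = simulate_mean_states(X0, net.J, H if gamma_r > 0 else None, dyn_g)
    mean_states = X_mean.T.reshape(len(ages), n_inits, N)
    m_target = np.einsum("an,ain->ai", xis, mean_states).mean(axis=1) / N
    m_input = np.einsum("an,ain->ai", etas, mean_states).mean(axis=1) / N
    return m_target, m_input, mean_states


@dataclass(frozen=True)
class RecallResult:
    """Outcome of one recall trial for mapping age mu."""

    mu: int
    mean_target_overlap: float
    mean_input_overlap: float
    best_competitor_overlap: float
    best_competitor: str
    success: bool
    per_init_target_overlap: np.ndarray
    per_init_success: np.ndarray


def recall_trial(
    net: TrainedNetwork,
    mu: int,
    probes: ProbeSet | None = None,
    gamma_r: float | None = None,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
) -> RecallResult:
    """Evoked-recall trial for the mapping of age ``mu``.

    Recall succeeds when the initial-state-averaged, time-averaged overlap
    with target mu strictly exceeds that with every competitor: the other
    analyzed targets, all analyzed inputs (including input mu itself) and
    the random probes.
    """
    if gamma_r is None:
        gamma_r = net.params.gamma_learn
    P = len(net.mapping_set)
    M = min(DEFAULT_ANALYSIS_WINDOW, P)
    if not 1 <= mu <= P:
        raise IndexError(f"mu {mu} out of range 1..{P}")
    if probes is None:
        probes = generate_probe_set(net.n_neurons, 10, net.seeds.seed("probes"))
    m_t, m_i, mean_states = mean_overlap_profile(
        net, [mu], gamma_r, n_inits, dyn, seeds
    )
    states = mean_states[0]  # (n_inits, N)
    N = net.n_neurons
    ages = [a for a in range(1, M + 1)]
    comp_patterns = []
    comp_labels = []
    for a in ages:
        if a != mu:
            comp_patterns.append(net.mapping_set.by_age(a).target)
            comp_labels.append(f"target[{a}]")
        comp_patterns.append(net.mapping_set.by_age(a).input)
        comp_labels.append(f"input[{a}]")
    for k in range(len(probes)):
        comp_patterns.append(probes.probes[k])
        comp_labels.append(f"probe[{k}]")
    C = np.stack(comp_patterns).astype(float)  # (n_comp, N)
    comp_per_init = C @ states.T / N  # (n_comp, n_inits)
    comp_means = comp_per_init.mean(axis=1)
    best = int(np.argmax(comp_means))
    xi = net.mapping_set.by_age(mu).target.astype(float)
    per_init_target = states @ xi / N
    per_init_success = per_init_target > comp_per_init.max(axis=0)
    return RecallResult(
        mu=mu,
        mean_target_overlap=float(m_t[0]),
        mean_input_overlap=float(m_i[0]),
        best_competitor_overlap=float(comp_means[best]),
        best_competitor=comp_labels[best],
        success=bool(m_t[0] > comp_means[best]),
        per_init_target_overlap=per_init_target,
        per_init_success=per_init_success,
    )


def overlap_difference(
    net: TrainedNetwork,
    mu: int,
    gamma_r: float | None = None,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
) -> float:
    """D_mu = m̄(target mu) - m̄(input mu), both under input mu."""
    if gamma_r is None:
        gamma_r = net.params.gamma_learn
    m_t, m_i, _ = mean_overlap_profile(net, [mu], gamma_r, n_inits, dyn, seeds)
    return float(m_t[0] - m_i[0])


@dataclass(frozen=True)
class CapacityResult:
    """D_mu profile and memory capacity of a network ensemble."""

    D: np.ndarray  # ensemble-averaged D_mu, mu = 1..M
    capacity: int
    theta: float
    per_network_D: np.ndarray  # (n_networks, M)
    per_network_capacity: np.ndarray
    m_target: np.ndarray  # ensemble-averaged overlap with target, per age
    m_input: np.ndarray


def _capacity_from_D(D: np.ndarray, theta: float) -> int:
    C = 0
    for mu in range(len(D)):
        if D[mu] > theta:
            C = mu + 1
        else:
            break
    return C


def capacity(
    nets,
    gamma_r: float | None = None,
    theta: float = DEFAULT_THETA,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
    M: int | None = None,
    seeds=None,
) -> CapacityResult:
    """Memory capacity of one or more trained networks.

    The D_mu sequence is averaged over the ensemble first; the capacity is
    the largest age mu such that the averaged D exceeds ``theta`` for every
    age up to mu (0 if it fails already at mu = 1).  Per-network capacities
    are reported alongside.
    """
    if isinstance(nets, TrainedNetwork):
        nets = [nets]
    nets = list(nets)
    if not nets:
        raise ValueError("empty network ensemble")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if M is None:
        M = min(DEFAULT_ANALYSIS_WINDOW, min(len(n.mapping_set) for n in nets))
    ages = np.arange(1, M + 1)
    all_D, all_mt, all_mi = [], [], []
    for net in nets:
        g = net.params.gamma_learn if gamma_r is None else gamma_r
        m_t, m_i, _ = mean_overlap_profile(net, ages, g, n_inits, dyn, seeds)
        all_mt.append(m_t)
        all_mi.append(m_i)
        all_D.append(m_t - m_i)
    per_D = np.stack(all_D)
    D = per_D.mean(axis=0)
    return CapacityResult(
        D=D,
        capacity=_capacity_from_D(D, theta),
        theta=theta,
        per_network_D=per_D,
        per_network_capacity=np.array([_capacity_from_D(d, theta) for d in per_D]),
        m_target=np.stack(all_mt).mean(axis=0),
        m_input=np.stack(all_mi).mean(axis=0),
    )


# ---------------------------------------------------------------------------
# spontaneous activity


@dataclass(frozen=True)
class SpontaneousStats:
    """Per-target SD of the spontaneous overlap and its average over ages."""

    sd: np.ndarray  # SD(mu) for mu = 1..M
    average_sd: float  # mean of sd over the first M targets
    probe_sd: float  # mean SD of the probe overlaps (control)
    mean: np.ndarray  # time-mean overlap per target (≈ 0 by odd symmetry)
    target_overlaps: np.ndarray  # (M, T) overlap samples, post-transient
    probe_overlaps: np.ndarray  # (K, T)
    times: np.ndarray


def spontaneous_stats(
    net: TrainedNetwork,
    M: int = DEFAULT_ANALYSIS_WINDOW,
    dyn: DynamicsParams = DynamicsParams(),
    seeds=None,
    probes: ProbeSet | None = None,
) -> SpontaneousStats:
    """Statistics of the input-free dynamics against the last M targets.

    A single spontaneous trajectory is integrated; its overlap with each of
    the M most recent targets and with the control probes is recorded, and
    the population SD over the post-transient window is returned per
    pattern.  In the response regime the target SDs exceed the probe SD
    (the activity selectively approaches learned targets); in the
    non-response regime the dynamics sit on fixed points and all SDs are 0.
    """
    if M > len(net.mapping_set):
        raise ValueError("M exceeds the number of stored mappings")
    if probes is None:
        probes = generate_probe_set(net.n_neurons, 10, net.seeds.seed("probes"))
    rng = _resolve_rng(net, seeds)
    x0 = initial_state(net.n_neurons, rng)
    traj = simulate(x0, net.J, None, dyn.with_gamma(0.0))
    mask = traj.times >= dyn.t_transient
    if mask.sum() < 2:
        raise ValueError("measurement window too short")
    states = traj.states[mask]
    times = traj.times[mask]
    N = net.n_neurons
    xis = np.stack(
        [net.mapping_set.by_age(a).target for a in range(1, M + 1)]
    ).astype(float)
    t_over = xis @ states.T / N  # (M, T)
    p_over = probes.probes.astype(float) @ states.T / N
    sd = t_over.std(axis=1)
    return SpontaneousStats(
        sd=sd,
        average_sd=float(sd.mean()),
        probe_sd=float(p_over.std(axis=1).mean()),
        mean=t_over.mean(axis=1),
        target_overlaps=t_over,
        probe_overlaps=p_over,
        times=times,
    )


# ---------------------------------------------------------------------------
# connection-matrix projections


@dataclass(frozen=True)
class ProjectionQuad:
    """The four projections of J onto a mapping's target/input pair.

    Field names read left-to-right: ``c_target_input`` is
    target^T J input / N.  A Mattis-type matrix has ``c_target_target``
    dominant; the response-regime matrix has ``c_target_target`` and
    ``c_target_input`` salient positive with ``c_input_target`` and
    ``c_input_input`` salient negative.
    """

    c_target_target: float
    c_target_input: float
    c_input_target: float
    c_input_input: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.c_target_target,
                self.c_target_input,
                self.c_input_target,
                self.c_input_input,
            ]
        )


def project(J: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """c_ab = a^T J b / N."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    J = np.asarray(J, dtype=float)
    if J.shape != (a.shape[0], b.shape[0]) or a.ndim != 1 or b.ndim != 1:
        raise ValueError("shape mismatch between J and patterns")
    return float(a @ J @ b / J.shape[0])


def matrix_quad(J: np.ndarray, mapping: Mapping) -> ProjectionQuad:
    xi = mapping.target.astype(float)
    eta = mapping.input.astype(float)
    return ProjectionQuad(
        c_target_target=project(J, xi, xi),
        c_target_input=project(J, xi, eta),
        c_input_target=project(J, eta, xi),
        c_input_input=project(J, eta, eta),
    )


def quad_vs_age(net: TrainedNetwork, M: int | None = None) -> list[ProjectionQuad]:
    """Projection quads for ages 1..M (1 = latest)."""
    if M is None:
        M = min(DEFAULT_ANALYSIS_WINDOW, len(net.mapping_set))
    return [matrix_quad(net.J, net.mapping_set.by_age(a)) for a in range(1, M + 1)]


# ---------------------------------------------------------------------------
# power-law decay fits


@dataclass(frozen=True)
class DecayFit:
    """Least-squares power-law fit value ∝ mu^(-exponent) on log-log axes."""

    exponent: float
    amplitude: float
    mu_range: tuple[int, int]
    residual: float  # RMS residual of log(value) around the fit


def fit_decay_exponent(values, mu_range: tuple[int, int] | None = None) -> DecayFit:
    """Fit ``values[mu-1] = c * mu**(-exponent)`` by least squares in logs.

    ``values`` is indexed by age mu starting at 1; all values in the fit
    range must be positive.
    """
    values = np.asarray(values, dtype=float)
    mus = np.arange(1, len(values) + 1)
    if mu_range is None:
        mu_range = (1, len(values))
    lo, hi = mu_range
    sel = (mus >= lo) & (mus <= hi)
    v = values[sel]
    m = mus[sel]
    if len(v) < 2:
        raise ValueError("fit range must contain at least two points")
    if np.any(v <= 0):
        raise ValueError("values must be positive over the fit range")
    X = np.log(m)
    Y = np.log(v)
    slope, intercept = np.polyfit(X, Y, 1)
    resid = Y - (slope * X + intercept)
    return DecayFit(
        exponent=float(-slope),
        amplitude=float(np.exp(intercept)),
        mu_range=(int(lo), int(hi)),
        residual=float(np.sqrt(np.mean(resid**2))),
    )
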