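"""Coupled neural-synaptic dynamics: sequential supervised Hebbian learning.

While a mapping (input eta, target xi) is being learned, the input is held
at strength gamma_learn and the connections evolve concurrently with the
activity:

    dJ_ij/dt = epsilon * (xi_i - x_i) * x_j      (i != j)

epsilon is the inverse of the time-scale ratio of synaptic to neural
dynamics.  The rule decomposes into an anti-Hebbian part (-x_i x_j) and a
supervised part (xi_i x_j); it vanishes identically when the activity
matches the target, so learning self-terminates.  Mappings are learned
sequentially on a single carried-over connection matrix (palimpsest
storage): new mappings overwrite traces of old ones, and capacity is the
number of recent mappings still recallable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dynamics import DEFAULT_GAIN, OverlapSeries
from .patterns import (
    Mapping,
    MappingSet,
    SeedBundle,
    initial_connections,
    initial_state,
)

__all__ = [
    "LearningParams",
    "LearningRecord",
    "TrainedNetwork",
    "LearningConvergenceError",
    "synaptic_field",
    "learn_mapping",
    "learn_sequence",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class LearningParams:
    """Parameters of one learning step.

    ``gamma_learn`` is the constant input strength during learning,
    ``epsilon`` the synaptic rate (inverse time-scale ratio).  A step is
    converged when the target overlap, averaged over a sliding window of
    one neural time unit, reaches ``convergence_threshold`` (tanh
    saturation prevents exactly ±1).  ``t_max`` bounds each step; hitting
    it raises rather than silently truncating.
    """

    gamma_learn: float = 16.0
    epsilon: float = 0.01
    dt: float = 0.01
    convergence_threshold: float = 0.95
    t_max: float = 5000.0
    record_stride: int = 10
    gain: float = DEFAULT_GAIN

    def __post_init__(self):
        if self.gamma_learn <= 0 or self.epsilon <= 0:
            raise ValueError("gamma_learn and epsilon must be positive")
        if not 0 < self.convergence_threshold < 1:
            raise ValueError("convergence_threshold must lie in (0, 1)")
        if not 0 < self.dt < 1:
            raise ValueError("dt must lie in (0, 1)")


@dataclass(frozen=True)
class LearningRecord:
    """Outcome of one learning step."""

    index: int
    duration: float
    trace: OverlapSeries  # overlap with the target over the step
    converged: bool


class LearningConvergenceError(RuntimeError):
    """A learning step hit t_max before matching its target."""

    def __init__(self, message: str, record: LearningRecord):
        super().__init__(message)
        self.record = record


@dataclass(frozen=True)
class TrainedNetwork:
    """A connection matrix shaped by sequential learning, with provenance."""

    J: np.ndarray
    mapping_set: MappingSet
    params: LearningParams
    records: tuple[LearningRecord, ...]
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.J.shape[0]

    @property
    def seeds(self) -> SeedBundle:
        return SeedBundle(self.seed)


def synaptic_field(x: np.ndarray, xi: np.ndarray, epsilon: float) -> np.ndarray:
    """dJ/dt = epsilon (xi - x) x^T with zero diagonal."""
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x.shape != xi.shape or x.ndim != 1:
        raise ValueError("x and xi must be 1-d arrays of equal length")
    dJ = epsilon * np.outer(xi - x, x)
    np.fill_diagonal(dJ, 0.0)
    return dJ


def learn_mapping(
    x0: np.ndarray,
    J0: np.ndarray,
    mapping: Mapping,
    params: LearningParams,
) -> tuple[np.ndarray, LearningRecord]:
    """Run the coupled dynamics for one mapping until the target is matched.

    Neural and synaptic updates share the Euler step ``params.dt`` (the
    synapses are slower by epsilon, so the neural time scale dominates
    stiffness).  Returns the updated connection matrix and a record of the
    step; raises :class:`LearningConvergenceError` at ``t_max``.
    """
    x = np.asarray(x0, dtype=float).copy()
    J = np.asarray(J0, dtype=float).copy()
    if np.any(np.abs(x) > 1):
        raise ValueError("x0 entries must lie in [-1, 1]")
    if J.shape != (x.shape[0], x.shape[0]):
        raise ValueError("J0 must be square and match x0")
    eta = mapping.input.astype(float)
    xi = mapping.target.astype(float)
    dt, gain = params.dt, params.gain
    gamma, eps = params.gamma_learn, params.epsilon
    n_max = int(round(params.t_max / dt))
    win = max(int(round(1.0 / dt)), 1)
    buf = np.zeros(win)
    N = x.shape[0]
    t_rec, m_rec = [0.0], [float(xi @ x / N)]
    for step in range(1, n_max + 1):
        x_new = x + dt * (np.tanh(gain * (J @ x + gamma * eta)) - x)
        J += np.outer((eps * dt) * (xi - x), x)
        np.fill_diagonal(J, 0.0)
        x = x_new
        m = xi @ x / N
        buf[step % win] = m
        if step % params.record_stride == 0:
            t_rec.append(step * dt)
            m_rec.append(float(m))
        if step >= win and buf.mean() >= params.convergence_threshold:
            trace = OverlapSeries(
                times=np.array(t_rec),
                values=np.array(m_rec),
                reference=f"target[{mapping.index}]",
            )
            rec = LearningRecord(
                index=mapping.index, duration=step * dt, trace=trace, converged=True
            )
            return J, rec
    trace = OverlapSeries(
        times=np.array(t_rec), values=np.array(m_rec), reference=f"target[{mapping.index}]"
    )
    rec = LearningRecord(
        index=mapping.index, duration=params.t_max, trace=trace, converged=False
    )
    raise LearningConvergenceError(
        f"learning step {mapping.index} did not converge within t_max={params.t_max}",
        rec,
    )


def learn_sequence(
    mapping_set: MappingSet,
    params: LearningParams,
    seeds: SeedBundle | int,
) -> TrainedNetwork:
    """Learn every mapping in order on one carried-over connection matrix.

    The initial connections are random binary ±1/sqrt(N); each step starts
    from a fresh random activity state drawn from the ``learning_x0``
    stream, while the connection matrix carries over from the previous
    step.  Deterministic given the seed bundle.
    """
    if not isinstance(seeds, SeedBundle):
        seeds = SeedBundle(int(seeds))
    N = mapping_set.n_neurons
    J = initial_connections(N, seeds.rng("initial_j"))
    x_rng = seeds.rng("learning_x0")
    records = []
    for mapping in mapping_set.mappings:
        x0 = initial_state(N, x_rng)
        try:
            J, rec = learn_mapping(x0, J, mapping, params)
        except LearningConvergenceError as err:
            raise LearningConvergenceError(
                f"sequence failed at step {mapping.index}: {err}", err.record
            ) from err
        records.append(rec)
    return TrainedNetwork(
        J=J,
        mapping_set=mapping_set,
        params=params,
        records=tuple(records),
        seed=seeds.root,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 + JSON manifest in file attrs)

def save_network(net: TrainedNetwork, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=net.J)
        f.create_dataset("inputs", data=net.mapping_set.inputs())
        f.create_dataset("targets", data=net.mapping_set.targets())
        f.attrs["params"] = json.dumps(asdict(net.params))
        f.attrs["seed"] = net.seed
        f.attrs["mapping_seed"] = net.mapping_set.seed
        g = f.create_group("records")
        for rec in net.records:
            sub = g.create_group(str(rec.index))
            sub.attrs["duration"] = rec.duration
            sub.attrs["converged"] = rec.converged
            sub.create_dataset("times", data=rec.trace.times)
            sub.create_dataset("values", data=rec.trace.values)


def load_network(path: str | Path) -> TrainedNetwork:
    import h5py

    from .patterns import Mapping

    with h5py.File(path, "r") as f:
        J = f["J"][()]
        inputs = f["inputs"][()].astype(np.int8)
        targets = f["targets"][()].astype(np.int8)
        params = LearningParams(**json.loads(f.attrs["params"]))
        seed = int(f.attrs["seed"])
        mseed = int(f.attrs["mapping_seed"])
        mappings = tuple(
            Mapping(index=k + 1, input=inputs[k], target=targets[k])
            for k in range(inputs.shape[0])
        )
        ms = MappingSet(n_neurons=J.shape[0], mappings=mappings, seed=mseed)
        records = []
        for key in sorted(f["records"], key=int):
            sub = f["records"][key]
            trace = OverlapSeries(
                times=sub["times"][()],
                values=sub["values"][()],
                reference=f"target[{key}]",
            )
            records.append(
                LearningRecord(
                    index=int(key),
                    duration=float(sub.attrs["duration"]),
                    trace=trace,
                    converged=bool(sub.attrs["converged"]),
                )
            )
    return TrainedNetwork(
        J=J, mapping_set=ms, params=params, records=tuple(records), seed=seed
    )
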