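"""Random binary pattern ensembles and random initial conditions.

Every object the model consumes is generated here: the input/target
pattern pairs ("mappings") to be learned, control probe patterns used as
a null reference when measuring overlaps, the random initial activity
vectors, and the random initial connection matrix.

All generators are deterministic functions of their arguments.  A single
root seed per experiment is split into named, independent streams (see
:class:`SeedBundle`), so any sub-experiment can be replayed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Mapping",
    "MappingSet",
    "ProbeSet",
    "SeedBundle",
    "generate_mapping_set",
    "generate_probe_set",
    "initial_state",
    "initial_connections",
    "save_mapping_set",
    "load_mapping_set",
]

#: amplitude of the initial binary connection entries; entries are drawn
#: uniformly from {-a, +a} with a = INITIAL_J_SCALE / sqrt(N), keeping the
#: recurrent drive O(1) at the start of learning.
INITIAL_J_SCALE = 1.0

# Named sub-streams derived from a root seed.  Each name maps to a fixed
# spawn index so that streams are independent and individually replayable.
_STREAM_INDEX = {
    "patterns": 0,
    "probes": 1,
    "initial_j": 2,
    "learning_x0": 3,
    "recall_x0": 4,
    "analysis": 5,
}


@dataclass(frozen=True)
class SeedBundle:
    """Deterministic split of one root seed into named independent streams."""

    root: int

    def rng(self, stream: str) -> np.random.Generator:
        if stream not in _STREAM_INDEX:
            raise KeyError(f"unknown seed stream {stream!r}")
        ss = np.random.SeedSequence(self.root, spawn_key=(_STREAM_INDEX[stream],))
        return np.random.default_rng(ss)

    def seed(self, stream: str) -> int:
        """A 31-bit integer seed for the named stream."""
        return int(self.rng(stream).integers(0, 2**31 - 1))


def _random_signs(rng: np.random.Generator, shape) -> np.ndarray:
    """i.i.d. uniform ±1 entries, stored as int8."""
    return (2 * rng.integers(0, 2, size=shape) - 1).astype(np.int8)


@dataclass(frozen=True)
class Mapping:
    """One input/target pair, indexed by the order it is learned.

    ``index`` counts learning steps (1 = learned first).  Measurement code
    re-indexes by *age*, where age 1 is the mapping learned last.
    """

    index: int
    input: np.ndarray  # eta, ±1 entries
    target: np.ndarray  # xi, ±1 entries

    def __post_init__(self):
        eta, xi = np.asarray(self.input), np.asarray(self.target)
        if eta.shape != xi.shape or eta.ndim != 1:
            raise ValueError("input and target must be 1-d arrays of equal length")
        for name, v in (("input", eta), ("target", xi)):
            if not np.all(np.abs(v) == 1):
                raise ValueError(f"{name} entries must be exactly ±1")

    @property
    def n_neurons(self) -> int:
        return self.input.shape[0]


@dataclass(frozen=True)
class MappingSet:
    """An ordered collection of mappings sharing one network size."""

    n_neurons: int
    mappings: tuple[Mapping, ...]
    seed: int

    def __post_init__(self):
        for k, m in enumerate(self.mappings, start=1):
            if m.n_neurons != self.n_neurons:
                raise ValueError("all mappings must share n_neurons")
            if m.index != k:
                raise ValueError("mapping indices must be consecutive from 1")

    def __len__(self) -> int:
        return len(self.mappings)

    def by_age(self, age: int) -> Mapping:
        """Mapping that was learned ``age`` steps ago (age 1 = latest)."""
        if not 1 <= age <= len(self.mappings):
            raise IndexError(f"age {age} out of range 1..{len(self.mappings)}")
        return self.mappings[len(self.mappings) - age]

    def inputs(self) -> np.ndarray:
        """(P, N) int8 array of inputs in learning order."""
        return np.stack([m.input for m in self.mappings])

    def targets(self) -> np.ndarray:
        return np.stack([m.target for m in self.mappings])


@dataclass(frozen=True)
class ProbeSet:
    """Control patterns from the same ±1 ensemble as inputs and targets."""

    probes: np.ndarray  # (K, N) int8
    seed: int

    def __len__(self) -> int:
        return self.probes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.probes.shape[1]


def generate_mapping_set(n_neurons: int, n_mappings: int, seed: int) -> MappingSet:
    """Draw ``n_mappings`` random ±1 input/target pairs of length ``n_neurons``.

    Entries are i.i.d. uniform on {-1, +1}; the result is a deterministic
    function of its arguments.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if n_mappings < 1:
        raise ValueError("n_mappings must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    mappings = []
    for k in range(1, n_mappings + 1):
        eta = _random_signs(rng, n_neurons)
        xi = _random_signs(rng, n_neurons)
        mappings.append(Mapping(index=k, input=eta, target=xi))
    return MappingSet(n_neurons=n_neurons, mappings=tuple(mappings), seed=seed)


def generate_probe_set(n_neurons: int, n_probes: int = 10, seed: int = 0) -> ProbeSet:
    """Draw ``n_probes`` control patterns from the target/input ensemble."""
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    return ProbeSet(probes=_random_signs(rng, (n_probes, n_neurons)), seed=seed)


def initial_state(n_neurons: int, rng: np.random.Generator | int) -> np.ndarray:
    """Random activity vector, entries uniform on [-1, 1]."""
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(-1.0, 1.0, size=n_neurons)


def initial_connections(
    n_neurons: int,
    rng: np.random.Generator | int,
    scale: float = INITIAL_J_SCALE,
) -> np.ndarray:
    """Random binary connection matrix with zero diagonal.

    Off-diagonal entries are drawn from {-scale/sqrt(N), +scale/sqrt(N)}
    with equal probability; the network is fully connected without
    self-connections.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    amp = scale / np.sqrt(n_neurons)
    J = amp * (2 * rng.integers(0, 2, size=(n_neurons, n_neurons)) - 1).astype(float)
    np.fill_diagonal(J, 0.0)
    return J


# ---------------------------------------------------------------------------
# serialization: JSON header + CSV matrices; round-trip is bit-exact because
# patterns are small signed integers.

def save_mapping_set(ms: MappingSet, path: str | Path) -> None:
    """Write a mapping set as ``<path>.json`` + ``<path>.csv``.

    The CSV holds inputs then targets as rows (2P rows of N entries).
    """
    path = Path(path)
    header = {"n_neurons": ms.n_neurons, "n_mappings": len(ms), "seed": ms.seed}
    path.with_suffix(".json").write_text(json.dumps(header))
    mat = np.vstack([ms.inputs(), ms.targets()])
    np.savetxt(path.with_suffix(".csv"), mat, fmt="%d", delimiter=",")


def load_mapping_set(path: str | Path) -> MappingSet:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    mat = np.loadtxt(path.with_suffix(".csv"), dtype=np.int8, delimiter=",", ndmin=2)
    P = header["n_mappings"]
    mappings = tuple(
        Mapping(index=k + 1, input=mat[k], target=mat[P + k]) for k in range(P)
    )
    return MappingSet(
        n_neurons=header["n_neurons"], mappings=mappings, seed=header["seed"]
    )
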