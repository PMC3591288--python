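"""Composite experiments: phase diagrams, regime classification, capacity
scaling, and TOML-configured runs.

The two learning parameters — input strength gamma_learn and synaptic
rate epsilon — span a phase plane with two regimes: the response (R)
regime (large gamma, small epsilon) with chaotic spontaneous activity and
a multi-mapping capacity that grows as ~0.2 N, and the non-response (NR)
regime where only the latest target and its reverse are fixed points and
the capacity is 0 or 1.  The boundary is traced by the line where the
capacity exceeds one, which coincides with a ridge of spontaneous-overlap
SD.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import DynamicsParams
from .learning import LearningConvergenceError, LearningParams, learn_sequence
from .measures import (
    DEFAULT_ANALYSIS_WINDOW,
    DEFAULT_N_INITS,
    DEFAULT_THETA,
    capacity,
    spontaneous_stats,
)
from .patterns import generate_mapping_set

__all__ = [
    "PhasePoint",
    "ScalingResult",
    "fit_capacity_slope",
    "train_ensemble",
    "phase_scan",
    "classify_regime",
    "capacity_scaling",
    "derive_seed",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("bifmem")


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


def derive_seed(root: int, *key: int) -> int:
    """Deterministic 31-bit child seed from a root seed and an index path."""
    ss = np.random.SeedSequence(root, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def train_ensemble(
    n_neurons: int,
    n_mappings: int,
    params: LearningParams,
    n_networks: int,
    seed: int,
):
    """Train ``n_networks`` independent networks, each with its own random
    mapping set and initial conditions derived from ``seed``."""
    nets = []
    for i in range(n_networks):
        net_seed = derive_seed(seed, 7, i)
        ms = generate_mapping_set(n_neurons, n_mappings, derive_seed(seed, 8, i))
        logger.info(
            "training network %d/%d (N=%d, P=%d, gamma=%g, eps=%g, seed=%d)",
            i + 1, n_networks, n_neurons, n_mappings,
            params.gamma_learn, params.epsilon, net_seed,
        )
        net = learn_sequence(ms, params, net_seed)
        logger.info(
            "  converged; mean step duration %.1f time units",
            float(np.mean([r.duration for r in net.records])),
        )
        nets.append(net)
    return nets


@dataclass(frozen=True)
class PhasePoint:
    """One point of the (gamma_learn, epsilon) phase plane."""

    gamma_learn: float
    epsilon: float
    capacity: float
    average_sd: float
    regime: str  # "R", "NR" or "boundary"
    failed: bool = False


def classify_regime(capacity_value: float, sd: float | None = None) -> str:
    """R when the capacity exceeds one, NR otherwise."""
    return "R" if capacity_value > 1 else "NR"


def phase_scan(
    grid,
    n_neurons: int = 100,
    n_mappings: int = 40,
    n_networks: int = 3,
    seed: int = 0,
    gamma_r: float | None = None,
    theta: float = DEFAULT_THETA,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
    M: int = DEFAULT_ANALYSIS_WINDOW,
) -> list[PhasePoint]:
    """Ensemble capacity and average spontaneous SD over a (gamma, eps) grid.

    ``grid`` is an iterable of (gamma_learn, epsilon) pairs.  Per-point
    failures (e.g. non-convergent learning) are recorded as failed points
    and the scan continues.  After the scan, points with capacity in
    (0.5, 1.5] whose SD is not below any same-gamma neighbor are relabelled
    "boundary" (the SD ridge divides the regimes).
    """
    grid = [(float(g), float(e)) for g, e in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    points: list[PhasePoint] = []
    for j, (g, e) in enumerate(grid):
        params = LearningParams(gamma_learn=g, epsilon=e)
        try:
            nets = train_ensemble(
                n_neurons, n_mappings, params, n_networks, derive_seed(seed, 11, j)
            )
            cap = capacity(
                nets, gamma_r=gamma_r, theta=theta, n_inits=n_inits, dyn=dyn,
                M=min(M, n_mappings),
            )
            sds = [
                spontaneous_stats(net, M=min(M, n_mappings), dyn=dyn).average_sd
                for net in nets
            ]
            avg_sd = float(np.mean(sds))
            points.append(
                PhasePoint(
                    gamma_learn=g, epsilon=e, capacity=float(cap.capacity),
                    average_sd=avg_sd, regime=classify_regime(cap.capacity, avg_sd),
                )
            )
        except LearningConvergenceError as err:
            logger.warning("phase point (%g, %g) failed: %s", g, e, err)
            points.append(
                PhasePoint(
                    gamma_learn=g, epsilon=e, capacity=float("nan"),
                    average_sd=float("nan"), regime="NR", failed=True,
                )
            )
    # boundary: capacity near one and locally maximal SD among same-gamma points
    by_gamma: dict[float, list[int]] = {}
    for idx, p in enumerate(points):
        by_gamma.setdefault(p.gamma_learn, []).append(idx)
    out = list(points)
    for g, idxs in by_gamma.items():
        sds = [points[i].average_sd for i in idxs]
        best = np.nanmax(sds) if np.any(np.isfinite(sds)) else np.nan
        for i in idxs:
            p = points[i]
            if (
                not p.failed
                and 0.5 < p.capacity <= 1.5
                and np.isfinite(best)
                and p.average_sd >= best - 1e-12
            ):
                out[i] = PhasePoint(
                    gamma_learn=p.gamma_learn, epsilon=p.epsilon,
                    capacity=p.capacity, average_sd=p.average_sd,
                    regime="boundary",
                )
    return out


@dataclass(frozen=True)
class ScalingResult:
    """Capacity versus network size with a through-origin linear fit."""

    n_values: np.ndarray
    capacities: np.ndarray  # ensemble capacity per N
    slope: float  # capacity ≈ slope * N
    residual: float


def fit_capacity_slope(n_values, capacities) -> tuple[float, float]:
    """Least-squares slope of capacity = a * N through the origin,
    with the RMS residual of the fit."""
    n_arr = np.asarray(n_values, dtype=float)
    c_arr = np.asarray(capacities, dtype=float)
    if n_arr.shape != c_arr.shape or n_arr.size < 2:
        raise ValueError("need matching arrays of at least two sizes")
    slope = float((c_arr @ n_arr) / (n_arr @ n_arr))
    resid = float(np.sqrt(np.mean((c_arr - slope * n_arr) ** 2)))
    return slope, resid


def capacity_scaling(
    n_values,
    params: LearningParams = LearningParams(),
    n_mappings: int = 40,
    n_networks: int = 3,
    seed: int = 0,
    gamma_r: float | None = None,
    theta: float = DEFAULT_THETA,
    n_inits: int = DEFAULT_N_INITS,
    dyn: DynamicsParams = DynamicsParams(),
) -> ScalingResult:
    """Ensemble capacity at each size N and the least-squares slope of
    capacity = a * N through the per-N ensemble means."""
    n_values = sorted(int(n) for n in n_values)
    if len(n_values) < 2:
        raise ValueError("need at least two network sizes")
    caps = []
    for j, N in enumerate(n_values):
        nets = train_ensemble(
            N, n_mappings, params, n_networks, derive_seed(seed, 21, j)
        )
        cap = capacity(
            nets, gamma_r=gamma_r, theta=theta, n_inits=n_inits, dyn=dyn,
            M=min(DEFAULT_ANALYSIS_WINDOW, n_mappings),
        )
        caps.append(float(cap.capacity))
        logger.info("N=%d ensemble capacity %.1f", N, cap.capacity)
    slope, resid = fit_capacity_slope(n_values, caps)
    n_arr = np.asarray(n_values, dtype=float)
    c_arr = np.asarray(caps)
    return ScalingResult(
        n_values=n_arr.astype(int), capacities=c_arr, slope=slope, residual=resid
    )


def load_config(path: str | Path) -> dict:
    """Load a TOML manifest into params objects.

    Recognized sections: ``[learning]`` -> LearningParams, ``[dynamics]``
    -> DynamicsParams, ``[model]`` (n_neurons, n_mappings, n_networks,
    seed), ``[measures]`` (theta, n_inits, M), ``[scan]`` (gamma_grid,
    epsilon_grid or explicit points).  Unknown keys raise.
    """
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    cfg: dict = {}
    if "learning" in raw:
        cfg["learning"] = LearningParams(**raw["learning"])
    if "dynamics" in raw:
        cfg["dynamics"] = DynamicsParams(**raw["dynamics"])
    for sec in ("model", "measures", "scan"):
        if sec in raw:
            cfg[sec] = dict(raw[sec])
    return cfg
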