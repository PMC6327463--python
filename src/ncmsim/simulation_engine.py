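"""Iterative core: sparse vector-matrix relaxation of a knowledge map.

Each iteration multiplies the current state vector through the relationship
matrix (cost proportional to the number of stored edges), squashes the raw
sums into (-1, +1) with a bounded odd activation (Elliott by default), and
re-applies any clamps.  Iteration continues until the mean squared difference
between successive squashed states falls below a tolerance; an optional
post-convergence sweep flags "overtraining" (any later MSE rebound back above
tolerance).

No weights are ever learned: the dynamics relax the *state*, the matrix is
fixed.  A node with no incoming edges and no clamp decays to exactly 0, which
downstream classification treats as "indeterminate".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional

import numpy as np
import yaml

from .knowledge_map import KnowledgeMap

__all__ = [
    "elliott",
    "ACTIVATIONS",
    "SimulationProtocol",
    "SimulationResult",
    "initial_state",
    "step",
    "mse",
    "run",
]


def elliott(x):
    """Elliott squashing function x / (1 + |x|), odd and bounded in (-1, 1)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("elliott() requires finite input")
    out = arr / (1.0 + np.abs(arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _logistic_symmetric(x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation requires finite input")
    out = 2.0 / (1.0 + np.exp(-arr)) - 1.0
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _tanh(x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation requires finite input")
    out = np.tanh(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


ACTIVATIONS: Dict[str, Callable] = {
    "elliott": elliott,
    "logistic-symmetric": _logistic_symmetric,
    "hyperbolic-tangent": _tanh,
}


def _as_label_set(value: Optional[Iterable[str]]) -> FrozenSet[str]:
    if value is None:
        return frozenset()
    if isinstance(value, str):
        return frozenset({value})
    return frozenset(str(v) for v in value)


@dataclass(frozen=True)
class SimulationProtocol:
    """Initial and clamped node assignments plus run-control knobs.

    ``on_nodes``/``off_nodes`` are transient: they set the node to +1/-1 for
    iteration 1 only, after which the dynamics take over.  ``locked_on``/
    ``locked_off`` are clamps re-applied after every activation, so a locked
    node holds exactly +/-1 for the entire run (constitutive overexpression /
    knockout).
    """

    on_nodes: FrozenSet[str] = frozenset()
    off_nodes: FrozenSet[str] = frozenset()
    locked_on: FrozenSet[str] = frozenset()
    locked_off: FrozenSet[str] = frozenset()
    activation: str = "elliott"
    convergence_tolerance: float = 0.001
    max_iterations: int = 1000
    overtraining_check: bool = True
    seed: int = 0  # reserved for stochastic extensions; core run is deterministic

    def __post_init__(self) -> None:
        for name in ("on_nodes", "off_nodes", "locked_on", "locked_off"):
            object.__setattr__(self, name, _as_label_set(getattr(self, name)))
        sets = [self.on_nodes, self.off_nodes, self.locked_on, self.locked_off]
        names = ["on_nodes", "off_nodes", "locked_on", "locked_off"]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(
                        f"{names[a]} and {names[b]} overlap: {sorted(overlap)}"
                    )
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}"
            )
        if not self.convergence_tolerance > 0:
            raise ValueError("convergence_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def validate_against(self, kmap: KnowledgeMap) -> None:
        for name in ("on_nodes", "off_nodes", "locked_on", "locked_off"):
            for label in getattr(self, name):
                if label not in kmap:
                    raise KeyError(f"{name} names unknown concept {label!r}")

    # -- config-file plumbing ----------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationProtocol":
        aliases = {
            "on": "on_nodes",
            "off": "off_nodes",
            "tolerance": "convergence_tolerance",
        }
        kwargs = {}
        for key, value in (data or {}).items():
            kwargs[aliases.get(key, key)] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SimulationProtocol":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: protocol config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "on": sorted(self.on_nodes),
            "off": sorted(self.off_nodes),
            "locked_on": sorted(self.locked_on),
            "locked_off": sorted(self.locked_off),
            "activation": self.activation,
            "tolerance": self.convergence_tolerance,
            "max_iterations": self.max_iterations,
            "overtraining_check": self.overtraining_check,
            "seed": self.seed,
        }


@dataclass
class SimulationResult:
    final_state: np.ndarray
    iterations_to_converge: Optional[int]
    mse_trajectory: List[float]
    converged: bool
    overtraining_detected: bool
    labels: List[str] = field(default_factory=list)

    def state_by_label(self) -> Dict[str, float]:
        return dict(zip(self.labels, self.final_state.tolist()))


def initial_state(kmap: KnowledgeMap, protocol: SimulationProtocol) -> np.ndarray:
    """All zeros except +1 for on/locked-on and -1 for off/locked-off nodes."""
    protocol.validate_against(kmap)
    x = np.zeros(kmap.n_nodes, dtype=float)
    for label in protocol.on_nodes | protocol.locked_on:
        x[kmap.index(label)] = 1.0
    for label in protocol.off_nodes | protocol.locked_off:
        x[kmap.index(label)] = -1.0
    return x


def _clamp_indices(kmap: KnowledgeMap, protocol: SimulationProtocol):
    on = np.array(sorted(kmap.index(l) for l in protocol.locked_on), dtype=int)
    off = np.array(sorted(kmap.index(l) for l in protocol.locked_off), dtype=int)
    return on, off


def step(
    state: np.ndarray,
    kmap: KnowledgeMap,
    protocol: SimulationProtocol,
    matrix=None,
) -> np.ndarray:
    """One iteration: sparse VMM, activation, then clamps.  Input untouched.

    raw_j = sum_i W[i][j] * state_i, i.e. each node sums its weighted inputs.
    ``matrix`` may carry a prebuilt CSR weight matrix to avoid rebuilding it
    every call (run() does this).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (kmap.n_nodes,):
        raise ValueError(
            f"state length {state.shape} does not match map size {kmap.n_nodes}"
        )
    if matrix is None:
        matrix = kmap.weight_matrix()  # raises if indeterminate edges remain
    raw = state @ matrix
    new = ACTIVATIONS[protocol.activation](raw)
    on_idx, off_idx = _clamp_indices(kmap, protocol)
    if on_idx.size:
        new[on_idx] = 1.0
    if off_idx.size:
        new[off_idx] = -1.0
    return new


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference (1/N) * sum_j (a_j - b_j)^2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("MSE undefined for empty vectors")
    d = a - b
    return float(np.dot(d, d) / a.size)


def run(kmap: KnowledgeMap, protocol: SimulationProtocol) -> SimulationResult:
    """Iterate to steady state; MSE compares successive squashed states.

    Convergence is declared at the first iteration whose MSE drops below the
    tolerance; ``final_state`` is the state at that iteration.  When
    ``overtraining_check`` is on, iteration continues to ``max_iterations``
    and any later MSE at or above tolerance raises ``overtraining_detected``.
    """
    fuzzy = kmap.to_fuzzy() if kmap.has_indeterminate else kmap
    protocol.validate_against(fuzzy)
    matrix = fuzzy.weight_matrix()
    tol = protocol.convergence_tolerance

    x = initial_state(fuzzy, protocol)
    trajectory: List[float] = []
    converged_at: Optional[int] = None
    final: Optional[np.ndarray] = None
    overtrained = False

    for t in range(1, protocol.max_iterations + 1):
        x_new = step(x, fuzzy, protocol, matrix=matrix)
        m = mse(x_new, x) if x.size else 0.0
        trajectory.append(m)
        x = x_new
        if converged_at is None:
            if m < tol:
                converged_at = t
                final = x.copy()
                if not protocol.overtraining_check:
                    break
        elif m >= tol:
            overtrained = True

    if final is None:
        final = x.copy()

    return SimulationResult(
        final_state=final,
        iterations_to_converge=converged_at,
        mse_trajectory=trajectory,
        converged=converged_at is not None,
        overtraining_detected=overtrained,
        labels=list(fuzzy.labels),
    )
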