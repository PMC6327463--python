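"""Synthetic knowledge maps for testing: random maps with a prescribed shape,
maps with analytically known attractors, and a small hand-wired stem-cell toy.

The real curated relationship database these tools emulate is not public; the
generators here only reproduce its *reported shape* (node count, mean degree,
positive-edge bias) and provide fixtures whose steady states are known in
closed form, so the engine and the statistics can be tested end to end with
no external data.  The toy stem-cell wiring is openly fictional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .knowledge_map import INDETERMINATE, KnowledgeMap, NeutrosophicWeight, save_map
from .simulation_engine import SimulationProtocol

__all__ = [
    "GeneratorSpec",
    "generate_random_map",
    "PlantedAttractor",
    "generate_planted_attractor_map",
    "ToyFixture",
    "toy_stemcell_fixture",
    "write_fixture_files",
]

#: Mean degree of the emulated database: 27,566 edges over 3,589 nodes.
PAPER_SCALE_MEAN_DEGREE = 27566 / 3589


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape parameters for a random map: size, density, sign bias, seed."""

    n_nodes: int
    mean_degree: float = PAPER_SCALE_MEAN_DEGREE
    positive_fraction: float = 0.66
    indeterminate_fraction: float = 0.0
    weight_magnitude_range: Tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 < self.mean_degree <= self.n_nodes:
            raise ValueError("need 0 < mean_degree <= n_nodes")
        for name in ("positive_fraction", "indeterminate_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.weight_magnitude_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("weight_magnitude_range must satisfy 0 < lo <= hi <= 1")

    @property
    def n_edges(self) -> int:
        return int(round(self.n_nodes * self.mean_degree))


def generate_random_map(spec: GeneratorSpec) -> KnowledgeMap:
    """Uniform-random directed edges, exact edge count, reproducible from seed.

    Each edge is positive with probability ``positive_fraction`` (negative
    otherwise), with magnitude drawn from ``weight_magnitude_range``; a
    fraction of edges is then replaced by the indeterminate value.  Duplicate
    draws are redrawn so the edge count is exact.
    """
    n = spec.n_nodes
    m = spec.n_edges
    if m > n * n:
        raise ValueError(f"cannot place {m} distinct edges in a {n}x{n} matrix")
    rng = np.random.default_rng(spec.seed)

    chosen: set[int] = set()
    while len(chosen) < m:
        draw = rng.integers(0, n * n, size=m - len(chosen))
        chosen.update(int(c) for c in draw)
    cells = sorted(chosen)

    signs = np.where(rng.random(m) < spec.positive_fraction, 1.0, -1.0)
    lo, hi = spec.weight_magnitude_range
    mags = np.full(m, lo) if lo == hi else rng.uniform(lo, hi, size=m)
    indet = rng.random(m) < spec.indeterminate_fraction

    labels = [f"G{i:04d}" for i in range(n)]
    edges: Dict[Tuple[int, int], NeutrosophicWeight] = {}
    for cell, sign, mag, is_indet in zip(cells, signs, mags, indet):
        key = (cell // n, cell % n)
        edges[key] = (
            INDETERMINATE if is_indet else NeutrosophicWeight(float(sign * mag))
        )
    return KnowledgeMap(labels=labels, edges=edges)


@dataclass(frozen=True)
class PlantedAttractor:
    """A map whose steady state is known in closed form, plus how to run it."""

    kmap: KnowledgeMap
    protocol: SimulationProtocol
    expected_state: np.ndarray


def generate_planted_attractor_map(
    n_nodes: int, loop_gain: float, seed: int = 0
) -> PlantedAttractor:
    """Plant a node whose steady value is (g - 1)/g for effective gain g.

    Locked driver nodes supply a constant total input a = g - 1 (split into
    unit-or-smaller weights so no single edge exceeds 1) to a target node.
    Its fixed point under Elliott squashing solves x = a/(1 + a), which is
    exactly x* = (g - 1)/g and satisfies x = g*x/(1 + g*x).  Remaining nodes
    get no incoming edges and settle at exactly 0.
    """
    if loop_gain < 1.0:
        raise ValueError("loop_gain must be >= 1")
    a = loop_gain - 1.0
    n_drivers = max(1, math.ceil(a)) if a > 0 else 0
    if n_nodes < 1 + n_drivers:
        raise ValueError(
            f"gain {loop_gain} needs {n_drivers} driver nodes; n_nodes={n_nodes} too small"
        )
    labels = ["TARGET"]
    labels += [f"DRIVER{i}" for i in range(n_drivers)]
    labels += [f"FILLER{i}" for i in range(n_nodes - 1 - n_drivers)]
    kmap = KnowledgeMap(labels=labels)
    if n_drivers:
        w = a / n_drivers
        for i in range(n_drivers):
            kmap.add_edge(f"DRIVER{i}", "TARGET", w)
    protocol = SimulationProtocol(
        locked_on=frozenset(f"DRIVER{i}" for i in range(n_drivers))
    )
    expected = np.zeros(n_nodes)
    expected[0] = (loop_gain - 1.0) / loop_gain
    expected[1 : 1 + n_drivers] = 1.0
    return PlantedAttractor(kmap=kmap, protocol=protocol, expected_state=expected)


# ---------------------------------------------------------------------------
# Toy stem-cell fixture.  ~40 nodes; wiring is FICTIONAL and exists only to
# exercise protocol mechanics (reprogramming-factor activation, knockout via
# a locked-off node, up/down panels) at a scale where every steady value can
# be predicted by hand.
# ---------------------------------------------------------------------------

_CORE = ["OCT3/4", "SOX2", "KLF4", "CMYC"]

# 15 pluripotency-panel markers (the four core factors drive the other 13).
_PLURI_TARGETS = [
    "NANOG", "GDF3", "REX1", "FGF4", "ESG1", "DPPA2", "DPPA4", "hTERT",
    "SALL4", "SSEA-3", "SSEA-4", "TRA-1-81", "ALP",
]
_PLURI_PANEL = ["OCT3/4", "SOX2"] + _PLURI_TARGETS

# Rett-style panel: driven purely by the MECP2 knockout node.
_RETT_UP = ["BDNF", "FKBP5", "IGF2", "DLX5", "DLX6", "SGK1", "MPP1", "GAMT", "FXYD1"]
_RETT_DOWN = ["UBE3A", "GRID1"]

_NSC_MARKERS = ["PAX6", "NESTIN", "VIMENTIN"]
_EXTRAS = ["LET7", "MECP2", "TUBB3", "MAP2", "GFAP", "AFP", "BRACHYURY"]


@dataclass(frozen=True)
class ToyFixture:
    kmap: KnowledgeMap
    protocols: Mapping[str, SimulationProtocol]
    panels: Mapping[str, Mapping[str, str]]


def toy_stemcell_fixture() -> ToyFixture:
    """Hand-wired ~40-node map with two runnable experiment designs.

    * ``oskm``: the four core factors are transiently turned on; their mutual
      all-to-all positive wiring is self-sustaining (symmetric fixed point
      x = 3x/(1 + 3x) = 2/3), so all 15 pluripotency-panel nodes end positive.
    * ``rett``: MECP2 is locked off (-1); it represses the nine up-panel genes
      (weight -1, so they settle at +0.5) and activates the two down-panel
      genes (weight +1, settling at -0.5).
    """
    labels = (
        _CORE + _PLURI_TARGETS + _NSC_MARKERS + _EXTRAS + _RETT_UP + _RETT_DOWN
    )
    kmap = KnowledgeMap(labels=labels)

    # self-sustaining reprogramming core: complete digraph on the 4 factors
    for src in _CORE:
        for dst in _CORE:
            if src != dst:
                kmap.add_edge(src, dst, 1.0)
    # core drives the 13 downstream pluripotency markers
    for dst in _PLURI_TARGETS:
        kmap.add_edge("OCT3/4", dst, 1.0)
        kmap.add_edge("SOX2", dst, 1.0)
    # neural wiring (illustrative; decays without a sustained driver)
    for dst in _NSC_MARKERS:
        kmap.add_edge("SOX2", dst, 1.0)
    kmap.add_edge("LET7", "SOX2", -1.0)
    # knockout wiring: MECP2 represses the Rett up-panel, activates the down-panel
    for dst in _RETT_UP:
        kmap.add_edge("MECP2", dst, -1.0)
    for dst in _RETT_DOWN:
        kmap.add_edge("MECP2", dst, 1.0)

    protocols = {
        "oskm": SimulationProtocol(on_nodes=frozenset(_CORE)),
        "rett": SimulationProtocol(
            on_nodes=frozenset({"SOX2"}),
            off_nodes=frozenset({"LET7"}),
            locked_off=frozenset({"MECP2"}),
        ),
    }
    panels = {
        "pluripotency": {label: "up" for label in _PLURI_PANEL},
        "rett": {**{label: "up" for label in _RETT_UP},
                 **{label: "down" for label in _RETT_DOWN}},
    }
    return ToyFixture(kmap=kmap, protocols=protocols, panels=panels)


def write_fixture_files(directory) -> List[str]:
    """Emit the toy fixture as CSV/YAML files; returns the paths written."""
    import os

    import yaml

    fixture = toy_stemcell_fixture()
    os.makedirs(directory, exist_ok=True)
    written = []

    map_path = os.path.join(directory, "toy_stemcell_map.csv")
    save_map(
        fixture.kmap,
        map_path,
        header_comment=(
            "FICTIONAL toy wiring for testing protocol mechanics only; "
            "not a curated biological network."
        ),
    )
    written.append(map_path)

    for name, protocol in fixture.protocols.items():
        path = os.path.join(directory, f"protocol_{name}.yaml")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)
        written.append(path)

    for name, panel in fixture.panels.items():
        path = os.path.join(directory, f"panel_{name}.csv")
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("label,expected\n")
            for label, expected in panel.items():
                fh.write(f"{label},{expected}\n")
        written.append(path)
    return written
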