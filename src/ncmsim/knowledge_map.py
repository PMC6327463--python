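"""Neutrosophic knowledge maps: data model, CSV I/O, and descriptive statistics.

A knowledge map is a labelled, sparse, directed, signed graph over N concepts
(genes, proteins, miRNAs, phenotypes).  Edge weights are real causal strengths
in [-1, +1], or *indeterminate* ("I") when a relationship is known to exist but
its sign/strength is not.  The map is equivalently an NxN relationship matrix
whose cell [i][j] holds the effect of concept i ON concept j; cells that are
zero or empty mean "no known relationship" and are never stored.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse

__all__ = [
    "NeutrosophicWeight",
    "INDETERMINATE",
    "ConceptNode",
    "KnowledgeMap",
    "MapStatistics",
    "MapFormatError",
    "load_map",
    "save_map",
    "to_fuzzy",
    "compute_statistics",
]


class MapFormatError(ValueError):
    """Raised for structural or lexical problems in a relationship-matrix CSV."""


@dataclass(frozen=True)
class NeutrosophicWeight:
    """One relationship value: a real causal strength in [-1, +1], or indeterminate.

    ``value is None`` encodes the indeterminate ("I") relationship.  Zero is
    reserved for "no known relationship" and is not a representable weight:
    absent edges are simply not stored.
    """

    value: Optional[float]

    def __post_init__(self) -> None:
        if self.value is not None:
            v = float(self.value)
            if not math.isfinite(v):
                raise ValueError(f"weight must be finite, got {self.value!r}")
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"weight must lie in [-1, +1], got {v!r}")
            if v == 0.0:
                raise ValueError(
                    "weight 0 means 'no relationship' and cannot be stored as an edge"
                )
            object.__setattr__(self, "value", v)

    @property
    def indeterminate(self) -> bool:
        return self.value is None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "I" if self.indeterminate else f"{self.value:g}"


#: Shared singleton for the indeterminate relationship.
INDETERMINATE = NeutrosophicWeight(None)

WeightLike = Union[NeutrosophicWeight, float, int, str]


def _as_weight(w: WeightLike) -> NeutrosophicWeight:
    if isinstance(w, NeutrosophicWeight):
        return w
    if isinstance(w, str):
        if w.strip().upper() == "I":
            return INDETERMINATE
        raise ValueError(f"cannot interpret {w!r} as a weight")
    return NeutrosophicWeight(float(w))


@dataclass(frozen=True)
class ConceptNode:
    """A named concept at a fixed 0-based position in the map's node order."""

    index: int
    label: str


@dataclass
class KnowledgeMap:
    """N labelled concepts plus a sparse mapping (source, target) -> weight."""

    labels: List[str] = field(default_factory=list)
    edges: Dict[Tuple[int, int], NeutrosophicWeight] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(lbl).strip() for lbl in self.labels]
        seen = set()
        for lbl in self.labels:
            if lbl in seen:
                raise MapFormatError(f"duplicate concept label {lbl!r}")
            seen.add(lbl)
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}
        n = len(self.labels)
        for (i, j), w in list(self.edges.items()):
            if not (0 <= i < n and 0 <= j < n):
                raise MapFormatError(f"edge ({i}, {j}) outside node range [0, {n})")
            self.edges[(i, j)] = _as_weight(w)

    # -- container protocol -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeMap):
            return NotImplemented
        return self.labels == other.labels and self.edges == other.edges

    def nodes(self) -> Iterator[ConceptNode]:
        for i, lbl in enumerate(self.labels):
            yield ConceptNode(i, lbl)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown concept label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def add_edge(self, source: str, target: str, weight: WeightLike) -> None:
        self.edges[(self.index(source), self.index(target))] = _as_weight(weight)

    def weight(self, source: str, target: str) -> Optional[NeutrosophicWeight]:
        return self.edges.get((self.index(source), self.index(target)))

    # -- derived forms ------------------------------------------------------

    @property
    def has_indeterminate(self) -> bool:
        return any(w.indeterminate for w in self.edges.values())

    def to_fuzzy(self) -> "KnowledgeMap":
        """Return a copy with every indeterminate edge dropped (weight -> 0)."""
        return KnowledgeMap(
            labels=list(self.labels),
            edges={k: w for k, w in self.edges.items() if not w.indeterminate},
        )

    def weight_matrix(self) -> sparse.csr_array:
        """The NxN matrix W with W[i, j] = weight of edge i -> j, as CSR.

        Raises if any edge is still indeterminate; call :meth:`to_fuzzy` first.
        """
        if self.has_indeterminate:
            raise ValueError(
                "map contains indeterminate edges; apply to_fuzzy() before "
                "building the numeric weight matrix"
            )
        n = self.n_nodes
        if not self.edges:
            return sparse.csr_array((n, n), dtype=float)
        rows, cols, vals = zip(
            *((i, j, w.value) for (i, j), w in self.edges.items())
        )
        return sparse.csr_array(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )


def to_fuzzy(kmap: KnowledgeMap) -> KnowledgeMap:
    """Functional alias for :meth:`KnowledgeMap.to_fuzzy`."""
    return kmap.to_fuzzy()


# ---------------------------------------------------------------------------
# CSV dialect: first row / first column carry concept labels; body cell (i, j)
# holds the weight of edge (row concept i -> column concept j).  Empty, blank
# and literal-zero cells mean "no edge"; the token "I" (case-insensitive,
# trimmed) means indeterminate.  RFC-4180 quoting for labels with commas.
# ---------------------------------------------------------------------------


def load_map(path) -> KnowledgeMap:
    """Read a relationship-matrix CSV into a :class:`KnowledgeMap`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh)]
    # ignore comment lines (fixture files carry provenance headers)
    rows = [r for r in rows if not (r and r[0].lstrip().startswith("#"))]
    if not rows:
        raise MapFormatError(f"{path}: empty file, expected a header row")
    header = rows[0]
    labels = [c.strip() for c in header[1:]]
    n = len(labels)
    body = rows[1:]
    if len(body) != n:
        raise MapFormatError(
            f"{path}: non-square matrix: {n} header columns but {len(body)} body rows"
        )
    edges: Dict[Tuple[int, int], NeutrosophicWeight] = {}
    for i, row in enumerate(body):
        if len(row) != n + 1:
            raise MapFormatError(
                f"{path}: row {i + 2} has {len(row)} cells, expected {n + 1} "
                f"(label + {n} weights)"
            )
        row_label = row[0].strip()
        if row_label != labels[i]:
            raise MapFormatError(
                f"{path}: row label {row_label!r} at position {i} does not match "
                f"header label {labels[i]!r}"
            )
        for j, raw in enumerate(row[1:]):
            token = raw.strip()
            if token == "" or token == "0":
                continue
            if token.upper() == "I":
                edges[(i, j)] = INDETERMINATE
                continue
            try:
                value = float(token)
            except ValueError:
                raise MapFormatError(
                    f"{path}: unparseable cell at row {labels[i]!r}, "
                    f"column {labels[j]!r}: {raw!r}"
                ) from None
            if value == 0.0:
                continue
            try:
                edges[(i, j)] = NeutrosophicWeight(value)
            except ValueError as exc:
                raise MapFormatError(
                    f"{path}: invalid weight at row {labels[i]!r}, "
                    f"column {labels[j]!r}: {exc}"
                ) from None
    return KnowledgeMap(labels=labels, edges=edges)


def save_map(kmap: KnowledgeMap, path, header_comment: Optional[str] = None) -> None:
    """Write *kmap* in the dialect :func:`load_map` reads.

    Numeric weights use ``repr`` so a round-trip reproduces them exactly.
    """
    n = kmap.n_nodes
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow([""] + kmap.labels)
        for i in range(n):
            cells: List[str] = [kmap.labels[i]]
            for j in range(n):
                w = kmap.edges.get((i, j))
                if w is None:
                    cells.append("0")
                elif w.indeterminate:
                    cells.append("I")
                else:
                    cells.append(repr(w.value))
            writer.writerow(cells)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapStatistics:
    """Node/edge counts, mean degrees and the sign bias of a map.

    ``positive_fraction``/``negative_fraction`` are computed over determinate
    nonzero edges only and double as the pretest probabilities (p+, p-) of the
    validation null.  Undefined quantities (empty map, no determinate edges)
    are reported as NaN.
    """

    n_nodes: int
    n_edges: int
    mean_in_degree: float
    mean_out_degree: float
    positive_fraction: float
    negative_fraction: float
    indeterminate_count: int


def compute_statistics(kmap: KnowledgeMap) -> MapStatistics:
    n_nodes = kmap.n_nodes
    n_edges = kmap.n_edges
    n_indet = sum(1 for w in kmap.edges.values() if w.indeterminate)
    n_pos = sum(1 for w in kmap.edges.values() if not w.indeterminate and w.value > 0)
    n_det = n_edges - n_indet
    mean_deg = n_edges / n_nodes if n_nodes else math.nan
    pos_frac = n_pos / n_det if n_det else math.nan
    neg_frac = 1.0 - pos_frac if n_det else math.nan
    return MapStatistics(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_in_degree=mean_deg,
        mean_out_degree=mean_deg,
        positive_fraction=pos_frac,
        negative_fraction=neg_frac,
        indeterminate_count=n_indet,
    )
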