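import numpy as np
import pytest

from ncmsim.knowledge_map import INDETERMINATE, KnowledgeMap, NeutrosophicWeight


def make_random_map(rng: np.random.Generator, n_max: int = 12,
                    indet_prob: float = 0.15) -> KnowledgeMap:
    """Arbitrary small map for round-trip / oracle tests (test-local generator,
    independent of the package's synthetic_fixtures module)."""
    n = int(rng.integers(0, n_max + 1))
    labels = []
    for i in range(n):
        label = f"node-{i}"
        style = rng.integers(0, 4)
        if style == 1:
            label = f"gene {i}, variant"  # comma forces RFC-4180 quoting
        elif style == 2:
            label = f"miR-{i}-5p"
        elif style == 3:
            label = f'G"{i}"'
        labels.append(label)
    edges = {}
    for i in range(n):
        for j in range(n):
            r = rng.random()
            if r < 0.25:
                if rng.random() < indet_prob:
                    edges[(i, j)] = INDETERMINATE
                else:
                    mag = float(rng.uniform(1e-6, 1.0))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    edges[(i, j)] = NeutrosophicWeight(sign * mag)
    return KnowledgeMap(labels=labels, edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def abc_map():
    """The 3-node example map: A->B=+1, B->C=-0.5, C->A=I."""
    return KnowledgeMap(
        labels=["A", "B", "C"],
        edges={(0, 1): NeutrosophicWeight(1.0),
               (1, 2): NeutrosophicWeight(-0.5),
               (2, 0): INDETERMINATE},
    )
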