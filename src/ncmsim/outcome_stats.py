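"""Expression calls from converged states, scored with an exact binomial test.

Converged node values are classified by sign: > 0 expressed/upregulated,
< 0 repressed/downregulated, exactly 0 indeterminate (excluded from scoring).
Agreement with an expected-outcome panel is tested against a *biased* null:
the per-trial success probability is the network's fraction of positive edges
(p+, the pretest probability of a positive prediction), not 1/2.

Three exact modes are provided:

* ``all_success`` - P(all n trials succeed) = p^n; requires k = n.
* ``point_mass``  - P(exactly k successes) = C(n, k) p^k (1-p)^(n-k).
* ``upper_tail``  - P(at least k successes), the conventional one-sided test.

All are computed with exact integer binomial coefficients - no normal
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .knowledge_map import KnowledgeMap, compute_statistics

__all__ = [
    "ExpressionCall",
    "ValidationReport",
    "classify",
    "pretest_probabilities",
    "binomial_pvalue",
    "evaluate",
    "EXPRESSED",
    "REPRESSED",
    "INDETERMINATE_CALL",
]

EXPRESSED = "expressed"
REPRESSED = "repressed"
INDETERMINATE_CALL = "indeterminate"

_MODES = ("all_success", "point_mass", "upper_tail")


@dataclass(frozen=True)
class ExpressionCall:
    label: str
    call: str
    value: float


def classify(state: Sequence[float], kmap: KnowledgeMap) -> List[ExpressionCall]:
    """One sign-based call per node: > 0 expressed, < 0 repressed, 0 indeterminate."""
    values = np.asarray(state, dtype=float)
    if values.shape != (kmap.n_nodes,):
        raise ValueError(
            f"state length {values.shape} does not match map size {kmap.n_nodes}"
        )
    calls = []
    for label, v in zip(kmap.labels, values.tolist()):
        if v > 0:
            call = EXPRESSED
        elif v < 0:
            call = REPRESSED
        else:
            call = INDETERMINATE_CALL
        calls.append(ExpressionCall(label, call, v))
    return calls


def pretest_probabilities(kmap: KnowledgeMap) -> Tuple[float, float]:
    """(p+, p-): fractions of positive/negative determinate edges in the map."""
    stats = compute_statistics(kmap)
    if math.isnan(stats.positive_fraction):
        raise ValueError(
            "pretest probabilities undefined: map has no determinate nonzero edges"
        )
    return stats.positive_fraction, stats.negative_fraction


def binomial_pvalue(k: int, n: int, p_success: float, mode: str = "upper_tail") -> float:
    """Exact binomial probability of k successes in n trials at bias p_success."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p_success <= 1.0:
        raise ValueError(f"p_success must lie in [0, 1], got {p_success}")
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {_MODES}")
    if n == 0:
        return 1.0
    p = float(p_success)
    q = 1.0 - p
    if mode == "all_success":
        if k != n:
            raise ValueError("all_success mode requires k == n")
        return p**n
    if mode == "point_mass":
        return math.comb(n, k) * p**k * q ** (n - k)
    # upper_tail: exact sum of point masses for j = k .. n
    return min(1.0, math.fsum(math.comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1)))


def _poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact success-count distribution for independent trials with mixed p_i."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


_UP = {"up", "+", "+1", "1", "expressed", "upregulated"}
_DOWN = {"down", "-", "-1", "repressed", "downregulated"}


def _expected_sign(raw: Union[str, int, float]) -> int:
    if isinstance(raw, str):
        token = raw.strip().lower()
        if token in _UP:
            return +1
        if token in _DOWN:
            return -1
        raise ValueError(f"cannot interpret expected outcome {raw!r} (use up/down)")
    value = float(raw)
    if value > 0:
        return +1
    if value < 0:
        return -1
    raise ValueError("expected outcome must be nonzero")


@dataclass
class ValidationReport:
    """Per-node agreement with an expected panel plus the biased binomial test."""

    n_evaluated: int
    n_correct: int
    n_indeterminate_excluded: int
    pretest_positive: float
    pretest_negative: float
    p_value: float
    test_mode: str
    per_node: List[Tuple[str, str, str, bool]] = field(default_factory=list)

    @property
    def agreement_percent(self) -> float:
        """100 * k / n, the headline accuracy of the panel."""
        if self.n_evaluated == 0:
            return math.nan
        return 100.0 * self.n_correct / self.n_evaluated

    def rounded_p(self, sig_figs: int = 2) -> float:
        if self.p_value == 0:
            return 0.0
        exponent = math.floor(math.log10(abs(self.p_value)))
        return round(self.p_value, -exponent + sig_figs - 1)

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_correct": self.n_correct,
            "n_indeterminate_excluded": self.n_indeterminate_excluded,
            "agreement_percent": None
            if math.isnan(self.agreement_percent)
            else self.agreement_percent,
            "pretest_positive": self.pretest_positive,
            "pretest_negative": self.pretest_negative,
            "p_value": self.p_value,
            "test_mode": self.test_mode,
            "per_node": [
                {"label": lbl, "expected": exp, "predicted": pred, "agree": ok}
                for (lbl, exp, pred, ok) in self.per_node
            ],
        }


def evaluate(
    calls: Sequence[ExpressionCall],
    expected: Mapping[str, Union[str, int, float]],
    kmap: Optional[KnowledgeMap] = None,
    mode: Optional[str] = None,
    pretest: Optional[Tuple[float, float]] = None,
    uniform_null: bool = True,
) -> ValidationReport:
    """Score predicted calls against an expected up/down panel.

    ``pretest`` overrides the map-derived (p+, p-) - e.g. (0.66, 0.34).  With
    ``uniform_null`` (default) every trial uses p+ as its chance-success
    probability regardless of expected sign; the stricter alternative uses p+
    for expected-up and p- for expected-down trials (a Poisson-binomial null
    when the panel mixes signs).  ``mode=None`` selects ``all_success`` when
    every evaluated prediction agrees, otherwise ``point_mass``.
    """
    if pretest is None:
        if kmap is None:
            raise ValueError("need either a map or explicit pretest probabilities")
        pretest = pretest_probabilities(kmap)
    p_plus, p_minus = pretest
    if not math.isclose(p_plus + p_minus, 1.0, abs_tol=1e-9):
        raise ValueError("pretest probabilities must sum to 1")

    by_label = {c.label: c for c in calls}
    known = set(by_label)
    if kmap is not None:
        known |= set(kmap.labels)
    per_node: List[Tuple[str, str, str, bool]] = []
    trial_probs: List[float] = []
    n = k = excluded = 0
    for label, raw_expected in expected.items():
        if label not in known:
            raise KeyError(f"expected panel names unknown concept {label!r}")
        sign = _expected_sign(raw_expected)
        expected_name = "up" if sign > 0 else "down"
        call = by_label.get(label)
        predicted = call.call if call is not None else INDETERMINATE_CALL
        if predicted == INDETERMINATE_CALL:
            excluded += 1
            per_node.append((label, expected_name, predicted, False))
            continue
        agree = (sign > 0) == (predicted == EXPRESSED)
        n += 1
        k += int(agree)
        trial_probs.append(p_plus if (uniform_null or sign > 0) else p_minus)
        per_node.append((label, expected_name, predicted, agree))

    if mode is None:
        mode = "all_success" if k == n else "point_mass"

    if n == 0:
        p_value = 1.0
    elif uniform_null or len(set(trial_probs)) == 1:
        p_value = binomial_pvalue(k, n, trial_probs[0], mode=mode)
    else:
        pmf = _poisson_binomial_pmf(trial_probs)
        if mode == "all_success":
            if k != n:
                raise ValueError("all_success mode requires k == n")
            p_value = float(pmf[n])
        elif mode == "point_mass":
            p_value = float(pmf[k])
        else:
            p_value = float(min(1.0, pmf[k:].sum()))

    return ValidationReport(
        n_evaluated=n,
        n_correct=k,
        n_indeterminate_excluded=excluded,
        pretest_positive=p_plus,
        pretest_negative=p_minus,
        p_value=p_value,
        test_mode=mode,
        per_node=per_node,
    )
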