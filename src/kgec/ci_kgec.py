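"""Contribution-index (CI) scoring and key-group selection.

Each active component i that hits at least one effective protein contributes
a set λ_i of effective proteins (its targets within the optimization space).
With ω_i = total predicted target count of the component, ν_i = |λ_i|, and
W = number of effective proteins, the contribution index of a component is
CI_i = ν_i / W.

Two selection views are provided:

* the literal dynamic 0-1 knapsack over (values ν_i, weights ω_i, capacity
  W), which maximizes the summed coverage counts of a component subset, and
* a cumulative union-coverage curve (components ordered by CI descending, or
  greedily by marginal set cover), whose value after j components is
  |λ_(1) ∪ ... ∪ λ_(j)| / W.

The key group of effective components (KGEC) is the shortest prefix of the
curve reaching a coverage threshold (default 90%).  The accumulation view is
the default because overlapping target sets make summed ν_i overstate true
coverage; the knapsack value is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .components import CTNetwork

__all__ = [
    "CIInput",
    "component_ci",
    "KnapsackResult",
    "knapsack_select",
    "accumulation_curve",
    "select_kgec",
    "CIResult",
    "run_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CIInput:
    """Per-component effective-target sets and sizes.

    ``lambda_sets`` maps component id -> set of effective proteins it
    targets (λ_i, non-empty); ``omega`` maps id -> total predicted target
    count (ω_i >= ν_i); ``n_effective`` is W.
    """

    lambda_sets: dict[str, frozenset[str]]
    omega: dict[str, int]
    n_effective: int

    def __post_init__(self):
        if self.n_effective < 1:
            raise ValueError("W (number of effective proteins) must be >= 1")
        if not self.lambda_sets:
            raise ValueError("no components associated with effective proteins")
        for comp, lam in self.lambda_sets.items():
            nu = len(lam)
            om = self.omega.get(comp)
            if om is None:
                raise ValueError(f"component {comp!r} missing from omega")
            if not (0 <= nu <= om):
                raise ValueError(f"component {comp!r}: ν={nu} exceeds ω={om}")
            if nu > self.n_effective:
                raise ValueError(f"component {comp!r}: ν={nu} exceeds W")

    @property
    def m(self) -> int:
        return len(self.lambda_sets)

    @property
    def component_ids(self) -> list[str]:
        return sorted(self.lambda_sets)

    def nu(self, comp: str) -> int:
        return len(self.lambda_sets[comp])

    @classmethod
    def from_networks(cls, ct: CTNetwork, effective: Sequence[str] | set,
                      ) -> "CIInput":
        """Build from a C-T network and the effective-protein set.

        Components whose targets miss the effective proteins entirely are
        excluded (they cannot contribute coverage).
        """
        eff = frozenset(effective)
        if not eff:
            raise ValueError("empty effective-protein set")
        lam: dict[str, frozenset[str]] = {}
        omega: dict[str, int] = {}
        for comp, tset in ct.target_sets().items():
            inter = tset & eff
            if inter:
                lam[comp] = frozenset(inter)
                omega[comp] = len(tset)
        return cls(lambda_sets=lam, omega=omega, n_effective=len(eff))


def component_ci(inp: CIInput) -> pd.DataFrame:
    """Per-component CI table, ranked by CI descending (ties by id)."""
    rows = [
        (comp, inp.nu(comp), inp.omega[comp], inp.nu(comp) / inp.n_effective)
        for comp in inp.component_ids
    ]
    df = pd.DataFrame(rows, columns=["component", "nu", "omega", "ci"])
    df = df.sort_values(["ci", "component"], ascending=[False, True],
                        ignore_index=True)
    df["ci_percent"] = (df["ci"] * 100).round(2)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass(frozen=True)
class KnapsackResult:
    value: int
    subset: tuple[str, ...]
    capacity: int


def knapsack_01(values: Sequence[int], weights: Sequence[int],
                capacity: int) -> tuple[int, tuple[int, ...]]:
    """Standard dynamic 0-1 knapsack over non-negative integer instances.

    The DP is the recurrence c[i, w] = max(c[i-1, w], v_i + c[i-1, w-w_i])
    with c[0, ·] = c[·, 0] = 0.  Returns the optimum c[m, capacity] and the
    indices of one optimal subset, reconstructed by backtracking (on a tie
    the item is left out, which is deterministic).
    """
    if capacity < 0:
        raise ValueError("capacity must be non-negative")
    values = np.asarray(values, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.int64)
    if (values < 0).any() or (weights < 0).any():
        raise ValueError("negative knapsack value or weight")

    m = len(values)
    c = np.zeros((m + 1, capacity + 1), dtype=np.int64)
    for i in range(1, m + 1):
        wi, vi = weights[i - 1], values[i - 1]
        c[i] = c[i - 1]
        if wi <= capacity:
            take = c[i - 1, : capacity - wi + 1] + vi
            np.maximum(c[i, wi:], take, out=c[i, wi:])

    picked: list[int] = []
    w = capacity
    for i in range(m, 0, -1):
        if c[i, w] != c[i - 1, w]:
            picked.append(i - 1)
            w -= int(weights[i - 1])
    picked.reverse()
    return int(c[m, capacity]), tuple(picked)


def knapsack_select(inp: CIInput, capacity: int | None = None) -> KnapsackResult:
    """0-1 knapsack over the components: maximize Σν_i with Σω_i <= capacity.

    Capacity defaults to W.  Items are taken in id-ascending order so the
    reconstructed subset is reproducible.
    """
    if capacity is None:
        capacity = inp.n_effective
    ids = inp.component_ids
    value, picked = knapsack_01([inp.nu(c) for c in ids],
                                [inp.omega[c] for c in ids], capacity)
    return KnapsackResult(value=value,
                          subset=tuple(ids[i] for i in picked),
                          capacity=int(capacity))


def accumulation_curve(
    inp: CIInput, order: str = "ci_desc"
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Cumulative union-coverage curve over an ordering of the components.

    ``order="ci_desc"``: components sorted by CI descending (ties by id);
    ``order="greedy_marginal"``: classic greedy maximum coverage, picking at
    each step the component with the largest marginal gain (ties by id).

    Returns (ordered ids, curve of cumulative coverage fractions, per-step
    marginal gains in proteins).
    """
    if order not in ("ci_desc", "greedy_marginal"):
        raise ValueError(f"order must be 'ci_desc' or 'greedy_marginal', got {order!r}")
    W = inp.n_effective
    if order == "ci_desc":
        ordered = sorted(inp.component_ids, key=lambda c: (-inp.nu(c), c))
    else:
        remaining = set(inp.component_ids)
        covered: set[str] = set()
        ordered = []
        while remaining:
            best = min(remaining,
                       key=lambda c: (-len(inp.lambda_sets[c] - covered), c))
            ordered.append(best)
            covered |= inp.lambda_sets[best]
            remaining.remove(best)

    covered = set()
    curve = np.empty(len(ordered))
    marginals = np.empty(len(ordered), dtype=np.int64)
    for j, comp in enumerate(ordered):
        gain = len(inp.lambda_sets[comp] - covered)
        covered |= inp.lambda_sets[comp]
        marginals[j] = gain
        curve[j] = len(covered) / W
    return ordered, curve, marginals


def select_kgec(ordered: Sequence[str], curve: np.ndarray,
                threshold: float = 0.90) -> list[str]:
    """Shortest prefix of the ordering whose coverage reaches the threshold.

    If the threshold is unreachable the full list is returned with a
    warning stating the achieved maximum.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    # curve entries are exact ratios of integers; guard float round-off
    hits = np.nonzero(curve >= threshold - 1e-12)[0]
    if hits.size == 0:
        warnings.warn(
            f"coverage threshold {threshold:.2%} unreachable; maximum "
            f"achievable is {curve[-1]:.2%}; returning all components",
            stacklevel=2,
        )
        return list(ordered)
    return list(ordered[: hits[0] + 1])


@dataclass(frozen=True)
class CIResult:
    """Full CI-model output: ranking, curve, knapsack value and the KGEC."""

    ci_table: pd.DataFrame
    order: list[str]
    curve: np.ndarray
    marginals: np.ndarray
    knapsack: KnapsackResult
    kgec: list[str]
    threshold: float
    order_mode: str
    n_effective: int

    @property
    def coverage_achieved(self) -> float:
        """Union coverage of the selected KGEC (fraction of W)."""
        return float(self.curve[len(self.kgec) - 1]) if self.kgec else 0.0

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, len(self.order) + 1),
            "component": self.order,
            "marginal_gain": self.marginals,
            "cumulative_coverage": self.curve,
        })


def run_ci(inp: CIInput, threshold: float = 0.90,
           order: str = "ci_desc") -> CIResult:
    """Score, rank, knapsack, accumulate and cut: the full CI model."""
    table = component_ci(inp)
    ordered, curve, marginals = accumulation_curve(inp, order=order)
    ks = knapsack_select(inp)
    kgec = select_kgec(ordered, curve, threshold=threshold)
    result = CIResult(ci_table=table, order=ordered, curve=curve,
                      marginals=marginals, knapsack=ks, kgec=kgec,
                      threshold=threshold, order_mode=order,
                      n_effective=inp.n_effective)
    logger.info("KGEC: %d / %d components reach %.2f%% coverage "
                "(threshold %.0f%%, order=%s, knapsack value %d)",
                len(kgec), inp.m, 100 * result.coverage_achieved,
                100 * threshold, order, ks.value)
    return result
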