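"""Hypergeometric over-representation analysis (ORA) and pathway coverage.

Given a query gene set and a GMT collection of pathway gene sets, each
pathway is tested for over-representation with the upper-tail hypergeometric
probability P(X >= k), where the population is the background universe, the
successes are the pathway genes, and the draws are the query genes mapped
into the universe.  Significance follows the conventional raw p < 0.05
criterion, with Benjamini-Hochberg adjustment available.

Pathway coverage — the fraction of one significant-pathway set recovered by
another, |A ∩ B| / |B| — is the validation statistic for the optimization
space and the selected key component group: the pathways enriched in the
selected proteins/targets should recover most pathways enriched in the
pathogenic genes themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from gseapy.parser import read_gmt
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayCollection",
    "ora",
    "significant_pathways",
    "CoverageResult",
    "pathway_coverage",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets plus the background universe.

    The universe defaults to the union of all pathway genes; when an
    explicit universe is supplied, pathway genes outside it are dropped so
    the containment invariant holds.
    """

    gene_sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        for name, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"empty pathway {name!r}")
            if not genes <= self.universe:
                raise ValueError(f"pathway {name!r} not contained in universe")

    @classmethod
    def from_sets(cls, gene_sets: Mapping[str, Iterable[str]],
                  universe: Iterable[str] | None = None) -> "PathwayCollection":
        sets = {name: frozenset(genes) for name, genes in gene_sets.items()}
        if universe is None:
            uni = frozenset().union(*sets.values()) if sets else frozenset()
        else:
            uni = frozenset(universe)
            sets = {n: g & uni for n, g in sets.items()}
            sets = {n: g for n, g in sets.items() if g}
        if not sets:
            raise ValueError("no non-empty pathways")
        return cls(gene_sets=sets, universe=uni)

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "PathwayCollection":
        """Read a standard GMT file (name, description, genes...)."""
        return cls.from_sets(read_gmt(str(path)), universe=universe)

    def __len__(self) -> int:
        return len(self.gene_sets)


def ora(query: Iterable[str], pathways: PathwayCollection,
        alpha: float = 0.05, adjust: str = "none") -> pd.DataFrame:
    """Upper-tail hypergeometric test of a query set against each pathway.

    For a pathway of size n in a universe of size M with q = |query ∩
    universe| draws and overlap k, p = P(X >= k) under Hypergeom(M, n, q).
    ``adjust`` is ``"none"`` (raw p, the conventional criterion) or ``"BH"``
    (Benjamini-Hochberg); the ``significant`` column uses the adjusted p
    when BH is requested.  A pathway whose overlap equals the query size and
    the universe is flagged ``degenerate`` (the test carries no information).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    query = set(query)
    mapped = query & pathways.universe
    if not mapped:
        raise ValueError("query does not intersect the pathway universe")
    M = len(pathways.universe)
    q = len(mapped)

    rows = []
    for name in sorted(pathways.gene_sets):
        genes = pathways.gene_sets[name]
        n = len(genes)
        k = len(mapped & genes)
        p = float(hypergeom.sf(k - 1, M, n, q))
        rows.append((name, k, n, q, M, p, n == M and k == q))
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size",
                                     "query_size", "universe_size", "p",
                                     "degenerate"])
    if adjust == "BH":
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = float("nan")
        df["significant"] = df["p"] < alpha
    df = df.sort_values(["p", "pathway"], ignore_index=True)
    logger.info("ORA: %d / %d pathways significant (alpha=%g, adjust=%s, "
                "query %d/%d in universe)", int(df["significant"].sum()),
                len(df), alpha, adjust, q, len(query))
    return df


def significant_pathways(result: pd.DataFrame) -> set[str]:
    """Names of pathways flagged significant in an ORA result table."""
    return set(result.loc[result["significant"], "pathway"])


@dataclass(frozen=True)
class CoverageResult:
    """|A ∩ B| / |B| with the Venn intersection retained."""

    fraction: float
    n_intersection: int
    n_reference: int
    intersection: tuple[str, ...]

    @property
    def percent(self) -> float:
        return round(100.0 * self.fraction, 2)


def pathway_coverage(set_a: Iterable[str], set_b: Iterable[str]) -> CoverageResult:
    """Fraction of reference pathway set B recovered by A: |A ∩ B| / |B|."""
    a, b = set(set_a), set(set_b)
    if not b:
        raise ValueError("reference pathway set B is empty")
    inter = sorted(a & b)
    return CoverageResult(fraction=len(inter) / len(b),
                          n_intersection=len(inter), n_reference=len(b),
                          intersection=tuple(inter))
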