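"""Herbal-component screening and the component-target (C-T) network.

The component table (in the style of a TCMSP export) carries three ADME
screening properties per compound: oral bioavailability OB (%F), Caco-2
monolayer permeability score, and drug-likeness DL.  A component passes the
activity screen iff OB >= 30, Caco-2 > -0.4 and DL >= 0.18 (the Caco-2 rule
is strict: scores of exactly -0.4 denote non-permeable compounds), or if a
curator whitelisted it for high content / known bioactivity despite failing
the rules.

Targets predicted for the active components by one or more tools are merged
by union (with per-edge tool provenance retained) into a bipartite C-T
network, whose two per-side mean degrees are the headline descriptive
statistics of such networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "COMPONENT_COLUMNS",
    "load_components",
    "load_target_table",
    "filter_active",
    "CTNetwork",
    "merge_predictions",
    "ct_degree_stats",
]

logger = logging.getLogger(__name__)

COMPONENT_COLUMNS = [
    "id", "name", "herbs", "formula", "mw", "ob", "caco2", "dl", "whitelisted",
]

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}


def load_components(path: str | Path) -> pd.DataFrame:
    """Read a components.tsv table (header row, columns COMPONENT_COLUMNS).

    ``herbs`` is a ``;``-separated list of herb codes; ``whitelisted`` is
    parsed as a boolean.  Numeric properties may be empty (missing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str, "herbs": str,
                                            "formula": str})
    missing = [c for c in COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate component ids {dups}")
    df["whitelisted"] = (
        df["whitelisted"].astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)
    )
    for col in ("mw", "ob", "caco2", "dl"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if (df["mw"].dropna() <= 0).any():
        raise ValueError(f"{path}: non-positive molecular weight")
    return df


def load_target_table(path: str | Path) -> pd.DataFrame:
    """Read a target-prediction table with columns (component, gene, tool)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"component", "gene", "tool"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def filter_active(
    components: pd.DataFrame,
    ob_min: float = 30.0,
    caco2_min: float = -0.4,
    dl_min: float = 0.18,
    on_missing: str = "reject",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the ADME activity screen.

    A component passes iff (ob >= ob_min AND caco2 > caco2_min AND
    dl >= dl_min) OR it is whitelisted.  Boundary semantics: OB and DL
    inclusive, Caco-2 strict.

    ``on_missing`` controls non-whitelisted components with a missing
    property: ``"reject"`` (default) or ``"pass"`` (treat the missing
    property as satisfying its rule).

    Returns the passing sub-table (original order) and a report dict with
    per-rule rejection counts.
    """
    if on_missing not in ("reject", "pass"):
        raise ValueError(f"on_missing must be 'reject' or 'pass', got {on_missing!r}")
    for name, val in (("ob_min", ob_min), ("caco2_min", caco2_min), ("dl_min", dl_min)):
        if not pd.notna(val):
            raise ValueError(f"{name} must be finite")

    ob, caco2, dl = components["ob"], components["caco2"], components["dl"]
    fill = on_missing == "pass"
    # comparisons with NaN are False; re-apply the missing-value policy
    ok_ob = ob.ge(ob_min) | (fill & ob.isna())
    ok_caco2 = caco2.gt(caco2_min) | (fill & caco2.isna())
    ok_dl = dl.ge(dl_min) | (fill & dl.isna())
    rules = ok_ob & ok_caco2 & ok_dl
    passed = rules | components["whitelisted"]

    has_missing = ob.isna() | caco2.isna() | dl.isna()
    report = {
        "n_input": int(len(components)),
        "n_pass": int(passed.sum()),
        "n_pass_rules": int(rules.sum()),
        "n_whitelist_rescued": int((components["whitelisted"] & ~rules).sum()),
        "n_fail_ob": int((~ok_ob & ~passed).sum()),
        "n_fail_caco2": int((~ok_caco2 & ~passed).sum()),
        "n_fail_dl": int((~ok_dl & ~passed).sum()),
        "n_missing_rejected": int((has_missing & ~passed).sum())
        if on_missing == "reject" else 0,
    }
    logger.info("ADME screen: %(n_pass)d / %(n_input)d components pass "
                "(%(n_whitelist_rescued)d whitelist-rescued)", report)
    return components.loc[passed].copy(), report


@dataclass(frozen=True)
class CTNetwork:
    """Bipartite component-target network.

    ``edges`` has one row per unique (component, gene) pair with a ``tools``
    column holding the sorted tuple of prediction tools supporting the edge.
    """

    edges: pd.DataFrame

    @property
    def components(self) -> list[str]:
        return sorted(self.edges["component"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.edges["gene"].unique())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def target_sets(self) -> dict[str, frozenset[str]]:
        """Per-component target gene sets."""
        return {
            comp: frozenset(group["gene"])
            for comp, group in self.edges.groupby("component", sort=True)
        }

    def write(self, path: str | Path) -> None:
        out = self.edges.copy()
        out["tools"] = out["tools"].map(";".join)
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def merge_predictions(
    tables: Iterable[pd.DataFrame],
    known_components: Iterable[str] | None = None,
    min_tools: int = 1,
) -> CTNetwork:
    """Union target predictions from several tools into one C-T network.

    Edges are deduplicated by (component, gene); the set of supporting tools
    is kept as provenance.  ``min_tools`` filters edges supported by fewer
    tools (default 1 = plain union).  If ``known_components`` is given,
    predictions for ids outside it are an error.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no prediction tables given")
    cat = pd.concat(tables, ignore_index=True)
    need = {"component", "gene", "tool"}
    if not need.issubset(cat.columns):
        raise ValueError(f"prediction tables need columns {sorted(need)}")
    for col in need:
        cat[col] = cat[col].astype(str).str.strip()

    if known_components is not None:
        known = set(known_components)
        unknown = sorted(set(cat["component"]) - known)
        if unknown:
            raise ValueError(f"unknown component ids in predictions: {unknown}")

    grouped = (
        cat.groupby(["component", "gene"], sort=True)["tool"]
        .agg(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"tool": "tools"})
    )
    grouped = grouped[grouped["tools"].map(len) >= min_tools].reset_index(drop=True)
    logger.info("C-T network: %d components, %d targets, %d edges (min_tools=%d)",
                grouped["component"].nunique(), grouped["gene"].nunique(),
                len(grouped), min_tools)
    return CTNetwork(edges=grouped)


def ct_degree_stats(ct: CTNetwork) -> dict[str, float]:
    """Per-side size and mean-degree statistics of a C-T network.

    ``mean_targets_per_component`` = edges / components (the average number
    of predicted targets per compound); ``mean_components_per_target`` =
    edges / targets (how many compounds hit an average target).
    """
    if ct.n_edges == 0:
        raise ValueError("empty C-T network")
    n_comp = ct.edges["component"].nunique()
    n_tar = ct.edges["gene"].nunique()
    return {
        "n_components": int(n_comp),
        "n_targets": int(n_tar),
        "n_edges": int(ct.n_edges),
        "mean_targets_per_component": ct.n_edges / n_comp,
        "mean_components_per_target": ct.n_edges / n_tar,
    }


def herb_count_summary(components: pd.DataFrame) -> dict[str, int]:
    """Raw per-herb membership sum vs unique component count.

    Components shared by several herbs are counted once per herb in the raw
    sum, so the two totals differ whenever sharing exists; both are reported.
    """
    herb_lists = components["herbs"].fillna("").str.split(";")
    raw_sum = int(herb_lists.map(lambda hs: len([h for h in hs if h])).sum())
    return {"raw_herb_sum": raw_sum, "unique_components": int(len(components))}
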