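"""ADME screening and the component-target bipartite network."""

import numpy as np
import pandas as pd
import pytest

from kgec.components import (load_components, filter_active,
                             merge_predictions, ct_degree_stats,
                             herb_count_summary, CTNetwork)


def _table(rows):
    cols = ["id", "name", "herbs", "formula", "mw", "ob", "caco2", "dl",
            "whitelisted"]
    return pd.DataFrame(rows, columns=cols)


def _row(cid, ob, caco2, dl, wl=False):
    return (cid, f"cmp-{cid}", "JYH", "C9H8O3", 164.16, ob, caco2, dl, wl)


class TestFilterActive:
    def test_exact_boundary_semantics(self):
        # OB and DL are inclusive cutoffs; Caco-2 is strict, so a component
        # sitting exactly on all three boundaries fails on Caco-2 alone.
        df = _table([_row("C1", 30.0, -0.4, 0.18)])
        active, report = filter_active(df)
        assert len(active) == 0
        assert report["n_fail_caco2"] == 1

    def test_boundary_passes_once_caco2_clears(self):
        df = _table([_row("C1", 30.0, -0.39, 0.18)])
        active, _ = filter_active(df)
        assert list(active["id"]) == ["C1"]

    def test_whitelist_overrides_failed_rules(self):
        df = _table([_row("C1", 12.0, -1.0, 0.05, wl=True)])
        active, report = filter_active(df)
        assert list(active["id"]) == ["C1"]
        assert report["n_whitelist_rescued"] == 1

    def test_missing_property_policy(self):
        df = _table([_row("C1", np.nan, 0.5, 0.5)])
        rejected, _ = filter_active(df, on_missing="reject")
        assert len(rejected) == 0
        passed, _ = filter_active(df, on_missing="pass")
        assert len(passed) == 1

    def test_thresholds_at_minus_infinity_pass_everything(self):
        rng = np.random.default_rng(3)
        df = _table([_row(f"C{i}", rng.uniform(0, 100),
                          rng.uniform(-2, 2), rng.uniform(0, 1))
                     for i in range(200)])
        active, _ = filter_active(df, ob_min=-np.inf, caco2_min=-np.inf,
                                  dl_min=-np.inf)
        assert len(active) == len(df)

    def test_random_table_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(11)
        df = _table([_row(f"C{i:04d}", rng.uniform(0, 60),
                          rng.uniform(-1, 0), rng.uniform(0, 0.4),
                          wl=bool(rng.random() < 0.1))
                     for i in range(1000)])
        active, _ = filter_active(df)
        expected = {
            r.id for r in df.itertuples()
            if (r.ob >= 30.0 and r.caco2 > -0.4 and r.dl >= 0.18)
            or r.whitelisted
        }
        assert set(active["id"]) == expected


class TestMergePredictions:
    def test_same_edge_from_two_tools_collapses_with_provenance(self):
        t1 = pd.DataFrame({"component": ["C1"], "gene": ["G1"],
                           "tool": ["sea"]})
        t2 = pd.DataFrame({"component": ["C1"], "gene": ["G1"],
                           "tool": ["hitpick"]})
        ct = merge_predictions([t1, t2])
        assert ct.n_edges == 1
        assert ct.edges.loc[0, "tools"] == ("hitpick", "sea")

    def test_min_tools_filters_single_tool_edges(self):
        t = pd.DataFrame({"component": ["C1", "C1"], "gene": ["G1", "G2"],
                          "tool": ["sea", "sea"]})
        assert merge_predictions([t], min_tools=3).n_edges == 0

    def test_unknown_component_ids_listed(self):
        t = pd.DataFrame({"component": ["C9"], "gene": ["G1"],
                          "tool": ["sea"]})
        with pytest.raises(ValueError, match="C9"):
            merge_predictions([t], known_components={"C1"})

    def test_union_equals_set_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        tables = []
        for tool in ("sea", "hitpick", "swisstarget"):
            n = int(rng.integers(50, 150))
            tables.append(pd.DataFrame({
                "component": [f"C{rng.integers(1, 10)}" for _ in range(n)],
                "gene": [f"G{rng.integers(1, 40)}" for _ in range(n)],
                "tool": [tool] * n,
            }))
        ct = merge_predictions(tables)
        oracle = set()
        for t in tables:
            oracle |= set(zip(t["component"], t["gene"]))
        assert set(zip(ct.edges["component"], ct.edges["gene"])) == oracle
        total_rows = sum(len(t) for t in tables)
        assert ct.n_edges <= total_rows


class TestCTDegreeStats:
    def test_printed_count_arithmetic(self):
        # bipartite graph with the printed study sizes: 193 components,
        # 1220 targets, 6399 edges -> per-side means 33.16 and 5.25
        rng = np.random.default_rng(0)
        edges = _random_bipartite(rng, 193, 1220, 6399)
        ct = CTNetwork(edges=edges)
        stats = ct_degree_stats(ct)
        assert round(stats["mean_targets_per_component"], 2) == 33.16
        assert round(stats["mean_components_per_target"], 2) == 5.25

    def test_single_edge(self):
        ct = CTNetwork(edges=pd.DataFrame(
            {"component": ["C1"], "gene": ["G1"], "tools": [("sea",)]}))
        stats = ct_degree_stats(ct)
        assert stats["mean_targets_per_component"] == 1.0
        assert stats["mean_components_per_target"] == 1.0

    def test_empty_network_rejected(self):
        ct = CTNetwork(edges=pd.DataFrame(
            columns=["component", "gene", "tools"]))
        with pytest.raises(ValueError):
            ct_degree_stats(ct)


def _random_bipartite(rng, n_comp, n_tar, n_edges):
    """Random bipartite edge table with exactly the requested side sizes
    and edge count (every component and target touched at least once)."""
    comps = [f"C{i:04d}" for i in range(n_comp)]
    tars = [f"G{i:05d}" for i in range(n_tar)]
    pairs = set()
    for i, t in enumerate(tars):  # touch every target
        pairs.add((comps[i % n_comp], t))
    while len(pairs) < n_edges:
        need = n_edges - len(pairs)
        ci = rng.integers(0, n_comp, size=2 * need)
        ti = rng.integers(0, n_tar, size=2 * need)
        for c, t in zip(ci, ti):
            pairs.add((comps[c], tars[t]))
            if len(pairs) == n_edges:
                break
    rows = sorted(pairs)
    return pd.DataFrame({"component": [c for c, _ in rows],
                         "gene": [t for _, t in rows],
                         "tools": [("sea",)] * len(rows)})


def test_herb_count_summary_reports_raw_and_unique():
    df = _table([
        ("C1", "a", "JYH;LQ", "C9H8O3", 164.2, 40, 0.5, 0.3, False),
        ("C2", "b", "JYH", "C9H8O3", 164.2, 40, 0.5, 0.3, False),
    ])
    summary = herb_count_summary(df)
    assert summary == {"raw_herb_sum": 3, "unique_components": 2}


def test_load_components_round_trips_fixture(bundle):
    df = load_components(bundle.components)
    assert len(df) == bundle.manifest["counts"]["n_components"]
    assert df["whitelisted"].dtype == bool
    assert (df["mw"] > 0).all()
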