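"""Contribution index, 0-1 knapsack, accumulation curve, KGEC cut."""

import itertools

import numpy as np
import pytest

from kgec.ci_kgec import (CIInput, component_ci, knapsack_01,
                          knapsack_select, accumulation_curve, select_kgec,
                          run_ci)


def _inp(lams, omegas=None, W=None):
    lam = {k: frozenset(v) for k, v in lams.items()}
    if omegas is None:
        omegas = {k: len(v) for k, v in lam.items()}
    if W is None:
        W = len(frozenset().union(*lam.values()))
    return CIInput(lambda_sets=lam, omega=omegas, n_effective=W)


def _random_input(rng, m, W):
    universe = [f"P{i}" for i in range(W)]
    lam = {}
    omegas = {}
    for i in range(m):
        nu = int(rng.integers(1, W + 1))
        lam[f"C{i:02d}"] = frozenset(
            rng.choice(universe, size=nu, replace=False).tolist())
        omegas[f"C{i:02d}"] = nu + int(rng.integers(0, 5))
    return CIInput(lambda_sets=lam, omega=omegas, n_effective=W)


class TestComponentCI:
    def test_ci_is_nu_over_w(self):
        inp = _inp({"C1": [f"P{i}" for i in range(9)]}, W=10)
        table = component_ci(inp)
        assert table.loc[0, "ci"] == pytest.approx(0.9)
        assert table.loc[0, "ci_percent"] == 90.00

    def test_ranking_ties_broken_by_id(self):
        inp = _inp({"C2": ["P1", "P2"], "C1": ["P2", "P3"], "C3": ["P1"]},
                   W=3)
        table = component_ci(inp)
        assert list(table["component"]) == ["C1", "C2", "C3"]

    def test_fixture_equals_cardinality_oracle(self):
        rng = np.random.default_rng(2)
        inp = _random_input(rng, m=20, W=30)
        table = component_ci(inp).set_index("component")
        for comp, lam in inp.lambda_sets.items():
            assert table.loc[comp, "ci"] == pytest.approx(len(lam) / 30)

    def test_zero_w_rejected(self):
        with pytest.raises(ValueError):
            CIInput(lambda_sets={"C1": frozenset({"P1"})},
                    omega={"C1": 1}, n_effective=0)


class TestKnapsack:
    def test_classic_instance_verified_by_enumeration(self):
        # values (60,100,120), weights (10,20,30), capacity 50
        vals, wts = [60, 100, 120], [10, 20, 30]
        value, picked = knapsack_01(vals, wts, capacity=50)
        # independent oracle: enumerate all 8 subsets
        best = max(sum(vals[i] for i in s)
                   for r in range(4)
                   for s in itertools.combinations(range(3), r)
                   if sum(wts[i] for i in s) <= 50)
        assert best == 220
        assert value == 220
        assert set(picked) == {1, 2}

    def test_zero_capacity(self):
        inp = _inp({"C1": ["P1"]}, W=1)
        res = knapsack_select(inp, capacity=0)
        assert res.value == 0 and res.subset == ()

    def test_dp_equals_exhaustive_enumeration_on_random_instances(self):
        # 100 random instances with m <= 15 against a brute-force subset max
        rng = np.random.default_rng(123)
        for trial in range(100):
            m = int(rng.integers(2, 16))
            W = int(rng.integers(5, 30))
            inp = _random_input(rng, m, W)
            cap = int(rng.integers(0, 2 * W))
            res = knapsack_select(inp, capacity=cap)
            ids = inp.component_ids
            vals = np.array([inp.nu(c) for c in ids])
            wts = np.array([inp.omega[c] for c in ids])
            masks = np.arange(1 << m)[:, None]
            chosen = (masks >> np.arange(m)) & 1
            tot_w = chosen @ wts
            tot_v = chosen @ vals
            brute = tot_v[tot_w <= cap].max()
            assert res.value == brute, f"trial {trial}"
            # returned subset is feasible and achieves the DP value
            assert sum(inp.omega[c] for c in res.subset) <= cap
            assert sum(inp.nu(c) for c in res.subset) == res.value

    def test_everything_fits_when_capacity_is_total_weight(self):
        rng = np.random.default_rng(9)
        inp = _random_input(rng, m=10, W=20)
        total_w = sum(inp.omega.values())
        res = knapsack_select(inp, capacity=total_w)
        assert res.value == sum(inp.nu(c) for c in inp.component_ids)
        assert set(res.subset) == set(inp.component_ids)


class TestAccumulationCurve:
    def test_duplicate_component_adds_no_marginal_coverage(self):
        inp = _inp({"C1": ["P1", "P2"], "C2": ["P1", "P2"]}, W=4)
        _, curve, marginals = accumulation_curve(inp)
        assert marginals.tolist() == [2, 0]
        assert curve.tolist() == [0.5, 0.5]

    def test_disjoint_sets_accumulate_running_sum(self):
        inp = _inp({"C1": ["P1", "P2"], "C2": ["P3"], "C3": ["P4", "P5"]},
                   W=5)
        order, curve, _ = accumulation_curve(inp)
        running = np.cumsum([inp.nu(c) for c in order]) / 5
        assert curve.tolist() == pytest.approx(running.tolist())
        assert order == ["C1", "C3", "C2"]  # ν descending, ties by id

    def test_monotone_bounded_and_exact_final_value(self):
        rng = np.random.default_rng(21)
        for order in ("ci_desc", "greedy_marginal"):
            inp = _random_input(rng, m=25, W=40)
            _, curve, _ = accumulation_curve(inp, order=order)
            assert np.all(np.diff(curve) >= 0)
            assert curve[-1] <= 1.0
            union = frozenset().union(*inp.lambda_sets.values())
            assert curve[-1] == pytest.approx(len(union) / 40)

    def test_greedy_prefix_dominates_ci_descending_order(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            inp = _random_input(rng, m=15, W=30)
            _, curve_ci, _ = accumulation_curve(inp, order="ci_desc")
            _, curve_gr, _ = accumulation_curve(inp, order="greedy_marginal")
            assert np.all(curve_gr >= curve_ci - 1e-12)


class TestSelectKGEC:
    def test_first_threshold_crossing(self):
        order = ["C1", "C2", "C3", "C4"]
        curve = np.array([0.5, 0.8, 0.92, 0.95])
        assert select_kgec(order, curve, threshold=0.90) == \
            ["C1", "C2", "C3"]

    def test_full_coverage_prefix_at_threshold_one(self):
        inp = _inp({"C1": ["P1", "P2"], "C2": ["P3"]}, W=3)
        order, curve, _ = accumulation_curve(inp)
        sel = select_kgec(order, curve, threshold=1.0)
        assert curve[len(sel) - 1] == pytest.approx(1.0)

    def test_unreachable_threshold_warns_and_returns_all(self):
        inp = _inp({"C1": ["P1"]}, W=10)
        order, curve, _ = accumulation_curve(inp)
        with pytest.warns(UserWarning, match="unreachable"):
            sel = select_kgec(order, curve, threshold=0.90)
        assert sel == order

    def test_prefix_length_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(31)
        inp = _random_input(rng, m=20, W=25)
        order, curve, _ = accumulation_curve(inp)
        for threshold in (0.3, 0.5, 0.75, 0.9):
            sel = select_kgec(order, curve, threshold=threshold)
            scan = next((j + 1 for j, v in enumerate(curve)
                         if v >= threshold), len(order))
            assert len(sel) == scan

    def test_selection_length_non_decreasing_in_threshold(self):
        rng = np.random.default_rng(13)
        inp = _random_input(rng, m=15, W=20)
        order, curve, _ = accumulation_curve(inp)
        lengths = [len(select_kgec(order, curve, threshold=t))
                   for t in (0.2, 0.4, 0.6, 0.8, float(curve[-1]))]
        assert lengths == sorted(lengths)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            select_kgec(["C1"], np.array([1.0]), threshold=1.5)


def test_run_ci_assembles_consistent_result():
    rng = np.random.default_rng(4)
    inp = _random_input(rng, m=12, W=20)
    res = run_ci(inp, threshold=0.9)
    assert res.kgec == res.order[: len(res.kgec)]  # KGEC is a prefix
    assert res.coverage_achieved >= 0.9 or len(res.kgec) == inp.m
    assert len(res.ci_table) == inp.m
    assert res.knapsack.capacity == inp.n_effective


def test_ci_input_from_networks_drops_non_contributing_components(bundle):
    from kgec.network_core import load_ppi, load_disease_genes
    from kgec.components import load_target_table, merge_predictions
    from kgec.optspace import build_dtc, extract_optspace

    ppi = load_ppi(bundle.ppi)
    disease = set(load_disease_genes(bundle.disease_genes))
    ct = merge_predictions([load_target_table(bundle.targets)])
    space = extract_optspace(build_dtc(ppi, set(ct.targets), disease))
    inp = CIInput.from_networks(ct, space.effective_proteins)
    eff = set(space.effective_proteins)
    tsets = ct.target_sets()
    for comp, lam in inp.lambda_sets.items():
        assert lam == tsets[comp] & eff
        assert inp.omega[comp] == len(tsets[comp])
    excluded = set(tsets) - set(inp.lambda_sets)
    assert all(not (tsets[c] & eff) for c in excluded)
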