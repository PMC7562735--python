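# Methods

## The selection model

The pipeline treats formula optimization as a coverage problem on the PPI
network. Pathogenic genes and predicted component targets are projected into
the PPI; their induced union — the disease-targets-components (DTC) network —
is the arena in which component relevance is judged. The hub rule (keep
nodes whose degree strictly exceeds the DTC average degree `D_avg`) is a
deliberately simple centrality filter: it discards the low-degree periphery
where neither disease biology nor drug action concentrates, and the
surviving *effective proteins* form the optimization space. Component
selection then maximizes coverage of that space, not structural similarity
between compounds — the premise being that a compound subset jointly
touching most effective proteins preserves the formula's systems-level
action.

Assumptions worth stating explicitly:

* the PPI is an unweighted, undirected simple graph; interaction confidence
  and direction are ignored;
* gene symbols match exactly (trimmed, case-sensitive); alias resolution is
  out of scope, so inputs must share a naming convention;
* disease-gene weights (literature-report counts) annotate nodes and rank
  reporting but do not enter the hub rule or the contribution index;
* target predictions are taken at face value; the merge across tools is a
  union because no voting rule is part of the model (a `min_tools`
  parameter is exposed for stricter use).

## Contribution index, knapsack, and the coverage curve

For each active component *i* with effective-target set `λ_i`, total target
count `ω_i`, and `ν_i = |λ_i|`, the contribution index is `CI_i = ν_i / W`
with `W` the number of effective proteins. Two selection views are computed
deliberately side by side:

* the **literal 0-1 knapsack** (values `ν_i`, weights `ω_i`, capacity `W`,
  standard DP with strict-improvement tie-break) maximizes summed coverage
  counts; because `λ` sets overlap, its optimum overstates true union
  coverage;
* the **union-coverage accumulation curve** orders components (CI
  descending with id tie-break, or greedy maximum marginal coverage) and
  records `|λ_(1) ∪ … ∪ λ_(j)| / W` per prefix.

The KGEC is cut from the curve — the shortest prefix reaching the coverage
threshold (default 0.90) — since a percentage-of-proteins-covered target is
a statement about unions, not sums. The knapsack optimum is reported
alongside as the model's upper bound on summed coverage. The greedy order
prefix-dominates the CI order (verified property), but CI-descending is the
default because it keeps the ranking interpretable as a per-component score.
Note that `W` counts *all* effective proteins, including disease-specific
ones no component targets, so full coverage is generally unreachable; when
the threshold is unreachable the full ranking is returned with a warning.

All ties everywhere break by component id ascending, making every output a
pure function of the inputs.

## Enrichment validation

ORA uses the upper-tail hypergeometric probability `P(X ≥ k)` with the
universe defaulting to the union of the GMT's genes (overridable). The
significance criterion is raw `p < 0.05`, matching common practice in this
literature; Benjamini-Hochberg adjustment is offered because raw-p ORA is
statistically weak, and both columns are always written. Pathway coverage
`|A ∩ B| / |B|` quantifies how much of the pathogenic-gene pathway
landscape the selected proteins or targets recover; it is reported with the
Venn intersection list. GO analysis is the same ORA over a GO-term GMT; no
ontology-graph propagation is performed.

## ADME screen

Boundary semantics follow the published wording: OB and DL cutoffs are
inclusive (`≥ 30 %`, `≥ 0.18`), the Caco-2 cutoff is strict (`> −0.4`,
because a score of exactly −0.4 denotes a non-permeable compound). The
whitelist is an explicit boolean column, not a hard-coded name list: the
"high content / high bioactivity" exception is a curator decision and
belongs in the data, not the code. Components with missing properties are
rejected by default (`on_missing="reject"`), with a permissive policy
available.

## Mass arithmetic

Average molecular weight uses an embedded IUPAC standard-atomic-weight
table; monoisotopic mode is available but not the default, since component
databases print average-mass MWs. Adduct m/z is `MW ± 1.00728` Da (proton
mass). A consistency checker flags table rows whose printed m/z shift
contradicts the ion label (positive-mode shift under a negative-mode label);
such rows are flagged, never silently corrected.

## Synthetic data: what it emulates, and what it does not

`synthetic_data.generate_fixture` produces the five inputs with controlled
structure, all sampling from one seeded NumPy generator in documented order
(byte-identical files per seed):

| parameter | default | rationale |
|---|---|---|
| `n_ppi_genes` / `ppi_mean_degree` | 1200 / 8 | preferential-attachment graph: heavy-tailed degrees like real PPI unions, at desk scale |
| `n_disease_genes` / `weight_max` | 200 / 100 | degree-weighted draw — curated disease catalogs are biased toward well-studied hubs; weights emulate report counts |
| `n_components` | 120 | scaled-down component catalog; ADME columns drawn so roughly a third pass, plus a 5 % whitelist |
| `targets_mean` / `targets_dispersion` | 30 / 5 | per-component target count `1 + NegBinomial(mean − 1, r)`: minimum 1, mean exactly `targets_mean`, overdispersed like multi-tool predictions |
| `frac_targets_in_disease` | 0.35 | expected fraction of target draws landing in the disease pool; directly sets the essential-common category size (0 empties it) |
| `n_pathways`, size 10–80 | 50 | each pathway mixes ~40 % disease genes, ~40 % targets, ~20 % background, so enrichment has signal |

The generator emulates the *shape* of the real inputs — degree
heterogeneity, disease/target overlap, pathway signal — not their biology:
gene symbols are synthetic, target predictions are independent draws rather
than chemistry-driven, and pathway composition is stylized. Passing tests
therefore demonstrate algorithmic correctness and pipeline reproducibility,
not that real-data coverage percentages will match any particular value; at
the default desk scale the effective-protein pathway coverage lands around
30–50 %, well below what a full-size curated study reports.
`planted_enrichment_case` additionally builds a query/pathway pair with one
pathway enriched by construction, used to verify that ORA recovers a known
signal across seeds.

## Numerical and degenerate-input choices

* Hub rule uses strict `>`; a degree-regular DTC network (no node above
  average) is an explicit error, not an empty result.
* The optimization-space edge rule defaults to the induced subgraph (both
  endpoints hubs) so the space is a self-contained network; `incident`
  keeps all hub-touching edges, in which case non-hub endpoints appear in
  the output flagged `is_hub=False` and are *not* effective proteins.
* Knapsack DP is exact integer arithmetic; no scaling is needed because
  `ω_i` are counts. Backtracking leaves an item out on ties.
* Curve thresholds compare with a `1e-12` slack because curve values are
  exact ratios of integers but stored as floats.
* Coverage and CI percentages are rounded to 2 decimals only at the
  reporting boundary; full precision is kept internally.
* Pipeline outputs contain no timestamps; the manifest records a config
  hash, so double-run byte-identity is testable and tested.

Problem sizes in the test suite and acceptance script (600–2,000-gene PPIs,
20–120 components, knapsack oracles at m ≤ 15, 200-seed enrichment
replicates) were chosen as the smallest scales at which every structural
property of the method is exercised, and run in seconds.

## Known limitations

* No identifier mapping: inputs using mixed symbol conventions silently
  shrink the intersection.
* The hub rule is global; a single dense module can dominate the
  optimization space.
* ORA ignores gene-length/annotation bias and treats the GMT union as the
  universe unless told otherwise; raw-p significance inflates counts.
* The knapsack view and the coverage view can disagree on marginal
  components; only the coverage view defines the KGEC cut.
* Published full-scale network sizes and coverage percentages depend on
  specific database snapshots and are treated as shape references only; the
  package makes no attempt to reproduce them from scratch.
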