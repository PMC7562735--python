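"""Synthetic input generator for the whole pipeline.

Emulates, at desk scale and with synthetic gene symbols, the five inputs the
pipeline consumes: a background PPI edge list, a weighted disease-gene table
(DisGeNET-style literature-report counts), a component property table
(TCMSP-style ADME columns), per-tool component-target prediction tables, and
a GMT pathway collection.  All sampling comes from a single seeded NumPy
generator in a fixed documented order, so a given spec reproduces its files
byte for byte.

The generator controls the statistical structure that matters downstream:
the PPI is a preferential-attachment (hence heavy-tailed degree) simple
graph; disease genes are a weighted subset of PPI genes; each component
draws a 1 + negative-binomial number of distinct targets, a configurable
fraction of them from the disease-gene pool (which directly sets the size
of the essential-common category); pathways mix disease genes, component
targets and background genes so enrichment has signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import chem_mass
from .enrichment import PathwayCollection

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture",
           "targets_per_component_moments", "planted_enrichment_case"]

TOOLS = ("sea", "hitpick", "swisstarget")
HERB_CODES = ("JYH", "LQ", "PGY", "HL", "DH", "CS", "DG", "DS")

# Small organic-formula building blocks for synthetic component records.
_ELEMENT_RANGES = {"C": (6, 30), "H": (6, 40), "O": (0, 12), "N": (0, 2)}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic input bundle.

    Defaults are a scaled-down analogue of a formula-optimization study on
    a complex autoimmune disease: a ~1,200-gene PPI background, 200 weighted
    disease genes, 120 herbal components averaging 30 predicted targets
    each, about a third of target draws landing in the disease-gene pool,
    and 50 pathways of 10-80 genes.
    """

    n_ppi_genes: int = 1200
    ppi_mean_degree: float = 8.0
    n_disease_genes: int = 200
    weight_max: int = 100
    n_components: int = 120
    targets_mean: float = 30.0
    targets_dispersion: float = 5.0
    frac_targets_in_disease: float = 0.35
    n_pathways: int = 50
    pathway_size_min: int = 10
    pathway_size_max: int = 80
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_ppi_genes", self.n_ppi_genes >= 10),
            ("ppi_mean_degree", 0 < self.ppi_mean_degree < self.n_ppi_genes),
            ("n_disease_genes",
             0 < self.n_disease_genes <= self.n_ppi_genes),
            ("weight_max", self.weight_max >= 1),
            ("n_components", self.n_components >= 1),
            ("targets_mean", self.targets_mean >= 1),
            ("targets_dispersion", self.targets_dispersion > 0),
            ("frac_targets_in_disease",
             0 <= self.frac_targets_in_disease <= 1),
            ("n_pathways", self.n_pathways >= 1),
            ("pathway_size_min", self.pathway_size_min >= 1),
            ("pathway_size_max",
             self.pathway_size_max >= self.pathway_size_min),
            ("seed", isinstance(self.seed, (int, np.integer))),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid FixtureSpec field: {name}")


def targets_per_component_moments(spec: FixtureSpec) -> tuple[float, float]:
    """Analytic (mean, variance) of the per-component target count.

    The count is 1 + NegBinomial with mean mu = targets_mean - 1 and
    dispersion r = targets_dispersion (variance mu + mu^2/r), so the
    minimum is 1 and the mean is exactly ``targets_mean``.
    """
    mu = spec.targets_mean - 1.0
    var = mu + mu * mu / spec.targets_dispersion
    return spec.targets_mean, var


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of the generated files plus the manifest dict."""

    ppi: Path
    disease_genes: Path
    components: Path
    targets: Path
    pathways: Path
    manifest_path: Path
    manifest: dict

    def target_tables(self) -> list[Path]:
        return [self.targets]


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _sample_targets(rng: np.random.Generator, spec: FixtureSpec,
                    disease_pool: np.ndarray, other_pool: np.ndarray) -> list[str]:
    mu = spec.targets_mean - 1.0
    r = spec.targets_dispersion
    if mu > 0:
        k = 1 + int(rng.negative_binomial(r, r / (r + mu)))
    else:
        k = 1
    k = min(k, len(disease_pool) + len(other_pool))
    n_dis = int(rng.binomial(k, spec.frac_targets_in_disease))
    n_dis = min(n_dis, len(disease_pool))
    n_other = min(k - n_dis, len(other_pool))
    picks = []
    if n_dis:
        picks.append(rng.choice(disease_pool, size=n_dis, replace=False))
    if n_other:
        picks.append(rng.choice(other_pool, size=n_other, replace=False))
    return sorted(np.concatenate(picks).tolist()) if picks else []


def _random_formula(rng: np.random.Generator) -> str:
    parts = []
    for el, (lo, hi) in _ELEMENT_RANGES.items():
        n = int(rng.integers(lo, hi + 1))
        if n:
            parts.append(f"{el}{n}" if n > 1 else el)
    return "".join(parts)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Write the five input files plus a manifest into ``outdir``.

    Sampling order (one RNG stream): PPI graph seed, disease-gene choice
    and weights, per-component properties, per-component target draws
    (component order), per-edge tool assignment, pathway composition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # 1. PPI: preferential attachment, relabelled to synthetic symbols.
    m_attach = max(1, round(spec.ppi_mean_degree / 2))
    graph_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(spec.n_ppi_genes, m_attach, seed=graph_seed)
    symbols = _gene_symbols(spec.n_ppi_genes)
    g = nx.relabel_nodes(g, dict(zip(range(spec.n_ppi_genes), symbols)))
    ppi_path = outdir / "ppi.tsv"
    with open(ppi_path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")

    # 2. Disease genes: degree-weighted subset of PPI genes (literature-
    #    curated disease catalogs are biased toward well-studied hubs).
    degrees = np.array([g.degree(s) for s in symbols], dtype=float)
    disease = np.sort(rng.choice(symbols, size=spec.n_disease_genes,
                                 replace=False, p=degrees / degrees.sum()))
    weights = rng.integers(1, spec.weight_max + 1, size=spec.n_disease_genes)
    dis_path = outdir / "disease_genes.tsv"
    with open(dis_path, "w") as fh:
        fh.write("gene\tweight\n")
        for gene, w in zip(disease, weights):
            fh.write(f"{gene}\t{int(w)}\n")

    # 3. Component property table.
    comp_ids = [f"C{i:04d}" for i in range(1, spec.n_components + 1)]
    comp_path = outdir / "components.tsv"
    with open(comp_path, "w") as fh:
        fh.write("id\tname\therbs\tformula\tmw\tob\tcaco2\tdl\twhitelisted\n")
        for cid in comp_ids:
            n_herbs = int(rng.integers(1, 4))
            herbs = ";".join(sorted(rng.choice(HERB_CODES, size=n_herbs,
                                               replace=False)))
            formula = _random_formula(rng)
            mw = chem_mass.average_mass(formula)
            ob = float(rng.uniform(0, 90))
            caco2 = float(rng.uniform(-2, 2))
            dl = float(rng.uniform(0, 1))
            whitelisted = bool(rng.random() < 0.05)
            fh.write(f"{cid}\tcompound-{cid[1:]}\t{herbs}\t{formula}\t"
                     f"{mw:.3f}\t{ob:.2f}\t{caco2:.3f}\t{dl:.3f}\t"
                     f"{str(whitelisted).lower()}\n")

    # 4. Target predictions with tool provenance.
    disease_set = set(disease.tolist())
    other_pool = np.array([s for s in symbols if s not in disease_set])
    disease_pool = np.array(sorted(disease_set))
    n_edges = 0
    rows: list[tuple[str, str, str]] = []
    for cid in comp_ids:
        genes = _sample_targets(rng, spec, disease_pool, other_pool)
        n_edges += len(genes)
        for gene in genes:
            primary = TOOLS[int(rng.integers(len(TOOLS)))]
            rows.append((cid, gene, primary))
            if rng.random() < 0.25:  # a second tool confirms the edge
                alt = [t for t in TOOLS if t != primary]
                rows.append((cid, gene, alt[int(rng.integers(len(alt)))]))
    targets_path = outdir / "targets.tsv"
    with open(targets_path, "w") as fh:
        fh.write("component\tgene\ttool\n")
        for comp, gene, tool in rows:
            fh.write(f"{comp}\t{gene}\t{tool}\n")

    # 5. Pathways: mix of disease genes, targets and background genes.
    target_union = np.array(sorted({gene for _, gene, _ in rows}))
    pw_path = outdir / "pathways.gmt"
    with open(pw_path, "w") as fh:
        for i in range(1, spec.n_pathways + 1):
            size = int(rng.integers(spec.pathway_size_min,
                                    spec.pathway_size_max + 1))
            n_dis = min(int(round(0.4 * size)), len(disease_pool))
            n_tar = min(int(round(0.4 * size)), len(target_union))
            n_bg = min(size - n_dis - n_tar, len(other_pool))
            picks = [rng.choice(disease_pool, size=n_dis, replace=False),
                     rng.choice(target_union, size=n_tar, replace=False),
                     rng.choice(other_pool, size=n_bg, replace=False)]
            genes = sorted(set(np.concatenate(picks).tolist()))
            fh.write(f"PW{i:03d}\tsynthetic pathway {i}\t" +
                     "\t".join(genes) + "\n")

    manifest = {
        "seed": int(spec.seed),
        "spec": {k: (float(v) if isinstance(v, float) else int(v))
                 for k, v in asdict(spec).items()},
        "counts": {
            "n_ppi_nodes": int(g.number_of_nodes()),
            "n_ppi_edges": int(g.number_of_edges()),
            "n_disease_genes": int(spec.n_disease_genes),
            "n_components": int(spec.n_components),
            "n_target_pairs": int(n_edges),
            "n_target_rows": int(len(rows)),
            "n_pathways": int(spec.n_pathways),
        },
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return FixtureBundle(ppi=ppi_path, disease_genes=dis_path,
                         components=comp_path, targets=targets_path,
                         pathways=pw_path, manifest_path=manifest_path,
                         manifest=manifest)


def planted_enrichment_case(
    seed: int,
    n_universe: int = 400,
    n_pathways: int = 25,
    pathway_size: int = 25,
    query_size: int = 40,
    planted_overlap: int = 15,
) -> tuple[set[str], PathwayCollection, str]:
    """A query set with one pathway enriched by construction.

    Background pathways are uniform draws from the universe; the planted
    pathway is forced to share ``planted_overlap`` genes with the query
    (far above the hypergeometric expectation), so ORA should rank it
    minimum-p.  Returns (query, collection, planted pathway name).
    """
    if planted_overlap > min(pathway_size, query_size):
        raise ValueError("planted_overlap exceeds pathway or query size")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_symbols(n_universe))
    query = rng.choice(genes, size=query_size, replace=False)
    sets: dict[str, set[str]] = {}
    for i in range(1, n_pathways):
        sets[f"PW{i:03d}"] = set(
            rng.choice(genes, size=pathway_size, replace=False).tolist())
    planted_name = "PW_PLANTED"
    non_query = np.array(sorted(set(genes.tolist()) - set(query.tolist())))
    planted = set(rng.choice(query, size=planted_overlap, replace=False).tolist())
    planted |= set(rng.choice(non_query, size=pathway_size - planted_overlap,
                              replace=False).tolist())
    sets[planted_name] = planted
    collection = PathwayCollection.from_sets(sets, universe=genes.tolist())
    return set(query.tolist()), collection, planted_name
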