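"""End-to-end pipeline: disease network → ADME screen → C-T network →
disease-targets-components network → optimization space → CI/KGEC →
enrichment validation, with a reproducible run manifest.

The run is a pure function of (input files, config): outputs carry no
timestamps, every stage writes deterministic plain-text tables, and the
manifest records the config hash and per-stage counts so two runs of the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import __version__
from .network_core import (load_ppi, load_disease_genes,
                           build_weighted_network, degree_summary,
                           write_network)
from .components import (load_components, load_target_table, filter_active,
                         merge_predictions, ct_degree_stats,
                         herb_count_summary)
from .optspace import build_dtc, extract_optspace, category_tables
from .ci_kgec import CIInput, run_ci
from .enrichment import PathwayCollection, ora, significant_pathways, \
    pathway_coverage

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds of one pipeline run; round-trips through YAML."""

    ppi: str
    disease_genes: str
    components: str
    targets: list[str]
    pathways: str
    outdir: str
    ob_min: float = 30.0
    caco2_min: float = -0.4
    dl_min: float = 0.18
    min_tools: int = 1
    edge_rule: str = "induced"
    coverage_threshold: float = 0.90
    alpha: float = 0.05
    adjust: str = "none"
    order: str = "ci_desc"
    on_missing: str = "reject"
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("coverage_threshold", 0 < self.coverage_threshold <= 1),
            ("alpha", 0 < self.alpha < 1),
            ("min_tools", self.min_tools >= 1),
            ("edge_rule", self.edge_rule in ("induced", "incident")),
            ("adjust", self.adjust in ("none", "BH")),
            ("order", self.order in ("ci_desc", "greedy_marginal")),
            ("on_missing", self.on_missing in ("reject", "pass")),
            ("targets", bool(self.targets)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid config field: {name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write outputs + manifest to outdir.

    Returns the manifest dict.  On a stage error, a partial manifest naming
    the failed stage is written before the exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "kgec",
        "version": __version__,
        "config": yaml.safe_load(config.to_yaml()),
        "config_hash": config.config_hash(),
        "counts": {},
    }
    counts = manifest["counts"]

    try:
        # 1. Weighted disease gene regulatory network.
        ppi = load_ppi(config.ppi)
        disease = load_disease_genes(config.disease_genes)
        disease_net = build_weighted_network(ppi, disease)
        _, mean_deg = degree_summary(disease_net)
        write_network(disease_net, out / "disease_network_edges.tsv",
                      out / "disease_network_nodes.tsv")
        counts["ppi_nodes"] = ppi.number_of_nodes()
        counts["ppi_edges"] = ppi.number_of_edges()
        counts["disease_genes"] = len(disease)
        counts["disease_network_nodes"] = disease_net.number_of_nodes()
        counts["disease_network_edges"] = disease_net.number_of_edges()
        counts["disease_network_mean_degree"] = round(mean_deg, 4)

        # 2. ADME screen.
        comp_table = load_components(config.components)
        active, screen_report = filter_active(
            comp_table, ob_min=config.ob_min, caco2_min=config.caco2_min,
            dl_min=config.dl_min, on_missing=config.on_missing)
        active.to_csv(out / "active_components.tsv", sep="\t", index=False,
                      lineterminator="\n")
        counts["components_collected"] = screen_report["n_input"]
        counts["active_components"] = screen_report["n_pass"]
        counts["adme_screen"] = screen_report
        counts["herb_counts"] = herb_count_summary(comp_table)

        # 3. C-T network restricted to active components.
        active_ids = set(active["id"])
        tables = [load_target_table(p) for p in config.targets]
        tables = [t[t["component"].isin(active_ids)] for t in tables]
        ct = merge_predictions(tables, known_components=set(comp_table["id"]),
                               min_tools=config.min_tools)
        ct.write(out / "ct_edges.tsv")
        stats = ct_degree_stats(ct)
        counts["ct"] = {k: (round(v, 4) if isinstance(v, float) else v)
                        for k, v in stats.items()}

        # 4. DTC network and optimization space.
        dtc = build_dtc(ppi, targets=ct.targets, disease=set(disease))
        space = extract_optspace(dtc, edge_rule=config.edge_rule)
        space.write(out / "optspace_nodes.tsv", out / "optspace_edges.tsv")
        cats = category_tables(space)
        counts["dtc_nodes"] = dtc.number_of_nodes()
        counts["dtc_edges"] = dtc.number_of_edges()
        counts["dtc_average_degree"] = round(space.d_avg, 4)
        counts["effective_proteins"] = space.n_effective
        counts["optspace_edges"] = space.graph.number_of_edges()
        counts["categories"] = {c: len(g) for c, g in cats.items()}

        # 5. CI model and KGEC selection.
        ci_in = CIInput.from_networks(ct, space.effective_proteins)
        ci = run_ci(ci_in, threshold=config.coverage_threshold,
                    order=config.order)
        ci.ci_table.to_csv(out / "ci_table.tsv", sep="\t", index=False,
                           lineterminator="\n", float_format="%.6f")
        ci.curve_table().to_csv(out / "curve.tsv", sep="\t", index=False,
                                lineterminator="\n", float_format="%.6f")
        (out / "kgec.txt").write_text("".join(f"{c}\n" for c in ci.kgec))
        counts["ci_components"] = ci_in.m
        counts["kgec_size"] = len(ci.kgec)
        counts["kgec_coverage_percent"] = round(100 * ci.coverage_achieved, 2)
        counts["knapsack_value"] = ci.knapsack.value

        # 6. Enrichment validation: effective proteins and KGEC targets
        #    against the pathogenic-gene enrichment reference.
        pathways = PathwayCollection.from_gmt(config.pathways)
        res_dis = ora(set(disease), pathways, alpha=config.alpha,
                      adjust=config.adjust)
        res_eff = ora(set(space.effective_proteins), pathways,
                      alpha=config.alpha, adjust=config.adjust)
        kgec_targets = set().union(
            *(ci_in.lambda_sets[c] for c in ci.kgec)) if ci.kgec else set()
        res_kgec = ora(kgec_targets, pathways, alpha=config.alpha,
                       adjust=config.adjust)
        for name, res in (("enrichment_disease", res_dis),
                          ("enrichment_effective", res_eff),
                          ("enrichment_kgec", res_kgec)):
            res.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                       lineterminator="\n", float_format="%.6g")
        sig_dis = significant_pathways(res_dis)
        sig_eff = significant_pathways(res_eff)
        sig_kgec = significant_pathways(res_kgec)
        cov_eff = pathway_coverage(sig_eff, sig_dis) if sig_dis else None
        cov_kgec = pathway_coverage(sig_kgec, sig_dis) if sig_dis else None
        coverage_report = {
            "significant_pathways": {
                "disease_genes": len(sig_dis),
                "effective_proteins": len(sig_eff),
                "kgec_targets": len(sig_kgec),
            },
            "effective_vs_disease_percent":
                cov_eff.percent if cov_eff else None,
            "kgec_vs_disease_percent":
                cov_kgec.percent if cov_kgec else None,
        }
        with open(out / "coverage_report.yaml", "w") as fh:
            yaml.safe_dump(coverage_report, fh, sort_keys=True)
        counts["coverage"] = coverage_report
    except Exception as exc:
        manifest["failed_stage"] = _failed_stage_name(counts)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        raise

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline complete: %s", out / "manifest.yaml")
    return manifest


_STAGE_ORDER = [
    ("disease_network", "disease_network_nodes"),
    ("adme_screen", "active_components"),
    ("ct_network", "ct"),
    ("optimization_space", "effective_proteins"),
    ("ci_kgec", "kgec_size"),
    ("enrichment", "coverage"),
]


def _failed_stage_name(counts: dict) -> str:
    """First stage whose sentinel count is absent (= the one that failed)."""
    for stage, sentinel in _STAGE_ORDER:
        if sentinel not in counts:
            return stage
    return "finalize"
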