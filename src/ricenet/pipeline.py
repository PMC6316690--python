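"""End-to-end driver: counts -> DE screen -> two state networks -> candidates.

``run_all`` executes the whole analysis on either a simulated dataset or
a user-supplied count matrix, returns every intermediate object for
programmatic use, and (optionally) writes deterministic TSV/JSON/GraphML
outputs: with a fixed config and seed two runs produce byte-identical
tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import candidate_selection as cs
from . import expression as expr
from . import go_enrichment as go
from . import network_build as nb
from . import network_metrics as nm
from .exceptions import ConfigurationError, EmptyMatrixError
from .expression import CONDITIONS, CountMatrix
from .synthetic_data import SyntheticConfig, SyntheticTruth, generate_dataset, generate_annotations

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """All analysis parameters with their reference defaults."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    tau: float = 0.9
    alpha: float = 0.01
    hub_threshold: int = 200
    clustering_method: str = "mean_local"
    scaled_thresholds: bool = True
    low_degree: int = 50
    high_degree: int = 700
    n_go_terms: int = 12

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synthetic = SyntheticConfig.from_dict(raw.pop("synthetic", {}))
        unknown = set(raw) - {f for f in cls.__dataclass_fields__ if f != "synthetic"}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=synthetic, **raw)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "synthetic"
        }
        d["synthetic"] = self.synthetic.to_dict()
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    counts: CountMatrix
    truth: SyntheticTruth | None
    size_factors: pd.Series
    log_expr: pd.DataFrame
    de_table: pd.DataFrame
    de_sets: expr.DEGeneSets
    networks: dict
    metrics: dict
    summaries: dict
    thresholds: tuple
    candidates: pd.DataFrame
    candidates_de: pd.DataFrame
    enrichment: pd.DataFrame | None
    annotations: go.AnnotationSet | None


def build_state_networks(
    log_expr: pd.DataFrame, samples: pd.DataFrame, universe, tau: float
) -> dict:
    """One thresholded, isolate-free network per condition over the universe."""
    networks = {}
    for condition in CONDITIONS:
        ids = nb.condition_samples(samples, condition)
        graph = nb.correlation_graph(log_expr, ids, genes=universe, tau=tau)
        networks[condition] = nb.drop_isolated(graph)
    return networks


def run_all(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    counts: CountMatrix | None = None,
    truth: SyntheticTruth | None = None,
    annotations: go.AnnotationSet | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the full two-state analysis.

    Without ``counts`` a dataset is simulated from ``config.synthetic``
    (``seed`` overrides its seed and derives the annotation seed).  With
    real ``counts`` a user ``annotations`` set enables the enrichment
    stage.
    """
    config = config or PipelineConfig()
    if counts is None:
        syn = config.synthetic
        if seed is not None:
            from dataclasses import replace

            syn = replace(syn, seed=int(seed) % 2**31)
        counts, _, truth = generate_dataset(syn)
        if annotations is None:
            ann_universe = list(counts.gene_ids)
            annotations = generate_annotations(
                truth, ann_universe, seed=(syn.seed + 1) % 2**31, n_terms=config.n_go_terms
            )

    filtered = expr.filter_noninformative(counts)
    factors = expr.size_factors(filtered)
    log_expr = expr.log_expression(expr.normalize(filtered, factors))
    de = expr.de_table(log_expr, filtered.samples, alpha=config.alpha)
    de_sets = expr.classify_de(de, alpha=config.alpha)
    if not de_sets.union:
        raise EmptyMatrixError(
            "no differentially expressed gene at alpha="
            f"{config.alpha}; the network universe is empty"
        )

    networks = build_state_networks(log_expr, filtered.samples, de_sets.union, config.tau)
    for condition, graph in networks.items():
        if graph.n_nodes == 0:
            raise EmptyMatrixError(
                f"the {condition}-state network has no connected node at tau={config.tau}"
            )
    metrics = {c: nm.node_metrics(g) for c, g in networks.items()}
    summaries = {
        c: nm.summarize(
            g, hub_threshold=config.hub_threshold, clustering_method=config.clustering_method
        )
        for c, g in networks.items()
    }

    if config.scaled_thresholds:
        low, _ = cs.scale_thresholds(networks["normal"].n_nodes)
        _, high = cs.scale_thresholds(networks["stress"].n_nodes)
    else:
        low, high = config.low_degree, config.high_degree
    deg_normal = cs.align_degrees(de_sets.union, metrics["normal"])
    deg_stress = cs.align_degrees(de_sets.union, metrics["stress"])
    selected = cs.select_candidates(deg_normal, deg_stress, low, high)
    candidates = cs.build_candidate_table(
        selected, metrics["normal"], metrics["stress"], de_table=de
    )
    candidates_de = cs.de_intersected(candidates)

    enrichment = None
    if annotations is not None and len(candidates) > 0:
        restricted = {
            t: term
            for t, term in annotations.items()
            if term.genes & set(de_sets.union)
        }
        if restricted:
            enrichment = go.fisher_enrichment(
                list(candidates["gene"]), de_sets.union, restricted
            )

    result = PipelineResult(
        config=config,
        counts=filtered,
        truth=truth,
        size_factors=factors,
        log_expr=log_expr,
        de_table=de,
        de_sets=de_sets,
        networks=networks,
        metrics=metrics,
        summaries=summaries,
        thresholds=(low, high),
        candidates=candidates,
        candidates_de=candidates_de,
        enrichment=enrichment,
        annotations=annotations,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write all derived tables with fixed formatting (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.counts.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    result.size_factors.to_frame().to_csv(
        outdir / "size_factors.tsv", sep="\t", index_label="sample", float_format=FLOAT_FORMAT
    )
    result.de_table.to_csv(
        outdir / "de_table.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    for condition, graph in result.networks.items():
        graph.write_edgelist(outdir / f"network_{condition}_edges.tsv")
        graph.write_graphml(outdir / f"network_{condition}.graphml")
        result.metrics[condition].to_csv(
            outdir / f"node_metrics_{condition}.tsv", sep="\t", float_format=FLOAT_FORMAT
        )
        nm.degree_distribution(graph).to_csv(
            outdir / f"degree_distribution_{condition}.tsv", sep="\t", index=False
        )
        nm.clustering_distribution(
            result.metrics[condition]["cc_binary"]
        ).to_csv(
            outdir / f"clustering_distribution_{condition}.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FORMAT,
        )
    summary = pd.DataFrame(
        {c: s.to_dict() for c, s in result.summaries.items()}
    )
    summary.to_csv(outdir / "network_summary.tsv", sep="\t", index_label="property", float_format=FLOAT_FORMAT)
    result.candidates.to_csv(
        outdir / "candidates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    result.candidates_de.to_csv(
        outdir / "candidates_de.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    if result.enrichment is not None:
        result.enrichment.to_csv(
            outdir / "enrichment_candidates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
    meta = {
        "config": result.config.to_dict(),
        "thresholds": {"low": result.thresholds[0], "high": result.thresholds[1]},
        "n_de_union": len(result.de_sets.union),
    }
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
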