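"""Select switch-gene candidates by differential connectivity.

A candidate has few partners in the normal-state network (degree below
the scaled low threshold) and many in the salinity-state network (degree
above the scaled high threshold).  Thresholds scale the reference
fractions 50/1446 and 700/1446 to each network's connected-node count.
The table is evaluated against the simulation's ground truth.
"""

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from ricenet import candidate_selection as cs
from ricenet import expression as expr
from ricenet import network_metrics as nm
from ricenet.network_build import SignedWeightedGraph
from ricenet.synthetic_data import SyntheticTruth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    netdir = ROOT / "scratch" / "networks"
    results = ROOT / "results"
    graphs = {
        c: SignedWeightedGraph.from_networkx(nx.read_graphml(netdir / f"{c}.graphml"))
        for c in ("normal", "stress")
    }
    metrics = {c: nm.node_metrics(g) for c, g in graphs.items()}
    low, _ = cs.scale_thresholds(graphs["normal"].n_nodes)
    _, high = cs.scale_thresholds(graphs["stress"].n_nodes)
    print(
        f"scaled thresholds: degree_normal < {low} "
        f"(of {graphs['normal'].n_nodes} nodes), degree_stress > {high} "
        f"(of {graphs['stress'].n_nodes} nodes)"
    )

    universe = sorted(set(metrics["normal"].index) | set(metrics["stress"].index))
    deg_normal = cs.align_degrees(universe, metrics["normal"])
    deg_stress = cs.align_degrees(universe, metrics["stress"])
    small = cs.select_small_degree(deg_normal, low)
    print(f"{len(small)} small-degree genes in the normal-state network")
    selected = cs.select_stress_hubs(small, deg_stress, high)
    de = expr.read_de_table(results / "de_table.tsv")
    table = cs.build_candidate_table(selected, metrics["normal"], metrics["stress"], de_table=de)
    table.to_csv(results / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
    de_view = cs.de_intersected(table)
    de_view.to_csv(results / "candidates_de.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"{len(table)} candidates; {len(de_view)} also differentially expressed")

    truth = SyntheticTruth.from_json(ROOT / "scratch" / "simulated" / "truth.json")
    found = set(table["gene"])
    switch = truth.switch_genes
    evaluation = {
        "low_threshold": low,
        "high_threshold": high,
        "n_small_degree": len(small),
        "n_candidates": len(table),
        "n_candidates_de": len(de_view),
        "switch_recall": len(found & switch) / len(switch),
        "false_discovery_proportion": len(found - switch) / max(len(found), 1),
    }
    with open(results / "candidate_evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=1)
    print(
        f"against ground truth: recall {evaluation['switch_recall']:.2f}, "
        f"FDP {evaluation['false_discovery_proportion']:.2f}"
    )
    print(f"wrote candidate tables and evaluation to {results}")


if __name__ == "__main__":
    main()
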