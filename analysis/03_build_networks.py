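"""Build the normal-state and salinity-state co-expression networks.

Over the DE-union gene universe, each condition's samples (both stages
pooled) give a complete signed Pearson-correlation graph; pairs with
|r| >= 0.9 become binary edges and unconnected genes are dropped.
GraphML and edge lists go to scratch/networks/ for the metric scripts.
"""

from pathlib import Path

from ricenet import expression as expr
from ricenet import network_build as nb

ROOT = Path(__file__).resolve().parents[1]
TAU = 0.9
ALPHA = 0.01


def main() -> None:
    indir = ROOT / "scratch" / "simulated"
    cm = expr.CountMatrix.read(indir / "counts.tsv", indir / "samples.tsv")
    filtered = expr.filter_noninformative(cm)
    log_expr = expr.log_expression(expr.normalize(filtered, expr.size_factors(filtered)))
    table = expr.de_table(log_expr, filtered.samples, alpha=ALPHA)
    universe = expr.classify_de(table, alpha=ALPHA).union
    print(f"network universe: {len(universe)} DE genes; threshold |r| >= {TAU}")

    netdir = ROOT / "scratch" / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    for condition in ("normal", "stress"):
        ids = nb.condition_samples(filtered.samples, condition)
        graph = nb.correlation_graph(log_expr, ids, genes=universe, tau=TAU)
        graph = nb.drop_isolated(graph)
        graph.write_graphml(netdir / f"{condition}.graphml")
        graph.write_edgelist(netdir / f"{condition}_edges.tsv")
        print(
            f"  {condition}-state network: {graph.n_nodes} connected nodes, "
            f"{graph.n_edges} edges (from {len(ids)} samples)"
        )
    print(f"wrote GraphML + edge lists to {netdir}")


if __name__ == "__main__":
    main()
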