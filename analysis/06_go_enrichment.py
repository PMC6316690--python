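"""Functional enrichment of the DE genes and of the candidate list.

Per-stage DE gene lists are tested against all simulated genes;
the differential-connectivity candidates are tested against the DE
union (the universe they were selected from).  With planted annotations
the module term should dominate the candidate enrichment.
"""

from pathlib import Path

import pandas as pd

from ricenet import expression as expr
from ricenet import go_enrichment as go

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    indir = ROOT / "scratch" / "simulated"
    results = ROOT / "results"
    cm = expr.CountMatrix.read(indir / "counts.tsv", indir / "samples.tsv")
    all_genes = expr.filter_noninformative(cm).gene_ids
    de = expr.read_de_table(results / "de_table.tsv")
    sets = expr.classify_de(de, alpha=0.01)

    for stage in ("seedling", "booting"):
        annotations = go.load_annotations(indir / "annotations.gmt", all_genes)
        table = go.fisher_enrichment(sets.significant(stage), all_genes, annotations)
        table.to_csv(
            results / f"enrichment_{stage}.tsv", sep="\t", index=False, float_format="%.4g"
        )
        top = table.iloc[0]
        print(
            f"{stage} DE genes ({len(sets.significant(stage))}): top term "
            f"{top['term']} ({top['name']}), adjusted p = {top['p_adjusted']:.3g}"
        )

    candidates = pd.read_csv(results / "candidates.tsv", sep="\t")
    annotations = go.load_annotations(indir / "annotations.gmt", sets.union)
    table = go.fisher_enrichment(list(candidates["gene"]), sets.union, annotations)
    table.to_csv(
        results / "enrichment_candidates.tsv", sep="\t", index=False, float_format="%.4g"
    )
    top = table.iloc[0]
    print(
        f"candidates ({len(candidates)}) vs DE union ({len(sets.union)}): top term "
        f"{top['term']} ({top['name']}), odds ratio {top['odds_ratio']:.2f}, "
        f"adjusted p = {top['p_adjusted']:.3g}"
    )
    print(f"wrote enrichment tables to {results}")


if __name__ == "__main__":
    main()
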