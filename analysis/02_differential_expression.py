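"""Screen for salt-responsive genes, stage by stage.

Reads the simulated counts, removes all-zero genes, normalizes with
median-of-ratios size factors, and tests stress vs normal within each
stage (Welch t on log2 expression, BH adjustment per stage).  Writes the
full DE table and prints the stage-level counts — the union of the two
stages' significant genes is the universe both state networks are built
over.
"""

from pathlib import Path

from ricenet import expression as expr

ROOT = Path(__file__).resolve().parents[1]
ALPHA = 0.01


def main() -> None:
    indir = ROOT / "scratch" / "simulated"
    cm = expr.CountMatrix.read(indir / "counts.tsv", indir / "samples.tsv")
    filtered = expr.filter_noninformative(cm)
    dropped = len(cm.gene_ids) - len(filtered.gene_ids)
    factors = expr.size_factors(filtered)
    log_expr = expr.log_expression(expr.normalize(filtered, factors))
    table = expr.de_table(log_expr, filtered.samples, alpha=ALPHA)
    sets = expr.classify_de(table, alpha=ALPHA)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "de_table.tsv", sep="\t", index=False, float_format="%.4g")

    print(f"{dropped} non-informative gene(s) removed; {len(filtered.gene_ids)} tested")
    print(f"size factors span {factors.min():.2f}-{factors.max():.2f}")
    for stage in ("seedling", "booting"):
        print(
            f"  {stage}: {len(sets.up[stage])} up, {len(sets.down[stage])} down "
            f"(adjusted p < {ALPHA})"
        )
    print(
        f"DE union: {len(sets.union)} genes "
        f"({len(sets.seedling_only)} seedling-only, {len(sets.booting_only)} booting-only, "
        f"{len(sets.both)} in both stages)"
    )
    print(f"wrote {results / 'de_table.tsv'}")


if __name__ == "__main__":
    main()
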