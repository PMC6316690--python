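"""Simulate the two-condition RNA-seq experiment used by the analysis.

Generates the standard synthetic regime — 600 genes, one 60-gene
co-expression module containing 20 switch genes, two conditions x two
stages x 10 replicates — and writes the raw dataset (counts, sample
sheet, ground truth, synthetic GO annotations) under scratch/simulated/.
Downstream scripts (02-06) read from there; derived tables go to
results/.
"""

from pathlib import Path

from ricenet.go_enrichment import write_gmt
from ricenet.synthetic_data import SyntheticConfig, generate_annotations, generate_dataset, write_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    cm, samples, truth = generate_dataset(config)
    outdir = ROOT / "scratch" / "simulated"
    write_dataset(cm, truth, outdir)
    annotations = generate_annotations(truth, cm.gene_ids, seed=SEED + 1)
    write_gmt(annotations, outdir / "annotations.gmt")

    n_module = sum(m is not None for m in truth.module_assignment_stress.values())
    print(f"simulated {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples (seed {SEED})")
    print(f"  planted module members: {n_module} ({len(truth.switch_genes)} switch genes)")
    print(f"  planted DE genes: {len(truth.de_genes)}")
    print(f"  library-size range: {cm.counts.sum().min()}-{cm.counts.sum().max()} reads")
    print(f"wrote counts/samples/truth/annotations to {outdir}")


if __name__ == "__main__":
    main()
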