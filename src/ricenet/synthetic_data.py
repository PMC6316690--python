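"""Synthetic two-condition RNA-seq count matrices with known ground truth.

The generator emulates the data regime of a two-condition (normal vs
salt stress) x two-stage (seedling vs booting) replicated RNA-seq
experiment at desk scale, with every feature the downstream network
analysis keys on planted explicitly:

* co-expression modules: genes in a module share a per-sample latent
  factor; the within-module correlation target is ``rho_normal`` under
  the normal condition and ``rho_stress`` under stress, and a fraction
  of members load negatively (planting negative correlations);
* switch genes: module members whose loading is zeroed under the normal
  condition, so they are near-isolated in the normal-state network but
  highly connected under stress — the differential-connectivity
  phenotype candidate selection is meant to recover;
* differentially expressed genes: mean shifts of at least two-fold
  under stress in an assigned stage.  Module members model a coherent
  salt-response program: they are all DE (up, in both stages, effect
  sizes from the upper half of ``log2fc_range``) so the program enters
  the DE gene universe the networks are built over and its stress
  correlations are not broken by stage-specific mean shifts; remaining
  DE genes get random stage/direction and the full effect-size range;
* negative-binomial counts with variance ``mu + dispersion * mu**2``
  and per-sample library-size factors drawn log-uniform in [0.5, 2] to
  exercise normalization.

Latent model, per condition c and sample s: a module factor
``f_{m,s} ~ N(0,1)`` per module; for gene g in module m,
``z = sign_g * sqrt(rho_c) * f_{m,s} + sqrt(1 - rho_c) * eps``; for
unassigned genes ``z = eps``.  The count mean is
``mu = libsize_s * exp(mean_log_expression + beta_g * 1[c=stress] + z)``
with ``beta_g = +/- log2fc * ln 2`` for DE genes in their DE stage.

All randomness flows from one seeded generator: identical configs
(including seed) give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expression import CountMatrix, CONDITIONS, STAGES
from .go_enrichment import AnnotationSet, GoTerm

LN2 = float(np.log(2.0))


@dataclass
class SyntheticConfig:
    """Simulation parameters; defaults are the package's standard regime.

    The defaults describe a 600-gene experiment with one 60-gene
    co-expression module containing 20 switch genes, 25% DE genes with
    2- to 32-fold shifts, tight module correlation under stress
    (rho 0.95) and slightly looser under normal (rho 0.9), mild
    count-level overdispersion (0.01), and 10 replicates per
    condition x stage cell (20 samples per condition).
    """

    n_genes: int = 600
    n_modules: int = 1
    module_sizes: tuple = (60,)
    rho_normal: float = 0.9
    rho_stress: float = 0.95
    frac_negative: float = 0.2
    n_switch: int = 20
    frac_de: float = 0.25
    log2fc_range: tuple = (2.0, 5.0)
    nb_dispersion: float = 0.01
    mean_log_expression: float = 8.0
    replicates_per_cell: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_modules != len(self.module_sizes):
            raise ConfigurationError("n_modules must match len(module_sizes)")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("module sizes sum above n_genes")
        for rho in (self.rho_normal, self.rho_stress):
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError("correlation targets must lie in [0, 1)")
        if not 0.0 <= self.frac_negative <= 1.0:
            raise ConfigurationError("frac_negative must lie in [0, 1]")
        if self.n_switch < 0 or self.n_switch > sum(self.module_sizes):
            raise ConfigurationError("n_switch must lie in [0, sum(module_sizes)]")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError("frac_de must lie in [0, 1]")
        low, high = self.log2fc_range
        if low < 1.0 or high < low:
            raise ConfigurationError("log2fc_range must satisfy 1 <= low <= high")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.replicates_per_cell < 2:
            raise ConfigurationError(
                "replicates_per_cell must be >= 2 (correlation undefined below)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["log2fc_range"] = list(self.log2fc_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "module_sizes" in d:
            d["module_sizes"] = tuple(d["module_sizes"])
        if "log2fc_range" in d:
            d["log2fc_range"] = tuple(d["log2fc_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``module_assignment_normal`` maps switch genes to ``None`` (their
    loading is zeroed under normal) while ``module_assignment_stress``
    keeps them in their module; ``de_genes`` maps each planted DE gene
    to its (stage, direction, log2fc).  Switch genes are always a
    subset of the DE genes.
    """

    module_assignment_normal: dict
    module_assignment_stress: dict
    loading_sign: dict
    switch_genes: set
    de_genes: dict

    def to_json(self, path) -> None:
        payload = {
            "module_assignment_normal": self.module_assignment_normal,
            "module_assignment_stress": self.module_assignment_stress,
            "loading_sign": self.loading_sign,
            "switch_genes": sorted(self.switch_genes),
            "de_genes": {
                g: {"stage": s, "direction": d, "log2fc": f}
                for g, (s, d, f) in sorted(self.de_genes.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_assignment_normal=payload["module_assignment_normal"],
            module_assignment_stress=payload["module_assignment_stress"],
            loading_sign=payload["loading_sign"],
            switch_genes=set(payload["switch_genes"]),
            de_genes={
                g: (v["stage"], v["direction"], v["log2fc"])
                for g, v in payload["de_genes"].items()
            },
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate counts, sample sheet and ground truth from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_genes = config.n_genes

    # module membership: contiguous blocks from the top of the gene list
    module_of = np.full(n_genes, -1)
    start = 0
    for m, size in enumerate(config.module_sizes):
        module_of[start : start + size] = m
        start += size
    member_idx = np.nonzero(module_of >= 0)[0]

    sign = np.ones(n_genes)
    neg = rng.random(len(member_idx)) < config.frac_negative
    sign[member_idx[neg]] = -1.0

    switch_idx = rng.choice(member_idx, size=config.n_switch, replace=False)
    is_switch = np.zeros(n_genes, dtype=bool)
    is_switch[switch_idx] = True

    # planted DE genes: the whole module is a coherent stress-induced
    # program (up, both stages, strong shifts); remaining DE genes are
    # drawn from the non-module genes with random stage and direction
    n_de = max(int(round(config.frac_de * n_genes)), len(member_idx))
    non_member = np.nonzero(module_of < 0)[0]
    extra_idx = rng.choice(
        non_member, size=min(n_de - len(member_idx), len(non_member)), replace=False
    )
    lo, hi = config.log2fc_range
    mid = (lo + hi) / 2.0
    de_genes: dict[str, tuple] = {}
    for i in sorted(member_idx):
        de_genes[genes[i]] = ("both", "up", float(rng.uniform(mid, hi)))
    stage_choices = ("seedling", "booting", "both")
    for i in sorted(extra_idx):
        stage = stage_choices[rng.choice(3, p=(0.475, 0.475, 0.05))]
        direction = "up" if rng.random() < 0.5 else "down"
        de_genes[genes[i]] = (stage, direction, float(rng.uniform(lo, hi)))

    # sample sheet, fixed order: condition-major, then stage, then replicate
    records = []
    for condition in CONDITIONS:
        for stage in STAGES:
            for rep in range(1, config.replicates_per_cell + 1):
                records.append(
                    {
                        "sample": f"{condition}_{stage}_r{rep:02d}",
                        "condition": condition,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(records).set_index("sample")
    n_samples = len(samples)
    libsize = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))

    rho = {"normal": config.rho_normal, "stress": config.rho_stress}
    condition_arr = samples["condition"].to_numpy()
    stage_arr = samples["stage"].to_numpy()

    factors = rng.standard_normal((config.n_modules, n_samples))
    eps = rng.standard_normal((n_genes, n_samples))
    z = eps.copy()
    for cond in CONDITIONS:
        cols = condition_arr == cond
        r = rho[cond]
        for i in member_idx:
            if cond == "normal" and is_switch[i]:
                continue  # zeroed loading: pure noise under normal
            m = module_of[i]
            z[i, cols] = sign[i] * np.sqrt(r) * factors[m, cols] + np.sqrt(1.0 - r) * eps[i, cols]

    beta = np.zeros((n_genes, n_samples))
    stress_cols = condition_arr == "stress"
    for gene, (stage, direction, log2fc) in de_genes.items():
        i = genes.index(gene)
        if stage == "both":
            cols = stress_cols
        else:
            cols = stress_cols & (stage_arr == stage)
        beta[i, cols] = (1.0 if direction == "up" else -1.0) * log2fc * LN2

    mu = libsize[None, :] * np.exp(config.mean_log_expression + beta + z)
    alpha = config.nb_dispersion
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples.index),
        samples=samples,
    )
    truth = SyntheticTruth(
        module_assignment_normal={
            g: (int(module_of[i]) if module_of[i] >= 0 and not is_switch[i] else None)
            for i, g in enumerate(genes)
        },
        module_assignment_stress={
            g: (int(module_of[i]) if module_of[i] >= 0 else None)
            for i, g in enumerate(genes)
        },
        loading_sign={g: int(sign[i]) for i, g in enumerate(genes)},
        switch_genes={genes[i] for i in switch_idx},
        de_genes=de_genes,
    )
    return cm, samples, truth


def generate_annotations(
    truth: SyntheticTruth,
    gene_ids,
    seed: int,
    n_terms: int = 12,
    term_size_range: tuple = (10, 80),
) -> AnnotationSet:
    """Synthetic GO-style annotation set for enrichment testing.

    One term collects the stress-module members (the planted salt-response
    gene set, diluted with a few random genes); the remaining terms are
    random gene sets, so planted candidates should enrich the module term
    and nothing else systematically.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    module_genes = sorted(
        g for g, m in truth.module_assignment_stress.items() if m is not None
    )
    extra = rng.choice(
        [g for g in gene_ids if g not in set(module_genes)],
        size=max(2, len(module_genes) // 10),
        replace=False,
    )
    annotations: AnnotationSet = {
        "GO:SYN0001": GoTerm(
            "GO:SYN0001",
            "response to salt stress (planted module)",
            "BP",
            frozenset(module_genes) | frozenset(extra.tolist()),
        )
    }
    namespaces = ("BP", "MF", "CC")
    lo, hi = term_size_range
    for t in range(2, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        term_id = f"GO:SYN{t:04d}"
        annotations[term_id] = GoTerm(
            term_id,
            f"synthetic term {t}",
            namespaces[t % 3],
            frozenset(members.tolist()),
        )
    return annotations


def write_dataset(cm: CountMatrix, truth: SyntheticTruth, outdir) -> None:
    """Write counts TSV, sample sheet TSV and truth JSON into a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.write(outdir / "counts.tsv", outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")
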