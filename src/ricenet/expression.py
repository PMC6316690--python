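"""Count handling, normalization and the differential-expression screen.

The screen that feeds the network stages works on a genes x samples count
matrix with a sample sheet assigning each library to a condition
(``normal`` / ``stress``) and developmental stage (``seedling`` /
``booting``).  Processing follows the usual RNA-seq path:

1. drop genes whose counts are zero in every sample (non-informative),
2. per-sample size factors by the median-of-ratios rule,
3. per-stage two-group comparison of stress vs normal on
   ``log2(normalized + 1)`` with a Welch t-test,
4. Benjamini-Hochberg adjustment within each stage's test family and an
   up/down/ns call at ``p_adj < alpha``.

The Welch test is a deliberately simple stand-in for a negative-binomial
DE engine; downstream network construction only consumes the resulting
gene lists, and externally computed DE tables can be imported with
:func:`read_de_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyMatrixError, InputError

CONDITIONS = ("normal", "stress")
STAGES = ("seedling", "booting")

SAMPLE_COLUMNS = ("condition", "stage", "replicate")


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts plus sample metadata.

    ``counts`` is indexed by gene id with one column per sample;
    ``samples`` is indexed by sample id with columns
    ``condition``, ``stage`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise InputError("duplicate gene ids in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            raise InputError("count matrix columns do not match sample sheet")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise InputError(f"sample sheet missing column {col!r}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise InputError(f"unknown condition(s): {sorted(bad_cond)}")
        bad_stage = set(self.samples["stage"]) - set(STAGES)
        if bad_stage:
            raise InputError(f"unknown stage(s): {sorted(bad_stage)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise InputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountMatrix":
        return replace(self, counts=self.counts.loc[list(genes)])

    # -- I/O -----------------------------------------------------------------

    def write(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts=counts, samples=samples)


def filter_noninformative(cm: CountMatrix) -> CountMatrix:
    """Remove genes whose counts are zero in every sample.

    Gene order is preserved.  Raises :class:`EmptyMatrixError` when no
    gene survives.
    """
    keep = (cm.counts.to_numpy() > 0).any(axis=1)
    if not keep.any():
        raise EmptyMatrixError("all genes have zero counts in every sample")
    return replace(cm, counts=cm.counts.loc[keep])


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    For sample *j* the factor is the median over reference genes of
    ``counts[g, j] / geometric_mean_g`` where the reference set is the
    genes with strictly positive counts in all samples.  If no such gene
    exists the geometric mean is taken over each gene's positive entries
    and the per-sample median runs over genes with a positive count in
    that sample (logged fallback); if a sample still has no usable gene
    an :class:`InputError` is raised.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        log_geo = logx[all_positive].mean(axis=1)
        ratios = np.exp(logx[all_positive] - log_geo[:, None])
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no gene with positive counts in all samples; "
            "falling back to per-sample positive-count medians",
            stacklevel=2,
        )
        factors = np.empty(x.shape[1])
        pos = x > 0
        informative = pos.any(axis=1)
        log_geo = np.full(x.shape[0], np.nan)
        for g in np.nonzero(informative)[0]:
            log_geo[g] = logx[g, pos[g]].mean()
        for j in range(x.shape[1]):
            usable = pos[:, j] & informative
            if not usable.any():
                raise InputError(f"size factor undefined for sample {counts.columns[j]!r}")
            factors[j] = np.median(np.exp(logx[usable, j] - log_geo[usable]))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise InputError("size factors must be positive and cover all samples")
    return counts / factors


def log_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """``log2(normalized + 1)`` — the scale used for testing and correlation."""
    return np.log2(normalized + 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    log_expr: pd.DataFrame, samples: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Per-gene Welch two-sample comparison, stress vs normal, within a stage.

    ``log_expr`` must already be on the log2 scale.  Returns a frame with
    columns ``gene``, ``stage``, ``log2fc`` (mean stress minus mean
    normal) and ``p_raw``.  When both groups have zero variance, p is 1
    for equal means and 0 otherwise (degenerate-separation convention).
    """
    if stage not in STAGES:
        raise InputError(f"unknown stage {stage!r}")
    in_stage = samples["stage"] == stage
    stress_ids = samples.index[in_stage & (samples["condition"] == "stress")]
    normal_ids = samples.index[in_stage & (samples["condition"] == "normal")]
    if len(stress_ids) < 2 or len(normal_ids) < 2:
        raise InputError("need at least two replicates per group")
    x = log_expr[stress_ids].to_numpy(dtype=float)
    y = log_expr[normal_ids].to_numpy(dtype=float)
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    log2fc = mx - my

    se2 = vx / nx + vy / ny
    p = np.ones(len(log2fc))
    ok = se2 > 0
    t = log2fc[ok] / np.sqrt(se2[ok])
    df = se2[ok] ** 2 / (
        (vx[ok] / nx) ** 2 / (nx - 1) + (vy[ok] / ny) ** 2 / (ny - 1)
    )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = ~ok & (log2fc != 0)
    p[degenerate] = 0.0
    return pd.DataFrame(
        {"gene": log_expr.index, "stage": stage, "log2fc": log2fc, "p_raw": p}
    ).reset_index(drop=True)


def de_table(
    log_expr: pd.DataFrame, samples: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Full DE table over both stages with BH adjustment and up/down calls.

    Adjustment is performed within each stage's family of tests.  The
    ``call`` column is ``up``/``down`` for significant genes
    (``p_adj < alpha``) by the sign of ``log2fc``, else ``ns``.
    """
    parts = []
    for stage in STAGES:
        part = differential_expression(log_expr, samples, stage)
        part["p_adj"] = bh_adjust(part["p_raw"].to_numpy())
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    sig = table["p_adj"] < alpha
    table["call"] = "ns"
    table.loc[sig & (table["log2fc"] > 0), "call"] = "up"
    table.loc[sig & (table["log2fc"] <= 0), "call"] = "down"
    return table


def read_de_table(path) -> pd.DataFrame:
    """Import an externally computed DE table (gene, stage, log2fc, p_adj[, ...]).

    Adds ``call`` if absent using ``p_adj < 0.01`` and the fold-change sign,
    so tables from dedicated count-based DE engines can drive the network
    stages directly.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "stage", "log2fc", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"DE table missing columns: {sorted(missing)}")
    if "call" not in table.columns:
        sig = table["p_adj"] < 0.01
        table["call"] = "ns"
        table.loc[sig & (table["log2fc"] > 0), "call"] = "up"
        table.loc[sig & (table["log2fc"] <= 0), "call"] = "down"
    return table


@dataclass
class DEGeneSets:
    """Significant genes per stage and the union universe."""

    up: dict[str, list[str]]
    down: dict[str, list[str]]
    union: list[str]
    seedling_only: list[str]
    booting_only: list[str]
    both: list[str]

    def significant(self, stage: str) -> list[str]:
        return self.up[stage] + self.down[stage]


def classify_de(table: pd.DataFrame, alpha: float = 0.01) -> DEGeneSets:
    """Partition significant genes by stage and direction; build the union.

    The union (genes significant in at least one stage) is the node
    universe for both state networks.  Gene order within each list
    follows the input table.
    """
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    sig_sets: dict[str, set[str]] = {}
    for stage in STAGES:
        part = table[table["stage"] == stage]
        sig = part[part["p_adj"] < alpha]
        up[stage] = list(sig.loc[sig["log2fc"] > 0, "gene"])
        down[stage] = list(sig.loc[sig["log2fc"] <= 0, "gene"])
        sig_sets[stage] = set(up[stage]) | set(down[stage])
    seen: set[str] = set()
    union: list[str] = []
    for stage in STAGES:
        for g in up[stage] + down[stage]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    both = sorted(sig_sets["seedling"] & sig_sets["booting"])
    return DEGeneSets(
        up=up,
        down=down,
        union=union,
        seedling_only=sorted(sig_sets["seedling"] - sig_sets["booting"]),
        booting_only=sorted(sig_sets["booting"] - sig_sets["seedling"]),
        both=both,
    )
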