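"""Two-state differential-connectivity candidate selection.

Candidate salt-response genes are those with few partners in the
normal-state network (degree strictly below a low threshold) that become
hubs in the salinity-state network (degree strictly above a high
threshold).  The reference thresholds are degree < 50 and degree > 700
on networks of ~1446 connected nodes; for smaller networks the same
fractions of the node count can be used (``scale_thresholds``).

Genes in the shared universe that were dropped as isolates from one
network count as degree 0 there — being partnerless is exactly the
normal-state half of the phenotype.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InputError

REFERENCE_NODES = 1446
FRAC_LOW = 50 / REFERENCE_NODES
FRAC_HIGH = 700 / REFERENCE_NODES


def align_degrees(universe, metrics: pd.DataFrame, column: str = "degree") -> pd.Series:
    """Metric values over a gene universe, 0 for genes absent from the network."""
    return metrics[column].reindex(list(universe)).fillna(0.0)


def select_small_degree(degrees_normal: pd.Series, low_threshold: int = 50) -> list[str]:
    """Genes with normal-state degree strictly below the threshold."""
    return list(degrees_normal.index[degrees_normal < low_threshold])


def select_stress_hubs(
    candidates, degrees_stress: pd.Series, high_threshold: int = 700
) -> list[str]:
    """Subset of candidates with stress-state degree strictly above the threshold.

    Candidates missing from the stress metric table are excluded with a
    warning (they cannot be hubs there).
    """
    selected = []
    missing = []
    for gene in candidates:
        if gene not in degrees_stress.index:
            missing.append(gene)
        elif degrees_stress[gene] > high_threshold:
            selected.append(gene)
    if missing:
        warnings.warn(
            f"{len(missing)} candidate(s) absent from the stress network; excluded",
            stacklevel=2,
        )
    return selected


def scale_thresholds(
    n_nodes: int, frac_low: float = FRAC_LOW, frac_high: float = FRAC_HIGH
) -> tuple[int, int]:
    """Degree thresholds proportional to network size.

    ``low = round(frac_low * n_nodes)`` (clamped to >= 1 so the strict
    "< low" filter stays satisfiable by isolated genes) and
    ``high = round(frac_high * n_nodes)``.  The reference network size
    recovers (50, 700) exactly.
    """
    if n_nodes <= 0:
        raise InputError("n_nodes must be positive")
    low = max(1, int(round(frac_low * n_nodes)))
    high = max(1, int(round(frac_high * n_nodes)))
    return low, high


def build_candidate_table(
    selected,
    metrics_normal: pd.DataFrame,
    metrics_stress: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    annotations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotated candidate table, sorted by stress degree (desc), ties by gene.

    Joins both networks' node metrics (0 where a gene is absent), the DE
    stage/direction of each gene (``none`` when the gene is not in the
    DE table or not significant) and optional free-text annotations.
    Use :func:`de_intersected` for the view restricted to DE genes.
    """
    selected = list(selected)
    columns = ["degree", "weighted_degree", "cc_binary", "cc_onnela"]
    rows: dict[str, list] = {"gene": selected}
    for suffix, metrics in (("normal", metrics_normal), ("stress", metrics_stress)):
        for col in columns:
            aligned = metrics[col].reindex(selected).fillna(0.0)
            rows[f"{col}_{suffix}"] = aligned.to_numpy()
    table = pd.DataFrame(rows)

    de_stage = {}
    de_direction = {}
    if de_table is not None:
        sig = de_table[de_table["call"] != "ns"]
        for gene, part in sig.groupby("gene"):
            stages = set(part["stage"])
            de_stage[gene] = "both" if len(stages) == 2 else next(iter(stages))
            calls = set(part["call"])
            de_direction[gene] = next(iter(calls)) if len(calls) == 1 else "mixed"
    table["de_stage"] = [de_stage.get(g, "none") for g in table["gene"]]
    table["de_direction"] = [de_direction.get(g, "none") for g in table["gene"]]
    table["annotation"] = [
        (annotations or {}).get(g, "") for g in table["gene"]
    ]
    table["degree_normal"] = table["degree_normal"].astype(int)
    table["degree_stress"] = table["degree_stress"].astype(int)
    return table.sort_values(
        ["degree_stress", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def de_intersected(table: pd.DataFrame) -> pd.DataFrame:
    """Candidates that are also differentially expressed in >= 1 stage."""
    return table[table["de_stage"] != "none"].reset_index(drop=True)


def select_candidates(
    degrees_normal: pd.Series,
    degrees_stress: pd.Series,
    low_threshold: int,
    high_threshold: int,
) -> list[str]:
    """Full two-state filter: degree_normal < low and degree_stress > high."""
    small = select_small_degree(degrees_normal, low_threshold)
    return select_stress_hubs(small, degrees_stress, high_threshold)
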