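"""GO over-representation analysis with Fisher's exact test.

For each term the 2x2 table (in-list/out-of-list x in-term/out-of-term)
over a fixed gene universe is tested one-sided for over-representation;
the p-value is the upper hypergeometric tail P(X >= k).  The reported
odds ratio is the sample estimate a*d / (b*c) (a conditional-MLE
estimate is available as an option), and p-values are BH-adjusted across
all terms tested in the run, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .expression import bh_adjust

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC", "NA")


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    name: str
    namespace: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise InputError(f"term {self.term_id} has no genes")


AnnotationSet = dict


def _parse_description(desc: str) -> tuple[str, str]:
    # GMT description field "name|BP" carries the namespace; plain names get NA
    if "|" in desc:
        name, namespace = desc.rsplit("|", 1)
        if namespace in NAMESPACES:
            return name, namespace
    return desc, "NA"


def load_annotations(path, universe) -> AnnotationSet:
    """Read a GMT (``term<TAB>description<TAB>gene...``) or two-column
    ``gene<TAB>term`` TSV, restricted to a gene universe.

    Genes outside the universe are dropped (count logged); terms left
    empty are removed; duplicate term ids are an error.
    """
    universe = set(universe)
    raw: dict[str, tuple[str, str, set]] = {}
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    is_gmt = any(len(line.split("\t")) > 2 for line in lines)
    if is_gmt:
        for line in lines:
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed GMT line: {line[:50]!r}")
            term_id, desc, genes = fields[0], fields[1], fields[2:]
            if term_id in raw:
                raise InputError(f"duplicate term id {term_id!r}")
            name, namespace = _parse_description(desc)
            raw[term_id] = (name, namespace, set(genes))
    else:
        pairs: dict[str, set] = {}
        for line in lines:
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputError(f"malformed gene-term line: {line[:50]!r}")
            gene, term_id = fields
            pairs.setdefault(term_id, set()).add(gene)
        raw = {t: (t, "NA", genes) for t, genes in pairs.items()}

    annotations: AnnotationSet = {}
    n_dropped = 0
    for term_id, (name, namespace, genes) in raw.items():
        kept = genes & universe
        n_dropped += len(genes) - len(kept)
        if kept:
            annotations[term_id] = GoTerm(term_id, name, namespace, frozenset(kept))
    if n_dropped:
        logger.info("dropped %d gene annotations outside the universe", n_dropped)
    return annotations


def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(annotations):
            term = annotations[term_id]
            desc = f"{term.name}|{term.namespace}"
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term_id}\t{desc}\t{genes}\n")


def fisher_pvalue_greater(k, K, n, N):
    """One-sided over-representation p-value P(X >= k), X ~ Hypergeom(N, K, n).

    Vectorized over array inputs.
    """
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, N, K, n)


def _odds_ratio(a: int, b: int, c: int, d: int, estimator: str) -> float:
    if estimator == "sample":
        if b * c == 0:
            return float("nan")
        return a * d / (b * c)
    if estimator == "conditional":
        return float(
            stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic
        )
    raise InputError(f"unknown odds-ratio estimator {estimator!r}")


def fisher_enrichment(
    gene_list,
    universe,
    annotations: AnnotationSet,
    odds_ratio: str = "sample",
) -> pd.DataFrame:
    """Per-term enrichment table sorted by raw p-value.

    Columns: term, name, type, k (list genes in term), K (term size),
    n (list size), N (universe size), p_value, odds_ratio, p_adjusted.
    The odds ratio is NaN when its denominator cell product b*c is 0
    while a*d > 0 (no finite estimate), and 0 for a disjoint list.
    """
    gene_list = set(gene_list)
    universe = set(universe)
    if not gene_list:
        raise InputError("empty gene list")
    if len(universe) < 2:
        raise InputError("universe must contain at least two genes")
    if not gene_list <= universe:
        raise InputError("gene list must be a subset of the universe")
    N, n = len(universe), len(gene_list)
    rows = []
    for term_id in sorted(annotations):
        term = annotations[term_id]
        term_genes = term.genes & universe
        if not term_genes:
            continue
        K = len(term_genes)
        if K > N:
            raise InputError(f"term {term_id} larger than the universe")
        a = len(gene_list & term_genes)
        b = n - a
        c = K - a
        d = N - K - b
        rows.append(
            {
                "term": term_id,
                "name": term.name,
                "type": term.namespace,
                "k": a,
                "K": K,
                "n": n,
                "N": N,
                "p_value": float(fisher_pvalue_greater(a, K, n, N)),
                "odds_ratio": _odds_ratio(a, b, c, d, odds_ratio),
            }
        )
    if not rows:
        raise InputError("no annotated term overlaps the universe")
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.minimum(bh_adjust(table["p_value"].to_numpy()), 1.0)
    return table.sort_values(["p_value", "term"]).reset_index(drop=True)
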