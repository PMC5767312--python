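"""Singular enrichment analysis (SEA) of GO terms.

One input gene list is tested per term against a user-supplied annotated
background with the upper-tail hypergeometric distribution. Annotations
are first propagated up the ontology DAG (true-path rule: a gene annotated
to a term is implicitly annotated to every ancestor via is_a / part_of
edges). A term is reported significant when its input-list mapping count
reaches the minimum mapping entries (default 5) and its p-value is at or
below the significance level (default raw p = 0.01; an optional BH switch
is available but off by default, matching the convention of SEA tools
whose reported term p-values are unadjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

from droughtprime.diffexpr import bh_adjust


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    x: int  # input genes annotated to the term
    n: int  # annotated input genes
    K: int  # background genes annotated to the term
    N: int  # annotated background genes
    p: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts for {self.term}: x={self.x}, n={self.n}, K={self.K}, N={self.N}"
            )


def check_dag(dag: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise OntologyError(f"ontology graph contains a cycle: {cycle}")


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], dag: nx.DiGraph
) -> dict[str, set[str]]:
    """True-path propagation: annotate each gene to every ancestor of each
    of its direct terms. Edges point child → parent. Idempotent."""
    check_dag(dag)
    ancestors: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        full: set[str] = set()
        for term in terms:
            full.add(term)
            if term in dag:
                if term not in ancestors:
                    # descendants along child→parent edges = ontology ancestors
                    ancestors[term] = nx.descendants(dag, term)
                full |= ancestors[term]
        out[gene] = full
    return out


def hypergeometric_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X ≥ x) for X ~ Hypergeometric(N, K, n).

    N: background size, K: background genes with the term, n: input size,
    x: input genes with the term. Stable in log space for large N.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(n, K)):
        raise ValueError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, x={x}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(
    input_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    dag: nx.DiGraph | None = None,
    p_threshold: float = 0.01,
    min_mapping: int = 5,
    descriptions: Mapping[str, str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric SEA over every term carried by the background.

    Genes without any GO annotation are excluded from both the background
    count N and the input count n; input genes outside the background are
    dropped with a warning. Results are sorted by p. When ``bh_correct``
    is on, the significance gate applies to BH-adjusted values instead of
    raw p (reported in a ``q`` column either way).
    """
    background = set(background_genes)
    inp = set(input_genes)
    stray = inp - background
    if stray:
        warnings.warn(
            f"{len(stray)} input gene(s) not in background were dropped", stacklevel=2
        )
        inp &= background

    if dag is not None:
        ann = propagate_annotations(
            {g: t for g, t in annotations.items() if g in background}, dag
        )
    else:
        ann = {g: set(t) for g, t in annotations.items() if g in background}

    annotated_bg = {g for g, t in ann.items() if t}
    annotated_inp = inp & annotated_bg
    if not annotated_inp:
        raise ValueError("no annotated genes in the input list")

    N, n = len(annotated_bg), len(annotated_inp)
    term_bg: dict[str, int] = {}
    term_inp: dict[str, int] = {}
    for gene in annotated_bg:
        for term in ann[gene]:
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in annotated_inp:
                term_inp[term] = term_inp.get(term, 0) + 1

    rows = []
    for term, K in sorted(term_bg.items()):
        x = term_inp.get(term, 0)
        p = hypergeometric_upper_tail(N, K, n, x)
        rows.append(
            {
                "term": term,
                "description": (descriptions or {}).get(term, ""),
                "x": x,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    gate = table["q"] if bh_correct else table["p"]
    table["significant"] = (table["x"] >= min_mapping) & (gate <= p_threshold)
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    # container invariants, checked on every run
    for row in table.itertuples():
        EnrichmentResult(
            term=row.term, description=row.description, x=row.x, n=row.n,
            K=row.K, N=row.N, p=row.p, significant=row.significant,
        )
    return table
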