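"""Over-representation analysis of a gene list against gene-set collections.

For each gene set the 2x2 contingency table is laid out as in the classic
annotation-tool convention: a = list genes with the annotation, b = list
genes without, c = genome genes (excluding the list) with the annotation,
d = genome genes (excluding the list) without.  The p-value is the one-sided
Fisher exact test for over-representation — the hypergeometric upper tail
P(X >= a) with population N = a+b+c+d, K = a+c annotated genes and n = a+b
draws — computed in log space via scipy's survival function.  Raw p-values
are reported; Benjamini-Hochberg adjustment is an opt-in extra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import false_discovery_control, hypergeom

from .io import GeneSet


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d counts: list-with/without annotation, rest-of-genome with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def population(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def annotated(self) -> int:  # K: annotated genes in the universe
        return self.a + self.c

    @property
    def list_size(self) -> int:  # n: draws
        return self.a + self.b


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    table: ContingencyTable
    p_value: float
    q_value: float | None = None


def build_contingency(
    gene_list: Iterable[str],
    gene_set: GeneSet,
    universe: Iterable[str],
) -> ContingencyTable:
    """Count the 2x2 overlap of *gene_list* with *gene_set* inside *universe*.

    The gene set is intersected with the universe before counting; a list
    gene outside the universe is an error.
    """
    L = set(gene_list)
    U = set(universe)
    outside = L - U
    if outside:
        raise ValueError(
            f"gene(s) in list but not in universe: {sorted(outside)[:5]}"
        )
    S = gene_set.members & U
    a = len(L & S)
    return ContingencyTable(
        a=a,
        b=len(L) - a,
        c=len(S) - a,
        d=len(U) - len(L | S),
    )


def fisher_upper_tail(t: ContingencyTable) -> float:
    """One-sided over-representation p-value: hypergeometric P(X >= a).

    Degenerate margins (empty list or no annotated genes in the universe)
    give p = 1 by convention.
    """
    if t.list_size == 0 or t.annotated == 0:
        return 1.0
    # sf(a-1) = P(X >= a); scipy evaluates the tail in log space
    p = float(hypergeom.sf(t.a - 1, t.population, t.annotated, t.list_size))
    return min(max(p, 0.0), 1.0) or 5e-324  # keep p strictly positive


def enrich(
    gene_list: Sequence[str],
    collections: Sequence[GeneSet],
    universe: Sequence[str] | None = None,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Test every set in *collections* for over-representation in *gene_list*.

    Results are sorted ascending by (p-value, set_id).  If *universe* is not
    given it defaults to the union of all collection members plus the query
    list, with a warning — supply the array or genome gene universe for
    results comparable across collections.  ``adjust=True`` adds
    Benjamini-Hochberg q-values (raw p-values stay primary).
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    if universe is None:
        members: set[str] = set(gene_list)
        for s in collections:
            members |= s.members
        universe = sorted(members)
        warnings.warn(
            "no universe supplied; defaulting to the union of collection "
            "members and the query list",
            stacklevel=2,
        )
    if not universe:
        raise ValueError("universe is empty")

    results = []
    for s in collections:
        t = build_contingency(gene_list, s, universe)
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                description=s.description,
                table=t,
                p_value=fisher_upper_tail(t),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_id))
    if adjust and results:
        qs = false_discovery_control([r.p_value for r in results], method="bh")
        results = [
            EnrichmentResult(r.set_id, r.description, r.table, r.p_value, float(q))
            for r, q in zip(results, qs)
        ]
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    """TSV in the annotation-table column layout plus the p-value."""
    adjusted = any(r.q_value is not None for r in results)
    with open(path, "w", newline="") as fh:
        cols = [
            "set_id", "description",
            "list_with_ann", "list_no_ann", "genome_with_ann", "genome_no_ann",
            "p_value",
        ]
        if adjusted:
            cols.append("q_value")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            row = [
                r.set_id, r.description,
                str(r.table.a), str(r.table.b), str(r.table.c), str(r.table.d),
                f"{r.p_value:.6g}",
            ]
            if adjusted:
                row.append("" if r.q_value is None else f"{r.q_value:.6g}")
            fh.write("\t".join(row) + "\n")
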