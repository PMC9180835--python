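"""Hypergeometric over-representation analysis of validated target genes and
the miRNA-gene-term association edge list.

The population is, by default, every gene with at least one annotation in the
supplied map (standard ORA practice); a custom population can be passed for
whole-transcriptome backgrounds.  p = P(X >= k) for X ~
Hypergeometric(N, K, n); no multiple-testing correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass
class AnnotationMap:
    gene_terms: dict[str, set[str]]          # gene -> term ids
    term_info: dict[str, tuple[str, str]]    # term -> (label, namespace)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AnnotationMap":
        """Build from a long-form table with columns gene, term and optional
        label / namespace."""
        gene_terms: dict[str, set[str]] = {}
        term_info: dict[str, tuple[str, str]] = {}
        for row in table.itertuples(index=False):
            gene_terms.setdefault(row.gene, set()).add(row.term)
            label = getattr(row, "label", "")
            ns = getattr(row, "namespace", "")
            term_info.setdefault(row.term, (label, ns))
        return cls(gene_terms, term_info)

    @property
    def population(self) -> set[str]:
        return set(self.gene_terms)

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    selected: set[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    population: set[str] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of ``selected`` genes; rows sorted by p."""
    if not selected:
        raise InputError("empty selected gene set")
    pop = population if population is not None else annotation.population
    extra = set(selected) - pop
    if extra:
        raise InputError(
            f"{len(extra)} selected genes are outside the population "
            f"(e.g. {sorted(extra)[:3]})"
        )
    N = len(pop)
    n = len(selected)
    rows = []
    terms = sorted(annotation.term_info)
    for term in terms:
        members = annotation.genes_with(term) & pop
        K = len(members)
        if K == 0:
            continue
        k = len(members & set(selected))
        p = hypergeom_tail(k, N, K, n)
        label, ns = annotation.term_info[term]
        rows.append(
            {"term": term, "label": label, "namespace": ns,
             "k": k, "n": n, "K": K, "N": N, "p": p,
             "significant": p < alpha}
        )
    df = pd.DataFrame(
        rows, columns=["term", "label", "namespace", "k", "n", "K", "N",
                       "p", "significant"],
    )
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def association_table(
    candidate_mirnas: set[str],
    hits: list,
    enrichment: pd.DataFrame,
    annotation: AnnotationMap,
) -> pd.DataFrame:
    """miRNA->gene and gene->term edges for the association network.

    miRNA->gene edges come from validated hits of candidate miRNAs;
    gene->term edges connect those genes to significantly enriched terms
    they are annotated with.
    """
    edges = []
    genes: set[str] = set()
    for h in hits:
        if h.mirna_id not in candidate_mirnas:
            continue
        edges.append({"source": h.mirna_id, "target": h.transcript_id,
                      "kind": "mirna-gene"})
        genes.add(h.transcript_id)
    sig_terms = set(enrichment.loc[enrichment["significant"], "term"])
    for gene in sorted(genes):
        for term in sorted(annotation.gene_terms.get(gene, ())):
            if term in sig_terms:
                edges.append({"source": gene, "target": term,
                              "kind": "gene-term"})
    return pd.DataFrame(edges, columns=["source", "target", "kind"]).drop_duplicates(
        ignore_index=True
    )
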