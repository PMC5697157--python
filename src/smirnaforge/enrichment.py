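"""GO category tabulation and pathway enrichment by the one-sided
hypergeometric (Fisher's exact) upper tail at p <= 0.05.

The annotation is a flat, pre-propagated gene -> term table over an explicit
background universe; genes without annotation remain in the universe.  No
multiple-testing correction is applied by default; Benjamini-Hochberg
q-values are available as an opt-in column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("molecular_function", "biological_process", "cellular_component", "pathway")


@dataclass
class AnnotationMap:
    gene_terms: dict[str, set[str]]                 # gene -> terms
    term_info: dict[str, tuple[str, str]]           # term -> (name, namespace)
    universe: set[str] = field(default_factory=set)  # background gene universe

    def __post_init__(self):
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}
        if not self.universe:
            self.universe = set(self.gene_terms)
        for term, (_, ns) in self.term_info.items():
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r} for term {term!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, universe: set[str] | None = None) -> "AnnotationMap":
        """Columns: gene, term_id, term_name, namespace."""
        gene_terms: dict[str, set[str]] = {}
        term_info: dict[str, tuple[str, str]] = {}
        for _, row in df.iterrows():
            gene_terms.setdefault(str(row["gene"]), set()).add(str(row["term_id"]))
            term_info[str(row["term_id"])] = (str(row["term_name"]), str(row["namespace"]))
        return cls(gene_terms, term_info, universe or set())

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail p-value: probability of >= k annotated genes among n draws
    from a universe of N containing K annotated genes."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    enriched: bool
    q_value: float | None = None


def enrich(
    target_genes: set[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """One result per term with >= 1 target gene, sorted by p-value; the
    enriched flag marks raw p <= alpha.  ``bh=True`` adds
    Benjamini-Hochberg q-values (reported, not used for the flag)."""
    targets = set(target_genes)
    if not targets <= annotation.universe:
        raise ValueError("target genes must be a subset of the background universe")
    if not targets:
        return []
    N = len(annotation.universe)
    n = len(targets)
    results = []
    for term, (name, ns) in sorted(annotation.term_info.items()):
        genes = annotation.genes_with(term)
        k = len(genes & targets)
        if k == 0:
            continue
        K = len(genes)
        p = hypergeom_tail(N, K, n, k)
        results.append(EnrichmentResult(term, name, ns, k, n, K, N, p, p <= alpha))
    results.sort(key=lambda r: (r.p_value, r.term))
    if bh and results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def go_classify(target_genes: set[str], annotation: AnnotationMap) -> dict[str, pd.DataFrame]:
    """Per-namespace table of term -> (gene count, percentage of the
    namespace's term-assignments).  A gene with terms in two namespaces is
    counted once per namespace assignment."""
    counts: dict[str, dict[str, int]] = {}
    for gene in target_genes:
        for term in annotation.gene_terms.get(gene, ()):
            name, ns = annotation.term_info[term]
            counts.setdefault(ns, {}).setdefault(term, 0)
            counts[ns][term] += 1
    tables = {}
    for ns, terms in counts.items():
        total = sum(terms.values())
        rows = [
            {"term": t, "name": annotation.term_info[t][0], "genes": c,
             "percent": 100.0 * c / total}
            for t, c in sorted(terms.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        tables[ns] = pd.DataFrame(rows, columns=["term", "name", "genes", "percent"])
    return tables
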