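"""Parent-Child-Union term enrichment with BH correction and a QC filter.

Classic term-for-term enrichment tests every term against the whole
population, which inflates significance along is_a chains: a gene
annotated to a deep term is also annotated to all its ancestors, so an
enriched leaf drags its parents with it.  The Parent-Child-Union test
conditions each term on the genes annotated to the *union of its
parents*: it asks whether the study set is enriched for the term among
genes that already carry the parent annotation, which removes most of
the inheritance artifact.

For a term t with parent-union gene set U (in the population):

    N = |U ∩ population|         K = |genes annotated to t| (within U)
    n = |U ∩ study|              k = |study genes annotated to t|

    p_raw = P[X >= k],  X ~ Hypergeometric(N, K, n)

Raw p-values are Benjamini-Hochberg adjusted over the tested terms
(terms with at least one propagated study gene).  Two further filters
mirror screening practice: near-root terms (level <= 2) are dropped as
uninformative, and a two-tailed pooled two-proportion z-test compares
each surviving category's frequency in the hit set against the screened
library, dropping categories whose hit-set frequency is not
significantly different (p > 0.05) — a guard against categories that are
merely over-represented in the library design itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from screensift.ontology import GeneOntology

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised on invalid enrichment inputs (empty study, bad p-values, ...)."""


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def parent_child_union_p(
    dag: GeneOntology,
    propagated: dict[str, set[str]],
    study: set[str],
    population: set[str],
    term: str,
) -> float:
    """Parent-Child-Union hypergeometric upper-tail p-value for one term.

    ``propagated`` must be ancestor-closed (true-path) gene -> term sets.
    A root term (no parents) degenerates to the classic term-for-term
    test against the whole population.  If no study gene is annotated to
    the parent union the test is undefined and returns 1 by convention.
    """
    term = dag.canonical(term)
    parents = dag.parents(term)
    if parents:
        in_union = lambda g: any(t in propagated.get(g, ()) for t in parents)  # noqa: E731
    else:  # root: condition on the whole population
        in_union = lambda g: True  # noqa: E731
    pop_union = {g for g in population if in_union(g)}
    study_union = {g for g in study if in_union(g)}
    if not study_union:
        logger.info("term %s: no study genes in parent union; p = 1", term)
        return 1.0
    K = sum(1 for g in pop_union if term in propagated.get(g, ()))
    k = sum(1 for g in study_union if term in propagated.get(g, ()))
    # upper tail: P[X >= k] with X ~ Hypergeom(N=|pop_union|, K, n=|study_union|)
    return float(stats.hypergeom.sf(k - 1, len(pop_union), K, len(study_union)))


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = list(map(float, p_values))
    if any(not 0 <= x <= 1 for x in p):
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


@dataclass
class ProportionsTest:
    """Pooled two-proportion z-test of x1/n1 vs x2/n2 (two-tailed).

    z = (p̂1 − p̂2) / sqrt(p̂(1 − p̂)(1/n1 + 1/n2)) with the combined
    proportion p̂ = (x1 + x2)/(n1 + n2).  When the pooled proportion is 0
    or 1 the statistic is undefined; p is set to 1 and ``degenerate``
    flagged.  ``depleted`` marks categories under-represented in the
    first sample (p̂1 < p̂2).
    """

    x1: int
    n1: int
    x2: int
    n2: int
    p_hat1: float = field(init=False)
    p_hat2: float = field(init=False)
    p_hat_pooled: float = field(init=False)
    z: float = field(init=False)
    p_two_tailed: float = field(init=False)
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise EnrichmentError("sample sizes must be positive")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise EnrichmentError("counts must satisfy 0 <= x <= n")
        self.p_hat1 = self.x1 / self.n1
        self.p_hat2 = self.x2 / self.n2
        self.p_hat_pooled = (self.x1 + self.x2) / (self.n1 + self.n2)
        pooled_var = (
            self.p_hat_pooled
            * (1 - self.p_hat_pooled)
            * (1 / self.n1 + 1 / self.n2)
        )
        if pooled_var <= 0:
            logger.info(
                "degenerate pooled proportion %.3f; z undefined, p = 1",
                self.p_hat_pooled,
            )
            self.z = math.nan
            self.p_two_tailed = 1.0
            self.degenerate = True
        else:
            self.z = (self.p_hat1 - self.p_hat2) / math.sqrt(pooled_var)
            self.p_two_tailed = float(2 * stats.norm.sf(abs(self.z)))

    @property
    def depleted(self) -> bool:
        return self.p_hat1 < self.p_hat2


def proportions_qc(x1: int, n1: int, x2: int, n2: int) -> ProportionsTest:
    """Two-tailed pooled two-proportion z-test (see :class:`ProportionsTest`)."""
    return ProportionsTest(x1, n1, x2, n2)


# ---------------------------------------------------------------------------
# the enrichment pass
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-term enrichment outcome with counts, p-values and QC statistics."""

    term: str
    name: str
    namespace: str
    level: int
    study_count: int
    study_size: int
    pop_count: int
    pop_size: int
    p_raw: float
    p_adjusted: float = math.nan
    qc: ProportionsTest | None = None
    kept: bool = False


def enrich(
    dag: GeneOntology,
    propagated: dict[str, set[str]],
    study: set[str],
    population: set[str],
    library: set[str] | None = None,
    alpha: float = 0.05,
    min_level: int = 2,
    qc_alpha: float = 0.05,
    keep_depleted: bool = True,
) -> list[EnrichmentResult]:
    """Run Parent-Child-Union enrichment of ``study`` against ``population``.

    Every term with at least one propagated study gene is tested; BH
    correction spans exactly the tested terms.  A result is ``kept`` when
    p_adjusted <= alpha, level > min_level (level 0 = namespace root),
    and — if a screened ``library`` gene list is supplied — the category's
    frequency among the study genes differs from its library frequency at
    qc_alpha in the two-proportion test.  Set ``keep_depleted=False`` to
    additionally drop categories under-represented in the study set.

    Returns all tested terms (kept and filtered) sorted by p_adjusted;
    callers can inspect why a term was dropped.
    """
    if not study:
        raise EnrichmentError("empty study set")
    if not 0 < alpha < 1:
        raise EnrichmentError(f"alpha {alpha} outside (0, 1)")
    if not study <= population:
        raise EnrichmentError("study set must be a subset of the population")
    terms = sorted({t for g in study for t in propagated.get(g, ())})
    results = []
    for term in terms:
        p = parent_child_union_p(dag, propagated, study, population, term)
        results.append(
            EnrichmentResult(
                term=term,
                name=dag.names.get(term, term),
                namespace=dag.namespaces.get(term, ""),
                level=dag.term_level(term),
                study_count=sum(1 for g in study if term in propagated.get(g, ())),
                study_size=len(study),
                pop_count=sum(
                    1 for g in population if term in propagated.get(g, ())
                ),
                pop_size=len(population),
                p_raw=p,
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, adj in zip(results, adjusted):
        r.p_adjusted = adj
        r.kept = adj <= alpha and r.level > min_level
        if library is not None:
            x2 = sum(1 for g in library if r.term in propagated.get(g, ()))
            r.qc = proportions_qc(r.study_count, len(study), x2, len(library))
            if r.qc.p_two_tailed > qc_alpha:
                r.kept = False
            if not keep_depleted and r.qc.depleted:
                r.kept = False
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class ParentChildEnrichment:
    """Enrichment model bound to an ontology and propagated annotations.

    Parameters
    ----------
    dag : GeneOntology
    annotations : dict
        gene -> direct term sets; propagated internally (true-path rule).

    ``fit(study, population, ...)`` returns an :class:`EnrichmentResults`.
    """

    def __init__(self, dag: GeneOntology, annotations: dict[str, set[str]]) -> None:
        from screensift.ontology import propagate

        self.dag = dag
        self.propagated = propagate(dag, annotations)

    def fit(
        self,
        study: set[str],
        population: set[str],
        library: set[str] | None = None,
        alpha: float = 0.05,
        min_level: int = 2,
        qc_alpha: float = 0.05,
    ) -> "EnrichmentResults":
        results = enrich(
            self.dag,
            self.propagated,
            set(study),
            set(population),
            library=set(library) if library is not None else None,
            alpha=alpha,
            min_level=min_level,
            qc_alpha=qc_alpha,
        )
        return EnrichmentResults(results, self.dag, alpha=alpha)


@dataclass
class EnrichmentResults:
    """All tested terms with filters applied; ``kept`` marks survivors."""

    results: list[EnrichmentResult]
    dag: GeneOntology
    alpha: float = 0.05

    @property
    def kept(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.kept]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "term": r.term,
                    "name": r.name,
                    "namespace": r.namespace,
                    "level": r.level,
                    "study_count": r.study_count,
                    "study_size": r.study_size,
                    "pop_count": r.pop_count,
                    "pop_size": r.pop_size,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adjusted,
                    "qc_z": r.qc.z if r.qc else math.nan,
                    "qc_p": r.qc.p_two_tailed if r.qc else math.nan,
                    "depleted": r.qc.depleted if r.qc else False,
                    "kept": r.kept,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Parent-Child-Union enrichment",
            "=" * 60,
            f"terms tested: {len(self.results)}   "
            f"kept at alpha {self.alpha}: {len(self.kept)}",
            "-" * 60,
        ]
        for r in self.kept[:15]:
            lines.append(
                f"  {r.term:<12s} L{r.level} {r.study_count:>3d}/{r.pop_count:<4d} "
                f"p_adj={r.p_adjusted:.3g}  {r.name[:30]}"
            )
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dot(self, path) -> None:
        export_dag_graph(self.kept, self.dag, path)


_NAMESPACE_COLORS = {
    "biological_process": "#4477aa",
    "cellular_component": "#228833",
    "molecular_function": "#ccbb44",
}


def export_dag_graph(results: list[EnrichmentResult], dag: GeneOntology, path) -> None:
    """Write a DOT graph of enriched terms plus their is_a ancestors.

    Enriched nodes are filled in their namespace color with opacity
    scaled by -log10(p_adjusted); ancestor context nodes are left
    unfilled.  An empty result list yields a header-only empty graph.
    """
    enriched = {r.term: r for r in results}
    nodes: set[str] = set()
    for term in enriched:
        nodes |= dag.ancestors(term, inclusive=True)
    max_score = max(
        (-math.log10(max(r.p_adjusted, 1e-300)) for r in results), default=1.0
    )
    lines = ["digraph enrichment {", "  rankdir=BT;", '  node [shape=box, style=""];']
    for term in sorted(nodes):
        label = f"{term}\\n{dag.names.get(term, '')}"
        attrs = [f'label="{label}"']
        if term in enriched:
            r = enriched[term]
            color = _NAMESPACE_COLORS.get(r.namespace, "#888888")
            intensity = -math.log10(max(r.p_adjusted, 1e-300)) / max(max_score, 1e-12)
            alpha_hex = format(int(64 + 191 * min(intensity, 1.0)), "02x")
            attrs.append('style="filled"')
            attrs.append(f'fillcolor="{color}{alpha_hex}"')
        lines.append(f'  "{term}" [{", ".join(attrs)}];')
    for term in sorted(nodes):
        for parent in sorted(dag.parents(term)):
            if parent in nodes:
                lines.append(f'  "{term}" -> "{parent}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
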