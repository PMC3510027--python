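"""Parent-Child-Union statistics, BH correction, QC filter, and enrich()."""

import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from _oracles import bh_sort_cummin, pcu_exhaustive, two_prop_z_longhand
from conftest import write_obo
from screensift import simulate as sim
from screensift.enrichment import (
    EnrichmentError,
    ParentChildEnrichment,
    bh_adjust,
    enrich,
    export_dag_graph,
    parent_child_union_p,
    proportions_qc,
)
from screensift.ontology import parse_gaf, parse_obo, propagate


def random_dag_case(rng, max_terms=12, max_genes=15, tmp_path=None, tag=""):
    """A random small layered DAG with annotations, study and population."""
    n_terms = int(rng.integers(4, max_terms + 1))
    n_genes = int(rng.integers(6, max_genes + 1))
    terms = [f"GO:{i + 1}" for i in range(n_terms)]
    edges = []
    for i, t in enumerate(terms[1:], start=1):
        n_par = int(rng.integers(1, min(2, i) + 1))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.append((t, terms[int(p)]))
    genes = [f"g{i}" for i in range(n_genes)]
    annots = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        annots[g] = {terms[int(i)] for i in rng.choice(n_terms, size=k, replace=False)}
    population = set(genes)
    study = set(
        rng.choice(genes, size=int(rng.integers(2, max(3, n_genes // 2))), replace=False)
    )
    obo = write_obo(tmp_path / f"case{tag}.obo", terms, edges)
    dag = parse_obo(obo)
    return dag, edges, annots, study, population, terms


class TestParentChildUnionP:
    def _toy(self, tmp_path):
        # root GO:1; GO:2 under root; genes g1..g10 annotated to GO:2's
        # parent (the root); g1..g5 additionally to GO:2
        obo = write_obo(tmp_path / "toy.obo", ["GO:1", "GO:2"], [("GO:2", "GO:1")])
        dag = parse_obo(obo)
        annots = {f"g{i}": {"GO:2"} if i <= 5 else {"GO:1"} for i in range(1, 11)}
        prop = propagate(dag, annots)
        population = set(annots)
        return dag, prop, population

    def test_saturated_conditioning_gives_one(self, tmp_path):
        # term annotated to every parent-union gene: enrichment impossible
        obo = write_obo(tmp_path / "sat.obo", ["GO:1", "GO:2"], [("GO:2", "GO:1")])
        dag = parse_obo(obo)
        prop = propagate(dag, {f"g{i}": {"GO:2"} for i in range(6)})
        p = parent_child_union_p(dag, prop, {"g0", "g1"}, set(prop), "GO:2")
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_toy(self, tmp_path):
        dag, prop, population = self._toy(tmp_path)
        study = {f"g{i}" for i in range(1, 6)}  # exactly the GO:2 genes
        p = parent_child_union_p(dag, prop, study, population, "GO:2")
        # enumeration over all 5-subsets of the 10 parent-union genes
        hits = sum(
            1 for sub in itertools.combinations(sorted(population), 5)
            if sum(1 for g in sub if g in study) >= 5
        )
        expected = hits / math.comb(10, 5)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(1 / math.comb(10, 5), abs=1e-12)

    def test_disjoint_study_gives_one(self, tmp_path):
        dag, prop, population = self._toy(tmp_path)
        study = {f"g{i}" for i in range(6, 9)}  # none annotated to GO:2
        p = parent_child_union_p(dag, prop, study, population, "GO:2")
        assert p == pytest.approx(1.0)

    def test_property_sweep_against_exhaustive_oracle(self, tmp_path):
        """PCU equals exhaustive enumeration on random small DAGs."""
        rng = np.random.default_rng(777)
        for case in range(60):
            dag, edges, annots, study, population, terms = random_dag_case(
                rng, tmp_path=tmp_path, tag=str(case)
            )
            prop = propagate(dag, annots)
            term = terms[int(rng.integers(len(terms)))]
            p_impl = parent_child_union_p(dag, prop, study, population, term)
            p_oracle = pcu_exhaustive(edges, annots, study, population, term)
            assert p_impl == pytest.approx(p_oracle, abs=1e-9), (case, term)

    def test_null_type_one_error_is_calibrated(self, tmp_path):
        """Per-term rejection rate at nominal 0.05 stays within binomial
        slack of 0.05 when the study set is a random population draw."""
        out = tmp_path / "fixed"
        truth = sim.generate_ontology(
            out, n_terms=60, n_genes=120, depth=4, n_planted=0, seed=9
        )
        dag = parse_obo(out / "ontology.obo")
        prop = propagate(dag, {g: set(t) for g, t in truth.annotations.items()})
        population = set(truth.population)
        # a mid-DAG term with a decent annotation count
        counts = {
            t: sum(1 for g in population if t in prop.get(g, ()))
            for t in dag.graph.nodes
        }
        term = max(
            (t for t in counts if dag.term_level(t) >= 2), key=lambda t: counts[t]
        )
        rng = np.random.default_rng(123)
        n_draws, rejected = 1000, 0
        pop_list = sorted(population)
        for _ in range(n_draws):
            study = set(rng.choice(pop_list, size=25, replace=False))
            if parent_child_union_p(dag, prop, study, population, term) <= 0.05:
                rejected += 1
        rate = rejected / n_draws
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_draws)


class TestBhAdjust:
    def test_closed_form_triplet(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_matches_reference_oracles_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            mine = bh_adjust(p)
            assert mine == pytest.approx(bh_sort_cummin(p), abs=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            assert mine == pytest.approx(sm.tolist(), abs=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        adj = bh_adjust(p)
        for i in range(40):
            for j in range(40):
                if p[i] <= p[j]:
                    assert adj[i] <= adj[j] + 1e-15

    def test_rejects_out_of_range(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.5, 1.2])


class TestProportionsQc:
    def test_equal_proportions_give_zero_z(self):
        t = proportions_qc(10, 100, 100, 1000)
        assert t.z == pytest.approx(0.0, abs=1e-12)
        assert t.p_two_tailed == pytest.approx(1.0)

    def test_matches_longhand_formula(self):
        t = proportions_qc(13, 130, 150, 7494)
        z, p = two_prop_z_longhand(13, 130, 150, 7494)
        assert t.z == pytest.approx(z, abs=1e-10)
        assert t.p_two_tailed == pytest.approx(p, abs=1e-10)
        assert t.p_hat_pooled == pytest.approx((13 + 150) / (130 + 7494))

    def test_degenerate_pooled_proportion_flagged(self):
        t = proportions_qc(0, 130, 0, 7494)
        assert t.degenerate
        assert t.p_two_tailed == 1.0
        assert math.isnan(t.z)

    def test_antisymmetry(self):
        a = proportions_qc(30, 200, 55, 900)
        b = proportions_qc(55, 900, 30, 200)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(EnrichmentError):
            proportions_qc(5, 4, 1, 10)


class TestEnrich:
    def test_planted_term_survives_all_filters(self, small_ontology):
        out, truth = small_ontology
        dag = parse_obo(out / "ontology.obo")
        annots = parse_gaf(out / "annotations.gaf")
        model = ParentChildEnrichment(dag, annots)
        pop = set(truth.population)
        res = model.fit(set(truth.study), pop, library=pop)
        kept = {r.term for r in res.kept}
        assert set(truth.planted) <= kept
        for r in res.kept:
            assert r.level > 2
            assert r.p_adjusted <= 0.05
            assert r.qc is not None and r.qc.p_two_tailed <= 0.05

    def test_null_studies_rarely_yield_survivors(self, tmp_path):
        """On unplanted ontologies a random study set should survive the
        BH + level + QC chain in at most 1 of 20 seeded runs."""
        n_with_survivors = 0
        for seed in range(20):
            out = tmp_path / f"null{seed}"
            truth = sim.generate_ontology(
                out, n_terms=120, n_genes=300, depth=4, n_planted=0,
                study_size=60, seed=seed,
            )
            dag = parse_obo(out / "ontology.obo")
            annots = {g: set(t) for g, t in truth.annotations.items()}
            prop = propagate(dag, annots)
            pop = set(truth.population)
            results = enrich(dag, prop, set(truth.study), pop, library=pop)
            if any(r.kept for r in results):
                n_with_survivors += 1
        assert n_with_survivors <= 1

    def test_level_filter_excludes_near_root_terms(self, tmp_path):
        # one term at level 1 whose annotations perfectly separate the study
        obo = write_obo(tmp_path / "lvl.obo", ["GO:1", "GO:2", "GO:3"],
                        [("GO:2", "GO:1"), ("GO:3", "GO:2")])
        dag = parse_obo(obo)
        genes = [f"g{i}" for i in range(20)]
        annots = {g: ({"GO:2"} if i < 5 else {"GO:1"}) for i, g in enumerate(genes)}
        prop = propagate(dag, annots)
        study = set(genes[:5])
        results = enrich(dag, prop, study, set(genes))
        by_term = {r.term: r for r in results}
        assert by_term["GO:2"].p_adjusted <= 0.05  # clearly enriched
        assert by_term["GO:2"].level == 1
        assert not by_term["GO:2"].kept  # but filtered as near-root

    def test_empty_study_rejected(self, tmp_path):
        obo = write_obo(tmp_path / "e.obo", ["GO:1"], [])
        dag = parse_obo(obo)
        with pytest.raises(EnrichmentError, match="empty study"):
            enrich(dag, {}, set(), {"g1"})

    def test_bh_family_is_exactly_the_tested_terms(self, small_ontology):
        out, truth = small_ontology
        dag = parse_obo(out / "ontology.obo")
        annots = parse_gaf(out / "annotations.gaf")
        prop = propagate(dag, annots)
        study, pop = set(truth.study), set(truth.population)
        results = enrich(dag, prop, study, pop)
        raw = [r.p_raw for r in results]
        expected = bh_sort_cummin(raw)
        for r, e in zip(results, expected):
            assert r.p_adjusted == pytest.approx(e, abs=1e-12)
        tested = {t for g in study for t in prop.get(g, ())}
        assert {r.term for r in results} == tested


class TestDagExport:
    def test_dot_contains_enriched_terms_and_ancestors(self, small_ontology, tmp_path):
        out, truth = small_ontology
        dag = parse_obo(out / "ontology.obo")
        annots = parse_gaf(out / "annotations.gaf")
        model = ParentChildEnrichment(dag, annots)
        pop = set(truth.population)
        res = model.fit(set(truth.study), pop, library=pop)
        dot = tmp_path / "graph.dot"
        export_dag_graph(res.kept, dag, dot)
        text = dot.read_text()
        expected_nodes = set()
        for r in res.kept:
            expected_nodes |= dag.ancestors(r.term, inclusive=True)
        for node in expected_nodes:
            assert f'"{node}"' in text

    def test_empty_results_yield_header_only_graph(self, small_ontology, tmp_path):
        out, _ = small_ontology
        dag = parse_obo(out / "ontology.obo")
        dot = tmp_path / "empty.dot"
        export_dag_graph([], dag, dot)
        text = dot.read_text()
        assert text.startswith("digraph") and "->" not in text
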