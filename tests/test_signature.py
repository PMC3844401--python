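"""Three-constraint queries, intersection signatures, profiles, subtraction."""

import numpy as np
import pytest

from obams import (
    BuildConfig,
    ComparisonGeneSet,
    QueryError,
    SignatureQuery,
    build_comparison_ontology,
    full_profile,
    obams_signature,
    query_gene_sets,
    subtraction_query,
)
from obams.comparison import GS_HUB, GS_ROOT, ComparisonOntology
from obams.ontology import IS_A, OntologyGraph, OntologyTerm, closure
from obams.synthio import (
    PopulationPanel,
    plant_markers,
    score_recovery,
    simulate_expression,
    simulate_ontology,
)

from conftest import brute_force_query, build_lymphocyte_panel, make_term, random_dag_panel


def hand_made_co(sets):
    """A ComparisonOntology with hand-authored gene sets: parent P with
    children A, B; two populations under A, one under B."""
    g = OntologyGraph()
    make_term(g, "H:1", "P")
    make_term(g, "H:2", "A", "H:1")
    make_term(g, "H:3", "B", "H:1")
    make_term(g, "GS:0000000", "Gene-sets")
    make_term(g, "GS:0000001", "mature immune cell comparisons", "GS:0000000")
    comparisons = {}
    pop_class = {}
    for i, (up_pop, down_pop, up_cls, down_cls, up_genes) in enumerate(sets, start=2):
        gsid = f"GS:{i:07d}"
        make_term(g, gsid, f"{up_pop} vs {down_pop}", "GS:0000001")
        g.add_edge(gsid, "has_up_regulated_genes_for", up_cls)
        g.add_edge(gsid, "has_down_regulated_genes_for", down_cls)
        comparisons[gsid] = ComparisonGeneSet(
            id=gsid, up_population=up_pop, down_population=down_pop,
            up_class=up_cls, down_class=down_cls,
            up_genes=up_genes, down_genes={},
        )
        pop_class[up_pop] = up_cls
        pop_class[down_pop] = down_cls
    g.validate()
    return ComparisonOntology(g, comparisons, pop_class, BuildConfig())


class TestQueryGeneSets:
    def test_leaf_vs_branch_returns_sibling_comparisons(self, lymphocyte_build):
        """One of 8 mapped B subtypes vs the B branch: 7 within-branch sets."""
        panel, ids, co = lymphocyte_build
        x = panel.population_to_class["b0"]
        sets = query_gene_sets(co, SignatureQuery(x, ids["mature B cell"], "up"))
        assert len(sets) == 7
        assert all(s.up_class == x for s in sets)
        assert all(s.down_class != x for s in sets)

    def test_mature_b_vs_lymphocyte_returns_256_sets(self, lymphocyte_build):
        panel, ids, co = lymphocyte_build
        sets = query_gene_sets(
            co, SignatureQuery(ids["mature B cell"], ids["mature lymphocyte"], "up")
        )
        assert len(sets) == 256  # 8 B subtypes x 32 NK/T subtypes

    def test_third_constraint_is_load_bearing(self, lymphocyte_build):
        panel, ids, co = lymphocyte_build
        desc_x = closure(co.graph, ids["mature B cell"], direction="down", reflexive=True)
        desc_y = closure(co.graph, ids["mature lymphocyte"], direction="down", reflexive=True)
        two_constraint = [
            c for c in co.comparisons.values()
            if c.up_class in desc_x and c.down_class in desc_y
        ]
        assert len(two_constraint) == 256 + 8 * 7  # within-B comparisons leak in

    def test_class_without_mapped_descendants_is_empty(self, lymphocyte_build):
        panel, ids, co = lymphocyte_build
        g2 = co.graph
        if "CLX:0999999" not in g2:
            g2.add_term(OntologyTerm(id="CLX:0999999", name="unsampled subtype",
                                     parents=[(IS_A, ids["mature B cell"])]))
        sets = query_gene_sets(
            co, SignatureQuery("CLX:0999999", ids["mature B cell"], "up")
        )
        assert sets == []

    def test_strict_mode_requires_ancestor(self, lymphocyte_build):
        panel, ids, co = lymphocyte_build
        with pytest.raises(QueryError, match="ancestor"):
            query_gene_sets(
                co, SignatureQuery(ids["mature B cell"], ids["mature NK cell"], "up")
            )
        # ad-hoc mode allows arbitrary references
        sets = query_gene_sets(
            co,
            SignatureQuery(ids["mature B cell"], ids["mature NK cell"], "up", ad_hoc=True),
        )
        assert len(sets) == 8 * 16

    def test_unknown_class_rejected(self, lymphocyte_build):
        *_, co = lymphocyte_build
        with pytest.raises(QueryError, match="ZZ:1"):
            query_gene_sets(co, SignatureQuery("ZZ:1", "ZZ:2", "up"))

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            panel = random_dag_panel(rng)
            truth = plant_markers(panel, markers_per_class=1, n_background=5,
                                  sigma=0.0, replicates=2, seed=1,
                                  classes=sorted(set(panel.population_to_class.values())))
            matrix, sheet = simulate_expression(truth, panel)
            co = build_comparison_ontology(panel.graph, sheet, matrix)
            for x in sorted(panel.graph.terms):
                for y in sorted(panel.graph.terms):
                    for direction in ("up", "down"):
                        q = SignatureQuery(x, y, direction, ad_hoc=True)
                        got = [c.id for c in query_gene_sets(co, q)]
                        want = [c.id for c in brute_force_query(co, x, y, direction)]
                        assert got == want


class TestObamsSignature:
    def test_hand_intersection_and_moments(self):
        co = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0, "g2": 1.6}),
            ("a2", "b1", "H:2", "H:3", {"g1": 2.0, "g3": 1.0}),
        ])
        sig = obams_signature(co, SignatureQuery("H:2", "H:1", "up"))
        assert sig.n_comparisons == 2
        assert [(e.gene, e.mean_log2_fold_change, e.sd_log2_fold_change)
                for e in sig.entries] == [("g1", 1.5, 0.5)]

    def test_single_set_is_returned_ranked(self):
        co = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0, "g2": 1.6, "g3": 1.2}),
        ])
        sig = obams_signature(co, SignatureQuery("H:2", "H:1", "up"))
        assert sig.genes == ["g2", "g3", "g1"]
        assert all(e.sd_log2_fold_change == 0 for e in sig.entries)

    def test_disjoint_sets_give_empty_ok_signature(self):
        co = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0}),
            ("a2", "b1", "H:2", "H:3", {"g2": 1.0}),
        ])
        sig = obams_signature(co, SignatureQuery("H:2", "H:1", "up"))
        assert sig.entries == [] and sig.status == "ok" and sig.n_comparisons == 2

    def test_zero_returned_sets_is_flagged(self):
        co = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0}),
        ])
        sig = obams_signature(co, SignatureQuery("H:3", "H:1", "up"))
        assert sig.status == "no_gene_sets" and sig.n_comparisons == 0

    def test_tie_break_is_lexicographic(self):
        co = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"gb": 1.0, "ga": 1.0, "gc": 0.5}),
        ])
        sig = obams_signature(co, SignatureQuery("H:2", "H:1", "up"))
        assert sig.genes == ["ga", "gb", "gc"]

    def test_monotone_restriction_under_more_populations(self):
        """Adding a mapped population under x can only shrink the signature."""
        small = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0, "g2": 1.6}),
        ])
        big = hand_made_co([
            ("a1", "b1", "H:2", "H:3", {"g1": 1.0, "g2": 1.6}),
            ("a2", "b1", "H:2", "H:3", {"g1": 2.0}),
        ])
        q = SignatureQuery("H:2", "H:1", "up")
        assert set(obams_signature(big, q).genes) <= set(obams_signature(small, q).genes)

    def test_up_down_duality(self, noiseless_build):
        """The down signature recovers the planted down markers with negative
        means, is disjoint from the up signature, and equals the up signature
        computed on the mirrored comparison classes."""
        panel, truth, co = noiseless_build
        for cls in sorted(truth.up_effects)[:4]:
            parent = [t for r, t in co.graph.terms[cls].parents if r == IS_A][0]
            up = obams_signature(co, SignatureQuery(cls, parent, "up"))
            down = obams_signature(co, SignatureQuery(cls, parent, "down"))
            assert set(down.genes) == set(truth.down_effects[cls])
            assert all(e.mean_log2_fold_change < 0 for e in down.entries)
            assert set(up.genes).isdisjoint(down.genes)
            # mirror route: the down signature must equal the intersection of
            # the up-query comparisons' own down-sets (reversal duality)
            sets = query_gene_sets(co, SignatureQuery(cls, parent, "up"))
            mirror_maps = [s.down_genes for s in sets]
            common = set(mirror_maps[0]).intersection(*mirror_maps[1:])
            assert common == set(down.genes)


class TestFullProfile:
    def test_direct_child_of_root_has_single_level(self):
        panel = simulate_ontology(levels=1, branching=3, seed=2)
        truth = plant_markers(panel, markers_per_class=2, n_background=10,
                              sigma=0.0, replicates=2, seed=2)
        matrix, sheet = simulate_expression(truth, panel)
        co = build_comparison_ontology(panel.graph, sheet, matrix)
        root = panel.graph.roots()[0]
        cls = sorted(truth.up_effects)[0]
        prof = full_profile(co, cls, root)
        assert len(prof.levels) == 1
        assert prof.levels[0][0] == cls and prof.levels[0][1] == root

    def test_planted_genes_recovered_per_level(self, noiseless_build):
        """3-level noiseless fixture: each profile level recovers exactly the
        genes planted at that level, and no gene repeats across levels."""
        panel, truth, co = noiseless_build
        root = panel.graph.roots()[0]
        leaf_cls = sorted(panel.population_to_class.values())[0]
        prof = full_profile(co, leaf_cls, root)
        assert len(prof.levels) == 2  # leaf vs mid, mid vs root
        seen = set()
        for cls, parent, sig in prof.levels:
            assert set(sig.genes) == set(truth.up_effects[cls])
            assert not seen & set(sig.genes)
            seen |= set(sig.genes)

    def test_levels_are_topologically_ordered(self, noiseless_build):
        panel, truth, co = noiseless_build
        root = panel.graph.roots()[0]
        leaf_cls = sorted(panel.population_to_class.values())[0]
        prof = full_profile(co, leaf_cls, root)
        classes = [cls for cls, _, _ in prof.levels]
        assert classes[0] == leaf_cls
        for i, cls in enumerate(classes):
            anc = closure(co.graph, cls, direction="up")
            assert anc.isdisjoint(classes[:i])

    def test_root_must_be_ancestor(self, noiseless_build):
        panel, truth, co = noiseless_build
        leaves = sorted(panel.population_to_class.values())
        with pytest.raises(QueryError, match="ancestor"):
            full_profile(co, leaves[0], leaves[1])


class TestSubtraction:
    def two_leaf_build(self, delta=2.0, extra_effects=None):
        panel = simulate_ontology(levels=1, branching=2, seed=3)
        truth = plant_markers(panel, markers_per_class=3, n_background=15,
                              delta=delta, sigma=0.0, replicates=2, seed=3)
        if extra_effects:
            for cls, genes in extra_effects.items():
                truth.up_effects.setdefault(cls, {}).update(genes)
                truth.genes.extend(g for g in genes if g not in truth.genes)
        matrix, sheet = simulate_expression(truth, panel)
        co = build_comparison_ontology(panel.graph, sheet, matrix)
        return panel, truth, co

    def test_single_sibling_equals_parent_signature(self):
        panel, truth, co = self.two_leaf_build()
        a, b = sorted(set(panel.population_to_class.values()))
        root = panel.graph.roots()[0]
        sub = subtraction_query(co, a, [b], fold_threshold=co.config.fold_threshold)
        ref = obams_signature(co, SignatureQuery(a, root, "up"))
        assert sub.genes == ref.genes
        assert sub.n_comparisons == ref.n_comparisons
        for e1, e2 in zip(sub.entries, ref.entries):
            assert e1.mean_log2_fold_change == pytest.approx(e2.mean_log2_fold_change)

    def test_identical_distributions_give_empty_signature(self):
        panel = simulate_ontology(levels=1, branching=3, seed=4)
        truth = plant_markers(panel, markers_per_class=0, n_background=20,
                              sigma=0.0, replicates=2, seed=4)
        matrix, sheet = simulate_expression(truth, panel)
        co = build_comparison_ontology(panel.graph, sheet, matrix)
        classes = sorted(set(panel.population_to_class.values()))
        sig = subtraction_query(co, classes[0], classes[1:],
                                fold_threshold=co.config.fold_threshold)
        assert sig.entries == []

    def test_planted_focus_genes_recovered_at_2fold(self):
        panel, truth, co = self.two_leaf_build(delta=2.0)
        a, b = sorted(set(panel.population_to_class.values()))
        sig = subtraction_query(co, a, [b], fold_threshold=2.0)
        assert set(sig.genes) == set(truth.up_effects[a])

    def test_strict_threshold_excludes_boundary_effect(self):
        # a gene whose fold change is exactly the threshold must be excluded
        panel, truth, co = self.two_leaf_build(delta=2.0)
        a, b = sorted(set(panel.population_to_class.values()))
        extra = {a: {"gboundary": 1.0}}  # exactly 2-fold
        panel2, truth2, co2 = self.two_leaf_build(delta=2.0, extra_effects=extra)
        sig = subtraction_query(co2, a, [b], fold_threshold=2.0)
        assert "gboundary" not in sig.genes
        assert "gboundary" in subtraction_query(co2, a, [b], fold_threshold=1.5).genes

    def test_threshold_below_build_threshold_rejected(self):
        panel, truth, co = self.two_leaf_build()
        a, b = sorted(set(panel.population_to_class.values()))
        with pytest.raises(QueryError, match="below the build threshold"):
            subtraction_query(co, a, [b], fold_threshold=1.2)

    def test_subtract_class_without_populations_named(self, noiseless_build):
        panel, truth, co = noiseless_build
        co.graph.add_term(OntologyTerm(id="SYN:0888888", name="unsampled",
                                       parents=[(IS_A, panel.graph.roots()[0])]))
        cls = sorted(truth.up_effects)[0]
        with pytest.raises(QueryError, match="SYN:0888888"):
            subtraction_query(co, cls, ["SYN:0888888"])
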