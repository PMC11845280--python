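import pytest

from netrewire.contextualize import (
    GENE_ONLY,
    TRANSCRIPT_PREFERRED,
    ContextOptions,
    build_reference_ddin,
    contextualize_sample,
    length_normalize,
    select_major_feature,
)
from netrewire.io import DDILibrary, DomainAnnotation, ExpressionTable
from netrewire.model import DomainId, Network, canonical_edge
from netrewire.simulate import ScenarioSpec, generate_scenario


def switch_fixture():
    """Two expressed proteins whose only backing domain pair sits on an
    isoform that the major transcript of u loses in this sample."""
    ppin = Network()
    ppin.add_edge("Pu", "Pv")
    ann = DomainAnnotation()
    ann.add_isoform("Pu", "Gu", "Tu1", ["PF1"], canonical=True)
    ann.add_isoform("Pu", "Gu", "Tu2", [])
    ann.add_isoform("Pv", "Gv", "Tv1", ["PF2"], canonical=True)
    ddi = DDILibrary()
    ddi.add("PF1", "PF2")
    expr = ExpressionTable(
        "transcript",
        {"Tu1": 2.0, "Tu2": 10.0, "Tv1": 5.0},
        {"Tu1": "Gu", "Tu2": "Gu", "Tv1": "Gv"},
    )
    return ppin, ann, ddi, expr


class TestLengthNormalize:
    def test_hand_computation(self):
        expr = ExpressionTable(
            "transcript",
            {"T1": 10.0, "T2": 10.0},
            {"T1": "G1", "T2": "G1"},
            {"T1": 1000, "T2": 2000},
        )
        out = length_normalize(expr)
        assert out.abundance["T1"] == pytest.approx(2 / 3 * 1e6)
        assert out.abundance["T2"] == pytest.approx(1 / 3 * 1e6)

    def test_single_transcript_normalizes_to_a_million(self):
        expr = ExpressionTable("transcript", {"T1": 7.0}, {"T1": "G1"}, {"T1": 123})
        assert length_normalize(expr).abundance["T1"] == pytest.approx(1e6)

    def test_all_zero_stays_zero(self):
        expr = ExpressionTable("transcript", {"T1": 0.0}, {"T1": "G1"})
        assert length_normalize(expr).abundance == {"T1": 0.0}

    def test_missing_length_for_expressed_transcript(self):
        expr = ExpressionTable("transcript", {"T1": 1.0}, {"T1": "G1"})
        with pytest.raises(ValueError, match="missing length"):
            length_normalize(expr)

    def test_gene_level_rejected(self):
        with pytest.raises(ValueError):
            length_normalize(ExpressionTable("gene", {"G1": 1.0}))


class TestSelectMajorFeature:
    @pytest.fixture
    def annotation(self):
        ann = DomainAnnotation()
        ann.add_isoform("P1", "G1", "T1", ["PF1"], canonical=True)
        ann.add_isoform("P1", "G1", "T2", [])
        return ann

    def test_gene_mode_above_threshold(self, annotation):
        expr = ExpressionTable("gene", {"G1": 5.0})
        opts = ContextOptions(threshold=1.0, mode=GENE_ONLY)
        assert select_major_feature(expr, "P1", annotation, opts) == ("G1", 5.0)

    def test_expressed_means_strictly_greater(self, annotation):
        expr = ExpressionTable("gene", {"G1": 1.0})
        opts = ContextOptions(threshold=1.0, mode=GENE_ONLY)
        assert select_major_feature(expr, "P1", annotation, opts) is None

    def test_transcript_mode_argmax(self, annotation):
        expr = ExpressionTable(
            "transcript", {"T1": 3.0, "T2": 4.0}, {"T1": "G1", "T2": "G1"}
        )
        opts = ContextOptions(threshold=1.0, mode=TRANSCRIPT_PREFERRED)
        assert select_major_feature(expr, "P1", annotation, opts) == ("T2", 4.0)

    def test_transcript_tie_breaks_lexicographically(self, annotation):
        expr = ExpressionTable(
            "transcript", {"T1": 4.0, "T2": 4.0}, {"T1": "G1", "T2": "G1"}
        )
        opts = ContextOptions(mode=TRANSCRIPT_PREFERRED)
        assert select_major_feature(expr, "P1", annotation, opts) == ("T1", 4.0)

    def test_unexpressed_protein_yields_none(self, annotation):
        expr = ExpressionTable("transcript", {}, {})
        opts = ContextOptions(mode=TRANSCRIPT_PREFERRED)
        assert select_major_feature(expr, "P1", annotation, opts) is None

    def test_gene_mode_sums_transcripts(self, annotation):
        expr = ExpressionTable(
            "transcript", {"T1": 0.7, "T2": 0.8}, {"T1": "G1", "T2": "G1"}
        )
        opts = ContextOptions(threshold=1.0, mode=GENE_ONLY)
        assert select_major_feature(expr, "P1", annotation, opts) == ("G1", pytest.approx(1.5))

    def test_unknown_protein_rejected(self, annotation):
        with pytest.raises(KeyError):
            select_major_feature(ExpressionTable("gene", {}), "P9", annotation,
                                 ContextOptions())


class TestBuildReferenceDdin:
    def test_documented_pair_backs_edge(self):
        ppin, ann, ddi, _ = switch_fixture()
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        edge = canonical_edge("Pu", "Pv")
        assert backing[edge] == {
            canonical_edge(str(DomainId("Pu", "PF1")), str(DomainId("Pv", "PF2")))
        }

    def test_dummy_fallback_without_documented_pair(self):
        ppin, ann, _, _ = switch_fixture()
        ddin, backing = build_reference_ddin(ppin, ann, DDILibrary())
        edge = canonical_edge("Pu", "Pv")
        assert backing[edge] == {
            canonical_edge("Pu|DUMMY|0", "Pv|DUMMY|0")
        }

    def test_domain_copies_expand_to_occurrence_instances(self):
        ppin = Network()
        ppin.add_edge("Pu", "Pv")
        ann = DomainAnnotation()
        ann.add_isoform("Pu", "Gu", "Tu1", ["PF1", "PF1"], canonical=True)
        ann.add_isoform("Pv", "Gv", "Tv1", ["PF2"], canonical=True)
        ddi = DDILibrary()
        ddi.add("PF1", "PF2")
        _, backing = build_reference_ddin(ppin, ann, ddi)
        assert len(backing[canonical_edge("Pu", "Pv")]) == 2

    def test_node_missing_from_annotation_is_named(self):
        ppin = Network()
        ppin.add_edge("Px", "Py")
        with pytest.raises(ValueError, match="Px"):
            build_reference_ddin(ppin, DomainAnnotation(), DDILibrary())


class TestContextualizeSample:
    def test_expressed_backed_edge_retained(self):
        ppin, ann, ddi, _ = switch_fixture()
        expr = ExpressionTable(
            "transcript",
            {"Tu1": 10.0, "Tu2": 2.0, "Tv1": 5.0},
            {"Tu1": "Gu", "Tu2": "Gu", "Tv1": "Gv"},
        )
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        result = contextualize_sample(ppin, ddin, backing, ann, expr)
        assert result.ppin.edges == ppin.edges

    def test_unexpressed_endpoint_drops_edges(self):
        ppin, ann, ddi, expr = switch_fixture()
        expr.abundance["Tv1"] = 0.0
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        result = contextualize_sample(ppin, ddin, backing, ann, expr)
        assert result.ppin.n_edges == 0
        assert "Pv" not in result.major

    def test_isoform_switch_removes_edge_despite_expression(self):
        ppin, ann, ddi, expr = switch_fixture()
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        result = contextualize_sample(ppin, ddin, backing, ann, expr)
        # both proteins are expressed ...
        assert set(result.major) == {"Pu", "Pv"}
        # ... yet the edge is gone: the major isoform Tu2 lacks PF1
        assert result.ppin.n_edges == 0

    def test_gene_only_mode_retains_edge_on_same_fixture(self):
        ppin, ann, ddi, expr = switch_fixture()
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        opts = ContextOptions(mode=GENE_ONLY)
        result = contextualize_sample(ppin, ddin, backing, ann, expr, opts)
        assert result.ppin.edges == ppin.edges

    def test_length_normalization_can_change_the_major_isoform(self):
        ppin, ann, ddi, _ = switch_fixture()
        # Tu1 has fewer fragments but is much shorter; per-length it wins
        expr = ExpressionTable(
            "transcript",
            {"Tu1": 6.0, "Tu2": 10.0, "Tv1": 5.0},
            {"Tu1": "Gu", "Tu2": "Gu", "Tv1": "Gv"},
            {"Tu1": 500, "Tu2": 5000, "Tv1": 1000},
        )
        ddin, backing = build_reference_ddin(ppin, ann, ddi)
        plain = contextualize_sample(ppin, ddin, backing, ann, expr)
        assert plain.ppin.n_edges == 0
        normalized = contextualize_sample(
            ppin, ddin, backing, ann, expr,
            ContextOptions(length_normalize=True),
        )
        assert normalized.ppin.n_edges == 1


class TestInvariants:
    """Structural guarantees over randomly generated scenarios."""

    def _fixtures(self, n=20):
        for seed in range(n):
            spec = ScenarioSpec(
                n_proteins=25, edge_density=0.15, ddi_backed_fraction=0.6,
                unannotated_fraction=0.3, background_flip_rate=0.3,
                n_samples_per_group=1, seed=seed,
            )
            scenario = generate_scenario(spec)
            _, table = scenario.groups["group1"][0]
            yield scenario, table

    def test_condition_network_is_subset_and_explained(self):
        for scenario, table in self._fixtures():
            ddin, backing = build_reference_ddin(
                scenario.ppin, scenario.annotation, scenario.ddi
            )
            result = contextualize_sample(
                scenario.ppin, ddin, backing, scenario.annotation, table
            )
            assert result.ppin.edges <= scenario.ppin.edges
            kept_domain_edges = result.ddin.edges
            for edge in result.ppin.edges:
                assert backing[edge] & kept_domain_edges

    def test_raising_threshold_never_adds_edges(self):
        for scenario, table in self._fixtures():
            ddin, backing = build_reference_ddin(
                scenario.ppin, scenario.annotation, scenario.ddi
            )
            edges = [
                contextualize_sample(
                    scenario.ppin, ddin, backing, scenario.annotation, table,
                    ContextOptions(threshold=t),
                ).ppin.edges
                for t in (0.5, 2.0, 10.0)
            ]
            assert edges[2] <= edges[1] <= edges[0]

    def test_dummy_neutrality_for_unannotated_pairs(self):
        # a pair with no domains anywhere: retention == both ends expressed
        ppin = Network()
        ppin.add_edge("Pa", "Pb")
        ann = DomainAnnotation()
        ann.add_isoform("Pa", "Ga", "Ta", [], canonical=True)
        ann.add_isoform("Pb", "Gb", "Tb", [], canonical=True)
        ddin, backing = build_reference_ddin(ppin, ann, DDILibrary())
        for ab_a, ab_b, expect in [(5.0, 5.0, 1), (5.0, 0.5, 0), (0.0, 5.0, 0)]:
            expr = ExpressionTable(
                "transcript", {"Ta": ab_a, "Tb": ab_b}, {"Ta": "Ga", "Tb": "Gb"}
            )
            result = contextualize_sample(ppin, ddin, backing, ann, expr)
            assert result.ppin.n_edges == expect

    def test_gene_only_all_expressed_dummy_backed_limit(self):
        # with nothing annotated and everything expressed, the condition
        # network reproduces the reference exactly
        spec = ScenarioSpec(
            n_proteins=30, edge_density=0.2, ddi_backed_fraction=0.0,
            unannotated_fraction=1.0, background_flip_rate=0.0,
            n_samples_per_group=1, seed=3,
        )
        scenario = generate_scenario(spec)
        ddin, backing = build_reference_ddin(
            scenario.ppin, scenario.annotation, scenario.ddi
        )
        _, table = scenario.groups["group1"][0]
        result = contextualize_sample(
            scenario.ppin, ddin, backing, scenario.annotation, table,
            ContextOptions(mode=GENE_ONLY),
        )
        assert result.ppin.edges == scenario.ppin.edges
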