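"""Gene-order representation, classification and adjacency distance."""

import pytest
from hypothesis import given, strategies as st

from mitoreorg.order import (
    GeneOrder, Token, reference_order, extract_gene_order, classify_order,
    shared_adjacency_distance, parse_order_string, format_order_string,
    FULL_GENE_COMPLEMENT,
)
from mitoreorg.simulate import SimSpec, generate_genome
from oracles import naive_adjacency_distance


def _names(order):
    return [t.name for t in order.linearized()]


class TestReferenceOrders:
    def test_vertebrate_ago_contains_wancy_block(self):
        names = _names(reference_order("vertebrate_AGO"))
        i = names.index("trnW")
        assert names[i: i + 6] == ["trnW", "trnA", "trnN", "OL", "trnC", "trnY"]

    def test_vertebrate_ago_has_22_trnas_and_full_complement(self):
        order = reference_order("vertebrate_AGO")
        trnas = [t for t in order if t.name.startswith("trn")]
        assert len(trnas) == 22
        assert {t.name for t in order} >= FULL_GENE_COMPLEMENT

    def test_ltpf_cluster_contiguous(self):
        names = _names(reference_order("neobatrachian_LTPF"))
        i = names.index("trnL(CUN)")
        assert names[i: i + 4] == ["trnL(CUN)", "trnT", "trnP", "trnF"]
        assert names[i + 4] == "CR"

    def test_unknown_reference_lists_available(self):
        with pytest.raises(ValueError, match="vertebrate_AGO"):
            reference_order("nope")


class TestRotationInvariance:
    def test_equality_under_rotation(self):
        order = reference_order("vertebrate_AGO")
        for k in (1, 5, 20, 38):
            assert order == order.rotated(k)

    @pytest.mark.parametrize("k_bp", [1, 137, 5000, 16000])
    def test_extraction_invariant_under_coordinate_rotation(self, ago_genome, k_bp):
        genome, _ = ago_genome
        rotated = genome.rotated(k_bp)
        assert extract_gene_order(rotated) == extract_gene_order(genome)

    def test_wrapping_cr_same_order_as_unwrapped(self, ago_genome):
        genome, _ = ago_genome
        # rotate so the CR (last feature) wraps the numbering origin
        cr = [f for f in genome.sorted_features() if f.name == "CR"][0]
        mid_cr = (cr.start + cr.length(genome.length) // 2) % genome.length
        rotated = genome.rotated(mid_cr)
        assert any(f.wraps_origin() for f in rotated.features)
        assert extract_gene_order(rotated) == extract_gene_order(genome)


class TestExtraction:
    def test_reference_genome_roundtrip(self, ago_genome):
        genome, _ = ago_genome
        assert extract_gene_order(genome) == reference_order("vertebrate_AGO")

    def test_pseudogene_retained_and_small_gap_ignored(self, ltpf_genome):
        genome, _ = ltpf_genome
        order = extract_gene_order(genome)
        assert any(t.name == "trnS(AGY)" and t.pseudo for t in order)
        assert not any(t.is_spacer() for t in order)

    def test_large_spacer_becomes_token(self, ago_genome):
        genome, _ = ago_genome
        # carve a 457 bp annotation gap by shrinking nad5's annotation
        import copy
        g = copy.deepcopy(genome)
        nad5 = [f for f in g.features if f.name == "nad5"][0]
        nad5.end -= 457
        order = extract_gene_order(g)
        assert "spacer(457)" in [t.name for t in order]


class TestClassification:
    def test_reference_ago_is_ago(self):
        assert classify_order(reference_order("vertebrate_AGO")).label == "AGO"

    def test_ltpf_is_rgo_with_cluster_feature(self):
        cls = classify_order(reference_order("neobatrachian_LTPF"))
        assert cls.label == "RGO"
        assert "LTPF_cluster" in cls.features
        assert cls.wancy_intact

    def test_gene_losses_reported(self):
        lost = {"trnA", "trnN", "trnC", "trnE"}
        toks = [t for t in reference_order("neobatrachian_LTPF")
                if t.name not in lost]
        cls = classify_order(GeneOrder(toks))
        assert cls.label == "RGO"
        assert set(cls.lost_genes) == lost
        assert not cls.wancy_intact

    def test_pseudogene_excluded_from_equality_but_reported(self, ltpf_genome):
        genome, _ = ltpf_genome
        cls = classify_order(extract_gene_order(genome))
        assert cls.label == "RGO"
        assert "trnS(AGY)_pseudo" in cls.features
        # no functional copy -> also reported as functionally lost
        assert "trnS(AGY)" in cls.lost_genes

    def test_trnh_translocation_and_trnm_duplication(self):
        base = list(reference_order("vertebrate_AGO").linearized())
        # move trnH next to the CR and duplicate trnM
        trnh = [t for t in base if t.name == "trnH"][0]
        base.remove(trnh)
        cr_at = [i for i, t in enumerate(base) if t.name == "CR"][0]
        base.insert(cr_at, trnh)
        trnm_at = [i for i, t in enumerate(base) if t.name == "trnM"][0]
        base.insert(trnm_at, Token("trnM", "+", False, 2))
        cls = classify_order(GeneOrder(base))
        assert cls.trnh_translocated
        assert cls.trnm_duplicated
        assert "trnM" in cls.duplicated_genes


class TestAdjacencyDistance:
    def test_identical_orders_distance_zero(self):
        ago = reference_order("vertebrate_AGO")
        assert shared_adjacency_distance(ago, ago) == 0

    def test_rotation_distance_zero(self):
        ago = reference_order("vertebrate_AGO")
        assert shared_adjacency_distance(ago, ago.rotated(11)) == 0

    def test_matches_naive_scan_on_references(self):
        a = reference_order("vertebrate_AGO")
        b = reference_order("neobatrachian_LTPF")
        expected = naive_adjacency_distance(list(a), list(b))
        assert shared_adjacency_distance(a, b) == expected
        assert expected > 0

    @given(st.integers(0, 38), st.integers(0, 38))
    def test_rotation_invariance_property(self, ka, kb):
        a = reference_order("vertebrate_AGO")
        b = reference_order("neobatrachian_LTPF")
        base = shared_adjacency_distance(a, b)
        assert shared_adjacency_distance(a.rotated(ka), b.rotated(kb)) == base


class TestOrderStrings:
    def test_roundtrip_with_strand_and_pseudo(self, ltpf_genome):
        genome, _ = ltpf_genome
        order = extract_gene_order(genome)
        assert parse_order_string(format_order_string(order)) == order

    def test_minus_strand_marked(self):
        s = format_order_string(reference_order("vertebrate_AGO"))
        assert "-trnQ" in s and "-nad6" in s


def test_single_tdrl_always_rgo():
    """Any order produced by >= 1 TDRL event on the ancestral order is RGO."""
    from mitoreorg.simulate import apply_random_tdrl
    ago = reference_order("vertebrate_AGO")
    for seed in range(10):
        derived, events = apply_random_tdrl(ago, 1, seed=seed)
        assert len(events) == 1
        assert classify_order(derived).label == "RGO"
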