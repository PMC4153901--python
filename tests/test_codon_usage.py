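"""Codon counting, RSCU and chi-square usage comparison."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from mitoreorg.model import MitoGenome, GeneFeature
from mitoreorg.codons import (
    CodonUsageTable, SENSE_CODONS, STOP_CODONS, CODON_TO_AA, SYN_FAMILIES,
    TRNA_CODON_MAP, count_codons, rscu, usage_by_trna, compare_usage_chi2,
)
from oracles import naive_codon_enumerator


def _cds_genome(seq, features=None, pad=30):
    """Genome holding one or more CDS features over an explicit sequence."""
    full = seq + "G" * pad
    feats = features or [GeneFeature("nad1", "CDS", "+", 0, len(seq))]
    return MitoGenome("toy", len(full), True, full, feats)


class TestGeneticCodeTables:
    def test_trna_map_partitions_sense_codons(self):
        seen = Counter()
        for codons in TRNA_CODON_MAP.values():
            seen.update(codons)
        assert set(seen) == set(SENSE_CODONS)
        assert all(v == 1 for v in seen.values())
        assert len(TRNA_CODON_MAP) == 22
        assert len(SENSE_CODONS) == 60

    def test_vertebrate_mito_reassignments(self):
        assert {"AGA", "AGG", "TAA", "TAG"} == set(STOP_CODONS)
        assert CODON_TO_AA["ATA"] == "M"
        assert CODON_TO_AA["TGA"] == "W"

    def test_leu_ser_split_families(self):
        assert SYN_FAMILIES["Leu(UUR)"] == frozenset({"TTA", "TTG"})
        assert SYN_FAMILIES["Ser(AGY)"] == frozenset({"AGT", "AGC"})
        assert len(SYN_FAMILIES) == 22


class TestCountCodons:
    def test_hand_countable_cds_with_rna_letters(self):
        g = _cds_genome("ATGATAAUGTAA".replace("U", "T"))
        t = count_codons(g)
        assert dict(t.pooled) == {"ATG": 2, "ATA": 1}
        assert t.total_codons == 3

    def test_overlapping_genes_counted_in_both(self):
        # atp8/atp6-style 10 nt overlap: both genes see the shared codons
        seq = "ATG" + "GCA" * 9 + "ATGGCC" + "CCT" * 8
        g = _cds_genome(seq, [
            GeneFeature("atp8", "CDS", "+", 0, 30),
            GeneFeature("atp6", "CDS", "+", 18, len(seq)),
        ])
        t = count_codons(g)
        overlap_codons = {"GCA"}
        assert all(t.per_gene["atp8"][c] > 0 for c in overlap_codons)
        assert all(t.per_gene["atp6"][c] > 0 for c in overlap_codons)
        assert t.pooled["GCA"] == t.per_gene["atp8"]["GCA"] + t.per_gene["atp6"]["GCA"]
        # with global deduplication the shared codons count once in pooled
        t2 = count_codons(g, dedupe_overlaps=True)
        assert t2.pooled["GCA"] < t.pooled["GCA"]
        assert t2.per_gene == t.per_gene

    def test_incomplete_terminal_codon_dropped(self):
        seq = "ATG" + "CTA" * 5 + "GC"  # 3k+2: last 2 nt dropped, no stop
        g = _cds_genome(seq)
        t = count_codons(g)
        expected = naive_codon_enumerator(seq, STOP_CODONS)
        assert t.pooled == expected
        assert t.total_codons == 6

    def test_internal_stop_flagged_not_fatal(self):
        seq = "ATG" + "AGA" + "CTA" * 3 + "TAA"
        g = _cds_genome(seq)
        with pytest.warns(UserWarning, match="internal stop"):
            t = count_codons(g)
        assert "nad1" in t.internal_stop_genes
        assert t.pooled["CTA"] == 3

    def test_ambiguous_codons_skipped_and_counted(self):
        seq = "ATG" + "CNA" + "CTA" * 2
        g = _cds_genome(seq)
        t = count_codons(g)
        assert t.skipped_ambiguous == 1
        assert t.total_codons == 3

    def test_missing_sequence_errors(self):
        g = MitoGenome("x", 100, True, None,
                       [GeneFeature("nad1", "CDS", "+", 0, 30)])
        with pytest.raises(ValueError, match="sequence"):
            count_codons(g)

    def test_minus_strand_gene_read_from_reverse_complement(self):
        from mitoreorg.model import revcomp
        sense = "ATGCTACTATAA"
        seq = revcomp(sense)
        g = _cds_genome(seq, [GeneFeature("nad6", "CDS", "-", 0, len(seq))])
        t = count_codons(g)
        assert dict(t.pooled) == {"ATG": 1, "CTA": 2}

    def test_agrees_with_naive_enumerator_on_synthetic_genome(self, ago_genome):
        genome, _ = ago_genome
        t = count_codons(genome)
        total = Counter()
        for f in genome.sorted_features():
            if f.kind == "CDS" and not f.pseudogene:
                total += naive_codon_enumerator(
                    genome.feature_sequence(f), STOP_CODONS)
        assert t.pooled == total


class TestRSCU:
    def test_skewed_four_codon_family(self):
        tab = CodonUsageTable("x", pooled=Counter({"GTT": 8}))
        r = rscu(tab)
        assert r.values["GTT"] == 4.0
        assert r.values["GTC"] == 0.0

    def test_equal_counts_give_unity(self):
        tab = CodonUsageTable("x", pooled=Counter(
            {c: 5 for c in SYN_FAMILIES["Pro"]}))
        r = rscu(tab)
        assert all(r.values[c] == 1.0 for c in SYN_FAMILIES["Pro"])

    def test_split_family_hand_calculation(self):
        tab = CodonUsageTable("x", pooled=Counter(
            {"CTT": 2, "CTC": 1, "CTA": 1, "CTG": 0, "TTA": 5, "TTG": 1}))
        r = rscu(tab)
        assert r.values["CTT"] == pytest.approx(2.0)
        assert r.values["TTA"] == pytest.approx(5 / 3)

    def test_zero_family_reported_missing(self):
        tab = CodonUsageTable("x", pooled=Counter({"AAA": 3}))
        assert rscu(tab).values["GGG"] is None

    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(0, 500), max_size=60))
    def test_normalization_property(self, counts):
        tab = CodonUsageTable("x", pooled=Counter(counts))
        r = rscu(tab)
        for fam, codons in SYN_FAMILIES.items():
            vals = [r.values[c] for c in codons]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(codons), abs=1e-12)
                assert sum(vals) / len(vals) == pytest.approx(1.0, abs=1e-12)


class TestUsageByTrna:
    def test_met_codons_route_to_trnm(self):
        tab = CodonUsageTable("x", pooled=Counter({"ATG": 2, "ATA": 3}),
                              total_codons=5)
        u = usage_by_trna(tab)
        assert u["trnM"] == 5
        assert sum(u.values()) == 5

    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(0, 100), max_size=60))
    def test_partition_conservation(self, counts):
        tab = CodonUsageTable("x", pooled=Counter(counts),
                              total_codons=sum(counts.values()))
        assert sum(usage_by_trna(tab).values()) == tab.total_codons

    def test_matches_generator_ledger(self, ago_genome):
        genome, ledger = ago_genome
        u = usage_by_trna(count_codons(genome))
        for trna, codons in TRNA_CODON_MAP.items():
            assert u[trna] == sum(
                ledger["pooled_counts"].get(c, 0) for c in codons)


class TestChi2:
    def test_identical_tables(self):
        a = CodonUsageTable("a", pooled=Counter({"AAA": 30, "AAG": 10}))
        chi2, df, p = compare_usage_chi2(a, a)
        assert chi2 == 0.0 and p == 1.0 and df == 1

    def test_scale_invariance(self):
        a = CodonUsageTable("a", pooled=Counter({"AAA": 10, "AAG": 10}))
        b = CodonUsageTable("b", pooled=Counter({"AAA": 30, "AAG": 30}))
        chi2, _, p = compare_usage_chi2(a, b)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        a = CodonUsageTable("a", pooled=Counter({"AAA": 30, "AAG": 10}))
        b = CodonUsageTable("b", pooled=Counter({"AAA": 10, "AAG": 30}))
        chi2, df, p = compare_usage_chi2(a, b)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_too_few_columns_errors(self):
        a = CodonUsageTable("a", pooled=Counter({"AAA": 5}))
        with pytest.raises(ValueError, match="columns"):
            compare_usage_chi2(a, a)

    def test_same_species_usage_not_distinguishable(self, ago_genome):
        """Two genomes drawn from the same usage model should not differ
        (the tRNA-loss comparisons expect p > 0.05 for the null)."""
        from mitoreorg.simulate import SimSpec, generate_genome
        spec = SimSpec(seed=21, n_species=2)
        a = count_codons(generate_genome(spec, 0)[0])
        b = count_codons(generate_genome(spec, 1)[0])
        _, _, p = compare_usage_chi2(a, b)
        assert p > 0.05
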