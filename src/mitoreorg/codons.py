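"""Codon counting, RSCU and codon-usage comparison under the vertebrate
mitochondrial genetic code (NCBI translation table 2).

Under this code AGA/AGG are stops, AUA codes Met and UGA codes Trp, which
leaves 60 sense codons decoded by 22 tRNA isotypes.  Synonymous families
follow the two-tRNA split for leucine (CUN vs UUR) and serine (UCN vs
AGY), so each family corresponds one-to-one with a tRNA isotype.

RSCU (relative synonymous codon usage) of codon c in family F of size n_F:

    RSCU_c = x_c / ((1/n_F) * sum_{c' in F} x_{c'})

i.e. the observed count divided by the family mean; 1 means no bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import Counter
from typing import Optional

from Bio.Data import CodonTable
from scipy import stats
import numpy as np

from .model import MitoGenome

__all__ = [
    "MITO_CODE_ID",
    "CODON_TO_AA",
    "STOP_CODONS",
    "SENSE_CODONS",
    "TRNA_CODON_MAP",
    "SYN_FAMILIES",
    "TRNA_AMINO_ACID",
    "CodonUsageTable",
    "RSCUTable",
    "count_codons",
    "rscu",
    "usage_by_trna",
    "compare_usage_chi2",
]

MITO_CODE_ID = 2
_TABLE = CodonTable.unambiguous_dna_by_id[MITO_CODE_ID]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

# Which codons each mitochondrial tRNA isotype decodes (DNA alphabet).
# The 22 sets partition the 60 sense codons.
TRNA_CODON_MAP: dict[str, frozenset[str]] = {
    "trnF": frozenset({"TTT", "TTC"}),
    "trnL(UUR)": frozenset({"TTA", "TTG"}),
    "trnL(CUN)": frozenset({"CTT", "CTC", "CTA", "CTG"}),
    "trnI": frozenset({"ATT", "ATC"}),
    "trnM": frozenset({"ATA", "ATG"}),
    "trnV": frozenset({"GTT", "GTC", "GTA", "GTG"}),
    "trnS(UCN)": frozenset({"TCT", "TCC", "TCA", "TCG"}),
    "trnP": frozenset({"CCT", "CCC", "CCA", "CCG"}),
    "trnT": frozenset({"ACT", "ACC", "ACA", "ACG"}),
    "trnA": frozenset({"GCT", "GCC", "GCA", "GCG"}),
    "trnY": frozenset({"TAT", "TAC"}),
    "trnH": frozenset({"CAT", "CAC"}),
    "trnQ": frozenset({"CAA", "CAG"}),
    "trnN": frozenset({"AAT", "AAC"}),
    "trnK": frozenset({"AAA", "AAG"}),
    "trnD": frozenset({"GAT", "GAC"}),
    "trnE": frozenset({"GAA", "GAG"}),
    "trnC": frozenset({"TGT", "TGC"}),
    "trnW": frozenset({"TGA", "TGG"}),
    "trnR": frozenset({"CGT", "CGC", "CGA", "CGG"}),
    "trnS(AGY)": frozenset({"AGT", "AGC"}),
    "trnG": frozenset({"GGT", "GGC", "GGA", "GGG"}),
}

# Synonymous families, with Leu and Ser each split into the two families
# served by their two distinct tRNAs.  Family label = 3-letter amino acid
# (plus the split tag for Leu/Ser).
_FAMILY_LABEL = {
    "trnL(UUR)": "Leu(UUR)", "trnL(CUN)": "Leu(CUN)",
    "trnS(UCN)": "Ser(UCN)", "trnS(AGY)": "Ser(AGY)",
}
_AA3 = {
    "F": "Phe", "L": "Leu", "I": "Ile", "M": "Met", "V": "Val", "S": "Ser",
    "P": "Pro", "T": "Thr", "A": "Ala", "Y": "Tyr", "H": "His", "Q": "Gln",
    "N": "Asn", "K": "Lys", "D": "Asp", "E": "Glu", "C": "Cys", "W": "Trp",
    "R": "Arg", "G": "Gly",
}
SYN_FAMILIES: dict[str, frozenset[str]] = {}
TRNA_AMINO_ACID: dict[str, str] = {}
for _trna, _codons in TRNA_CODON_MAP.items():
    _aa = CODON_TO_AA[sorted(_codons)[0]]
    TRNA_AMINO_ACID[_trna] = _aa
    _label = _FAMILY_LABEL.get(_trna, _AA3[_aa])
    SYN_FAMILIES[_label] = _codons

FAMILY_OF_CODON: dict[str, str] = {
    c: fam for fam, codons in SYN_FAMILIES.items() for c in codons
}


@dataclass
class CodonUsageTable:
    """Codon counts for the protein-coding genes of one genome."""

    genome_id: str
    per_gene: dict[str, Counter] = field(default_factory=dict)
    pooled: Counter = field(default_factory=Counter)
    total_codons: int = 0
    skipped_ambiguous: int = 0
    internal_stop_genes: tuple[str, ...] = ()


@dataclass
class RSCUTable:
    """RSCU values per codon; families with zero total are missing (None)."""

    families: dict[str, frozenset[str]]
    values: dict[str, Optional[float]]


def _codon_positions(feat, genome: MitoGenome) -> list[tuple[int, ...]]:
    """Genomic coordinates of each codon's three bases, 5'->3' in the gene
    frame (used for the optional global overlap deduplication)."""
    L = genome.length
    n = feat.length(L)
    if feat.strand == "+":
        coords = [(feat.start + k) % L for k in range(n)]
    else:
        coords = [(feat.end - 1 - k) % L for k in range(n)]
    return [tuple(coords[k: k + 3]) for k in range(0, n - n % 3, 3)]


def count_codons(genome: MitoGenome, dedupe_overlaps: bool = False) -> CodonUsageTable:
    """Count sense codons of every annotated (non-pseudo) protein-coding
    gene, each gene read in its own frame from its own strand.

    Terminal stop codons and incomplete terminal codons are excluded;
    codons containing ambiguity characters are skipped (counted in
    ``skipped_ambiguous``).  Internal stop codons are skipped and the gene
    flagged (pseudogene suspicion) with a warning.  By default, codons of
    physically overlapping genes are counted once *per gene* (so the
    overlap contributes to both genes); ``dedupe_overlaps=True`` instead
    counts each genomic codon once in the pooled table.
    """
    if genome.sequence is None:
        raise ValueError(f"{genome.id}: codon counting needs a sequence")
    table = CodonUsageTable(genome_id=genome.id)
    flagged: list[str] = []
    seen_positions: set[tuple[int, ...]] = set()
    for feat in genome.sorted_features():
        if feat.kind != "CDS" or feat.pseudogene:
            continue
        seq = genome.feature_sequence(feat).upper().replace("U", "T")
        seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[k: k + 3] for k in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons.pop()
        positions = _codon_positions(feat, genome) if dedupe_overlaps else None
        gene_counts: Counter = Counter()
        for idx, codon in enumerate(codons):
            if any(ch not in "ACGT" for ch in codon):
                table.skipped_ambiguous += 1
                continue
            if codon in STOP_CODONS:
                if feat.name not in flagged:
                    flagged.append(feat.name)
                    warnings.warn(
                        f"{genome.id}:{feat.name}: internal stop codon "
                        f"(pseudogene suspicion)", stacklevel=2)
                continue
            gene_counts[codon] += 1
            if dedupe_overlaps:
                pos = positions[idx]
                if pos in seen_positions:
                    continue
                seen_positions.add(pos)
            table.pooled[codon] += 1
            table.total_codons += 1
        key = feat.name if feat.copy_index == 1 else f"{feat.name}.{feat.copy_index}"
        table.per_gene[key] = gene_counts
    table.internal_stop_genes = tuple(flagged)
    return table


def rscu(table: CodonUsageTable, gene: Optional[str] = None) -> RSCUTable:
    """RSCU of every sense codon, computed on the pooled counts by default
    or on a single gene's counts when ``gene`` is given."""
    counts = table.pooled if gene is None else table.per_gene[gene]
    values: dict[str, Optional[float]] = {}
    for fam, codons in SYN_FAMILIES.items():
        total = sum(counts[c] for c in codons)
        if total == 0:
            for c in codons:
                values[c] = None
            continue
        mean = total / len(codons)
        for c in codons:
            values[c] = counts[c] / mean
    return RSCUTable(families=dict(SYN_FAMILIES), values=values)


def usage_by_trna(
    table: CodonUsageTable,
    trna_map: dict[str, frozenset[str]] = TRNA_CODON_MAP,
) -> dict[str, int]:
    """Total usage of the codons each tRNA isotype decodes.

    Because the isotype codon sets partition the sense codons, the values
    sum to ``table.total_codons`` (when the default map is used and the
    pooled table was built without global deduplication).
    """
    return {
        trna: sum(table.pooled[c] for c in codons)
        for trna, codons in trna_map.items()
    }


def compare_usage_chi2(
    a: CodonUsageTable,
    b: CodonUsageTable,
    min_expected: float = 1.0,
    pool_small: bool = True,
) -> tuple[float, int, float]:
    """Chi-square test of homogeneity on the 2 x K table of pooled sense-
    codon counts of two genomes.

    Columns where both genomes have zero counts are dropped; columns whose
    expected count falls below ``min_expected`` are pooled into a single
    'other' column (no Yates correction).  Returns (chi2, df, p).
    """
    codons = [c for c in SENSE_CODONS if a.pooled[c] + b.pooled[c] > 0]
    if not codons:
        raise ValueError("no usable codon columns")
    obs = np.array([[a.pooled[c] for c in codons],
                    [b.pooled[c] for c in codons]], dtype=float)
    if pool_small and obs.shape[1] > 1:
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        small = (expected < min_expected).any(axis=0)
        if small.any() and (~small).any():
            pooled_col = obs[:, small].sum(axis=1, keepdims=True)
            obs = np.hstack([obs[:, ~small], pooled_col])
        elif small.all():
            pass  # everything small: leave the table as-is
    if obs.shape[1] < 2:
        raise ValueError("fewer than 2 usable codon columns for the chi-square test")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)
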