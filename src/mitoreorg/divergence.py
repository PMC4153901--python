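"""Pairwise synonymous/nonsynonymous divergence (Nei–Gojobori 1986).

For each codon, every site is apportioned between synonymous and
nonsynonymous according to the fraction of its possible single-nucleotide
changes that preserve the amino acid (changes creating a stop codon are
excluded from the denominator).  Site counts of the two sequences are
averaged.  Differences in codons that differ at several positions are
averaged over all minimal substitution pathways; pathways that pass
through a stop codon are discarded (if every pathway does, all are kept
and stop-crossing steps count as nonsynonymous).  Proportions are
Jukes–Cantor corrected:

    d = -(3/4) * ln(1 - (4/3) p)

Everything uses the vertebrate mitochondrial genetic code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

from scipy import stats

from .model import MitoGenome
from .codons import CODON_TO_AA, STOP_CODONS

__all__ = [
    "DivergenceResult",
    "ng86_pairwise",
    "genome_pair_divergence",
    "compare_rate_groups",
    "syn_site_fraction",
    "jukes_cantor",
    "SaturationError",
    "MidSequenceStopError",
]

logger = logging.getLogger(__name__)

_NT = "ACGT"


class SaturationError(ValueError):
    """p >= 3/4: the Jukes–Cantor correction is undefined."""


class MidSequenceStopError(ValueError):
    """A stop codon occurs before the end of a coding sequence."""


def _syn_fractions() -> dict[str, tuple[float, float, float]]:
    out = {}
    for codon, aa in CODON_TO_AA.items():
        fr = []
        for pos in range(3):
            syn = tot = 0
            for nt in _NT:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                tot += 1
                syn += CODON_TO_AA[alt] == aa
            fr.append(syn / tot if tot else 0.0)
        out[codon] = tuple(fr)
    return out


_SYN_FRACTION = _syn_fractions()


def syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites of a sense codon (0..3)."""
    return sum(_SYN_FRACTION[codon])


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over minimal substitution pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                steps.append(False)
            else:
                steps.append(CODON_TO_AA.get(cur, "*") == CODON_TO_AA.get(nxt, "*"))
            cur = nxt
        paths.append((through_stop, steps))
    valid = [steps for through, steps in paths if not through]
    if not valid:
        valid = [steps for _, steps in paths]
    sd = sum(sum(steps) for steps in valid) / len(valid)
    nd = sum(len(steps) - sum(steps) for steps in valid) / len(valid)
    return sd, nd


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def jukes_cantor(p: float, what: str = "p") -> float:
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(f"{what} = {p:.4f} >= 3/4; distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DivergenceResult:
    gene: str
    pair_id: str
    codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: Optional[float]
    flags: tuple[str, ...] = ()


def ng86_pairwise(
    cds_a: str,
    cds_b: str,
    gene: str = "",
    pair_id: str = "",
) -> DivergenceResult:
    """NG86 dS/dN between two aligned, equal-length coding sequences.

    Incomplete terminal codons are trimmed; terminal stop codons and codon
    pairs containing gaps or ambiguity characters are skipped.  A stop
    codon before the end raises :class:`MidSequenceStopError`.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(
            f"{gene or 'pair'}: length mismatch {len(a)} != {len(b)}")
    n3 = len(a) - len(a) % 3
    a, b = a[:n3], b[:n3]
    ncod = n3 // 3
    S = N = Sd = Nd = 0.0
    used = 0
    flags: list[str] = []
    for k in range(ncod):
        c1, c2 = a[3 * k: 3 * k + 3], b[3 * k: 3 * k + 3]
        if any(ch not in _NT for ch in c1 + c2):
            continue
        stop1, stop2 = c1 in STOP_CODONS, c2 in STOP_CODONS
        if stop1 or stop2:
            if k == ncod - 1:  # terminal stop: excluded
                continue
            raise MidSequenceStopError(
                f"{gene or 'pair'}: stop codon at codon {k + 1} of {ncod}")
        used += 1
        S += (syn_site_fraction(c1) + syn_site_fraction(c2)) / 2.0
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        if key not in _PAIR_CACHE:
            _PAIR_CACHE[key] = _pathway_counts(*key)
        sd, nd = _PAIR_CACHE[key]
        Sd += sd
        Nd += nd
    N = 3.0 * used - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS, "pS")
    dN = jukes_cantor(pN, "pN")
    if dS == 0.0:
        omega = None
        flags.append("dS=0" if dN > 0 else "dS=0,dN=0")
    else:
        omega = dN / dS
    return DivergenceResult(
        gene=gene, pair_id=pair_id, codons=used,
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, flags=tuple(flags),
    )


def genome_pair_divergence(
    a: MitoGenome, b: MitoGenome
) -> list[DivergenceResult]:
    """NG86 divergence for every protein-coding gene shared by two annotated
    genomes.  Genes are paired by normalized name; no alignment is done, so
    length-mismatched genes are skipped with a log line (real data must be
    pre-aligned; simulated congeneric pairs match by construction)."""
    def cds_map(g: MitoGenome):
        return {f.name: f for f in g.sorted_features()
                if f.kind == "CDS" and not f.pseudogene and f.copy_index == 1}

    ca, cb = cds_map(a), cds_map(b)
    shared = sorted(set(ca) & set(cb))
    if not shared:
        raise ValueError(f"{a.id} vs {b.id}: no shared protein-coding genes")
    pair_id = f"{a.id}|{b.id}"
    out: list[DivergenceResult] = []
    for gene in shared:
        sa = a.feature_sequence(ca[gene])
        sb = b.feature_sequence(cb[gene])
        if len(sa) != len(sb):
            logger.warning("%s: %s length mismatch (%d vs %d bp); skipped",
                           pair_id, gene, len(sa), len(sb))
            continue
        try:
            out.append(ng86_pairwise(sa, sb, gene=gene, pair_id=pair_id))
        except (MidSequenceStopError, SaturationError) as exc:
            logger.warning("%s: %s skipped: %s", pair_id, gene, exc)
    return out


def compare_rate_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "mannwhitney",
) -> tuple[float, float]:
    """Two-sided comparison of two sets of per-gene rate estimates.

    Default is the Mann–Whitney U test (rank-based, no normality
    assumption); ``method='welch'`` gives Welch's t-test.
    """
    a = [v for v in group_a if v == v and math.isfinite(v)]
    b = [v for v in group_b if v == v and math.isfinite(v)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
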