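"""tRNA gene position vs codon usage.

The adaptive-gene-order hypothesis predicts that heavily used tRNA genes
sit close to the control region (CR), where transcription initiates.  The
test statistic is the correlation, over (genome, tRNA isotype) pairs,
between the physical distance of the tRNA gene's 5' end from the CR's 3'
end and the total usage of the codons that tRNA decodes in the 13
protein-coding genes.

Distances are measured along the circle in the annotation (heavy-strand
transcription) direction, modulo genome length, so a tRNA just upstream
of the CR gets a large distance, never a negative one.  For genomes with
duplicated CRs or tRNAs only the first copy (first encountered scanning
downstream from the CR 3' end) is analyzed; pseudogene tRNAs are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MitoGenome
from .codons import TRNA_CODON_MAP, TRNA_AMINO_ACID, count_codons, usage_by_trna

__all__ = [
    "TrnaUsageRecord",
    "CorrelationResult",
    "HYDROPHOBIC_AA",
    "trna_cr_distances",
    "assemble_dataset",
    "correlate",
    "correlation_report",
    "MissingControlRegionError",
    "ConstantInputError",
]

logger = logging.getLogger(__name__)

# Hydropathy classes for reporting (grouping only; affects no statistic).
HYDROPHOBIC_AA = frozenset("GAVLIPFMWC")


class MissingControlRegionError(ValueError):
    """Genome lacks an (intact) control region feature."""


class ConstantInputError(ValueError):
    """Correlation undefined: an input vector is constant."""


@dataclass(frozen=True)
class TrnaUsageRecord:
    species: str
    trna: str
    distance: int
    usage: int
    hydropathy: str

    def __post_init__(self):
        if self.distance < 0 or self.usage < 0:
            raise ValueError("distance and usage must be non-negative")


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def trna_cr_distances(
    genome: MitoGenome, direction: str = "downstream"
) -> dict[str, int]:
    """Distance (bp) of each non-pseudogene tRNA isotype's first copy from
    the control region's 3' end.

    ``direction='downstream'`` (default) measures the directed arc from
    the CR 3' end to the tRNA 5' end; ``'min_arc'`` takes the shorter of
    the two arcs.  For a '-' strand tRNA the 5' end is the annotation-end
    coordinate.
    """
    L = genome.length
    crs = [f for f in genome.sorted_features()
           if f.kind == "CR" and not f.pseudogene]
    if not crs:
        raise MissingControlRegionError(f"{genome.id}: no control region feature")
    cr = crs[0]  # first copy in genome scan order
    origin = cr.end % L
    out: dict[str, int] = {}
    for f in genome.sorted_features():
        if f.kind != "tRNA" or f.pseudogene:
            continue
        five_prime = f.start if f.strand == "+" else (f.end - 1) % L
        d = (five_prime - origin) % L
        if direction == "min_arc":
            d = min(d, L - d)
        elif direction != "downstream":
            raise ValueError(f"unknown distance direction {direction!r}")
        # first copy = smallest downstream distance from the CR 3' end
        if f.name not in out or d < out[f.name]:
            out[f.name] = d
    return out


def assemble_dataset(
    genomes: Iterable[MitoGenome],
    trna_map: dict[str, frozenset[str]] = TRNA_CODON_MAP,
    direction: str = "downstream",
) -> list[TrnaUsageRecord]:
    """One record per (genome, non-pseudogene tRNA isotype first copy):
    distance from the CR and usage of the decoded codons.

    Genomes that fail (e.g. missing CR or sequence) are skipped with a log
    line; an empty result raises.
    """
    records: list[TrnaUsageRecord] = []
    for g in genomes:
        try:
            dists = trna_cr_distances(g, direction=direction)
            usage = usage_by_trna(count_codons(g), trna_map)
        except (MissingControlRegionError, ValueError) as exc:
            logger.warning("skipping %s: %s", g.id, exc)
            continue
        for trna, d in sorted(dists.items()):
            if trna not in trna_map:
                continue
            aa = TRNA_AMINO_ACID[trna]
            records.append(TrnaUsageRecord(
                species=g.id,
                trna=trna,
                distance=d,
                usage=usage.get(trna, 0),
                hydropathy="hydrophobic" if aa in HYDROPHOBIC_AA else "hydrophilic",
            ))
    if not records:
        raise ValueError("no usable (distance, usage) records assembled")
    return records


def correlate(records: Sequence[TrnaUsageRecord]) -> CorrelationResult:
    """Pearson (raw values) and Spearman (average ranks, tie-aware)
    correlation between distance and usage, with two-tailed p-values."""
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    x = np.array([r.distance for r in records], dtype=float)
    y = np.array([r.usage for r in records], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        n=len(records),
    )


def correlation_report(
    genome_sets: dict[str, Sequence[MitoGenome]],
    trna_map: dict[str, frozenset[str]] = TRNA_CODON_MAP,
    direction: str = "downstream",
) -> pd.DataFrame:
    """Pooled, per-species and per-hydropathy-class correlations for each
    named genome set.  Rows whose correlation is undefined (too few points
    or constant input) carry NaN statistics."""
    if not genome_sets:
        raise ValueError("no genome sets given")
    rows = []

    def _row(set_name, scope, name, recs):
        base = dict(set=set_name, scope=scope, name=name, n=len(recs))
        try:
            res = correlate(recs)
            base.update(pearson_r=res.pearson_r, pearson_p=res.pearson_p,
                        spearman_rho=res.spearman_rho, spearman_p=res.spearman_p)
        except ValueError:
            base.update(pearson_r=np.nan, pearson_p=np.nan,
                        spearman_rho=np.nan, spearman_p=np.nan)
        rows.append(base)

    for set_name, genomes in genome_sets.items():
        if not len(genomes):
            raise ValueError(f"genome set {set_name!r} is empty")
        recs = assemble_dataset(genomes, trna_map, direction)
        _row(set_name, "pooled", set_name, recs)
        for species in sorted({r.species for r in recs}):
            _row(set_name, "species", species,
                 [r for r in recs if r.species == species])
        for cls in ("hydrophobic", "hydrophilic"):
            _row(set_name, "hydropathy", cls,
                 [r for r in recs if r.hydropathy == cls])
    return pd.DataFrame(rows)
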