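"""End-to-end pipeline orchestration.

A :class:`RunConfig` (usually loaded from a YAML file) fully determines a
run: inputs (GenBank paths or a simulation spec), stage toggles, the
output directory and a single seed from which every stochastic stage
draws a named substream.  The pipeline mirrors the analysis sequence of a
mitogenome-reorganization study: gene orders -> TDRL scenarios at the
WANCY hotspot -> codon usage / RSCU -> position-usage correlations ->
pairwise dS/dN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .model import MitoGenome
from .order import (
    GeneOrder, classify_order, extract_gene_order, format_order_string,
    reference_order,
)
from .tdrl import infer_tdrl, TdrlBoundError, TdrlInconsistencyError
from .codons import count_codons, rscu, usage_by_trna, SENSE_CODONS, CODON_TO_AA, FAMILY_OF_CODON
from .positions import correlation_report
from .divergence import genome_pair_divergence
from .simulate import SimSpec, generate_genome, evolve_pair
from .io import read_genbank, write_genbank

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_WANCY_NAMES = ("trnW", "trnA", "trnN", "OL", "trnC", "trnY")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    outdir: str = "mitoreorg_out"
    seed: int = 0
    inputs: list = field(default_factory=list)       # GenBank paths
    simulate: Optional[dict] = None                  # SimSpec kwargs + n_species
    pair_targets: Optional[dict] = None              # {"dS": float, "dN": float}
    sets: dict = field(default_factory=dict)         # name -> [genome ids]
    stages: dict = field(default_factory=lambda: {
        "orders": True, "tdrl": True, "codon_usage": True,
        "correlate": True, "dnds": True,
    })
    distance_direction: str = "downstream"
    dedupe_overlaps: bool = False
    min_spacer: int = 30


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _load_genomes(config: RunConfig, outdir: Path) -> list[MitoGenome]:
    genomes: list[MitoGenome] = []
    for p in config.inputs:
        genomes.extend(read_genbank(p))
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        spec = SimSpec(**sim)
        sim_genomes = []
        for i in range(spec.n_species):
            g, _ = generate_genome(spec, i)
            sim_genomes.append(g)
        write_genbank(sim_genomes, outdir / "simulated.gb")
        genomes.extend(sim_genomes)
    if not genomes:
        raise ValueError("no input genomes (neither 'inputs' nor 'simulate' given)")
    return genomes


def _wancy_segment(order: GeneOrder):
    """The observed tokens between trnW and trnY inclusive, or None."""
    toks = list(order.linearized())
    names = [t.name for t in toks]
    if "trnW" not in names or "trnY" not in names:
        return None
    i = names.index("trnW")
    j = len(names) - 1 - names[::-1].index("trnY")
    if j < i:
        return None
    return toks[i: j + 1]


def _stage_orders(genomes, orders, outdir: Path) -> pd.DataFrame:
    rows = []
    for g, order in zip(genomes, orders):
        cls = classify_order(order)
        rows.append({
            "id": g.id,
            "length": g.length,
            "label": cls.label,
            "features": ";".join(sorted(cls.features)) or "-",
            "order": format_order_string(order),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "orders.tsv", sep="\t", index=False)
    return df


def _stage_tdrl(genomes, orders, outdir: Path) -> None:
    ref = _wancy_segment(reference_order("vertebrate_AGO"))
    out = {}
    for g, order in zip(genomes, orders):
        seg = _wancy_segment(order)
        entry: dict = {}
        if seg is None:
            entry["status"] = "no WANCY segment"
        else:
            try:
                scenarios = infer_tdrl(ref, seg)
            except (TdrlBoundError, TdrlInconsistencyError) as exc:
                entry["status"] = f"error: {exc}"
            else:
                if [t.key(False) for t in seg] == [t.key(False) for t in ref]:
                    entry["status"] = "ancestral"
                elif not scenarios:
                    entry["status"] = "unexplained by a single TDRL"
                else:
                    entry["status"] = "explained"
                    entry["scenarios"] = [
                        {"start": s.start, "end": s.end, "fates": s.fates,
                         "cost": s.cost} for s in scenarios
                    ]
        out[g.id] = entry
    with open(outdir / "tdrl.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


def _stage_codon_usage(genomes, outdir: Path, dedupe: bool):
    usage_rows, rscu_rows = [], []
    tables = {}
    for g in genomes:
        table = count_codons(g, dedupe_overlaps=dedupe)
        tables[g.id] = table
        r = rscu(table)
        per_trna = usage_by_trna(table)
        for codon in SENSE_CODONS:
            usage_rows.append({
                "id": g.id, "codon": codon, "aa": CODON_TO_AA[codon],
                "family": FAMILY_OF_CODON[codon],
                "count": table.pooled[codon],
            })
            val = r.values[codon]
            rscu_rows.append({
                "id": g.id, "codon": codon, "aa": CODON_TO_AA[codon],
                "family": FAMILY_OF_CODON[codon],
                "count": table.pooled[codon],
                "rscu": "" if val is None else f"{val:.6f}",
            })
        for trna, n in sorted(per_trna.items()):
            usage_rows.append({
                "id": g.id, "codon": f"[{trna}]", "aa": "", "family": "",
                "count": n,
            })
    pd.DataFrame(usage_rows).to_csv(outdir / "codon_usage.tsv", sep="\t", index=False)
    pd.DataFrame(rscu_rows).to_csv(outdir / "rscu.tsv", sep="\t", index=False)
    return tables


def _stage_correlate(genomes, config: RunConfig, orders, outdir: Path) -> pd.DataFrame:
    by_id = {g.id: g for g in genomes}
    sets: dict[str, list[MitoGenome]] = {"all": list(genomes)}
    labels = {g.id: classify_order(o).label for g, o in zip(genomes, orders)}
    ago = [g for g in genomes if labels[g.id] == "AGO"]
    rgo = [g for g in genomes if labels[g.id] == "RGO"]
    if ago:
        sets["AGO"] = ago
    if rgo:
        sets["RGO"] = rgo
    for name, ids in (config.sets or {}).items():
        sets[name] = [by_id[i] for i in ids]
    df = correlation_report(sets, direction=config.distance_direction)
    df.to_csv(outdir / "correlations.tsv", sep="\t", index=False,
              float_format="%.10g")
    return df


def _stage_dnds(genomes, config: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    targets = config.pair_targets or {"dS": 0.10, "dN": 0.02}
    for i, g in enumerate(genomes):
        if g.sequence is None:
            continue
        partner, _ = evolve_pair(g, targets["dS"], targets["dN"],
                                 seed=config.seed * 100003 + i)
        for res in genome_pair_divergence(g, partner):
            rows.append({
                "pair": res.pair_id, "gene": res.gene, "codons": res.codons,
                "dS": f"{res.dS:.6f}", "dN": f"{res.dN:.6f}",
                "omega": "NA" if res.omega is None else f"{res.omega:.6f}",
                "flags": ";".join(res.flags) or "-",
            })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "dnds.tsv", sep="\t", index=False)
    return df


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    The config is echoed verbatim into the output directory and a run log
    records versions, the seed and per-genome skip reasons.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mitoreorg")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("mitoreorg %s, seed=%d", __version__, config.seed)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)
        genomes = _load_genomes(config, outdir)
        logger.info("loaded %d genomes", len(genomes))
        orders = [extract_gene_order(g, min_spacer=config.min_spacer)
                  for g in genomes]
        stages = config.stages
        if stages.get("orders", True):
            _stage_orders(genomes, orders, outdir)
        if stages.get("tdrl", True):
            _stage_tdrl(genomes, orders, outdir)
        if stages.get("codon_usage", True):
            _stage_codon_usage(genomes, outdir, config.dedupe_overlaps)
        if stages.get("correlate", True):
            _stage_correlate(genomes, config, orders, outdir)
        if stages.get("dnds", True):
            _stage_dnds(genomes, config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
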