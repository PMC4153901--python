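"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates anuran-like circular mitochondrial genomes
(~15-18 kb; 13 protein-coding genes, 2 rRNAs, up to 22 tRNAs, a control
region with tandem repeats, an O_L, optional pseudogenes/duplications)
whose gene orders derive from the vertebrate ancestral order, optionally
by random TDRL events.  Codon usage is drawn codon-by-codon from a
controllable model in which a synonymous family's weight can be linked
log-linearly to the distance of its tRNA gene from the control region
(coefficient ``beta``), and congeneric partners can be evolved to target
dS/dN values.  Every true parameter (codon counts, tRNA distances,
substitution counts, TDRL events) is recorded in a ledger so that each
pipeline stage can be checked against ground truth.

Sequence realism is secondary to statistical structure: tRNA features are
placeholders of realistic length carrying the right anticodon, not
foldable cloverleaves; no pipeline stage reads tRNA structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from collections import Counter
from typing import Optional, Sequence, Union

import numpy as np

from .model import MitoGenome, GeneFeature, revcomp
from .order import GeneOrder, Token, reference_order
from .tdrl import TDRLScenario, apply_tdrl
from .codons import (
    SENSE_CODONS,
    STOP_CODONS,
    CODON_TO_AA,
    TRNA_CODON_MAP,
    FAMILY_OF_CODON,
)
from .divergence import syn_site_fraction
from .positions import trna_cr_distances

__all__ = [
    "SimSpec",
    "GENE_CODONS",
    "generate_genome",
    "generate_correlated_set",
    "calibrate_beta",
    "evolve_pair",
    "apply_random_tdrl",
]

# Default per-gene codon counts (incl. the start codon, excl. the stop),
# near typical anuran values; cox1 ~ 516 codons.
GENE_CODONS: dict[str, int] = {
    "nad1": 324, "nad2": 344, "cox1": 516, "cox2": 229, "atp8": 55,
    "atp6": 227, "cox3": 260, "nad3": 115, "nad4L": 98, "nad4": 459,
    "nad5": 604, "nad6": 171, "cob": 380,
}

_RRNA_LEN = {"rrnS": 935, "rrnL": 1580}
_OL_LEN = 32

# tRNA anticodon placeholders: reverse complement of the alphabetically
# first codon the isotype decodes (gives the canonical GCT for trnS(AGY)).
TRNA_ANTICODON: dict[str, str] = {
    t: revcomp(sorted(c)[0]) for t, c in TRNA_CODON_MAP.items()
}

_CODON_TRNA: dict[str, str] = {
    c: t for t, codons in TRNA_CODON_MAP.items() for c in codons
}


@dataclass
class SimSpec:
    """Study-condition parameters for the generator.

    ``order`` is a reference-order name ('vertebrate_AGO',
    'neobatrachian_LTPF'), an explicit :class:`GeneOrder`, or a list of
    such (one per species).  ``beta`` is the log-linear link between a
    family's codon weight and its tRNA's distance from the CR (weight
    proportional to exp(-beta * distance / genome_length)); 0 = no link.
    """

    seed: int = 0
    n_species: int = 1
    order: Union[str, GeneOrder, list] = "vertebrate_AGO"
    gene_codons: dict = field(default_factory=lambda: dict(GENE_CODONS))
    beta: float = 0.0
    target_rho: Optional[float] = None
    dirichlet_alpha: Optional[float] = None
    pseudogenize: tuple = ()
    pseudo_relic_bp: int = 62
    cr_repeat_unit: int = 60
    cr_repeat_copies: int = 5
    cr_extra_bp: int = 880
    random_tdrl_events: int = 0
    id_prefix: str = "SYN"

    def rng_for(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key)))


def _resolve_order(spec: SimSpec, index: int) -> GeneOrder:
    o = spec.order
    if isinstance(o, list):
        o = o[index % len(o)]
    if isinstance(o, str):
        o = reference_order(o)
    return o


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _token_length(tok: Token, spec: SimSpec, rng: np.random.Generator) -> int:
    name = tok.name
    if tok.pseudo:
        return spec.pseudo_relic_bp
    if name == "CR":
        return spec.cr_repeat_unit * spec.cr_repeat_copies + spec.cr_extra_bp
    if name == "OL":
        return _OL_LEN
    if name.startswith("trn"):
        return int(rng.integers(68, 74))
    if name in _RRNA_LEN:
        return _RRNA_LEN[name]
    if name in spec.gene_codons:
        return 3 * spec.gene_codons[name] + 3  # codons + stop
    if name.startswith("spacer"):
        return int(name[name.index("(") + 1: -1])
    raise ValueError(f"cannot assign a length to token {name!r}")


def _kind_of(tok: Token) -> str:
    if tok.name == "CR":
        return "CR"
    if tok.name == "OL":
        return "OL"
    if tok.name.startswith("trn"):
        return "tRNA"
    if tok.name.startswith("rrn"):
        return "rRNA"
    if tok.name in GENE_CODONS:
        return "CDS"
    return "noncoding"


def _codon_weights(
    spec: SimSpec,
    distances: dict[str, int],
    genome_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-codon sampling probabilities.

    The distance link acts on *family* usage: family weight proportional
    to exp(-beta * distance / genome_length), split uniformly over the
    family's codons (so at beta=0 every family has equal expected usage
    and the realized distance-usage correlation is pure noise).  tRNAs
    that are pseudogenized or absent keep a neutral family weight: their
    codons are still translated (imported tRNAs).
    """
    w = np.empty(len(SENSE_CODONS))
    for i, c in enumerate(SENSE_CODONS):
        trna = _CODON_TRNA[c]
        fam_size = len(TRNA_CODON_MAP[trna])
        link = 1.0
        if spec.beta and trna in distances:
            link = math.exp(-spec.beta * distances[trna] / genome_length)
        w[i] = link / fam_size
    if spec.dirichlet_alpha:
        w = w * rng.gamma(spec.dirichlet_alpha, 1.0, len(SENSE_CODONS))
    return w / w.sum()


def _draw_cds(
    gene: str,
    n_codons: int,
    probs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, Counter]:
    """Sense-strand CDS: fixed ATG start, n_codons-1 drawn sense codons,
    TAA stop appended.  Returns (sequence, true codon counts excl. stop)."""
    counts = Counter({"ATG": 1})
    draws = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=probs)
    body = []
    for k in draws:
        codon = SENSE_CODONS[k]
        counts[codon] += 1
        body.append(codon)
    return "ATG" + "".join(body) + "TAA", counts


def generate_genome(
    spec: SimSpec, index: int = 0
) -> tuple[MitoGenome, dict]:
    """Generate one annotated genome plus its ground-truth ledger.

    The ledger records the realized gene order (with any random TDRL
    events), per-gene and pooled true codon counts, true tRNA-to-CR
    distances and the pseudogenized tokens.
    """
    rng = spec.rng_for(index)
    order = _resolve_order(spec, index)
    tdrl_events: list[TDRLScenario] = []
    if spec.random_tdrl_events:
        order, tdrl_events = apply_random_tdrl(
            order, spec.random_tdrl_events, rng=spec.rng_for(index, 1))
    if spec.pseudogenize:
        toks = []
        done = set()
        for t in order.linearized():
            if t.name in spec.pseudogenize and t.name not in done:
                toks.append(Token(t.name, t.strand, True, t.copy_index))
                done.add(t.name)
            else:
                toks.append(t)
        missing = set(spec.pseudogenize) - done
        if missing:
            raise ValueError(f"tokens to pseudogenize not in order: {missing}")
        order = GeneOrder(toks)

    tokens = list(order.linearized())
    if spec.beta and "CR" not in [t.name for t in tokens]:
        raise ValueError("distance-linked codon usage requires a CR in the order")

    # --- layout: assign coordinates token by token from position 0 ---------
    lengths = [_token_length(t, spec, rng) for t in tokens]
    genome_length = sum(lengths)
    feats: list[GeneFeature] = []
    pos = 0
    for tok, ln in zip(tokens, lengths):
        if not tok.is_spacer():
            feats.append(GeneFeature(
                name=tok.name,
                kind=_kind_of(tok),
                strand=tok.strand,
                start=pos,
                end=pos + ln,
                pseudogene=tok.pseudo,
                anticodon=TRNA_ANTICODON.get(tok.name)
                if tok.name.startswith("trn") else None,
            ))
        pos += ln

    genome = MitoGenome(
        id=f"{spec.id_prefix}{index:03d}",
        length=genome_length,
        circular=True,
        sequence=None,
        features=feats,
    )
    genome.assign_copy_indices()

    # --- true tRNA distances (needed before codon drawing when beta != 0) --
    try:
        distances = trna_cr_distances(genome)
    except ValueError:
        distances = {}

    probs = _codon_weights(spec, distances, genome_length, rng)

    # --- sequences ----------------------------------------------------------
    per_gene_counts: dict[str, Counter] = {}
    pooled: Counter = Counter()
    chunks: list[str] = []
    for tok, ln, feat_like in zip(tokens, lengths, _feat_iter(tokens, feats)):
        if tok.is_spacer():
            chunks.append(_random_seq(rng, ln))
            continue
        feat = feat_like
        if feat.kind == "CDS" and not feat.pseudogene:
            n_codons = spec.gene_codons[tok.name]
            sense, counts = _draw_cds(tok.name, n_codons, probs, rng)
            key = (feat.name if feat.copy_index == 1
                   else f"{feat.name}.{feat.copy_index}")
            per_gene_counts[key] = counts
            pooled.update(counts)
            seq = sense
        elif feat.kind == "CR" and not feat.pseudogene:
            unit = _random_seq(rng, spec.cr_repeat_unit)
            seq = unit * spec.cr_repeat_copies + _random_seq(rng, spec.cr_extra_bp)
        elif feat.kind == "tRNA" and not feat.pseudogene:
            body = _random_seq(rng, ln)
            ac = feat.anticodon or "NNN"
            seq = body[:30] + ac + body[33:]  # anticodon at a fixed offset
        else:
            seq = _random_seq(rng, ln)
        chunks.append(seq if feat.strand == "+" else revcomp(seq))

    genome.sequence = "".join(chunks)
    genome.validate()

    ledger = {
        "id": genome.id,
        "order": [str(t) for t in tokens],
        "tdrl_events": [
            {"start": s.start, "end": s.end, "fates": s.fates}
            for s in tdrl_events
        ],
        "codon_counts": {g: dict(c) for g, c in per_gene_counts.items()},
        "pooled_counts": dict(pooled),
        "total_codons": sum(pooled.values()),
        "trna_distances": dict(distances),
        "pseudogenes": [t.name for t in tokens if t.pseudo],
        "genome_length": genome_length,
    }
    return genome, ledger


def _feat_iter(tokens: Sequence[Token], feats: Sequence[GeneFeature]):
    """Align the token list (which may contain spacers) with the feature
    list (which does not)."""
    it = iter(feats)
    for tok in tokens:
        yield None if tok.is_spacer() else next(it)


def _planned_distances(spec: SimSpec, index: int) -> tuple[dict[str, int], int]:
    """tRNA distances the genome of ``index`` will have, without drawing
    sequences (replays the layout's length draws)."""
    rng = spec.rng_for(index)
    order = _resolve_order(spec, index)
    if spec.random_tdrl_events:
        order, _ = apply_random_tdrl(
            order, spec.random_tdrl_events, rng=spec.rng_for(index, 1))
    tokens = list(order.linearized())
    lengths = [_token_length(t, spec, rng) for t in tokens]
    L = sum(lengths)
    pos = 0
    dists: dict[str, int] = {}
    for tok, ln in zip(tokens, lengths):
        if tok.name.startswith("trn") and not tok.pseudo and tok.name not in dists:
            dists[tok.name] = pos  # layout starts at the CR 3' end
        pos += ln
    return dists, L


def calibrate_beta(
    spec: SimSpec,
    target_rho: float,
    n_replicates: int = 5,
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Choose the distance-link coefficient beta whose *realized* pooled
    Spearman correlation is closest to ``target_rho``.

    Count data cannot hit a target correlation exactly, so the calibration
    simulates family-level multinomial counts (cheap: no sequences) over a
    beta grid and picks the best mean; the realized value is then reported
    in the set ledger rather than promised.
    """
    from scipy import stats

    if target_rho > 0:
        raise ValueError("the distance link only produces rho <= 0")
    n_codons = sum(spec.gene_codons.values())
    per_species = [
        _planned_distances(spec, i) for i in range(spec.n_species)
    ]
    fam_sizes = np.array([len(TRNA_CODON_MAP[t]) for t in sorted(TRNA_CODON_MAP)])
    trnas = sorted(TRNA_CODON_MAP)
    if grid is None:
        grid = [0.0] + list(np.geomspace(0.01, 20.0, 25))
    rng = spec.rng_for(999_983)  # calibration substream
    best_beta, best_err = 0.0, float("inf")
    for beta in grid:
        rhos = []
        for _ in range(n_replicates):
            xs, ys = [], []
            for dists, L in per_species:
                names = [t for t in trnas if t in dists]
                w = np.array([math.exp(-beta * dists[t] / L) for t in names])
                counts = rng.multinomial(n_codons, w / w.sum())
                xs.extend(dists[t] for t in names)
                ys.extend(counts)
            rhos.append(stats.spearmanr(xs, ys).statistic)
        err = abs(float(np.mean(rhos)) - target_rho)
        if err < best_err:
            best_beta, best_err = float(beta), err
    return best_beta


def generate_correlated_set(spec: SimSpec) -> tuple[list[MitoGenome], dict]:
    """Generate ``spec.n_species`` genomes under a common codon-usage model
    and record the realized pooled distance-usage correlations computed
    from the true counts and distances.

    When ``spec.target_rho`` is set, the distance-link coefficient beta is
    first calibrated toward that realized correlation."""
    from scipy import stats  # local import keeps module load light

    if spec.target_rho is not None:
        spec = dc_replace(spec, beta=calibrate_beta(spec, spec.target_rho))
    genomes: list[MitoGenome] = []
    ledgers: list[dict] = []
    xs: list[float] = []
    ys: list[float] = []
    for i in range(spec.n_species):
        g, led = generate_genome(spec, i)
        genomes.append(g)
        ledgers.append(led)
        usage = {
            trna: sum(led["pooled_counts"].get(c, 0) for c in codons)
            for trna, codons in TRNA_CODON_MAP.items()
        }
        for trna, d in sorted(led["trna_distances"].items()):
            xs.append(float(d))
            ys.append(float(usage[trna]))
    realized: dict = {"n_points": len(xs)}
    if len(xs) >= 3 and len(set(xs)) > 1 and len(set(ys)) > 1:
        pr = stats.pearsonr(xs, ys)
        sr = stats.spearmanr(xs, ys)
        realized.update(
            pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
            spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        )
    combined = {"species": ledgers, "realized_correlation": realized,
                "beta": spec.beta, "target_rho": spec.target_rho,
                "seed": spec.seed}
    return genomes, combined


# ---------------------------------------------------------------------------
# congeneric partner evolution
# ---------------------------------------------------------------------------

def _p_from_d(d: float) -> float:
    """Invert the Jukes-Cantor map: expected proportion for a target distance.

    Targets whose expected proportion exceeds 0.70 are rejected: sampling
    noise around the JC singularity at p = 3/4 makes such distances
    unrecoverable in practice.
    """
    if d < 0:
        raise ValueError("target distance must be >= 0")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.70:
        raise ValueError(f"target distance {d} is saturated")
    return p


def _mutation_candidates(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if (CODON_TO_AA[alt] == aa) == synonymous:
                out.append((pos, nt))
    return out


def evolve_pair(
    genome: MitoGenome,
    target_dS: float,
    target_dN: float,
    seed: int,
) -> tuple[MitoGenome, dict]:
    """Evolve a congeneric partner genome at target NG86 dS and dN.

    Per gene, Poisson numbers of synonymous and nonsynonymous single-
    nucleotide substitutions (means ``pS*S`` and ``pN*N`` with p the
    Jukes-Cantor inverse of the target) are placed on distinct codons,
    never creating stop codons, so each compared codon differs at most at
    one position and the realized difference counts are recorded exactly.
    """
    if genome.sequence is None:
        raise ValueError("evolve_pair needs a genome with sequence")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    pS = _p_from_d(target_dS)
    pN = _p_from_d(target_dN)
    sequence = list(genome.sequence)
    per_gene: dict[str, dict] = {}
    for feat in genome.sorted_features():
        if feat.kind != "CDS" or feat.pseudogene:
            continue
        sense = genome.feature_sequence(feat)
        n3 = len(sense) - len(sense) % 3
        codons = [sense[k: k + 3] for k in range(0, n3, 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons.pop()
        S = sum(syn_site_fraction(c) for c in codons)
        N = 3.0 * len(codons) - S
        n_syn = int(rng.poisson(pS * S))
        n_non = int(rng.poisson(pN * N))
        if n_syn + n_non > len(codons):
            raise ValueError(
                f"{feat.name}: targets unreachable with one change per codon")
        idx = rng.permutation(len(codons))
        mutated = dict(enumerate(codons))
        placed_syn = placed_non = 0
        for ci in idx:
            if placed_syn < n_syn:
                cands = _mutation_candidates(codons[ci], synonymous=True)
                if cands:
                    pos, nt = cands[rng.integers(len(cands))]
                    mutated[ci] = codons[ci][:pos] + nt + codons[ci][pos + 1:]
                    placed_syn += 1
                    continue
            if placed_non < n_non:
                cands = _mutation_candidates(codons[ci], synonymous=False)
                if cands:
                    pos, nt = cands[rng.integers(len(cands))]
                    mutated[ci] = codons[ci][:pos] + nt + codons[ci][pos + 1:]
                    placed_non += 1
                    continue
            if placed_syn == n_syn and placed_non == n_non:
                break
        if placed_syn < n_syn or placed_non < n_non:
            raise ValueError(f"{feat.name}: could not place all substitutions")
        new_sense = "".join(mutated[k] for k in range(len(codons)))
        new_sense += sense[len(codons) * 3:]  # stop / trailing bases untouched
        _splice(sequence, genome.length, feat, new_sense)
        per_gene[feat.name] = {
            "Sd": placed_syn, "Nd": placed_non, "S": S, "N": N,
            "codons": len(codons),
        }
    partner = MitoGenome(
        id=f"{genome.id}_p",
        length=genome.length,
        circular=genome.circular,
        sequence="".join(sequence),
        features=[dc_replace(f) for f in genome.features],
    )
    ledger = {
        "base": genome.id, "partner": partner.id,
        "target_dS": target_dS, "target_dN": target_dN,
        "per_gene": per_gene,
        "Sd_total": sum(v["Sd"] for v in per_gene.values()),
        "Nd_total": sum(v["Nd"] for v in per_gene.values()),
    }
    return partner, ledger


def _splice(sequence: list, L: int, feat: GeneFeature, sense: str) -> None:
    genome_strand = sense if feat.strand == "+" else revcomp(sense)
    for off, ch in enumerate(genome_strand):
        sequence[(feat.start + off) % L] = ch


# ---------------------------------------------------------------------------
# random TDRL events
# ---------------------------------------------------------------------------

def apply_random_tdrl(
    order: GeneOrder,
    k: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_tract: int = 4,
) -> tuple[GeneOrder, list[TDRLScenario]]:
    """Apply ``k`` sequential random single-TDRL events to a gene order,
    returning the derived order and the recorded scenarios.  Identity
    events (duplicate-then-delete-the-copy) are rejected and resampled."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=0 if seed is None else seed))
    tokens = list(order.tokens)  # keep the caller's linearization
    scenarios: list[TDRLScenario] = []
    for _ in range(k):
        for _try in range(100):
            n = len(tokens)
            ln = int(rng.integers(1, min(max_tract, n) + 1))
            i = int(rng.integers(0, n - ln + 1))
            fates = []
            for _g in range(ln):
                keep_first = bool(rng.integers(0, 2))
                other = "pseudogenized" if rng.integers(0, 2) else "deleted"
                fates.append(("retained", other) if keep_first
                             else (other, "retained"))
            scen = TDRLScenario(i, i + ln - 1, tuple(fates))
            derived = apply_tdrl(tokens, scen)
            if [(t.name, t.strand, t.pseudo) for t in derived] != \
               [(t.name, t.strand, t.pseudo) for t in tokens]:
                tokens = derived
                scenarios.append(scen)
                break
        else:
            raise RuntimeError("could not sample a non-identity TDRL event")
    return GeneOrder(tokens), scenarios
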