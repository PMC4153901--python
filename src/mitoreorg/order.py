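"""Gene orders on the mitochondrial circle.

A :class:`GeneOrder` is a circular sequence of tokens (gene name, strand,
pseudogene flag, copy index).  Equality is rotation-invariant: two orders
are equal iff one is a rotation of the other with identical token
attributes (the genome's coordinate origin is arbitrary).

The module also provides the two reference arrangements relevant to
anuran mitogenomics — the vertebrate ancestral gene order (AGO) and the
neobatrachian arrangement whose trnL(CUN)-trnT-trnP-trnF block forms the
LTPF cluster next to the control region — plus classification of observed
orders against them and a shared-adjacency distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Iterable, Optional, Sequence

from .model import MitoGenome

__all__ = [
    "Token",
    "GeneOrder",
    "OrderClassification",
    "reference_order",
    "extract_gene_order",
    "classify_order",
    "shared_adjacency_distance",
    "parse_order_string",
    "format_order_string",
    "parse_compact_segment",
    "FULL_GENE_COMPLEMENT",
    "TRNA_TOKENS",
]


@dataclass(frozen=True)
class Token:
    """One gene (or non-coding element) in a gene order."""

    name: str
    strand: str = "+"
    pseudo: bool = False
    copy_index: int = 1

    def key(self, with_copy: bool = True):
        if with_copy:
            return (self.name, self.strand, self.pseudo, self.copy_index)
        return (self.name, self.strand, self.pseudo)

    def is_spacer(self) -> bool:
        return self.name.startswith("spacer")

    def __str__(self) -> str:
        s = "-" if self.strand == "-" else ""
        return f"{s}{self.name}" + ("'" if self.pseudo else "")


# The 37-gene vertebrate mitochondrial complement (13 CDS + 2 rRNA + 22 tRNA).
# (name, strand) in the ancestral arrangement, linearized at trnF.
_VERTEBRATE_AGO: tuple[tuple[str, str], ...] = (
    ("trnF", "+"), ("rrnS", "+"), ("trnV", "+"), ("rrnL", "+"),
    ("trnL(UUR)", "+"), ("nad1", "+"), ("trnI", "+"), ("trnQ", "-"),
    ("trnM", "+"), ("nad2", "+"), ("trnW", "+"), ("trnA", "-"),
    ("trnN", "-"), ("OL", "+"), ("trnC", "-"), ("trnY", "-"),
    ("cox1", "+"), ("trnS(UCN)", "-"), ("trnD", "+"), ("cox2", "+"),
    ("trnK", "+"), ("atp8", "+"), ("atp6", "+"), ("cox3", "+"),
    ("trnG", "+"), ("nad3", "+"), ("trnR", "+"), ("nad4L", "+"),
    ("nad4", "+"), ("trnH", "+"), ("trnS(AGY)", "+"), ("trnL(CUN)", "+"),
    ("nad5", "+"), ("nad6", "-"), ("trnE", "-"), ("cob", "+"),
    ("trnT", "+"), ("trnP", "-"), ("CR", "+"),
)

TRNA_TOKENS: tuple[str, ...] = tuple(
    n for n, _ in _VERTEBRATE_AGO if n.startswith("trn")
)

FULL_GENE_COMPLEMENT: frozenset[str] = frozenset(
    n for n, _ in _VERTEBRATE_AGO if n not in ("CR", "OL")
)


def _neobatrachian_ltpf() -> tuple[tuple[str, str], ...]:
    """Derive the neobatrachian order from the AGO: trnL(CUN), trnT, trnP
    and trnF leave their ancestral positions and form the LTPF cluster
    immediately upstream of the control region."""
    moved = {"trnL(CUN)", "trnT", "trnP", "trnF"}
    base = [(n, s) for n, s in _VERTEBRATE_AGO if n not in moved and n != "CR"]
    strands = dict(_VERTEBRATE_AGO)
    cluster = [(n, strands[n]) for n in ("trnL(CUN)", "trnT", "trnP", "trnF")]
    return tuple(base + cluster + [("CR", "+")])


_REFERENCES = {
    "vertebrate_AGO": _VERTEBRATE_AGO,
    "neobatrachian_LTPF": _neobatrachian_ltpf(),
}


class GeneOrder:
    """A circular, rotation-invariant gene order."""

    def __init__(self, tokens: Iterable[Token]):
        self.tokens: tuple[Token, ...] = tuple(tokens)
        if not self.tokens:
            raise ValueError("zero-length gene order")

    # -- rotation machinery -------------------------------------------------

    def rotations(self):
        n = len(self.tokens)
        for k in range(n):
            yield self.tokens[k:] + self.tokens[:k]

    def rotated(self, k: int) -> "GeneOrder":
        n = len(self.tokens)
        k %= n
        return GeneOrder(self.tokens[k:] + self.tokens[:k])

    def canonical(self, with_copy: bool = True) -> tuple:
        return min(tuple(t.key(with_copy) for t in rot) for rot in self.rotations())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __repr__(self) -> str:
        return f"GeneOrder({format_order_string(self)!r})"

    # -- views ---------------------------------------------------------------

    def functional(self) -> "GeneOrder":
        """Drop pseudogene and spacer tokens."""
        toks = [t for t in self.tokens if not t.pseudo and not t.is_spacer()]
        return GeneOrder(toks)

    def names(self) -> list[str]:
        return [t.name for t in self.tokens]

    def linearized(self) -> tuple[Token, ...]:
        """Rotation for display: starts at the token following the control
        region's 3' end (falls back to trnF, then the canonical rotation)."""
        names = self.names()
        if "CR" in names:
            k = (len(names) - 1 - names[::-1].index("CR") + 1) % len(names)
            return self.rotated(k).tokens
        if "trnF" in names:
            return self.rotated(names.index("trnF")).tokens
        return min(self.rotations(),
                   key=lambda rot: tuple(t.key() for t in rot))

    def equals_ignoring_copy(self, other: "GeneOrder") -> bool:
        return self.canonical(with_copy=False) == other.canonical(with_copy=False)


def reference_order(name: str) -> GeneOrder:
    """A canonical reference arrangement: 'vertebrate_AGO' or
    'neobatrachian_LTPF' (full 37-gene complement plus CR and OL)."""
    try:
        spec = _REFERENCES[name]
    except KeyError:
        raise ValueError(
            f"unknown reference order {name!r}; available: {sorted(_REFERENCES)}"
        ) from None
    return GeneOrder(Token(n, s) for n, s in spec)


def extract_gene_order(genome: MitoGenome, min_spacer: int = 30) -> GeneOrder:
    """Gene order of an annotated genome, in circle scan order.

    Non-coding gaps of at least ``min_spacer`` bp between annotated
    features become explicit ``spacer(<bp>)`` tokens; shorter gaps are
    ignored.  Pseudogenes are retained with their flag.
    """
    feats = genome.sorted_features()
    if not feats:
        raise ValueError(f"{genome.id}: no features")
    tokens: list[Token] = []
    counts: Counter = Counter()
    n = len(feats)
    for i, f in enumerate(feats):
        counts[f.name] += 1
        tokens.append(Token(f.name, f.strand, f.pseudogene, counts[f.name]))
        nxt = feats[(i + 1) % n]
        end = f.end if not f.wraps_origin() else f.end + genome.length
        if i == n - 1:
            gap = (nxt.start + genome.length - end) % genome.length
        else:
            gap = nxt.start - end
        if gap >= min_spacer:
            name = f"spacer({gap})"
            counts[name] += 1
            tokens.append(Token(name, "+", False, counts[name]))
    order = GeneOrder(tokens)
    return GeneOrder(order.linearized())


@dataclass
class OrderClassification:
    """AGO/RGO label plus named diagnostic features of an order."""

    label: str  # "AGO" or "RGO"
    ltpf_cluster: bool = False
    wancy_intact: bool = False
    trnh_translocated: bool = False
    trnm_duplicated: bool = False
    pseudogenes: tuple[str, ...] = ()
    lost_genes: tuple[str, ...] = ()
    duplicated_genes: tuple[str, ...] = ()

    @property
    def features(self) -> set[str]:
        out: set[str] = set()
        if self.ltpf_cluster:
            out.add("LTPF_cluster")
        if self.wancy_intact:
            out.add("WANCY_intact")
        if self.trnh_translocated:
            out.add("trnH_translocated")
        if self.trnm_duplicated:
            out.add("trnM_duplicated")
        out.update(f"{g}_pseudo" for g in self.pseudogenes)
        out.update(f"{g}_lost" for g in self.lost_genes)
        out.update(f"{g}_duplicated" for g in self.duplicated_genes)
        return out


def _contains_circular_run(names: Sequence[str], run: Sequence[str]) -> bool:
    n = len(names)
    if n < len(run):
        return False
    ext = list(names) + list(names[: len(run) - 1])
    run = list(run)
    return any(ext[i: i + len(run)] == run for i in range(n))


_WANCY = ("trnW", "trnA", "trnN", "OL", "trnC", "trnY")
_LTPF = ("trnL(CUN)", "trnT", "trnP", "trnF")


def classify_order(order: GeneOrder) -> OrderClassification:
    """Classify an order as ancestral (AGO) or rearranged (RGO) and report
    diagnostic features.

    Pseudogenes and spacers are excluded from the AGO equality test but
    reported as features; AGO additionally requires no gene losses,
    duplications or pseudogenes.  ``lost_genes`` lists genes of the
    37-gene complement with no *functional* copy, so a gene surviving
    only as a pseudogene counts as lost as well as pseudogenized.
    """
    functional = order.functional()
    names = functional.names()
    counts = Counter(names)
    pseudos = tuple(sorted(t.name for t in order.tokens if t.pseudo))
    lost = tuple(sorted(g for g in FULL_GENE_COMPLEMENT if counts[g] == 0))
    dup = tuple(sorted(g for g in counts if counts[g] > 1))

    ref = reference_order("vertebrate_AGO")
    is_ago = (
        not pseudos
        and not lost
        and not dup
        and functional.equals_ignoring_copy(ref)
    )
    ltpf = _contains_circular_run(names, _LTPF)
    wancy = _contains_circular_run(names, _WANCY)
    trnh_transloc = False
    if counts["trnH"] == 1:
        i = names.index("trnH")
        trnh_transloc = names[i - 1] != "nad4"
    return OrderClassification(
        label="AGO" if is_ago else "RGO",
        ltpf_cluster=ltpf,
        wancy_intact=wancy,
        trnh_translocated=trnh_transloc,
        trnm_duplicated=counts["trnM"] > 1,
        pseudogenes=pseudos,
        lost_genes=lost,
        duplicated_genes=dup,
    )


def _adjacency_set(order: GeneOrder) -> set[tuple]:
    toks = [t for t in order.tokens if not t.pseudo and not t.is_spacer()]
    n = len(toks)
    out = set()
    for i in range(n):
        a, b = toks[i], toks[(i + 1) % n]
        out.add(((a.name, a.strand), (b.name, b.strand)))
    return out


def shared_adjacency_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of strand-aware adjacent gene pairs present in one order but
    not the other (symmetric: the max over both directions).  Pseudogenes
    and spacers are excluded."""
    sa, sb = _adjacency_set(a), _adjacency_set(b)
    return max(len(sa - sb), len(sb - sa))


# -- order-string serialization ------------------------------------------------

def format_order_string(order: GeneOrder, sep: str = " ") -> str:
    """Serialize starting at the display linearization; '-' prefixes minus-
    strand tokens, a trailing apostrophe marks pseudogenes."""
    return sep.join(str(t) for t in order.linearized())


def parse_order_string(text: str) -> GeneOrder:
    """Inverse of :func:`format_order_string` (whitespace or commas)."""
    counts: Counter = Counter()
    tokens = []
    for raw in re.split(r"[,\s]+", text.strip()):
        if not raw:
            continue
        strand = "+"
        if raw.startswith("-"):
            strand = "-"
            raw = raw[1:]
        pseudo = raw.endswith("'")
        if pseudo:
            raw = raw[:-1]
        counts[raw] += 1
        tokens.append(Token(raw, strand, pseudo, counts[raw]))
    return GeneOrder(tokens)


# Compact single-letter dialect used for rearrangement-hotspot segments,
# e.g. "WA'N'OLANOL'CY".  Ambiguous letters: L = trnL(CUN), L2 = trnL(UUR),
# S = trnS(AGY), S2 = trnS(UCN).
_COMPACT = {
    "W": "trnW", "A": "trnA", "N": "trnN", "C": "trnC", "Y": "trnY",
    "F": "trnF", "V": "trnV", "I": "trnI", "Q": "trnQ", "M": "trnM",
    "D": "trnD", "K": "trnK", "G": "trnG", "R": "trnR", "H": "trnH",
    "E": "trnE", "T": "trnT", "P": "trnP",
    "L": "trnL(CUN)", "S": "trnS(AGY)", "L2": "trnL(UUR)", "S2": "trnS(UCN)",
    "OL": "OL", "CR": "CR",
}


def parse_compact_segment(text: str) -> list[Token]:
    """Parse a compact hotspot segment string into a linear token list.

    Strands are taken from the ancestral arrangement (the dialect does
    not encode them); primes mark pseudogenes.
    """
    strands = dict(_VERTEBRATE_AGO)
    toks: list[Token] = []
    counts: Counter = Counter()
    i = 0
    text = text.replace(" ", "").replace("_", "")
    while i < len(text):
        for lead in ("CR", "OL", "L2", "S2"):
            if text[i:].startswith(lead):
                name = _COMPACT[lead]
                i += len(lead)
                break
        else:
            ch = text[i].upper()
            if ch not in _COMPACT:
                raise ValueError(f"unrecognized token at {text[i:]!r}")
            name = _COMPACT[ch]
            i += 1
        pseudo = i < len(text) and text[i] == "'"
        if pseudo:
            i += 1
        counts[name] += 1
        toks.append(Token(name, strands.get(name, "+"), pseudo, counts[name]))
    return toks
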