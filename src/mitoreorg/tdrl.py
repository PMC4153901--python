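"""Tandem duplication–random loss (TDRL) scenario inference.

A single TDRL event duplicates a contiguous tract of genes in tandem and
then silences the redundant copies: for every gene in the tract exactly
one copy stays functional, while the other copy is either deleted
(leaving no trace in the order) or pseudogenized (leaving a flagged
token).  Given an ancestral and a derived segment, :func:`infer_tdrl`
returns every minimal-cost single event that transforms one into the
other; :func:`apply_tdrl` is the forward direction.

Segments are *linear* token sequences (rearrangement hotspots are local
tracts of the circle); strands travel with the tokens and are preserved
by the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Sequence

from .order import Token

__all__ = [
    "TDRLScenario",
    "infer_tdrl",
    "apply_tdrl",
    "tdrl_status",
    "TdrlInconsistencyError",
    "TdrlBoundError",
    "FATES",
]

FATES = ("retained", "pseudogenized", "deleted")


class TdrlInconsistencyError(ValueError):
    """Derived segment contains genes absent from the ancestral segment."""


class TdrlBoundError(ValueError):
    """Segment exceeds the exhaustive-search bound."""


@dataclass(frozen=True)
class TDRLScenario:
    """One tandem duplication of ancestral positions [start, end] with a
    per-gene, per-copy fate assignment.

    ``fates[g]`` is a ``(copy1_fate, copy2_fate)`` pair for the g-th gene
    of the duplicated tract; exactly one of the two is ``retained``.
    ``partial_left``/``partial_right`` flag boundary copies whose
    silencing is compatible with a partial (sub-gene) duplication of the
    tract edge.
    """

    start: int
    end: int
    fates: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("empty duplication interval")
        if len(self.fates) != self.end - self.start + 1:
            raise ValueError("fate table does not cover the duplicated tract")
        for f1, f2 in self.fates:
            if f1 not in FATES or f2 not in FATES:
                raise ValueError(f"unknown fate in {(f1, f2)}")
            if (f1 == "retained") == (f2 == "retained"):
                raise ValueError("exactly one copy of each gene must be retained")

    @property
    def n_duplicated(self) -> int:
        return self.end - self.start + 1

    @property
    def n_non_retained(self) -> int:
        return sum((f1 != "retained") + (f2 != "retained") for f1, f2 in self.fates)

    @property
    def cost(self) -> tuple[int, int]:
        return (self.n_duplicated, self.n_non_retained)

    @property
    def partial_left(self) -> bool:
        return self.fates[0][0] != "retained"

    @property
    def partial_right(self) -> bool:
        return self.fates[-1][1] != "retained"

    def describe(self, ancestral: Sequence[Token]) -> str:
        block = list(ancestral[self.start: self.end + 1])
        rows = [
            "tract : " + " ".join(str(t) for t in block),
            "copy1 : " + " ".join(
                _fate_mark(t, f1) for t, (f1, _) in zip(block, self.fates)),
            "copy2 : " + " ".join(
                _fate_mark(t, f2) for t, (_, f2) in zip(block, self.fates)),
        ]
        return "\n".join(rows)


def _fate_mark(tok: Token, fate: str) -> str:
    if fate == "deleted":
        return "." * max(1, len(str(tok)))
    if fate == "pseudogenized":
        return str(tok) + "'"
    return str(tok)


def _seg_key(tokens: Sequence[Token]) -> tuple:
    return tuple((t.name, t.strand, t.pseudo) for t in tokens)


def _renumber(tokens: Sequence[Token]) -> list[Token]:
    counts: Counter = Counter()
    out = []
    for t in tokens:
        counts[t.name] += 1
        out.append(Token(t.name, t.strand, t.pseudo, counts[t.name]))
    return out


def apply_tdrl(tokens: Sequence[Token], scenario: TDRLScenario) -> list[Token]:
    """Apply a single TDRL event to a linear token segment."""
    tokens = list(tokens)
    if not (0 <= scenario.start <= scenario.end < len(tokens)):
        raise ValueError("duplication interval outside the segment")
    block = tokens[scenario.start: scenario.end + 1]
    copies: list[Token] = []
    for copy in (0, 1):
        for tok, fate_pair in zip(block, scenario.fates):
            fate = fate_pair[copy]
            if fate == "deleted":
                continue
            copies.append(Token(tok.name, tok.strand,
                                fate == "pseudogenized" or tok.pseudo, 1))
    out = tokens[: scenario.start] + copies + tokens[scenario.end + 1:]
    return _renumber(out)


def _monotone_matchings(xs: Sequence[Token], block: Sequence[Token]):
    """All ways to match token list xs (in order) onto increasing positions
    of block, by (name, strand)."""
    def rec(xi: int, bi: int, acc: list[int]):
        if xi == len(xs):
            yield tuple(acc)
            return
        for p in range(bi, len(block) - (len(xs) - xi) + 1):
            if block[p].name == xs[xi].name and block[p].strand == xs[xi].strand:
                acc.append(p)
                yield from rec(xi + 1, p + 1, acc)
                acc.pop()

    yield from rec(0, 0, [])


def infer_tdrl(
    ancestral: Sequence[Token],
    derived: Sequence[Token],
    max_len: int = 12,
) -> list[TDRLScenario]:
    """All minimal-cost single-TDRL scenarios turning ``ancestral`` into
    ``derived`` (linear segments).

    Returns ``[]`` both when the segments are already identical (no event
    needed) and when no single event explains the derived segment.
    Minimality is lexicographic: fewest duplicated genes, then fewest
    non-retained copies; ties are all returned, ordered by leftmost tract.
    """
    anc = list(ancestral)
    der = list(derived)
    if len(anc) > max_len:
        raise TdrlBoundError(
            f"ancestral segment has {len(anc)} genes > bound {max_len}; "
            "raise max_len for longer tracts"
        )
    anc_names = Counter((t.name, t.strand) for t in anc)
    for t in der:
        if (t.name, t.strand) not in anc_names:
            raise TdrlInconsistencyError(
                f"derived token {t} has no ancestral counterpart"
            )
    if _seg_key(anc) == _seg_key(der):
        return []

    target = _seg_key(der)
    found: list[TDRLScenario] = []
    n = len(anc)
    for i in range(n):
        # prefix outside the tract must match the derived segment verbatim
        if _seg_key(anc[:i]) != _seg_key(der[:i]):
            continue
        for j in range(i, n):
            tail = n - 1 - j
            if tail and _seg_key(anc[-tail:]) != _seg_key(der[len(der) - tail:]):
                continue
            mid_end = len(der) - tail
            if mid_end < i:
                continue
            block = anc[i: j + 1]
            mid = der[i: mid_end]
            for scen in _match_block(block, mid, i, j):
                found.append(scen)
    if not found:
        return []
    best = min(s.cost for s in found)
    out = sorted(
        {s for s in found if s.cost == best},
        key=lambda s: (s.start, s.end, s.fates),
    )
    # defensive soundness check
    for s in out:
        if _seg_key(apply_tdrl(anc, s)) != target:
            raise AssertionError("internal error: unsound scenario")
    return out


def tdrl_status(ancestral: Sequence[Token], derived: Sequence[Token],
                max_len: int = 12) -> str:
    """Distinguish 'identical' (no event needed), 'explained' (>=1 single-
    TDRL scenario) and 'unexplained' derived segments."""
    if _seg_key(list(ancestral)) == _seg_key(list(derived)):
        return "identical"
    return "explained" if infer_tdrl(ancestral, derived, max_len) else "unexplained"


def _match_block(block, mid, i, j):
    """Yield scenarios for a duplicated tract ``block`` whose two merged
    copies must reproduce the observed middle tokens ``mid``."""
    L = len(block)
    seen = set()
    for k in range(len(mid) + 1):
        x1, x2 = mid[:k], mid[k:]
        for m1 in _monotone_matchings(x1, block):
            for m2 in _monotone_matchings(x2, block):
                fates = [["deleted", "deleted"] for _ in range(L)]
                ok = True
                for pos, tok in zip(m1, x1):
                    fates[pos][0] = "pseudogenized" if tok.pseudo else "retained"
                for pos, tok in zip(m2, x2):
                    fates[pos][1] = "pseudogenized" if tok.pseudo else "retained"
                for f1, f2 in fates:
                    if (f1 == "retained") + (f2 == "retained") != 1:
                        ok = False
                        break
                if not ok:
                    continue
                key = tuple(tuple(f) for f in fates)
                if key in seen:
                    continue
                seen.add(key)
                yield TDRLScenario(i, j, key)
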