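"""Independent reference implementations used to check the package.

Everything here is deliberately naive — forward enumeration, direct
textbook formulas, O(n^2) counting — and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import permutations, product

from mitoreorg.order import Token
from mitoreorg.tdrl import TDRLScenario

# --- TDRL: forward enumeration ------------------------------------------------

_FATE_PAIRS = (
    ("retained", "pseudogenized"),
    ("retained", "deleted"),
    ("pseudogenized", "retained"),
    ("deleted", "retained"),
)


def seg_key(tokens):
    return tuple((t.name, t.strand, t.pseudo) for t in tokens)


def forward_apply(tokens, start, end, fates):
    """Apply a TDRL event by direct construction (no shared code with
    mitoreorg.tdrl.apply_tdrl)."""
    out = list(tokens[:start])
    block = tokens[start: end + 1]
    for copy in (0, 1):
        for tok, fate in zip(block, fates):
            f = fate[copy]
            if f == "retained":
                out.append(Token(tok.name, tok.strand, tok.pseudo, 1))
            elif f == "pseudogenized":
                out.append(Token(tok.name, tok.strand, True, 1))
    out.extend(tokens[end + 1:])
    return out


def enumerate_all_tdrl(ancestral):
    """Map: derived segment key -> set of minimal (start, end, fates)
    triples, over every interval and fate assignment of a single event."""
    n = len(ancestral)
    by_derived: dict[tuple, list] = {}
    for i in range(n):
        for j in range(i, n):
            L = j - i + 1
            for fates in product(_FATE_PAIRS, repeat=L):
                derived = forward_apply(ancestral, i, j, fates)
                key = seg_key(derived)
                by_derived.setdefault(key, []).append((i, j, fates))
    minimal: dict[tuple, set] = {}
    anc_key = seg_key(ancestral)
    for key, events in by_derived.items():
        if key == anc_key:
            continue  # identity outcomes: no event needed
        def cost(ev):
            i, j, fates = ev
            return (j - i + 1,
                    sum((f1 != "retained") + (f2 != "retained")
                        for f1, f2 in fates))
        best = min(cost(ev) for ev in events)
        minimal[key] = {ev for ev in events if cost(ev) == best}
    return minimal


def brute_force_tdrl(ancestral, derived):
    """Minimal single-TDRL scenarios by exhaustive forward search."""
    target = seg_key(derived)
    if target == seg_key(ancestral):
        return set()
    return enumerate_all_tdrl(ancestral).get(target, set())


def scenario_triple(s: TDRLScenario):
    return (s.start, s.end, s.fates)


# --- gene order ---------------------------------------------------------------

def naive_adjacency_distance(a_tokens, b_tokens):
    """Adjacency-set difference by direct pairwise scan."""
    def pairs(tokens):
        toks = [t for t in tokens if not t.pseudo
                and not t.name.startswith("spacer")]
        out = set()
        for i, t in enumerate(toks):
            u = toks[(i + 1) % len(toks)]
            out.add((t.name, t.strand, u.name, u.strand))
        return out

    pa, pb = pairs(a_tokens), pairs(b_tokens)
    return max(len(pa - pb), len(pb - pa))


# --- correlation: direct formulas ---------------------------------------------

def direct_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def average_ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def direct_spearman(x, y):
    return direct_pearson(average_ranks(x), average_ranks(y))


# --- codon counting -----------------------------------------------------------

def naive_codon_enumerator(seq, stops):
    """Single-pass codon counts of one CDS string: trim incomplete tail,
    drop a terminal stop, skip stops and ambiguous codons."""
    seq = seq.upper().replace("U", "T")
    codons = [seq[i: i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if codons and codons[-1] in stops:
        codons.pop()
    counts = Counter()
    for c in codons:
        if any(ch not in "ACGT" for ch in c) or c in stops:
            continue
        counts[c] += 1
    return counts


# --- NG86 by explicit enumeration ---------------------------------------------

def ng86_oracle(a, b, code, stops):
    """Site and difference counts per Nei-Gojobori, everything enumerated
    longhand.  Returns (S, N, Sd, Nd)."""
    def sites(codon):
        s = 0.0
        for pos in range(3):
            syn = tot = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in stops:
                    continue
                tot += 1
                if code[alt] == code[codon]:
                    syn += 1
            if tot:
                s += syn / tot
        return s

    def diffs(c1, c2):
        positions = [i for i in range(3) if c1[i] != c2[i]]
        if not positions:
            return 0.0, 0.0
        all_paths, ok_paths = [], []
        for perm in permutations(positions):
            cur, sd, nd, bad = c1, 0, 0, False
            for pos in perm:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in stops:
                    bad = True
                    nd += 1
                elif cur in stops:
                    nd += 1
                elif code[cur] == code[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            all_paths.append((sd, nd))
            if not bad:
                ok_paths.append((sd, nd))
        paths = ok_paths or all_paths
        return (sum(p[0] for p in paths) / len(paths),
                sum(p[1] for p in paths) / len(paths))

    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    n3 = len(a) - len(a) % 3
    S = N = Sd = Nd = 0.0
    ncod = n3 // 3
    for k in range(ncod):
        c1, c2 = a[3 * k: 3 * k + 3], b[3 * k: 3 * k + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if c1 in stops or c2 in stops:
            continue
        S += (sites(c1) + sites(c2)) / 2
        sd, nd = diffs(c1, c2)
        Sd += sd
        Nd += nd
    N = 3 * sum(
        1 for k in range(ncod)
        if all(ch in "ACGT" for ch in a[3*k:3*k+3] + b[3*k:3*k+3])
        and a[3*k:3*k+3] not in stops and b[3*k:3*k+3] not in stops
    ) - S
    return S, N, Sd, Nd


# --- Mann-Whitney U by O(n^2) counting ----------------------------------------

def counting_mannwhitney_u(a, b):
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
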