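"""Reading and writing annotated mitogenomes.

GenBank flat files are read/written through Biopython; gene and product
qualifiers are normalized to MitoZoa-style tokens (cox1, nad5, trnL(CUN),
trnS(AGY), rrnS, rrnL, CR, OL) via an explicit, versioned alias table
shipped with the package (``data/gene_names.tsv``).  GenBank's 1-based
inclusive coordinates are converted to the internal 0-based half-open
convention on read and back on write; features joined across the
numbering origin (``join(x..L,1..y)``) become wrap features with
``start > end``.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation

from .model import MitoGenome, GeneFeature, CoordinateError
from .order import GeneOrder, extract_gene_order, format_order_string, parse_order_string

__all__ = [
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "write_gene_order_table",
    "read_gene_order_table",
    "normalize_gene_name",
    "UnknownGeneNameWarning",
]


class UnknownGeneNameWarning(UserWarning):
    """A feature name could not be normalized; kept as noncoding."""


def _load_alias_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = (resources.files("mitoreorg") / "data" / "gene_names.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, token = line.split("\t")
        table[alias.lower()] = token
    return table


_ALIASES = _load_alias_table()

# anticodon (DNA or RNA) -> disambiguated Leu/Ser isotype
_LEU_SER_BY_ANTICODON = {
    "TAA": "trnL(UUR)", "UAA": "trnL(UUR)",
    "TAG": "trnL(CUN)", "UAG": "trnL(CUN)",
    "TGA": "trnS(UCN)", "UGA": "trnS(UCN)",
    "GCT": "trnS(AGY)", "GCU": "trnS(AGY)",
}


def normalize_gene_name(
    raw: str, anticodon: Optional[str] = None
) -> Optional[str]:
    """Map a GenBank gene/product name to its normalized token, or None if
    unrecognized.  Ambiguous tRNA-Leu/tRNA-Ser names are resolved from an
    explicit (UUR)/(CUN)/(UCN)/(AGY) tag or from the anticodon."""
    name = raw.strip().rstrip("'").strip()
    # explicit split tag anywhere in the name, e.g. "tRNA-Leu (CUN)"
    m = re.search(r"\((UUR|CUN|UCN|AGY)\)", name, flags=re.I)
    base = _ALIASES.get(re.sub(r"\s*\(.*?\)\s*", "", name).lower())
    if base in ("trnL", "trnS") or (base is None and m):
        tag = m.group(1).upper() if m else None
        if tag in ("UUR", "CUN") :
            return f"trnL({tag})"
        if tag in ("UCN", "AGY"):
            return f"trnS({tag})"
        if anticodon:
            tok = _LEU_SER_BY_ANTICODON.get(anticodon.upper())
            if tok:
                return tok
        if base is not None:
            warnings.warn(
                f"{raw!r}: ambiguous Leu/Ser tRNA without anticodon; "
                "assuming the UUR/UCN isotype", UnknownGeneNameWarning,
                stacklevel=2)
            return "trnL(UUR)" if base == "trnL" else "trnS(UCN)"
    if base is not None:
        return base
    return _ALIASES.get(name.lower())


_KIND_BY_TYPE = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "CR",
    "rep_origin": "OL",
}

_TYPE_BY_KIND = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "CR": "D-loop",
    "OL": "rep_origin",
    "noncoding": "misc_feature",
}

_KIND_BY_TOKEN_PREFIX = (
    ("trn", "tRNA"), ("rrn", "rRNA"),
)


def _parse_anticodon(qualifiers: dict) -> Optional[str]:
    for val in qualifiers.get("anticodon", []):
        m = re.search(r"seq\s*:\s*([A-Za-z]{3})", val)
        if m:
            return m.group(1).upper()
        if re.fullmatch(r"[A-Za-z]{3}", val.strip()):
            return val.strip().upper()
    for val in qualifiers.get("note", []):
        m = re.search(r"anticodon[:=\s]+([A-Za-z]{3})", val)
        if m:
            return m.group(1).upper()
    return None


def _feature_bounds(feat: SeqFeature, length: int) -> tuple[int, int]:
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = loc.parts
        if len(parts) == 2 and int(parts[0].end) == length and int(parts[1].start) == 0:
            return int(parts[0].start), int(parts[1].end) % length
        return int(min(p.start for p in parts)), int(max(p.end for p in parts))
    return int(loc.start), int(loc.end)


def read_genbank(path: Union[str, Path]) -> list[MitoGenome]:
    """Parse a GenBank flat file into one :class:`MitoGenome` per record.

    Unknown gene names are kept as ``kind='noncoding'`` with a warning,
    never silently dropped; a '/pseudo' qualifier or a trailing apostrophe
    in the name marks pseudogenes.
    """
    genomes: list[MitoGenome] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        if length == 0:
            raise CoordinateError(f"{rec.id}: record has no length")
        topology = rec.annotations.get("topology", "circular")
        circular = topology != "linear"
        try:
            sequence = str(rec.seq)
            if set(sequence) <= {"N"}:
                sequence = None
        except Exception:  # undefined sequence (CONTIG etc.)
            sequence = None
        feats: list[GeneFeature] = []
        for f in rec.features:
            if f.type in ("source", "gene"):
                continue
            if f.type not in ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin",
                              "misc_feature", "misc_RNA"):
                continue
            q = f.qualifiers
            raw = (q.get("gene") or q.get("product") or q.get("standard_name")
                   or q.get("note") or [f.type])[0]
            anticodon = _parse_anticodon(q)
            token = normalize_gene_name(raw, anticodon)
            if token is None and f.type in ("D-loop", "rep_origin"):
                token = _KIND_BY_TYPE[f.type]
            if token is None:
                warnings.warn(
                    f"{rec.id}: unknown gene name {raw!r}; kept as noncoding",
                    UnknownGeneNameWarning, stacklevel=2)
                token = raw
                kind = "noncoding"
            else:
                kind = _KIND_BY_TYPE.get(f.type, "noncoding")
                if token in ("CR", "OL"):
                    kind = token
                else:
                    for prefix, k in _KIND_BY_TOKEN_PREFIX:
                        if token.startswith(prefix):
                            kind = k
            pseudo = ("pseudo" in q or "pseudogene" in q
                      or str(raw).strip().endswith("'"))
            start, end = _feature_bounds(f, length)
            strand = "-" if f.location.strand == -1 else "+"
            feats.append(GeneFeature(
                name=token, kind=kind, strand=strand,
                start=start, end=end, pseudogene=pseudo,
                anticodon=anticodon,
            ))
        genome = MitoGenome(rec.id, length, circular, sequence, feats)
        genome.assign_copy_indices()
        genome.validate()
        genomes.append(genome)
    if not genomes:
        raise ValueError(f"{path}: no GenBank records found")
    return genomes


def write_genbank(genomes: Iterable[MitoGenome], path: Union[str, Path]) -> None:
    """Write genomes as GenBank flat files (deterministic: fixed date)."""
    records = []
    for g in genomes:
        seq = Seq(g.sequence if g.sequence is not None else "N" * g.length)
        rec = SeqRecord(seq, id=g.id, name=g.id[:16], description="synthetic mitogenome")
        rec.annotations.update(
            molecule_type="DNA",
            topology="circular" if g.circular else "linear",
            data_file_division="VRT",
            date="01-JAN-2000",
            accessions=[g.id],
        )
        for f in g.sorted_features():
            strand = -1 if f.strand == "-" else 1
            if f.wraps_origin():
                loc = CompoundLocation([
                    SimpleLocation(f.start, g.length, strand),
                    SimpleLocation(0, f.end, strand),
                ])
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            q: dict = {"gene": [f.name]}
            if f.kind == "CDS":
                q["transl_table"] = ["2"]
                q["product"] = [f.name]
            elif f.kind in ("tRNA", "rRNA"):
                q["product"] = [f.name]
            if f.pseudogene:
                q["pseudo"] = [None]
            if f.anticodon:
                q["note"] = [f"anticodon:{f.anticodon}"]
            rec.features.append(SeqFeature(loc, type=_TYPE_BY_KIND[f.kind],
                                           qualifiers=q))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_fasta(genomes: Iterable[MitoGenome], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=f"{g.length} bp circular")
        for g in genomes if g.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_order_table(
    genomes: Sequence[MitoGenome], path: Union[str, Path],
    min_spacer: int = 30,
) -> None:
    """Tab-separated gene-order table: id, length, order string.

    The order string round-trips losslessly through
    :func:`read_gene_order_table` (strand sign, pseudogene apostrophes,
    spacer tokens)."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("no genomes to write")
    with open(path, "w") as fh:
        fh.write("id\tlength\torder\n")
        for g in genomes:
            order = extract_gene_order(g, min_spacer=min_spacer)
            fh.write(f"{g.id}\t{g.length}\t{format_order_string(order)}\n")


def read_gene_order_table(
    path: Union[str, Path],
) -> list[tuple[str, int, GeneOrder]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a gene-order table")
        for line in fh:
            if not line.strip():
                continue
            gid, length, order = line.rstrip("\n").split("\t")
            out.append((gid, int(length), parse_order_string(order)))
    return out
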