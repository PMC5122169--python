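"""Shared I/O and genomic-coordinate plumbing.

Conventions used throughout the package:

* intervals are **0-based, half-open** in memory and 1-based inclusive in
  GFF3 on disk;
* minus-strand gene sequences are stored reverse-complemented, i.e. always
  5'->3' of the gene, while the interval stays on the forward axis;
* genome FASTA is kept in the alphabet it was read in, but every snoRNA or
  target-RNA comparison happens in the RNA alphabet (T mapped to U at
  extraction time);
* Stockholm files are written in a canonical single-block form, ``#=GC``
  annotation lines after the sequence rows, so round trips are byte-stable.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# IUPAC nucleotide codes -> set of concrete RNA bases they stand for.
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

_VALID_SEQ = re.compile(r"^[ACGTUNRYSWKMBDHV]*$")

_RC_DNA = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")
_RC_RNA = str.maketrans("ACGUTNRYSWKMBDHV", "UGCAANYRSWMKVHDB")


def to_rna(seq: str) -> str:
    """Map a DNA/RNA string to the uppercase RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_RC_DNA)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_RC_RNA)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence; ``id`` is a whitespace-free token."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not _VALID_SEQ.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTUNRYSWKMBDHV"))
            raise ValueError(f"non-IUPAC characters in sequence {self.id}: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Nucleotides strictly between two non-overlapping intervals (<=0 if touching/overlapping)."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        lo, hi = sorted((self, other), key=lambda iv: iv.start)
        return hi.start - lo.end


@dataclass
class SnoGene:
    """A located snoRNA copy.

    ``seq`` is the gene's 5'->3' RNA sequence (reverse-complemented when the
    gene is on the minus strand); ``box_coords`` are gene-relative
    ``(name, start, end)`` triples, 0-based half-open.
    """

    gene_id: str
    species: str
    interval: GenomicInterval
    sno_class: str
    family: str
    seq: str = ""
    boxes: object | None = None
    box_coords: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.sno_class not in ("CD", "HACA"):
            raise ValueError(f"sno_class must be CD or HACA, got {self.sno_class!r}")

    def box_coord_tuples(self) -> tuple[tuple[str, int, int], ...]:
        if self.boxes is not None and hasattr(self.boxes, "hits"):
            return tuple((h.name, h.start, h.end) for h in self.boxes.hits)
        return self.box_coords


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`, uppercased.

    Raises :class:`ParseError` (naming the line) if sequence data precedes
    the first header.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}:{lineno}: expected FASTA header '>' before sequence data")
        break
    records = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "snofamkit"


def write_gff3(
    genes: Sequence[SnoGene],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write snoRNA genes as GFF3 ``ncRNA`` features.

    Internal 0-based half-open coordinates become 1-based inclusive columns
    4/5. Attributes carry family, class, species and gene-relative box
    coordinates.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        iv = g.interval
        if chrom_lengths is not None:
            length = chrom_lengths.get(iv.chrom)
            if length is not None and iv.end > length:
                raise ValueError(
                    f"gene {g.gene_id}: interval end {iv.end} beyond {iv.chrom} length {length}"
                )
        boxes = ",".join(f"{n}:{s}-{e}" for n, s, e in g.box_coord_tuples())
        attrs = [
            f"ID={g.gene_id}",
            f"family={g.family}",
            f"sno_class={g.sno_class}",
            f"species={g.species}",
        ]
        if boxes:
            attrs.append(f"boxes={boxes}")
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    _GFF_SOURCE,
                    "ncRNA",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[SnoGene]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _source, _ftype, start1, end1, _score, strand, _frame, attr_str = cols
        attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if kv)
        box_coords: list[tuple[str, int, int]] = []
        for item in filter(None, attrs.get("boxes", "").split(",")):
            name, span = item.split(":")
            s, e = span.split("-")
            box_coords.append((name, int(s), int(e)))
        genes.append(
            SnoGene(
                gene_id=attrs.get("ID", f"gene{lineno}"),
                species=attrs.get("species", ""),
                interval=GenomicInterval(chrom, int(start1) - 1, int(end1), strand),
                sno_class=attrs.get("sno_class", "CD"),
                family=attrs.get("family", ""),
                box_coords=tuple(box_coords),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Stockholm

#: characters allowed on the ``#=GC Boxes`` annotation line: box C/D letters
#: (internal copies lowercase), H/ACA letters, '.' elsewhere.
BOXES_ALPHABET = frozenset("CDdcHA.")


@dataclass
class FamilyAlignment:
    """A family-wide multiple alignment with Rfam-style column annotation.

    ``rows`` maps sequence id -> aligned (gapped) string, in insertion
    order; ``gc`` maps ``#=GC`` tag -> annotation line (``Boxes`` and
    ``SS_cons`` are the tags this package emits).
    """

    family_id: str
    rows: dict[str, str]
    gc: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()} | {len(s) for s in self.gc.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for family {self.family_id}: lengths {sorted(lengths)}")
        boxes = self.gc.get("Boxes")
        if boxes is not None:
            bad = sorted(set(boxes) - BOXES_ALPHABET)
            if bad:
                raise ValueError(f"invalid characters in Boxes line: {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def boxes_line(self) -> str | None:
        return self.gc.get("Boxes")

    @property
    def ss_cons(self) -> str | None:
        return self.gc.get("SS_cons")

    def conservation(self) -> list[float]:
        """Per-column fraction of the modal residue (gaps count as residues)."""
        cols = list(zip(*self.rows.values()))
        return [max(col.count(ch) for ch in set(col)) / len(col) for col in cols]


def write_stockholm(aln: FamilyAlignment, path: str | Path) -> None:
    Path(path).write_text(format_stockholm(aln))


def format_stockholm(aln: FamilyAlignment) -> str:
    name_w = max(
        [len(n) for n in aln.rows] + [len(f"#=GC {t}") for t in aln.gc] + [1]
    )
    out = io.StringIO()
    out.write("# STOCKHOLM 1.0\n")
    out.write(f"#=GF ID {aln.family_id}\n")
    for name, seq in aln.rows.items():
        out.write(f"{name:<{name_w}} {seq}\n")
    for tag, line in aln.gc.items():
        out.write(f"{f'#=GC {tag}':<{name_w}} {line}\n")
    out.write("//\n")
    return out.getvalue()


def read_stockholm(path: str | Path) -> FamilyAlignment:
    return parse_stockholm(Path(path).read_text(), source=str(path))


def parse_stockholm(text: str, source: str = "<string>") -> FamilyAlignment:
    family_id = ""
    rows: dict[str, str] = {}
    gc: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip()
        if not line or line == "//" or line.startswith("# STOCKHOLM"):
            continue
        if line.startswith("#=GF ID"):
            family_id = line.split(None, 2)[2]
        elif line.startswith("#=GC"):
            parts = line.split(None, 2)
            if len(parts) != 3:
                raise ParseError(f"{source}:{lineno}: malformed #=GC line")
            gc[parts[1]] = gc.get(parts[1], "") + parts[2]
        elif line.startswith("#"):
            continue
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"{source}:{lineno}: malformed sequence line")
            rows[parts[0]] = rows.get(parts[0], "") + parts[1]
    return FamilyAlignment(family_id=family_id, rows=rows, gc=gc)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; unlabelled internal nodes get deterministic
    preorder names N1..Nk."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=False
    )
    tree.is_rooted = True
    name_internal_nodes(tree)
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=False
    )
    tree.is_rooted = True
    name_internal_nodes(tree)
    return tree


def name_internal_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.taxon is not None and node.taxon.label:
            # keep the name on the taxon only, or the writer prints it twice
            node.label = None
        elif not node.label:
            k += 1
            node.label = f"N{k}"


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
        unquoted_underscores=True,
    ).strip()
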