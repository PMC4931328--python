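"""Reference sequences, gene annotations and tRNA coordinate arithmetic.

This module is the coordinate authority for the whole package.  Internally
every interval is 0-based, half-open (BED convention); every user-facing
report is 1-based, matching the way mitochondrial DNA positions are quoted
in the literature (e.g. the mt-tRNA(Met) wobble cytosine at mtDNA position
4432).

A :class:`ReferenceBundle` ties together

* a :class:`Genome` (contig name -> DNA string, U normalised to T),
* a list of :class:`GeneAnnotation` (BED6 intervals with a biotype), and
* a list of :class:`TrnaLayout` giving, for each tRNA gene, the sequential
  0-based index of the first anticodon base within the mature tRNA.  The
  wobble base (universal tRNA position 34) is defined as that first
  anticodon base.  Universal-numbering insertions/deletions are *not*
  modelled: layouts carry the sequential index directly, which is what
  sequential mtDNA coordinates require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

#: biotypes recognised in the optional 7th BED column
BIOTYPES = ("tRNA", "mRNA", "rRNA", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Raised for malformed reference inputs (FASTA/BED/layout)."""


class Genome:
    """A set of named DNA contigs with cached numeric encodings.

    Sequences are stored uppercased with U mapped to T.  Encoded views
    (plain, C->T collapsed, G->A collapsed) are built lazily and cached;
    the collapsed views support directional bisulfite alignment.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ReferenceError("genome has no contigs")
        for name, seq in contigs.items():
            if not seq:
                raise ReferenceError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ReferenceError(
                    f"contig {name!r} contains illegal characters: {sorted(bad)}"
                )
        self.contigs: dict[str, str] = dict(contigs)
        self._encoded: dict[str | None, dict[str, np.ndarray]] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def base(self, contig: str, pos: int) -> str:
        """Reference base (forward strand) at 0-based ``pos``."""
        return self.contigs[contig][pos]

    def encoded(self, transform: str | None = None) -> dict[str, np.ndarray]:
        """uint8 byte arrays per contig, optionally base-collapsed.

        ``transform`` is ``None`` (verbatim), ``"CT"`` (C->T) or ``"GA"``
        (G->A).  Results are cached on the instance.
        """
        if transform not in (None, "CT", "GA"):
            raise ValueError(f"unknown transform {transform!r}")
        if transform not in self._encoded:
            out = {}
            for name, seq in self.contigs.items():
                if transform == "CT":
                    seq = seq.replace("C", "T")
                elif transform == "GA":
                    seq = seq.replace("G", "A")
                out[name] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            self._encoded[transform] = out
        return self._encoded[transform]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval: 0-based half-open [start, end) on ``contig``."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    biotype: str = "other"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ReferenceError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise ReferenceError(
                f"gene {self.gene_id!r}: unknown biotype {self.biotype!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TrnaLayout:
    """Structural layout of a tRNA gene.

    ``anticodon_start`` is the sequential 0-based index of the first
    anticodon nucleotide within the mature tRNA; the wobble position
    (universal position 34) is exactly this index.
    """

    gene_id: str
    anticodon_start: int
    length: int

    def __post_init__(self):
        if not (0 <= self.anticodon_start <= self.length - 3):
            raise ReferenceError(
                f"layout {self.gene_id!r}: anticodon_start {self.anticodon_start} "
                f"outside [0, length-3] for length {self.length}"
            )


@dataclass
class ReferenceBundle:
    """Genome + annotations + tRNA layouts, cross-validated."""

    genome: Genome
    annotations: list[GeneAnnotation] = field(default_factory=list)
    layouts: list[TrnaLayout] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.annotations:
            if a.gene_id in seen:
                raise ReferenceError(f"duplicate gene_id {a.gene_id!r}")
            seen.add(a.gene_id)
            if a.contig not in self.genome:
                raise ReferenceError(
                    f"gene {a.gene_id!r}: unknown contig {a.contig!r}"
                )
            if a.end > self.genome.length(a.contig):
                raise ReferenceError(
                    f"gene {a.gene_id!r}: end {a.end} beyond contig "
                    f"{a.contig!r} length {self.genome.length(a.contig)}"
                )
        by_gene = {a.gene_id: a for a in self.annotations}
        for lay in self.layouts:
            ann = by_gene.get(lay.gene_id)
            if ann is None:
                raise ReferenceError(
                    f"layout {lay.gene_id!r} has no matching annotation"
                )
            if ann.biotype != "tRNA":
                raise ReferenceError(
                    f"layout {lay.gene_id!r}: annotation biotype is "
                    f"{ann.biotype!r}, expected 'tRNA'"
                )
            if ann.length != lay.length:
                raise ReferenceError(
                    f"layout {lay.gene_id!r}: length {lay.length} != "
                    f"annotation length {ann.length}"
                )
        self._by_gene = by_gene
        self._layout_by_gene = {l.gene_id: l for l in self.layouts}

    def gene(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._by_gene[gene_id]
        except KeyError:
            raise ReferenceError(f"unknown gene {gene_id!r}") from None

    def layout(self, gene_id: str) -> TrnaLayout:
        try:
            return self._layout_by_gene[gene_id]
        except KeyError:
            raise ReferenceError(f"gene {gene_id!r} has no tRNA layout") from None

    def transcript_sequence(self, gene_id: str) -> str:
        """Mature transcript-strand sequence (reverse-complemented on '-')."""
        a = self.gene(gene_id)
        seq = self.genome[a.contig][a.start:a.end]
        return revcomp(seq) if a.strand == "-" else seq

    def genes_overlapping(self, contig: str, pos: int, strand: str | None = None):
        """Annotations whose interval contains 0-based ``pos``."""
        return [
            a
            for a in self.annotations
            if a.contig == contig
            and a.start <= pos < a.end
            and (strand is None or a.strand == strand)
        ]


# ---------------------------------------------------------------------------
# loaders


def load_fasta(path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Sequences are uppercased and U is normalised to T so that downstream
    logic works on a DNA alphabet regardless of whether the reference was
    supplied as DNA or RNA.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ReferenceError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ReferenceError(f"FASTA record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ReferenceError(
                f"FASTA record {rec.id!r} contains illegal characters: {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise ReferenceError(f"no FASTA records found in {path}")
    return Genome(contigs)


def load_annotations(path, genome: Genome | None = None) -> list[GeneAnnotation]:
    """Parse a BED6(+biotype) annotation file.

    Columns: contig, start, end, gene_id, score (ignored), strand, and an
    optional 7th column with the biotype (default ``other``).  Coordinates
    are 0-based half-open.  When ``genome`` is given, intervals are checked
    against contig bounds.
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ReferenceError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}"
                )
            contig, start_s, end_s, gene_id, _score, strand = fields[:6]
            biotype = fields[6] if len(fields) > 6 else "other"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ReferenceError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ReferenceError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ReferenceError(f"{path}:{lineno}: unknown strand {strand!r}")
            if genome is not None:
                if contig not in genome:
                    raise ReferenceError(
                        f"{path}:{lineno}: unknown contig {contig!r}"
                    )
                if end > genome.length(contig):
                    raise ReferenceError(
                        f"{path}:{lineno}: end {end} beyond contig length "
                        f"{genome.length(contig)}"
                    )
            try:
                out.append(
                    GeneAnnotation(gene_id, contig, start, end, strand, biotype)
                )
            except ReferenceError as err:
                raise ReferenceError(f"{path}:{lineno}: {err}") from None
    return out


def load_layouts(path) -> list[TrnaLayout]:
    """Parse a TSV layout table: gene_id, anticodon_start, length."""
    out: list[TrnaLayout] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ReferenceError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                out.append(TrnaLayout(fields[0], int(fields[1]), int(fields[2])))
            except ValueError:
                raise ReferenceError(f"{path}:{lineno}: non-integer field") from None
            except ReferenceError as err:
                raise ReferenceError(f"{path}:{lineno}: {err}") from None
    return out


def load_bundle(fasta_path, bed_path, layout_path=None) -> ReferenceBundle:
    genome = load_fasta(fasta_path)
    annotations = load_annotations(bed_path, genome)
    layouts = load_layouts(layout_path) if layout_path else []
    return ReferenceBundle(genome, annotations, layouts)


# ---------------------------------------------------------------------------
# coordinate arithmetic


def gene_to_genomic(annotation: GeneAnnotation, seq_index: int) -> int:
    """Map a 0-based within-gene index to a 1-based genomic coordinate.

    Strand aware: on '+' the first gene base is ``start + 1``; on '-' it is
    ``end`` (the transcript runs right-to-left on the forward strand).
    """
    if not (0 <= seq_index < annotation.length):
        raise ReferenceError(
            f"seq_index {seq_index} outside gene {annotation.gene_id!r} "
            f"(length {annotation.length})"
        )
    if annotation.strand == "+":
        return annotation.start + seq_index + 1
    return annotation.end - seq_index


def genomic_to_gene(annotation: GeneAnnotation, pos_1based: int) -> int:
    """Inverse of :func:`gene_to_genomic` (raises if outside the gene)."""
    if annotation.strand == "+":
        idx = pos_1based - annotation.start - 1
    else:
        idx = annotation.end - pos_1based
    if not (0 <= idx < annotation.length):
        raise ReferenceError(
            f"position {pos_1based} outside gene {annotation.gene_id!r}"
        )
    return idx


def wobble_coordinate(bundle: ReferenceBundle, gene_id: str) -> int:
    """1-based genomic coordinate of a tRNA's wobble base (position 34).

    Defined as the first anticodon base taken from the gene's layout, e.g.
    mtDNA position 4432 for human MT-TM under the rCRS annotation.
    """
    layout = bundle.layout(gene_id)
    return gene_to_genomic(bundle.gene(gene_id), layout.anticodon_start)
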