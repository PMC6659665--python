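"""Data model and I/O for annotated circular mitochondrial genomes.

The central objects are :class:`GeneAnnotation` and :class:`MitogenomeRecord`.
Coordinates are 1-based inclusive throughout, as mitogenome papers print
them; features on the minority strand keep majority-strand coordinates with
a strand flag. A feature whose ``end`` is smaller than its ``start`` spans
the circular origin.

Supported formats: GenBank flat files (read), FASTA (read/write via
Biopython) and a tab-separated annotation-table dialect with one
``start-end`` location column per specimen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AnnotationParseError,
    BoundsError,
    MalformedAnnotationError,
)

#: feature categories
PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL = "control"

#: the 13 mitochondrial protein-coding genes, in canonical moth genome order
PCG_ORDER = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

#: full 37-gene + control-region order of the ditrysian lepidopteran
#: mitogenome, majority-strand orientation, starting at trnM
CANONICAL_GENE_ORDER = (
    "trnM", "trnI", "trnQ", "nad2", "trnW", "trnC", "trnY", "cox1",
    "trnL(UUR)", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3", "trnG",
    "nad3", "trnA", "trnR", "trnN", "trnS(AGN)", "trnE", "trnF", "nad5",
    "trnH", "nad4", "nad4l", "trnT", "trnP", "nad6", "cob", "trnS(UCN)",
    "nad1", "trnL(CUN)", "rrnL", "trnV", "rrnS", "control_region",
)

# Spelling normalisation: the literature mixes nd6/nad6, cytb/cob, and
# several labels for the A+T-rich control region.
_NAME_ALIASES = {
    "cytb": "cob",
    "cob": "cob",
    "at region": "control_region",
    "a+t region": "control_region",
    "a+t rich region": "control_region",
    "a+t-rich region": "control_region",
    "control region": "control_region",
    "control_region": "control_region",
    "d-loop": "control_region",
    "16s": "rrnL",
    "12s": "rrnS",
    "l-rrna": "rrnL",
    "s-rrna": "rrnS",
    "rrnl": "rrnL",
    "rrns": "rrnS",
}
for _i in range(1, 7):
    _NAME_ALIASES[f"nd{_i}"] = f"nad{_i}"
    _NAME_ALIASES[f"nad{_i}"] = f"nad{_i}"
_NAME_ALIASES["nd4l"] = "nad4l"
_NAME_ALIASES["nad4l"] = "nad4l"

_TRNA_RE = re.compile(r"^trn([A-Za-z])(\(([A-Za-z]{3})\))?$")


def normalize_gene_name(raw: str) -> str:
    """Map a printed gene label onto the controlled vocabulary.

    ``nd6`` and ``nad6`` collapse to ``nad6``, ``cytb`` to ``cob``, the
    various control-region labels to ``control_region``; tRNA labels keep
    their one-letter amino acid plus an optional anticodon-block qualifier,
    e.g. ``trnL(UUR)``.
    """
    label = raw.strip()
    key = label.lower()
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    m = _TRNA_RE.match(label)
    if m:
        aa = m.group(1).upper()
        qual = m.group(3)
        return f"trn{aa}({qual.upper()})" if qual else f"trn{aa}"
    return label


def categorize(name: str) -> str:
    """Infer the feature category from a normalised gene name."""
    if name == "control_region":
        return CONTROL
    if name.startswith("trn"):
        return TRNA
    if name.startswith("rrn"):
        return RRNA
    return PCG


@dataclass
class GeneAnnotation:
    """One annotated feature on a circular mitogenome.

    ``start``/``end`` are 1-based inclusive on majority-strand coordinates;
    ``end < start`` only for features spanning the circular origin.
    """

    name: str
    category: str
    strand: str  # "F" (majority) or "R" (minority)
    start: int
    end: int

    def __post_init__(self) -> None:
        self.name = normalize_gene_name(self.name)
        if not self.category:
            self.category = categorize(self.name)
        if self.strand not in ("F", "R"):
            raise MalformedAnnotationError(
                f"{self.name}: strand must be F or R, got {self.strand!r}"
            )
        if self.start < 1 or self.end < 1:
            raise BoundsError(f"{self.name}: coordinates must be >= 1")

    def length(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp; wrap-around features need genome_length."""
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise BoundsError(
                f"{self.name}: origin-spanning feature needs genome_length"
            )
        return genome_length - self.start + 1 + self.end

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: sequence (optional) plus ordered features."""

    id: str
    genome_length: int
    features: list[GeneAnnotation] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.genome_length != len(self.sequence):
                raise MalformedAnnotationError(
                    f"{self.id}: genome_length {self.genome_length} != "
                    f"sequence length {len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple[str, int], GeneAnnotation] = {}
        last_start = 0
        for f in self.features:
            if max(f.start, f.end) > self.genome_length:
                raise BoundsError(
                    f"{self.id}/{f.name}: {f.start}-{f.end} outside genome "
                    f"of {self.genome_length} bp"
                )
            if f.start < last_start:
                raise MalformedAnnotationError("features not sorted by start")
            last_start = f.start
        # identically named features must not overlap each other
        by_name: dict[str, list[GeneAnnotation]] = {}
        for f in self.features:
            by_name.setdefault(f.name, []).append(f)
        for name, feats in by_name.items():
            for a, b in zip(feats, feats[1:]):
                if not a.spans_origin and b.start <= a.end:
                    raise MalformedAnnotationError(
                        f"{self.id}: overlapping duplicate feature {name}"
                    )

    def feature(self, name: str) -> GeneAnnotation:
        name = normalize_gene_name(name)
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None


_LOCATION_RE = re.compile(r"^\s*([\d,]+)\s*[–—-]\s*([\d,]+)\s*$")


def _parse_location(cell: str, context: str) -> tuple[int, int]:
    m = _LOCATION_RE.match(cell)
    if not m:
        raise AnnotationParseError(
            f"{context}: cannot parse location {cell!r} (expected start-end)"
        )
    start = int(m.group(1).replace(",", ""))
    end = int(m.group(2).replace(",", ""))
    return start, end


def read_annotation_table(
    path: str | Path,
    sequence_source: str | Path | None = None,
) -> list[MitogenomeRecord]:
    """Read a Table-2-dialect annotation TSV into records.

    Columns: ``gene``, ``strand``, then one ``start-end`` location column
    per specimen (en dash or hyphen, thousands separators tolerated). When
    no sequence source is given, ``genome_length`` is the maximum end
    coordinate of the specimen's features. ``sequence_source`` may be a
    FASTA file whose record ids match the specimen columns.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise AnnotationParseError(f"{path}: empty annotation table")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0].lower() != "gene":
        raise AnnotationParseError(
            f"{path}: header must be gene<TAB>strand<TAB><specimen>..."
        )
    specimens = header[2:]
    sequences: dict[str, str] = {}
    if sequence_source is not None:
        for rec in SeqIO.parse(str(sequence_source), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()

    feats: dict[str, list[GeneAnnotation]] = {s: [] for s in specimens}
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(header):
            raise AnnotationParseError(
                f"{path}:{lineno}: expected {len(header)} columns, "
                f"got {len(cols)}"
            )
        gene, strand = cols[0], cols[1].strip()
        for spec, cell in zip(specimens, cols[2:]):
            if not cell.strip():
                continue  # feature absent in this specimen
            start, end = _parse_location(cell, f"{path}:{lineno}/{spec}")
            feats[spec].append(
                GeneAnnotation(gene, "", strand, start, end)
            )

    records = []
    for spec in specimens:
        seq = sequences.get(spec)
        if seq is not None:
            glen = len(seq)
        else:
            if not feats[spec]:
                raise AnnotationParseError(f"{path}: no features for {spec}")
            glen = max(max(f.start, f.end) for f in feats[spec])
        records.append(
            MitogenomeRecord(spec, glen, feats[spec], sequence=seq)
        )
    return records


def write_annotation_table(
    records: Iterable[MitogenomeRecord], path: str | Path
) -> None:
    """Write records as a Table-2-dialect TSV (inverse of the reader)."""
    records = list(records)
    order: list[tuple[str, str]] = []
    for rec in records:
        for f in rec.features:
            key = (f.name, f.strand)
            if key not in order:
                order.append(key)
    lines = ["gene\tstrand\t" + "\t".join(r.id for r in records)]
    for name, strand in order:
        cells = []
        for rec in records:
            hits = [
                f for f in rec.features
                if f.name == name and f.strand == strand
            ]
            cells.append(f"{hits[0].start}-{hits[0].end}" if hits else "")
        lines.append(f"{name}\t{strand}\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.sequence is None:
                raise MalformedAnnotationError(f"{rec.id}: no sequence")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


_GENBANK_TYPE_CATEGORY = {
    "CDS": PCG,
    "tRNA": TRNA,
    "rRNA": RRNA,
    "D-loop": CONTROL,
}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read one GenBank flat file into a :class:`MitogenomeRecord`.

    ``complement(...)`` locations map to strand R on majority-strand
    coordinates. Records lacking an ORIGIN block yield ``sequence=None``
    but keep their annotations. A missing LOCUS length is a parse error.
    """
    path = Path(path)
    try:
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc
    glen = len(seqrec.seq)
    if glen == 0:
        raise AnnotationParseError(f"{path}: missing LOCUS length")
    try:
        sequence: Optional[str] = str(seqrec.seq)
        if sequence is not None and set(sequence) <= {"N"}:
            sequence = None
    except Exception:  # undefined sequence (no ORIGIN block)
        sequence = None

    features = []
    for feat in seqrec.features:
        if feat.type not in _GENBANK_TYPE_CATEGORY:
            if not (
                feat.type == "misc_feature"
                and "control" in str(feat.qualifiers.get("note", "")).lower()
            ):
                continue
            category = CONTROL
            name = "control_region"
        else:
            category = _GENBANK_TYPE_CATEGORY[feat.type]
            quals = feat.qualifiers
            name = (
                quals.get("gene", quals.get("product", ["?"]))[0]
            )
            if category == CONTROL:
                name = "control_region"
        start = int(feat.location.start) + 1  # 0-based half-open -> 1-based
        end = int(feat.location.end)
        strand = "R" if feat.location.strand == -1 else "F"
        features.append(GeneAnnotation(name, category, strand, start, end))
    return MitogenomeRecord(
        seqrec.id or path.stem, glen, features, sequence=sequence
    )


def extract_gene_sequence(
    record: MitogenomeRecord, gene: GeneAnnotation | str
) -> str:
    """Return a feature's sense-strand sequence.

    Slices ``start..end`` inclusive, concatenating tail+head for
    origin-spanning features, and reverse-complements minority-strand
    features.
    """
    if isinstance(gene, str):
        gene = record.feature(gene)
    if record.sequence is None:
        raise MalformedAnnotationError(f"{record.id}: record has no sequence")
    seq = record.sequence
    if max(gene.start, gene.end) > record.genome_length:
        raise BoundsError(
            f"{gene.name}: {gene.start}-{gene.end} outside genome"
        )
    if gene.spans_origin:
        sub = seq[gene.start - 1 :] + seq[: gene.end]
    else:
        sub = seq[gene.start - 1 : gene.end]
    if gene.strand == "R":
        sub = str(Seq(sub).reverse_complement())
    return sub
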