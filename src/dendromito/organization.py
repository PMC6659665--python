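"""Genome-organization statistics on circular mitogenomes.

Covers the bookkeeping that comparative mitogenome studies tabulate:
signed junction lengths between adjacent features (positive = intergenic
spacer, negative = gene overlap, zero = abutting), counts of non-coding
and overlapping regions, per-gene start/stop codon surveys including
incomplete stops, and the gene-order signature around trnM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .errors import DegenerateRecordError, MalformedAnnotationError
from .genome_model import (
    PCG,
    MitogenomeRecord,
    extract_gene_sequence,
    normalize_gene_name,
)


@dataclass(frozen=True)
class Junction:
    """Signed spacer/overlap between two adjacent features.

    ``signed_length = downstream.start - upstream.end - 1`` on
    majority-strand coordinates, with circular wrap at the origin junction.
    """

    upstream_gene: str
    downstream_gene: str
    signed_length: int

    @property
    def label(self) -> str:
        return f"{self.upstream_gene}-{self.downstream_gene}"


@dataclass
class JunctionLedger:
    """All junctions around the circle for one record (circular closure:
    as many junctions as features)."""

    record_id: str
    junctions: list[Junction]

    def __iter__(self):
        return iter(self.junctions)

    def get(self, upstream: str, downstream: str) -> Junction:
        up = normalize_gene_name(upstream)
        down = normalize_gene_name(downstream)
        for j in self.junctions:
            if j.upstream_gene == up and j.downstream_gene == down:
                return j
        raise KeyError(f"{up}-{down}")


def compute_junctions(record: MitogenomeRecord) -> JunctionLedger:
    """One junction per adjacent feature pair, including the wrap junction
    from the last feature back to the first.

    Junctions are computed on majority-strand coordinates regardless of the
    strands of the flanking genes. The wrap junction's length is
    ``genome_length - upstream.end + downstream.start - 1``.
    """
    feats = record.features
    if len(feats) < 2:
        raise DegenerateRecordError(
            f"{record.id}: need at least 2 features for junctions"
        )
    junctions = []
    for up, down in zip(feats, feats[1:]):
        junctions.append(
            Junction(up.name, down.name, down.start - up.end - 1)
        )
    last, first = feats[-1], feats[0]
    wrap = record.genome_length - last.end + first.start - 1
    junctions.append(Junction(last.name, first.name, wrap))
    return JunctionLedger(record.id, junctions)


def _control_adjacent(ledger: JunctionLedger) -> set[int]:
    return {
        i
        for i, j in enumerate(ledger.junctions)
        if "control_region" in (j.upstream_gene, j.downstream_gene)
    }


def count_noncoding(ledger: JunctionLedger, exclude_control: bool = True) -> int:
    """Number of intergenic spacers (junctions with positive length).

    With ``exclude_control`` the junctions flanking the control region are
    skipped, matching the convention of counting spacers "in addition to
    the control region".
    """
    skip = _control_adjacent(ledger) if exclude_control else set()
    return sum(
        1
        for i, j in enumerate(ledger.junctions)
        if j.signed_length > 0 and i not in skip
    )


def overlap_summary(
    ledger: JunctionLedger,
) -> tuple[int, Optional[int], Optional[int]]:
    """(count, min_size, max_size) of gene overlaps (negative junctions).

    Sizes are absolute values; with zero overlaps the range is (0, None,
    None) so the undefined bounds are explicit rather than silently 0.
    """
    sizes = sorted(
        -j.signed_length for j in ledger.junctions if j.signed_length < 0
    )
    if not sizes:
        return 0, None, None
    return len(sizes), sizes[0], sizes[-1]


@dataclass
class CodonSurvey:
    """Start and stop codons of each protein-coding gene in one record.

    Stops are reported verbatim: a complete 3-letter codon, or the
    incomplete remainder "TA"/"T" (length = gene length mod 3) presumed to
    be completed to TAA by post-transcriptional polyadenylation.
    """

    record_id: str
    start_codons: dict[str, str]
    stop_codons: dict[str, str]


def codon_survey(record: MitogenomeRecord) -> CodonSurvey:
    """Survey first and terminal codons of every PCG (strand resolved)."""
    starts: dict[str, str] = {}
    stops: dict[str, str] = {}
    for feat in record.features:
        if feat.category != PCG:
            continue
        seq = extract_gene_sequence(record, feat)
        if len(seq) < 6:
            raise MalformedAnnotationError(
                f"{record.id}/{feat.name}: PCG shorter than 6 bp"
            )
        starts[feat.name] = seq[:3]
        remainder = len(seq) % 3
        stops[feat.name] = seq[-3:] if remainder == 0 else seq[-remainder:]
    return CodonSurvey(record.id, starts, stops)


def gene_order_signature(record: MitogenomeRecord) -> tuple[str, str]:
    """Canonical gene-order string rotated to start at trnM, plus a
    trnM-placement label: "standard" iff the order begins trnM, trnI, trnQ.

    Records lacking trnM get the unrotated order and label "unlabeled".
    """
    names = [f.name for f in record.features]
    if "trnM" not in names:
        return ",".join(names), "unlabeled"
    i = names.index("trnM")
    rotated = names[i:] + names[:i]
    label = "standard" if rotated[:3] == ["trnM", "trnI", "trnQ"] else "non-standard"
    return ",".join(rotated), label


# ---------------------------------------------------------------------------
# tabular writers

def write_junction_table(
    ledgers: Iterable[JunctionLedger],
    path: str | Path,
    labels: Optional[list[str]] = None,
) -> None:
    """Junction-table TSV: rows = junction labels, columns = specimens,
    signed integers (Unicode minus normalised to ASCII '-')."""
    ledgers = list(ledgers)
    if labels is None:
        labels = []
        for led in ledgers:
            for j in led.junctions:
                if j.label not in labels:
                    labels.append(j.label)
    lines = ["junction\t" + "\t".join(l.record_id for l in ledgers)]
    for label in labels:
        cells = []
        for led in ledgers:
            try:
                up, down = label.split("-", 1)
                cells.append(str(led.get(up, down).signed_length))
            except KeyError:
                cells.append("")
        lines.append(label + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_codon_table(
    surveys: Iterable[CodonSurvey], path: str | Path
) -> None:
    """Per-PCG "start/stop" strings, one row per record."""
    surveys = list(surveys)
    genes: list[str] = []
    for s in surveys:
        for g in s.start_codons:
            if g not in genes:
                genes.append(g)
    lines = ["record\t" + "\t".join(genes)]
    for s in surveys:
        cells = [
            f"{s.start_codons.get(g, '')}/{s.stop_codons.get(g, '')}"
            for g in genes
        ]
        lines.append(s.record_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
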