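"""High-level orchestration shared by the CLI, the analysis scripts and
the acceptance checks: ortholog extraction, per-gene alignment, dataset
construction, and region-wise diversity profiling."""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

from .alignment_concat import (
    ConcatenatedMatrix,
    GeneAlignment,
    align_pcg,
    align_rna,
    concatenate,
)
from .diversity import SlidingWindowProfile, sliding_pi
from .errors import MalformedAnnotationError
from .genome_model import (
    CANONICAL_GENE_ORDER,
    CONTROL,
    PCG,
    MitogenomeRecord,
    categorize,
    extract_gene_sequence,
)
from .organization import compute_junctions

Aligner = Literal["nw", "stack"]


def gene_orthologs(
    records: Sequence[MitogenomeRecord], gene: str
) -> dict[str, str]:
    """Sense-strand sequences of one gene across records (records lacking
    the gene are skipped)."""
    out: dict[str, str] = {}
    for rec in records:
        try:
            feat = rec.feature(gene)
        except KeyError:
            continue
        out[rec.id] = extract_gene_sequence(rec, feat)
    return out


def _stack(orthologs: Mapping[str, str], gene: str, category: str) -> GeneAlignment:
    lengths = {len(s) for s in orthologs.values()}
    if len(lengths) != 1:
        raise MalformedAnnotationError(
            f"{gene}: unequal lengths {sorted(lengths)}; "
            "stacking needs column-homologous input"
        )
    return GeneAlignment(gene, category, dict(orthologs))


def align_gene(
    orthologs: Mapping[str, str],
    gene: str,
    category: str,
    aligner: Aligner = "nw",
) -> GeneAlignment:
    """One gene's multiple alignment.

    ``aligner="nw"`` runs the codon-aware (PCG) or nucleotide (RNA)
    progressive aligner; ``"stack"`` asserts the sequences are already
    column-homologous (equal length, e.g. indel-free simulations) and
    stacks them — which for such input is exactly what the aligner
    returns, only cheaper.
    """
    if aligner == "stack":
        return _stack(orthologs, gene, category)
    if category == PCG:
        return align_pcg(orthologs, gene=gene)
    return align_rna(orthologs, gene=gene, category=category)


def build_gene_alignments(
    records: Sequence[MitogenomeRecord],
    genes: Optional[Sequence[str]] = None,
    aligner: Aligner = "nw",
    include_control: bool = False,
) -> list[GeneAlignment]:
    """Alignments for every requested gene (default: all 37 genes in
    canonical order, optionally plus the control region)."""
    if genes is None:
        genes = [
            g
            for g in CANONICAL_GENE_ORDER
            if include_control or g != "control_region"
        ]
    alignments = []
    for gene in genes:
        orthologs = gene_orthologs(records, gene)
        if not orthologs:
            continue
        alignments.append(
            align_gene(orthologs, gene, categorize(gene), aligner)
        )
    return alignments


def build_dataset(
    records: Sequence[MitogenomeRecord],
    scheme: str = "dataset1",
    aligner: Aligner = "nw",
    alignments: Optional[Sequence[GeneAlignment]] = None,
) -> ConcatenatedMatrix:
    """dataset1 (13 PCGs) or dataset2 (37 genes) supermatrix."""
    if alignments is None:
        genes: Optional[list[str]] = None
        if scheme == "dataset1":
            genes = [
                g for g in CANONICAL_GENE_ORDER
                if g not in ("control_region",)
                and not g.startswith(("trn", "rrn"))
            ]
        alignments = build_gene_alignments(records, genes, aligner)
    return concatenate(list(alignments), scheme)


def intergenic_sequences(
    records: Sequence[MitogenomeRecord],
) -> dict[str, dict[str, str]]:
    """Per-record spacer sequences keyed by junction label (positive
    junctions only; the wrap spacer included when present)."""
    out: dict[str, dict[str, str]] = {}
    for rec in records:
        ledger = compute_junctions(rec)
        feats = rec.features
        for k, junc in enumerate(ledger.junctions):
            if junc.signed_length <= 0:
                continue
            if "control_region" in (junc.upstream_gene, junc.downstream_gene):
                continue  # control region is profiled as its own region
            up = feats[k]
            if k + 1 < len(feats):
                seg = rec.sequence[up.end : up.end + junc.signed_length]
            else:  # wrap spacer after the final feature
                seg = (
                    rec.sequence[up.end :]
                    + rec.sequence[: feats[0].start - 1]
                )
            out.setdefault(junc.label, {})[rec.id] = seg
    return out


def region_profiles(
    records: Sequence[MitogenomeRecord],
    window: int = 100,
    step: int = 25,
    aligner: Aligner = "nw",
) -> list[SlidingWindowProfile]:
    """Sliding-window diversity per region: each PCG separately, the
    concatenated tRNAs, the concatenated rRNAs, the concatenated
    intergenic spacers, and the control region."""
    alignments = build_gene_alignments(
        records, aligner=aligner, include_control=True
    )
    by_cat: dict[str, list[GeneAlignment]] = {}
    profiles: list[SlidingWindowProfile] = []
    for aln in alignments:
        if aln.category == PCG:
            profiles.append(
                sliding_pi(aln.sequences, window, step, region=aln.gene)
            )
        else:
            by_cat.setdefault(
                "control" if aln.category == CONTROL else aln.category, []
            ).append(aln)
    for label, alns in by_cat.items():
        ids = sorted({rid for a in alns for rid in a.sequences})
        rows = {
            rid: "".join(
                a.sequences.get(rid, "-" * a.length) for a in alns
            )
            for rid in ids
        }
        profiles.append(sliding_pi(rows, window, step, region=label))

    spacers = intergenic_sequences(records)
    if spacers:
        parts: list[GeneAlignment] = []
        for label in spacers:
            seqs = spacers[label]
            if len(seqs) < 2:
                continue
            parts.append(align_gene(seqs, label, "spacer", aligner))
        if parts:
            ids = sorted({rid for a in parts for rid in a.sequences})
            rows = {
                rid: "".join(
                    a.sequences.get(rid, "-" * a.length) for a in parts
                )
                for rid in ids
            }
            if len(rows[ids[0]]) >= window:
                profiles.append(
                    sliding_pi(rows, window, step, region="intergenic")
                )
    return profiles
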