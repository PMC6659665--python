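"""Codon-aware alignment and supermatrix construction.

Protein-coding genes are aligned on their translated amino-acid sequences
(invertebrate mitochondrial code) and back-translated so every amino-acid
gap becomes a 3-base gap; RNA genes are aligned at the nucleotide level.
Pairwise alignment is global Needleman-Wunsch with affine gap costs; more
than two sequences are aligned progressively along a neighbor-joining
guide tree built from p-distances, merging profile against profile.

In this aligner a gap in one sequence may not immediately follow a gap in
the other (no insertion-deletion adjacency), which congeneric data never
needs and which keeps the dynamic programme exactly row-vectorisable. A
gap of length g costs ``open + (g - 1) * extend``.

Single-gene alignments are concatenated into the two standard mitogenome
phylogenomics datasets: dataset1 = the 13 protein-coding genes, one
partition each; dataset2 = all 37 genes, with the 22 tRNAs merged into one
partition and the 2 rRNAs into another (15 partitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import FrameError, MalformedAnnotationError
from .genome_model import CANONICAL_GENE_ORDER, PCG, RRNA, TRNA, categorize

NEG = -1e30  # effectively -infinity for the DP


# ---------------------------------------------------------------------------
# pairwise / profile-profile dynamic programme

def _affine_nw(
    prof_a: np.ndarray,
    prof_b: np.ndarray,
    submat: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[tuple[Optional[int], Optional[int]]]]:
    """Global affine-gap alignment of two profiles.

    Profiles are (length, alphabet) residue-frequency arrays (gaps carry
    zero frequency); the column score is the frequency-weighted mean
    substitution score. Returns the score and the aligned column path as
    (index_in_a | None, index_in_b | None) pairs. Ties prefer match, then
    gap-in-b, then gap-in-a, which makes the output deterministic.
    """
    n, m = prof_a.shape[0], prof_b.shape[0]
    scores = prof_a @ submat @ prof_b.T  # (n, m)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    if m:
        Y[0, 1:] = -gap_open - gap_extend * np.arange(m)
    if n:
        X[1:, 0] = -gap_open - gap_extend * np.arange(n)

    ext = gap_extend
    for i in range(1, n + 1):
        X[i, 1:] = np.maximum(M[i - 1, 1:] - gap_open, X[i - 1, 1:] - ext)
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = scores[i - 1] + best_prev[:-1]
        # Y[i, j] = max_{k<j} M[i, k] - open - (j-1-k)*ext, via running max
        run = np.maximum.accumulate(M[i, :-1] + ext * np.arange(m))
        Y[i, 1:] = run - gap_open - ext * np.arange(m)

    # traceback
    path: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    final = max(M[n, m], X[n, m], Y[n, m])
    state = "M" if M[n, m] >= final else ("X" if X[n, m] >= final else "Y")
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i, j] - scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < tol:
                state = "M"
            elif abs(X[i, j] - prev) < tol:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            path.append((i - 1, None))
            if i > 1 or j > 0:
                if abs(M[i - 1, j] - gap_open - X[i, j]) < tol:
                    state = "M"
                else:
                    state = "X"
            i -= 1
        else:
            path.append((None, j - 1))
            if j > 1 or i > 0:
                if abs(M[i, j - 1] - gap_open - Y[i, j]) < tol:
                    state = "M"
                else:
                    state = "Y"
            j -= 1
    path.reverse()
    return float(final), path


def _to_profile(
    rows: Sequence[str], alphabet: str
) -> np.ndarray:
    """Column residue-frequency array; gaps contribute nothing."""
    idx = {ch: k for k, ch in enumerate(alphabet)}
    length = len(rows[0])
    prof = np.zeros((length, len(alphabet)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch in idx:
                prof[j, idx[ch]] += 1.0
    norm = prof.sum(axis=1, keepdims=True)
    np.divide(prof, norm, out=prof, where=norm > 0)
    return prof


def _merge(
    rows_a: dict[str, str],
    rows_b: dict[str, str],
    path,
) -> dict[str, str]:
    out: dict[str, str] = {}
    for rid, row in rows_a.items():
        out[rid] = "".join(
            row[ia] if ia is not None else "-" for ia, _ in path
        )
    for rid, row in rows_b.items():
        out[rid] = "".join(
            row[ib] if ib is not None else "-" for _, ib in path
        )
    return out


def _guide_order(seqs: Mapping[str, str]) -> list[list[str]]:
    """Deterministic progressive-merge schedule from a p-distance guide.

    p-distances are taken over the shared prefix of each unaligned pair (a
    guide heuristic; congeneric genes are nearly co-linear). Clusters are
    merged greedily, nearest pair first, ties broken by lexicographic
    cluster label, which is exactly single-pass NJ-style agglomeration for
    these shallow guide trees.
    """
    ids = sorted(seqs)
    clusters: dict[str, list[str]] = {i: [i] for i in ids}
    dist: dict[tuple[str, str], float] = {}
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            sa, sb = seqs[a], seqs[b]
            L = min(len(sa), len(sb))
            if L == 0:
                d = 1.0
            else:
                diff = sum(1 for x, y in zip(sa[:L], sb[:L]) if x != y)
                d = (diff + abs(len(sa) - len(sb))) / max(len(sa), len(sb))
            dist[(a, b)] = dist[(b, a)] = d

    schedule: list[list[str]] = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = min(dist[(x, y)] for x in clusters[a] for y in clusters[b])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        schedule.append([a, b])
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return schedule


def _progressive_msa(
    seqs: Mapping[str, str],
    submat: np.ndarray,
    alphabet: str,
    gap_open: float,
    gap_extend: float,
) -> dict[str, str]:
    if not seqs:
        raise MalformedAnnotationError("empty ortholog set")
    blocks: dict[str, dict[str, str]] = {
        rid: {rid: seq} for rid, seq in seqs.items()
    }
    for a, b in _guide_order(seqs):
        rows_a, rows_b = blocks[a], blocks[b]
        prof_a = _to_profile(list(rows_a.values()), alphabet)
        prof_b = _to_profile(list(rows_b.values()), alphabet)
        _, path = _affine_nw(prof_a, prof_b, submat, gap_open, gap_extend)
        blocks[a] = _merge(rows_a, rows_b, path)
        del blocks[b]
    (_, merged), = blocks.items()
    return {rid: merged[rid] for rid in seqs}


# ---------------------------------------------------------------------------
# public alignment API

@dataclass
class GeneAlignment:
    """A single-gene multiple alignment (rows keyed by record id)."""

    gene: str
    category: str
    sequences: dict[str, str]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise MalformedAnnotationError(
                f"{self.gene}: ragged alignment rows"
            )


def _aa_matrix() -> tuple[np.ndarray, str]:
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = str(blosum.alphabet)
    return np.array(blosum), alphabet


def _nt_matrix(match: float, mismatch: float) -> tuple[np.ndarray, str]:
    alphabet = "ACGTN"
    mat = np.full((5, 5), mismatch)
    np.fill_diagonal(mat, match)
    mat[4, :] = 0.0  # N is neutral
    mat[:, 4] = 0.0
    return mat, alphabet


def translate_cds(seq: str, name: str = "cds", code: int = 5) -> str:
    """Translate an in-frame CDS, transiently completing an incomplete
    terminal codon with A's (post-transcriptional polyadenylation)."""
    s = seq.upper()
    if len(s) < 3:
        raise FrameError(f"{name}: CDS shorter than one codon")
    rem = len(s) % 3
    if rem:
        s = s + "A" * (3 - rem)
    try:
        return str(Seq(s).translate(table=code))
    except Exception as exc:
        raise FrameError(f"{name}: cannot translate ({exc})") from exc


def align_pcg(
    orthologs: Mapping[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    gene: str = "pcg",
) -> GeneAlignment:
    """Codon-aware alignment of orthologous CDSs.

    Translate (code 5) -> align amino acids (BLOSUM62, affine gaps) ->
    back-translate, so each amino-acid gap becomes a 3-base gap and the
    nucleotide alignment length is divisible by 3. An incomplete terminal
    codon is padded with alignment gaps, never with invented bases.
    """
    if len(orthologs) < 2:
        raise MalformedAnnotationError(f"{gene}: need >= 2 sequences")
    proteins = {
        rid: translate_cds(seq, f"{gene}/{rid}")
        for rid, seq in orthologs.items()
    }
    submat, alphabet = _aa_matrix()
    aa_aln = _progressive_msa(proteins, submat, alphabet, gap_open, gap_extend)
    nt_rows: dict[str, str] = {}
    for rid, aa_row in aa_aln.items():
        codons = [orthologs[rid][k : k + 3] for k in range(0, len(orthologs[rid]), 3)]
        out = []
        ci = 0
        for ch in aa_row:
            if ch == "-":
                out.append("---")
            else:
                codon = codons[ci]
                out.append(codon + "-" * (3 - len(codon)))
                ci += 1
        nt_rows[rid] = "".join(out)
    return GeneAlignment(gene, PCG, nt_rows)


def align_rna(
    orthologs: Mapping[str, str],
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = 8.0,
    gap_extend: float = 1.0,
    gene: str = "rna",
    category: str = TRNA,
) -> GeneAlignment:
    """Nucleotide-level global alignment for tRNA/rRNA/non-coding genes."""
    if not orthologs:
        raise MalformedAnnotationError(f"{gene}: empty ortholog set")
    submat, alphabet = _nt_matrix(match, mismatch)
    rows = _progressive_msa(
        {r: s.upper() for r, s in orthologs.items()},
        submat, alphabet, gap_open, gap_extend,
    )
    return GeneAlignment(gene, category, rows)


# ---------------------------------------------------------------------------
# concatenation

@dataclass
class ConcatenatedMatrix:
    """Supermatrix with named, contiguous, non-overlapping partitions
    (1-based inclusive coordinates)."""

    label: str
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def partition_rows(self, name: str) -> dict[str, str]:
        for pname, start, end in self.partitions:
            if pname == name:
                return {r: s[start - 1 : end] for r, s in self.rows.items()}
        raise KeyError(name)


def _canonical_sort(alignments: list[GeneAlignment]) -> list[GeneAlignment]:
    order = {g: i for i, g in enumerate(CANONICAL_GENE_ORDER)}
    return sorted(
        alignments, key=lambda a: (order.get(a.gene, len(order)), a.gene)
    )


def concatenate(
    alignments: Sequence[GeneAlignment],
    scheme: str = "dataset1",
) -> ConcatenatedMatrix:
    """Concatenate single-gene alignments into a partitioned supermatrix.

    dataset1: the 13 PCGs in canonical genome order, one partition per
    gene. dataset2: PCG partitions first (genome order), then all tRNAs
    concatenated as one partition, then the rRNAs as one partition, so
    partitions tile the matrix contiguously. Records missing from a gene
    get an all-gap block of that gene's length (with a warning).
    """
    if scheme not in ("dataset1", "dataset2"):
        raise ValueError(f"unknown scheme {scheme!r}")
    seen: set[str] = set()
    for aln in alignments:
        if aln.gene in seen:
            raise MalformedAnnotationError(f"duplicate gene {aln.gene}")
        seen.add(aln.gene)

    pcgs = _canonical_sort([a for a in alignments if a.category == PCG])
    if scheme == "dataset1":
        blocks: list[tuple[str, list[GeneAlignment]]] = [
            (a.gene, [a]) for a in pcgs
        ]
    else:
        trnas = _canonical_sort([a for a in alignments if a.category == TRNA])
        rrnas = _canonical_sort([a for a in alignments if a.category == RRNA])
        blocks = [(a.gene, [a]) for a in pcgs]
        if trnas:
            blocks.append(("tRNA", trnas))
        if rrnas:
            blocks.append(("rRNA", rrnas))

    all_ids = sorted({rid for _, alns in blocks for a in alns for rid in a.sequences})
    rows = {rid: [] for rid in all_ids}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for name, alns in blocks:
        start = pos + 1
        for aln in alns:
            for rid in all_ids:
                if rid in aln.sequences:
                    rows[rid].append(aln.sequences[rid])
                else:
                    warnings.warn(
                        f"{rid} missing from {aln.gene}; inserting gap block",
                        stacklevel=2,
                    )
                    rows[rid].append("-" * aln.length)
            pos += aln.length
        partitions.append((name, start, pos))
    return ConcatenatedMatrix(
        scheme, {rid: "".join(parts) for rid, parts in rows.items()}, partitions
    )


# ---------------------------------------------------------------------------
# writers

def write_fasta_alignment(matrix: ConcatenatedMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in matrix.rows.items():
            fh.write(f">{rid}\n{row}\n")


def write_phylip(matrix: ConcatenatedMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (full names, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.rows)} {matrix.length}\n")
        for rid, row in matrix.rows.items():
            fh.write(f"{rid}  {row}\n")


def write_nexus(matrix: ConcatenatedMatrix, path: str | Path) -> None:
    """NEXUS with a sets block holding the partition charsets."""
    lines = [
        "#NEXUS",
        "begin data;",
        f"  dimensions ntax={len(matrix.rows)} nchar={matrix.length};",
        "  format datatype=dna missing=? gap=-;",
        "  matrix",
    ]
    for rid, row in matrix.rows.items():
        lines.append(f"    {rid}  {row}")
    lines += ["  ;", "end;", "begin sets;"]
    for name, start, end in matrix.partitions:
        lines.append(f"  charset {name} = {start}-{end};")
    lines += ["end;", ""]
    Path(path).write_text("\n".join(lines))


def write_raxml_partitions(
    matrix: ConcatenatedMatrix, path: str | Path, by_codon: bool = False
) -> None:
    """RAxML-style partition file: ``DNA, name = start-end`` lines; with
    ``by_codon`` each PCG partition is split into three codon positions."""
    lines = []
    for name, start, end in matrix.partitions:
        is_pcg = categorize(name) == PCG
        if by_codon and is_pcg:
            for k in range(3):
                lines.append(
                    f"DNA, {name}_pos{k + 1} = {start + k}-{end}\\3"
                )
        else:
            lines.append(f"DNA, {name} = {start}-{end}")
    Path(path).write_text("\n".join(lines) + "\n")
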