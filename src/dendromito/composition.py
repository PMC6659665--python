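"""Base composition, strand skews, codon usage and RSCU.

Skews follow the standard definitions AT skew = (A-T)/(A+T) and
GC skew = (G-C)/(G+C), computed on the majority strand. Codon usage pools
in-frame protein-coding sequences under the invertebrate mitochondrial
genetic code (translation table 5), excludes stop codons, and reports
per-thousand frequencies and relative synonymous codon usage (RSCU).

Leucine and serine are each split into two synonymous families by codon
block, as mitogenome papers label them: Leu1 = CUN, Leu2 = UUR,
Ser1 = AGN, Ser2 = UCN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import DendromitoError

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _build_families(code_id: int) -> tuple[dict[str, str], set[str]]:
    """codon (RNA alphabet) -> family name, plus the stop-codon set."""
    table = unambiguous_dna_by_id[code_id]
    families: dict[str, str] = {}
    for codon_dna, aa in table.forward_table.items():
        codon = codon_dna.replace("T", "U")
        name = _AA3[aa]
        if name == "Leu":
            name = "Leu1" if codon.startswith("CU") else "Leu2"
        elif name == "Ser":
            name = "Ser1" if codon.startswith("AG") else "Ser2"
        families[codon] = name
    stops = {c.replace("T", "U") for c in table.stop_codons}
    return families, stops


@dataclass
class CompositionProfile:
    """Nucleotide counts and strand-asymmetry skews for one region.

    Skews with an undefined denominator (A+T = 0 or G+C = 0) are ``None``,
    never silently zero.
    """

    label: str
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else None

    @property
    def gc_skew(self) -> Optional[float]:
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else None


def composition_profile(sequence: str, region: str = "") -> CompositionProfile:
    """Count bases and derive AT content and skews; N's are excluded from
    all denominators. Raises on an empty (or all-N) sequence."""
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    if sum(counts.values()) == 0:
        raise DendromitoError(f"{region or 'sequence'}: no countable bases")
    return CompositionProfile(
        region, counts["A"], counts["C"], counts["G"], counts["T"]
    )


@dataclass
class CodonUsageTable:
    """Pooled codon counts, per-thousand frequencies and RSCU values.

    Codons are keyed in the RNA alphabet (e.g. UUA); stop codons are
    excluded by construction. ``family`` maps each codon to its synonymous
    family; ``zero_families`` flags families absent from the data (their
    RSCU is 0 by convention).
    """

    genetic_code: int
    counts: dict[str, int]
    family: dict[str, str]
    rscu: dict[str, float] = field(default_factory=dict)
    zero_families: set[str] = field(default_factory=set)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def per_thousand(self) -> dict[str, float]:
        total = self.total_codons
        return {c: n * 1000.0 / total for c, n in self.counts.items()}

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for codon, fam in self.family.items():
            out[fam] = out.get(fam, 0) + self.counts.get(codon, 0)
        return out

    def family_per_thousand(self) -> dict[str, float]:
        total = self.total_codons
        return {
            fam: n * 1000.0 / total for fam, n in self.family_counts().items()
        }


def codon_usage(
    cds_sequences: Sequence[str] | Mapping[str, str],
    genetic_code: int = 5,
) -> CodonUsageTable:
    """Pool codon counts across in-frame protein-coding sequences.

    Incomplete terminal codons (length mod 3 leftovers) and stop codons are
    excluded from the counts. An internal stop codon raises a frame warning
    naming the gene and codon position but is still excluded.
    """
    if isinstance(cds_sequences, Mapping):
        items = list(cds_sequences.items())
    else:
        items = [(f"seq{i + 1}", s) for i, s in enumerate(cds_sequences)]
    family, stops = _build_families(genetic_code)
    counts = {codon: 0 for codon in family}
    for name, seq in items:
        rna = seq.upper().replace("T", "U")
        ncodons = len(rna) // 3
        internal_stops: list[int] = []
        for k in range(ncodons):
            codon = rna[3 * k : 3 * k + 3]
            if codon in stops:
                if k < ncodons - 1:
                    internal_stops.append(k + 1)
                continue
            if codon in counts:
                counts[codon] += 1
        if internal_stops:
            warnings.warn(
                f"internal stop codon(s) in {name} at codon position(s) "
                + ", ".join(map(str, internal_stops)),
                stacklevel=2,
            )
    return CodonUsageTable(genetic_code, counts, family)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU: observed count / expected count under uniform usage
    within the codon's synonymous family, i.e.
    ``count * family_size / family_total``."""
    fam_counts = table.family_counts()
    fam_sizes: dict[str, int] = {}
    for fam in table.family.values():
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
    values: dict[str, float] = {}
    zero: set[str] = set()
    for codon, fam in table.family.items():
        if fam_counts[fam] == 0:
            values[codon] = 0.0
            zero.add(fam)
        else:
            values[codon] = (
                table.counts[codon] * fam_sizes[fam] / fam_counts[fam]
            )
    table.rscu = values
    table.zero_families = zero
    return table


def write_composition_table(
    profiles: Iterable[CompositionProfile], path: str | Path
) -> None:
    """One row per region/record: counts, AT%, skews."""
    lines = ["label\tA\tC\tG\tT\tat_content\tat_skew\tgc_skew"]
    for p in profiles:
        ats = "NA" if p.at_skew is None else f"{p.at_skew:.4f}"
        gcs = "NA" if p.gc_skew is None else f"{p.gc_skew:.4f}"
        lines.append(
            f"{p.label}\t{p.a}\t{p.c}\t{p.g}\t{p.t}"
            f"\t{p.at_content:.4f}\t{ats}\t{gcs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_rscu_table(table: CodonUsageTable, path: str | Path) -> None:
    """64-row (minus stops) codon table: family, count, per-thousand, RSCU."""
    per_k = table.per_thousand
    lines = ["codon\tfamily\tcount\tper_thousand\trscu"]
    for codon in sorted(table.family, key=lambda c: (table.family[c], c)):
        r = table.rscu.get(codon, float("nan"))
        lines.append(
            f"{codon}\t{table.family[codon]}\t{table.counts[codon]}"
            f"\t{per_k[codon]:.3f}\t{r:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
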