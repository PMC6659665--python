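#!/usr/bin/env python
"""Base composition, skews, codon survey, codon usage and RSCU on the
simulated genomes (run 01_simulate.py first). Writes
results/composition/.
"""

from pathlib import Path

from dendromito.composition import (
    codon_usage,
    composition_profile,
    rscu,
    write_composition_table,
    write_rscu_table,
)
from dendromito.genome_model import PCG, extract_gene_sequence, read_annotation_table
from dendromito.organization import codon_survey, write_codon_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "composition"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_annotation_table(
        ROOT / "simulated" / "annotations.tsv",
        sequence_source=ROOT / "simulated" / "genomes.fasta",
    )
    profiles = [composition_profile(r.sequence, r.id) for r in records]
    write_composition_table(profiles, OUT / "composition.tsv")
    ats = [p.at_content for p in profiles]
    print(f"A+T content across {len(records)} genomes: "
          f"{min(ats):.3f}-{max(ats):.3f} "
          f"(AT skew {profiles[0].at_skew:+.3f}, "
          f"GC skew {profiles[0].gc_skew:+.3f} for {profiles[0].label})")

    write_codon_table([codon_survey(r) for r in records], OUT / "codons.tsv")

    cds = {
        f"{rec.id}/{f.name}": extract_gene_sequence(rec, f)
        for rec in records for f in rec.features if f.category == PCG
    }
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # simulated CDSs drift into stops
        table = rscu(codon_usage(cds))
    write_rscu_table(table, OUT / "rscu.tsv")
    per_k = table.family_per_thousand()
    top = sorted(per_k, key=lambda f: -per_k[f])[:8]
    print(f"{table.total_codons} codons pooled; most frequent families: "
          + ", ".join(f"{f} ({per_k[f]:.0f}/1000)" for f in top[:4]))
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
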