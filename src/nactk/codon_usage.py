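"""Codon counting, per-species summaries and relative synonymous codon usage.

RSCU for a codon c in a synonymous family F is ``count(c) / (total(F) /
|F|)`` — the observed count relative to the expectation under uniform use
within the family, so family means are exactly 1 whenever the family is
observed at all, and single-codon families (ATG, TGG) are 1 when present.

Stop codons are excluded from RSCU and abundance (analysis over the 61 sense
codons) but their counts are still reported.  Codons containing ambiguous
bases are skipped and tallied separately, never imputed.  Output labels use
the RNA alphabet (AAG, UCU, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .sequence_io import SequenceRecord

_TABLE = CodonTable.unambiguous_dna_by_id[1]

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
ALL_CODONS: tuple[str, ...] = SENSE_CODONS + STOP_CODONS

#: synonymous families: amino acid -> tuple of codons (DNA alphabet)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in _TABLE.forward_table.items() if a == aa))
    for aa in FAMILIES
}

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "FAMILIES",
    "CodonUsageTable",
    "count_codons",
    "rscu",
    "rscu_table",
    "species_summary",
    "presence_matrix",
    "to_rna",
]


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def _normalize_cds(residues: str) -> str:
    return residues.upper().replace("U", "T").replace("-", "")


def count_codons(
    cds: SequenceRecord | str, frame: int = 0
) -> tuple[dict[str, int], int]:
    """Count codons in one CDS.

    Returns (counts over the 64 codons, number of skipped ambiguous codons).
    One terminal stop codon is included in the counts (reported under the
    stop codons, excluded from RSCU downstream).  A length not divisible by
    3 after ``frame`` raises ValueError — callers treat this per record.
    """
    residues = cds.residues if isinstance(cds, SequenceRecord) else cds
    seq = _normalize_cds(residues)[frame:]
    if len(seq) % 3 != 0:
        name = cds.id if isinstance(cds, SequenceRecord) else "<cds>"
        raise ValueError(f"{name}: CDS length {len(seq)} not divisible by 3")
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in counts:
            counts[codon] += 1
        else:
            skipped += 1  # ambiguous base
    return counts, skipped


def rscu(family_counts: Mapping[str, int]) -> dict[str, float | None]:
    """RSCU within one synonymous family.

    ``rscu_c = count_c / (family_total / family_size)``; all values are
    None when the family has no counts.
    """
    total = sum(family_counts.values())
    size = len(family_counts)
    if total == 0:
        return {c: None for c in family_counts}
    expected = total / size
    return {c: n / expected for c, n in family_counts.items()}


def rscu_table(sense_counts: Mapping[str, int]) -> dict[str, float | None]:
    """RSCU over all 61 sense codons from pooled counts."""
    out: dict[str, float | None] = {}
    for codons in FAMILIES.values():
        fam = {c: sense_counts.get(c, 0) for c in codons}
        out.update(rscu(fam))
    return out


@dataclass
class CodonUsageTable:
    """Per-species codon usage: counts, presence, average abundance, RSCU."""

    species_id: str
    n_genes: int
    counts: dict[str, int]  # all 64 codons
    skipped_ambiguous: int
    sense_counts: dict[str, int] = field(init=False)
    avg_abundance: dict[str, float] = field(init=False)
    rscu: dict[str, float | None] = field(init=False)
    presence: dict[str, bool] = field(init=False)

    def __post_init__(self) -> None:
        self.sense_counts = {c: self.counts.get(c, 0) for c in SENSE_CODONS}
        self.avg_abundance = {
            c: n / self.n_genes for c, n in self.sense_counts.items()
        }
        self.rscu = rscu_table(self.sense_counts)
        self.presence = {c: n > 0 for c, n in self.sense_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Table 4-shaped frame: one row per sense codon, RNA labels."""
        rows = []
        for codon in SENSE_CODONS:
            rows.append(
                {
                    "codon": to_rna(codon),
                    "amino_acid": _TABLE.forward_table[codon],
                    "count": self.sense_counts[codon],
                    "present": self.presence[codon],
                    "avg_abundance": self.avg_abundance[codon],
                    "rscu": self.rscu[codon],
                }
            )
        return pd.DataFrame(rows)


def species_summary(
    species_id: str, gene_counts: Sequence[Mapping[str, int]], skipped: int = 0
) -> CodonUsageTable:
    """Pool per-gene codon counts into one species table (>= 1 gene)."""
    if not gene_counts:
        raise ValueError(f"{species_id}: species summary needs at least one gene")
    pooled = {c: 0 for c in ALL_CODONS}
    for counts in gene_counts:
        for c, n in counts.items():
            pooled[c] += n
    return CodonUsageTable(
        species_id=species_id,
        n_genes=len(gene_counts),
        counts=pooled,
        skipped_ambiguous=skipped,
    )


def presence_matrix(summaries: Sequence[CodonUsageTable]) -> pd.DataFrame:
    """Species x codon presence with a per-codon 'present in N species' row.

    Returns a DataFrame indexed by species id over RNA codon labels, plus
    the aggregate row ``n_species_present``; ``attrs['universal']`` lists
    codons present in every species.
    """
    data = {
        s.species_id: {to_rna(c): s.presence[c] for c in SENSE_CODONS}
        for s in sorted(summaries, key=lambda s: s.species_id)
    }
    frame = pd.DataFrame(data).T
    n_present = frame.sum(axis=0).astype(int)
    out = frame.copy()
    out.loc["n_species_present"] = n_present
    out.attrs["universal"] = sorted(n_present[n_present == len(frame)].index)
    return out
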