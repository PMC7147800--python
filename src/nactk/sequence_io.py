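"""Sequence and tree I/O plus protein/CDS pairing.

Every pipeline stage consumes :class:`SequenceRecord` objects.  FASTA is read
and written through Biopython, newick through dendropy; the thin wrappers here
add the validation contracts the rest of the package relies on (unique ids,
alphabet checking, uppercase normalization).

Coordinates are 0-based half-open internally; every report emitted by the
package uses 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN-")

__all__ = [
    "SequenceRecord",
    "PairedRecord",
    "SequenceIOError",
    "read_fasta",
    "write_fasta",
    "pair_protein_cds",
    "read_newick",
    "write_newick",
    "write_tsv",
]


class SequenceIOError(ValueError):
    """Raised for malformed sequence input (bad residues, duplicate ids...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein or nucleotide sequence.

    Parameters
    ----------
    id:
        Unique token without whitespace.
    residues:
        Uppercase residue string; protein residues from the 20 amino acids
        plus X, DNA residues from A, C, G, T, N and the gap character.
    alphabet:
        ``"protein"`` or ``"dna"``.
    description:
        Free text carried through from the FASTA header.
    """

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceIOError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise SequenceIOError(f"{self.id}: empty sequence")
        if self.alphabet not in ("protein", "dna"):
            raise SequenceIOError(f"{self.id}: unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, res in enumerate(self.residues):
            if res not in allowed:
                raise SequenceIOError(
                    f"{self.id}: residue {res!r} at position {pos + 1} not in "
                    f"{self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairedRecord:
    """A protein together with its coding sequence and a translation check."""

    protein: SequenceRecord
    cds: SequenceRecord
    translation_ok: bool
    reason: str = ""


def _normalize(raw: str, alphabet: str, rec_id: str) -> str:
    seq = raw.upper()
    if alphabet == "protein" and seq.endswith("*"):
        seq = seq[:-1]  # single terminal stop tolerated and stripped
    return seq


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Residues are uppercased; a single terminal ``*`` in protein FASTA is
    stripped.  Duplicate ids, empty files and out-of-alphabet residues raise
    :class:`SequenceIOError` (with the offending position named).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq), alphabet, rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                alphabet=alphabet,
                description=rec.description[len(rec.id) :].strip(),
            )
        )
    if not records:
        raise SequenceIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping, id + description header)."""
    out = []
    for rec in records:
        description = rec.description or ""
        out.append(SeqRecord(Seq(rec.residues), id=rec.id, description=description))
    SeqIO.write(out, str(path), "fasta")


def _translate_matches(cds: str, protein: str, table: int) -> tuple[bool, str]:
    codon_table = CodonTable.unambiguous_dna_by_id[table]
    seq = cds.replace("-", "")
    if len(seq) % 3 != 0:
        return False, "cds length not divisible by 3"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in codon_table.stop_codons:
        codons = codons[:-1]  # exactly one terminal stop stripped
    if len(codons) != len(protein):
        return False, (
            f"cds encodes {len(codons)} residues, protein has {len(protein)}"
        )
    for i, codon in enumerate(codons):
        if codon in codon_table.stop_codons:
            return False, f"internal stop codon at codon {i + 1}"
        if "N" in codon:
            aa = None  # ambiguous codon: only X matches
        else:
            aa = codon_table.forward_table[codon]
        if protein[i] == "X":
            continue  # X in the protein matches any residue
        if aa is None or aa != protein[i]:
            return False, f"mismatch at residue {i + 1}"
    return True, ""


def pair_protein_cds(
    proteins: Sequence[SequenceRecord],
    cds: Sequence[SequenceRecord],
    genetic_code: int = 1,
) -> list[PairedRecord]:
    """Pair proteins with CDS records by id and verify the translation.

    ``translation_ok`` is true when the standard-code translation of the CDS
    (after dropping one terminal stop, if present) equals the protein, with a
    protein X matching any residue.  Unmatched ids raise.
    """
    prot_by_id = {p.id: p for p in proteins}
    cds_by_id = {c.id: c for c in cds}
    missing_cds = sorted(set(prot_by_id) - set(cds_by_id))
    missing_prot = sorted(set(cds_by_id) - set(prot_by_id))
    if missing_cds or missing_prot:
        raise SequenceIOError(
            f"unmatched ids: {missing_cds + missing_prot}"
        )
    pairs = []
    for pid in sorted(prot_by_id):
        ok, reason = _translate_matches(
            cds_by_id[pid].residues, prot_by_id[pid].residues, genetic_code
        )
        pairs.append(
            PairedRecord(
                protein=prot_by_id[pid],
                cds=cds_by_id[pid],
                translation_ok=ok,
                reason=reason,
            )
        )
    return pairs


def read_newick(path: str | Path, require_unique_leaves: bool = True) -> dendropy.Tree:
    """Read one newick tree, preserving leaf labels byte-exact."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise SequenceIOError(f"{path}: duplicate leaf labels") from exc
        raise
    if require_unique_leaves:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise SequenceIOError(f"{path}: duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """UTF-8 tab-delimited writer used for every tabular report."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
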