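"""Sequence I/O and codon-alignment construction.

Reads protein/nucleotide FASTA, back-translates a protein alignment onto its
coding sequences to produce a column-synchronized codon alignment, applies the
gap-column filter (columns where nearly all rows are gapped are dropped), and
computes pairwise identities. Cluster assignments (sequence id -> clade label)
are read from two-column TSV.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._gencode import STOP_CODONS, translate_codon

GAP = "-"
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*" + GAP)
NUCLEOTIDE_CHARS = frozenset("ACGTUN" + GAP)


class SeqIOError(ValueError):
    """Malformed sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over an amino-acid or nucleotide alphabet (gap '-')."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record with empty id")
        if not self.seq:
            raise SeqIOError(f"sequence record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


def _check_alphabet(rec: SequenceRecord, allowed: frozenset[str], kind: str) -> None:
    for pos, ch in enumerate(rec.seq):
        if ch not in allowed:
            raise SeqIOError(
                f"illegal {kind} character {ch!r} at position {pos} in record {rec.id!r}"
            )


def read_fasta(path: str | Path | io.TextIOBase, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read FASTA into records, uppercasing and stripping whitespace.

    ``alphabet`` is ``"protein"`` or ``"nucleotide"`` and controls character
    validation. Duplicate ids and empty files are errors.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = PROTEIN_CHARS if alphabet == "protein" else NUCLEOTIDE_CHARS
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise SeqIOError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = "".join(str(rec.seq).split()).upper().replace("U", "T" if alphabet == "nucleotide" else "U")
            out = SequenceRecord(rec.id, seq)
            _check_alphabet(out, allowed, alphabet)
            records.append(out)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass
class ProteinAlignment:
    """Aligned amino-acid sequences of equal length (gap '-')."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SeqIOError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SeqIOError(f"unequal alignment row lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate ids in alignment")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    def row(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.seq
        raise KeyError(f"unknown sequence id {seq_id!r}")

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def subset(self, ids: Sequence[str]) -> "ProteinAlignment":
        keep = [r for r in self.records if r.id in set(ids)]
        return ProteinAlignment(keep)


@dataclass
class CodonAlignment:
    """Aligned coding sequences; gaps occupy whole codons ('---').

    ``column_map`` optionally records, after filtering, each codon column's
    index in the original (unfiltered) alignment.
    """

    records: list[SequenceRecord]
    genetic_code: int = 1
    column_map: list[int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SeqIOError(f"unequal codon-alignment row lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise SeqIOError(f"codon-alignment length {length} not divisible by 3")
        for rec in self.records:
            for j in range(0, length, 3):
                codon = rec.seq[j : j + 3]
                if GAP in codon and codon != GAP * 3:
                    raise SeqIOError(
                        f"partial gap codon {codon!r} at codon column {j // 3} in {rec.id!r}"
                    )
                if codon in STOP_CODONS and j < length - 3:
                    raise SeqIOError(
                        f"internal stop codon {codon} at codon column {j // 3} in {rec.id!r}"
                    )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def n_codon_cols(self) -> int:
        return len(self.records[0]) // 3

    def row(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.seq
        raise KeyError(f"unknown sequence id {seq_id!r}")

    def codon(self, i: int, col: int) -> str:
        return self.records[i].seq[3 * col : 3 * col + 3]

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        keep = [r for r in self.records if r.id in set(ids)]
        return CodonAlignment(keep, self.genetic_code, self.column_map)

    def to_protein(self) -> ProteinAlignment:
        """Translate each row (gap codons to '-')."""
        prot = []
        for rec in self.records:
            aa = []
            for j in range(0, len(rec.seq), 3):
                codon = rec.seq[j : j + 3]
                aa.append(GAP if codon == GAP * 3 else translate_codon(codon))
            prot.append(SequenceRecord(rec.id, "".join(aa)))
        return ProteinAlignment(prot)


def backtranslate(protein_aln: ProteinAlignment, cds: Iterable[SequenceRecord]) -> CodonAlignment:
    """Thread each CDS through its protein-alignment row, expanding gaps to '---'.

    A terminal stop codon on a CDS is stripped. Every codon must translate to
    the residue it aligns under; internal stops and length mismatches raise.
    """
    cds_by_id = {}
    for rec in cds:
        if rec.id in cds_by_id:
            raise SeqIOError(f"duplicate CDS id {rec.id!r}")
        cds_by_id[rec.id] = rec.seq
    rows = []
    for prec in protein_aln.records:
        if prec.id not in cds_by_id:
            raise SeqIOError(f"no CDS for aligned protein {prec.id!r}")
        dna = cds_by_id[prec.id]
        if len(dna) % 3 == 0 and dna[-3:] in STOP_CODONS:
            dna = dna[:-3]
        n_res = len(prec.ungapped())
        if len(dna) != 3 * n_res:
            raise SeqIOError(
                f"CDS/protein length mismatch for {prec.id!r}: "
                f"{len(dna)} nt vs {n_res} residues ({3 * n_res} nt expected)"
            )
        out = []
        k = 0
        for col, aa in enumerate(prec.seq):
            if aa == GAP:
                out.append(GAP * 3)
                continue
            codon = dna[3 * k : 3 * k + 3]
            k += 1
            translated = translate_codon(codon) if "N" not in codon else None
            if translated == "*":
                raise SeqIOError(
                    f"internal stop codon {codon} in {prec.id!r} at protein column {col}"
                )
            if translated is not None and aa not in ("X", translated):
                raise SeqIOError(
                    f"codon {codon} of {prec.id!r} at column {col} translates to "
                    f"{translated}, expected {aa}"
                )
            out.append(codon)
        rows.append(SequenceRecord(prec.id, "".join(out)))
    return CodonAlignment(rows)


def filter_codon_columns(
    aln: CodonAlignment, min_present: int = 3
) -> tuple[CodonAlignment, list[int]]:
    """Drop codon columns with fewer than ``min_present`` non-gap rows.

    The default of 3 removes exactly the columns where all sequences except
    one or two are gapped. Returns the filtered alignment (with a
    ``column_map`` back to original 0-based codon columns) and the list of
    removed original column indices.
    """
    if min_present < 1:
        raise ValueError("min_present must be >= 1")
    n_cols = aln.n_codon_cols
    keep, removed = [], []
    for col in range(n_cols):
        present = sum(1 for i in range(aln.n_seqs) if aln.codon(i, col) != GAP * 3)
        (keep if present >= min_present else removed).append(col)
    if not keep:
        raise SeqIOError("filtering removed every codon column")
    rows = [
        SequenceRecord(rec.id, "".join(rec.seq[3 * c : 3 * c + 3] for c in keep))
        for rec in aln.records
    ]
    if aln.column_map is not None:  # compose with a previous filtering pass
        keep = [aln.column_map[c] for c in keep]
        removed = [aln.column_map[c] for c in removed]
    return CodonAlignment(rows, aln.genetic_code, column_map=keep), removed


def pairwise_identity(aln: ProteinAlignment | CodonAlignment, id_a: str, id_b: str) -> float:
    """Percent identity over columns where neither row is gapped (NaN if none)."""
    a, b = aln.row(id_a), aln.row(id_b)
    matches = compared = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        matches += x == y
    if compared == 0:
        return math.nan
    return 100.0 * matches / compared


class GroupAssignment(dict):
    """Mapping sequence id -> cluster label, with TSV round trip."""

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupAssignment":
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise SeqIOError(f"{path}:{lineno}: expected 'id<TAB>label'")
                seq_id, label = parts
                if seq_id in out:
                    raise SeqIOError(f"{path}:{lineno}: duplicate id {seq_id!r}")
                out[seq_id] = label
        if not out:
            raise SeqIOError(f"no assignments found in {path}")
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seq_id, label in self.items():
                fh.write(f"{seq_id}\t{label}\n")

    def labels(self) -> list[str]:
        """Distinct cluster labels in first-seen order."""
        seen: dict[str, None] = {}
        for lab in self.values():
            seen.setdefault(lab)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [s for s, lab in self.items() if lab == label]

    def validate_against(self, ids: Sequence[str], min_labels: int = 2) -> None:
        missing = [i for i in ids if i not in self]
        if missing:
            raise SeqIOError(f"ids missing a cluster label: {missing}")
        if len(self.labels()) < min_labels:
            raise SeqIOError(f"need >= {min_labels} distinct cluster labels")
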