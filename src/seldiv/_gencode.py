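"""Standard genetic code tables shared across the package.

Only the standard nuclear code (NCBI table 1) is wired in: the state space of
the codon substitution models is its 61 sense codons, and fourfold-degenerate
codon boxes are defined with respect to it.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_table.stop_codons)

#: the 61 sense codons of the standard code, in TCAG order
SENSE_CODONS: tuple[str, ...] = tuple(
    c1 + c2 + c3
    for c1 in NUCLEOTIDES
    for c2 in NUCLEOTIDES
    for c3 in NUCLEOTIDES
    if c1 + c2 + c3 not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> one-letter amino acid (sense codons only)
CODON_TO_AA: dict[str, str] = {c: _table.forward_table[c] for c in SENSE_CODONS}

#: first-two-nucleotide prefixes whose third position is fully degenerate
#: (Ala GCN, Arg CGN, Gly GGN, Leu CTN, Pro CCN, Ser TCN, Thr ACN, Val GTN)
FOURFOLD_PREFIXES = frozenset(
    p for p in (a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
    if all(p + n in CODON_TO_AA for n in NUCLEOTIDES)
    and len({CODON_TO_AA[p + n] for n in NUCLEOTIDES}) == 1
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition (A<->G or C<->T)."""
    return (a in PURINES) == (b in PURINES) and a != b


def is_transversion(a: str, b: str) -> bool:
    """True if a->b is a purine<->pyrimidine change."""
    return a != b and (a in PURINES) != (b in PURINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for stop; raises on other input."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None
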