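"""4DTv: transversion proportion at conserved fourfold-degenerate third positions.

The 4DTv distance between a pair of aligned coding sequences is the fraction
of third-codon positions, restricted to columns where both codons sit in the
same fourfold-degenerate codon box, that differ by a transversion. It runs
from 0 for freshly duplicated paralogs to ~0.5 at saturation, which makes it a
convenient relative clock for dating paralog pairs against known whole-genome
duplications. No multiple-hit correction is applied: the raw proportion is the
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._gencode import CODON_TO_AA, FOURFOLD_PREFIXES, is_transversion
from .seqio import GAP, CodonAlignment


@dataclass(frozen=True)
class FourDTvResult:
    """4DTv distance plus the site counts behind it.

    ``d4dtv`` is NaN (undefined) when the pair shares no conserved
    fourfold-degenerate site.
    """

    d4dtv: float
    n_4d_sites: int
    n_transversions: int
    site_positions: tuple[int, ...]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d4dtv)


def _pair_rows(aln: CodonAlignment) -> tuple[str, str]:
    if aln.n_seqs != 2:
        raise ValueError(
            f"expected a 2-sequence alignment, got {aln.n_seqs}; use d4dtv_table for many pairs"
        )
    return aln.records[0].seq, aln.records[1].seq


def conserved_4d_sites(aln: CodonAlignment) -> list[int]:
    """Codon columns where both codons are in the same fourfold-degenerate box.

    A column qualifies when neither codon is a gap, both are unambiguous,
    both encode the same amino acid, and both first-two-nucleotide prefixes
    are fourfold boxes. Codons of twofold members of split amino acids
    (Ser AGY, Leu TTR, Arg AGR) never qualify.
    """
    a, b = _pair_rows(aln)
    sites = []
    for col in range(aln.n_codon_cols):
        ca, cb = a[3 * col : 3 * col + 3], b[3 * col : 3 * col + 3]
        if GAP in ca or GAP in cb:
            continue
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:  # ambiguous or stop
            continue
        if CODON_TO_AA[ca] != CODON_TO_AA[cb]:
            continue
        if ca[:2] in FOURFOLD_PREFIXES and cb[:2] in FOURFOLD_PREFIXES:
            sites.append(col)
    return sites


def d4dtv(aln: CodonAlignment) -> FourDTvResult:
    """4DTv distance for a two-sequence codon alignment."""
    a, b = _pair_rows(aln)
    sites = conserved_4d_sites(aln)
    n_tv = sum(1 for col in sites if is_transversion(a[3 * col + 2], b[3 * col + 2]))
    value = n_tv / len(sites) if sites else math.nan
    return FourDTvResult(value, len(sites), n_tv, tuple(sites))


def d4dtv_table(
    aln: CodonAlignment, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """One row per requested id pair: gene pair, site counts, 4DTv to 3 decimals."""
    known = set(aln.ids)
    rows = []
    for id_a, id_b in pairs:
        for name in (id_a, id_b):
            if name not in known:
                raise KeyError(f"unknown sequence id {name!r}")
        res = d4dtv(aln.subset([id_a, id_b]))
        rows.append(
            {
                "gene_pair": f"{id_a}/{id_b}",
                "n_4d_sites": res.n_4d_sites,
                "n_transversions": res.n_transversions,
                "d4dtv": float(f"{res.d4dtv:.3f}") if res.defined else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["gene_pair", "n_4d_sites", "n_transversions", "d4dtv"])
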