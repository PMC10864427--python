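"""Enumeration of mutant/wildtype peptide windows around a substitution.

Class I HLA molecules present peptides of 8-12 residues, so every window
of those lengths that covers the substituted residue is a potential
neoepitope.  For a protein of length L and a substitution at 1-based
position p, the k-mer windows covering p start at
max(1, p-k+1) .. min(p, L-k+1); each yields a mutant/wildtype pair
differing at exactly one position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from neoprior.variants import AMINO_ACIDS, ProteinSubstitution

DEFAULT_LENGTHS: tuple[int, ...] = (8, 9, 10, 11, 12)


class SequenceMismatchError(ValueError):
    """The protein sequence does not carry the annotated wildtype residue."""


@dataclass(frozen=True)
class PeptidePair:
    """A mutant (MT) and wildtype (WT) peptide of equal length.

    The two sequences differ at exactly one position, ``mut_offset``
    (1-based within the peptide): the MT peptide carries the mutant
    residue there and the WT peptide the wildtype one.
    """

    gene: str
    substitution: ProteinSubstitution
    length: int
    mt_seq: str
    wt_seq: str
    mut_offset: int

    def __post_init__(self) -> None:
        if len(self.mt_seq) != self.length or len(self.wt_seq) != self.length:
            raise ValueError("peptide length disagrees with declared length")
        if not 1 <= self.mut_offset <= self.length:
            raise ValueError("mut_offset outside the peptide")
        diffs = [i for i in range(self.length) if self.mt_seq[i] != self.wt_seq[i]]
        if diffs != [self.mut_offset - 1]:
            raise ValueError(
                "MT and WT peptides must differ at exactly the mutated offset"
            )
        if self.mt_seq[self.mut_offset - 1] != self.substitution.mt_aa:
            raise ValueError("MT peptide does not carry the mutant residue")
        if self.wt_seq[self.mut_offset - 1] != self.substitution.wt_aa:
            raise ValueError("WT peptide does not carry the wildtype residue")


def window_count(protein_length: int, position: int, k: int) -> int:
    """Closed-form number of k-mer windows covering a 1-based position."""
    lo = max(1, position - k + 1)
    hi = min(position, protein_length - k + 1)
    return max(0, hi - lo + 1)


def enumerate_windows(
    protein_seq: str,
    substitution: ProteinSubstitution,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
) -> list[PeptidePair]:
    """All MT/WT peptide pairs whose window covers the substituted residue.

    Windows are returned in increasing length, then increasing start
    position, so output order is deterministic.  The protein sequence must
    carry the annotated wildtype residue at the substituted position and
    contain only the 20 canonical amino acids (binding predictors accept
    nothing else); selenocysteine or ambiguity codes are rejected.
    """
    protein_seq = protein_seq.upper()
    bad = sorted(set(protein_seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(
            f"protein for {substitution.gene} contains non-canonical "
            f"residue(s) {''.join(bad)}"
        )
    L = len(protein_seq)
    p = substitution.position
    if not 1 <= p <= L:
        raise SequenceMismatchError(
            f"{substitution.gene}: position {p} outside protein of length {L}"
        )
    found = protein_seq[p - 1]
    if found != substitution.wt_aa:
        raise SequenceMismatchError(
            f"{substitution.gene} position {p}: annotation expects "
            f"{substitution.wt_aa}, sequence has {found}"
        )
    pairs: list[PeptidePair] = []
    for k in sorted(set(lengths)):
        lo = max(1, p - k + 1)
        hi = min(p, L - k + 1)
        for start in range(lo, hi + 1):  # 1-based window start
            wt = protein_seq[start - 1: start - 1 + k]
            offset = p - start + 1
            mt = wt[: offset - 1] + substitution.mt_aa + wt[offset:]
            pairs.append(
                PeptidePair(
                    gene=substitution.gene,
                    substitution=substitution,
                    length=k,
                    mt_seq=mt,
                    wt_seq=wt,
                    mut_offset=offset,
                )
            )
    return pairs


def pairs_to_frame(pairs: Sequence[PeptidePair]) -> pd.DataFrame:
    """Tabulate peptide pairs (one row per pair) for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene": p.gene,
                "substitution": p.substitution.notation,
                "length": p.length,
                "mut_offset": p.mut_offset,
                "mt_seq": p.mt_seq,
                "wt_seq": p.wt_seq,
            }
            for p in pairs
        ],
        columns=["gene", "substitution", "length", "mut_offset", "mt_seq", "wt_seq"],
    )
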