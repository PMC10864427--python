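"""Worked-example dataset: six published breast-cancer neoantigen candidates.

The top three candidates from each of two patient-derived primary breast
cancer cell lines (PC-B-142CA, HER2+; PC-B-148CA, triple-negative), with
the predicted IC50 (nM) of the mutant and wildtype peptides on the
patient-restricted HLA class I allele and the point-mutation type seen by
Sanger sequencing.  Used by the README walkthrough and as a small real
anchor for the fold-change and ranking code paths.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExampleCandidate:
    cell_line: str
    gene: str
    substitution: str  # E274K-style notation
    allele: str
    mt_peptide: str
    mt_ic50: float  # nM
    wt_peptide: str
    wt_ic50: float  # nM
    reported_fold_change: float
    base_change: tuple[str, str]  # observed point mutation, reference > alternate


EXAMPLE_CANDIDATES: tuple[ExampleCandidate, ...] = (
    ExampleCandidate(
        "PC-B-142CA", "ADGRL1", "E274K", "HLA-A*11:01",
        "KTDIDLAVDK", 38.970, "KTDIDLAVDE", 24602.85, 631.32, ("G", "A"),
    ),
    ExampleCandidate(
        "PC-B-142CA", "PARP1", "E619K", "HLA-A*11:01",
        "AIEHFMKLYK", 13.346, "AIEHFMKLYE", 2110.72, 158.15, ("G", "A"),
    ),
    ExampleCandidate(
        "PC-B-142CA", "SEC14L2", "R43Q", "HLA-A*11:01",
        "LQARSFDLQK", 118.433, "LRARSFDLQK", 3646.31, 30.78, ("G", "A"),
    ),
    ExampleCandidate(
        "PC-B-148CA", "LSR", "I158F", "HLA-A*24:02",
        "YYQGRRFTI", 10.190, "YYQGRRITI", 33.99, 3.33, ("A", "T"),
    ),
    ExampleCandidate(
        "PC-B-148CA", "ALKBH6", "V83M", "HLA-A*24:02",
        "RYMDKVSNLSLF", 8.182, "RYVDKVSNLSLF", 22.59, 2.76, ("G", "A"),
    ),
    ExampleCandidate(
        "PC-B-148CA", "GAA", "I823T", "HLA-C*07:02",
        "LRAGYTIPL", 61.563, "LRAGYIIPL", 88.89, 1.44, ("T", "C"),
    ),
)
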