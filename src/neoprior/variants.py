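"""Somatic variant ingestion, VAF/FPKM computation and codon-level checks.

A tumor's missense variants arrive annotated with the reference and
alternate codon plus the protein-level substitution (``E274K`` style,
1-based residue index).  This module validates that annotation against the
standard genetic code, computes the variant allele fraction (VAF) for the
tumor DNA and tumor RNA samples and FPKM expression values, and reads
variants from VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


class AnnotationMismatchError(ValueError):
    """The annotated amino-acid change disagrees with the annotated codons."""


class MalformedInputError(ValueError):
    """An input file could not be parsed."""


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code; stops become ``*``."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"invalid codon {codon!r}: expected 3 letters over ACGT")
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class ProteinSubstitution:
    """A single-residue amino-acid substitution, e.g. ADGRL1 E274K."""

    gene: str
    position: int  # 1-based residue index in the protein
    wt_aa: str
    mt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("protein position is 1-based and must be >= 1")
        for aa in (self.wt_aa, self.mt_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{aa!r} is not a standard amino acid")
        if self.wt_aa == self.mt_aa:
            raise ValueError("substitution must change the residue")

    @property
    def notation(self) -> str:
        """Short notation such as ``E274K``."""
        return f"{self.wt_aa}{self.position}{self.mt_aa}"

    @classmethod
    def from_notation(cls, gene: str, notation: str) -> "ProteinSubstitution":
        """Parse ``E274K``-style notation."""
        if len(notation) < 3:
            raise ValueError(f"cannot parse substitution {notation!r}")
        wt, pos, mt = notation[0], notation[1:-1], notation[-1]
        if not pos.isdigit():
            raise ValueError(f"cannot parse substitution {notation!r}")
        return cls(gene=gene, position=int(pos), wt_aa=wt, mt_aa=mt)


@dataclass(frozen=True)
class CodonChange:
    """Outcome of comparing a reference and an alternate codon.

    ``kind`` is one of ``missense``, ``synonymous``, ``nonsense``
    (``nonsense`` also covers stop-loss, where the reference codon is a
    stop); amino acids are 1-letter, ``*`` for stop.
    """

    kind: str
    wt_aa: str
    mt_aa: str


def classify_substitution(codon_ref: str, codon_alt: str) -> CodonChange:
    """Classify a codon change as missense, synonymous or nonsense.

    Both codons are translated with the standard genetic code.  The change
    is *missense* when the amino acids differ and neither is a stop,
    *synonymous* when they are identical, and *nonsense* when a stop codon
    is gained or lost.
    """
    if codon_ref.upper() == codon_alt.upper():
        raise ValueError("reference and alternate codons are identical")
    wt = translate_codon(codon_ref)
    mt = translate_codon(codon_alt)
    if wt == mt:
        return CodonChange("synonymous", wt, mt)
    if wt == "*" or mt == "*":
        return CodonChange("nonsense", wt, mt)
    return CodonChange("missense", wt, mt)


def find_snv_codon_changes(
    wt_aa: str,
    mt_aa: str,
    base_change: tuple[str, str] | None = None,
) -> list[tuple[str, str, int]]:
    """All single-nucleotide codon changes producing a given substitution.

    Returns ``(codon_ref, codon_alt, changed_index)`` triples (0-based
    index within the codon).  When ``base_change`` is given, e.g.
    ``("G", "A")``, only edits replacing that reference base with that
    alternate base are returned — useful for checking that an observed
    point-mutation type (a G>A transition, say) can explain an annotated
    amino-acid change.
    """
    out = []
    for c1 in _codons_for(wt_aa):
        for i in range(3):
            for b in NUCLEOTIDES:
                if b == c1[i]:
                    continue
                if base_change is not None and (c1[i], b) != base_change:
                    continue
                c2 = c1[:i] + b + c1[i + 1:]
                if translate_codon(c2) == mt_aa:
                    out.append((c1, c2, i))
    return out


def _codons_for(aa: str) -> list[str]:
    if aa == "*":
        return list(_STANDARD.stop_codons)
    return sorted(c for c, a in _STANDARD.forward_table.items() if a == aa)


def compute_vaf(alt: int, depth: int) -> float:
    """Variant allele fraction: alternate reads over total depth at the site."""
    if depth < 1:
        raise ZeroDivisionError("VAF undefined at zero depth")
    if not 0 <= alt <= depth:
        raise ValueError(f"alt count {alt} outside [0, depth={depth}]")
    return alt / depth

def compute_fpkm(fragments: int, gene_length_bp: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if gene_length_bp < 1:
        raise ValueError("gene length must be >= 1 bp")
    if total_mapped < 1:
        raise ValueError("library size must be >= 1 mapped fragment")
    if fragments < 0:
        raise ValueError("fragment count must be non-negative")
    return fragments * 1e9 / (gene_length_bp * total_mapped)


@dataclass
class SomaticVariant:
    """One annotated somatic missense variant with tumor DNA/RNA support."""

    id: str
    gene: str
    transcript: str
    codon_ref: str
    codon_alt: str
    protein_pos: int
    dna_depth: int
    dna_alt: int
    rna_depth: int
    rna_alt: int

    def __post_init__(self) -> None:
        for codon in (self.codon_ref, self.codon_alt):
            if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
                raise ValueError(f"invalid codon {codon!r}")
        if self.codon_ref == self.codon_alt:
            raise ValueError("reference and alternate codons are identical")
        if not 0 <= self.dna_alt <= self.dna_depth:
            raise ValueError("DNA alt count outside [0, depth]")
        if not 0 <= self.rna_alt <= self.rna_depth:
            raise ValueError("RNA alt count outside [0, depth]")
        if self.protein_pos < 1:
            raise ValueError("protein position is 1-based and must be >= 1")

    @property
    def dna_vaf(self) -> float:
        return compute_vaf(self.dna_alt, self.dna_depth)

    @property
    def rna_vaf(self) -> float:
        return compute_vaf(self.rna_alt, self.rna_depth)

    @property
    def codon_change(self) -> CodonChange:
        return classify_substitution(self.codon_ref, self.codon_alt)

    @property
    def substitution(self) -> ProteinSubstitution:
        change = self.codon_change
        if change.kind != "missense":
            raise ValueError(f"variant {self.id} is {change.kind}, not missense")
        return ProteinSubstitution(
            gene=self.gene,
            position=self.protein_pos,
            wt_aa=change.wt_aa,
            mt_aa=change.mt_aa,
        )


@dataclass
class ParseResult:
    """Missense variants read from a VCF plus skip bookkeeping."""

    variants: list[SomaticVariant]
    skipped: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def parse_variants(
    vcf_path: str,
    sample_names: tuple[str, str] = ("TUMOR_DNA", "TUMOR_RNA"),
    annotation_key: str = "PSUB",
) -> ParseResult:
    """Read somatic missense variants from a VCF.

    The VCF must carry per-sample ``AD`` and ``DP`` FORMAT fields for the
    two named samples (tumor DNA and tumor RNA) and a protein-level
    annotation in INFO under ``annotation_key`` with the pipe-separated
    layout ``gene|transcript|E274K|GAG|AAG`` (gene, transcript,
    substitution notation, reference codon, alternate codon).

    Records that are not missense or that lack a required field are
    skipped with a logged warning and counted in ``ParseResult.skipped``;
    a disagreement between the annotated substitution and the annotated
    codons is a hard :class:`AnnotationMismatchError`.
    """
    dna_name, rna_name = sample_names
    variants: list[SomaticVariant] = []
    skipped: dict[str, int] = {}

    def skip(reason: str, rec_id: str) -> None:
        skipped[reason] = skipped.get(reason, 0) + 1
        logger.warning("skipping record %s: %s", rec_id, reason)

    try:
        vcf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise MalformedInputError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    with vcf:
        for sn in sample_names:
            if sn not in vcf.header.samples:
                raise MalformedInputError(
                    f"VCF {vcf_path} lacks required sample {sn!r}"
                )
        for i, rec in enumerate(vcf, start=1):
            rec_id = rec.id or f"record {i}"
            ann = rec.info.get(annotation_key)
            if ann is None:
                skip(f"missing INFO/{annotation_key}", rec_id)
                continue
            parts = str(ann).split("|")
            if len(parts) != 5:
                raise MalformedInputError(
                    f"record {i} ({rec_id}): INFO/{annotation_key} must have "
                    f"5 pipe-separated fields, found {len(parts)}"
                )
            gene, transcript, notation, codon_ref, codon_alt = parts
            change = classify_substitution(codon_ref, codon_alt)
            if change.kind != "missense":
                skip(change.kind, rec_id)
                continue
            annotated = ProteinSubstitution.from_notation(gene, notation)
            if (annotated.wt_aa, annotated.mt_aa) != (change.wt_aa, change.mt_aa):
                raise AnnotationMismatchError(
                    f"record {i} ({rec_id}): annotation {notation} disagrees "
                    f"with codons {codon_ref}>{codon_alt} "
                    f"({change.wt_aa}->{change.mt_aa})"
                )
            depths: dict[str, tuple[int, int]] = {}
            ok = True
            for sn in (dna_name, rna_name):
                fmt = rec.samples[sn]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if ad is None or dp is None or any(a is None for a in ad):
                    skip("missing AD/DP", rec_id)
                    ok = False
                    break
                depths[sn] = (int(dp), int(ad[-1]))
            if not ok:
                continue
            variants.append(
                SomaticVariant(
                    id=rec_id,
                    gene=gene,
                    transcript=transcript,
                    codon_ref=codon_ref,
                    codon_alt=codon_alt,
                    protein_pos=annotated.position,
                    dna_depth=depths[dna_name][0],
                    dna_alt=depths[dna_name][1],
                    rna_depth=depths[rna_name][0],
                    rna_alt=depths[rna_name][1],
                )
            )
    return ParseResult(variants=variants, skipped=skipped)


def read_expression(path: str) -> dict[str, float]:
    """Read a two-column ``gene_id<TAB>fpkm`` expression table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "fpkm"} <= set(df.columns):
        raise MalformedInputError(
            f"expression table {path} needs columns gene_id and fpkm"
        )
    if (df["fpkm"] < 0).any():
        raise MalformedInputError("FPKM values must be non-negative")
    return dict(zip(df["gene_id"], df["fpkm"].astype(float)))
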