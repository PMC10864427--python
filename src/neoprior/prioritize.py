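"""Six-criterion neoantigen filtering, fold-change ranking and reporting.

The filter mirrors a modified pVAC-Seq prioritization of somatic missense
variants:

1. tumor DNA and RNA depth >= 10x (inclusive),
2. tumor DNA and RNA variant allele fraction >= 0.4 (inclusive),
3. gene expression FPKM > 1 (strict),
4. primary-predictor MT IC50 <= 500 nM (inclusive),
5. MT IC50 <= 500 nM in at least 3 of the 5 consensus predictors,
6. WT/MT IC50 fold change > 1 (strict).

Every criterion is evaluated independently (no short-circuit) so reports
show every failure reason.  Survivors are ranked by descending fold
change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from neoprior.binding import (
    BestBinding,
    PredictionSource,
    PredictorPanel,
    best_allele_binding,
    consensus_vote,
)
from neoprior.peptides import DEFAULT_LENGTHS, PeptidePair, enumerate_windows
from neoprior.variants import SomaticVariant

logger = logging.getLogger(__name__)

CRITERION_NAMES = (
    "depth",
    "vaf",
    "fpkm",
    "ic50_primary",
    "ic50_consensus",
    "fold_change",
)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the six filter criteria (defaults as listed above).

    ``require_rna`` applies the depth and VAF cutoffs to the tumor RNA
    sample as well as the tumor DNA sample; switch it off to filter on
    DNA only.
    """

    min_depth: int = 10
    min_vaf: float = 0.4
    min_fpkm: float = 1.0
    max_ic50_primary: float = 500.0
    consensus_threshold: float = 500.0
    consensus_min_support: int = 3
    min_fold_change: float = 1.0
    require_rna: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_fpkm <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_vaf <= 1:
            raise ValueError("min_vaf must lie in (0, 1]")
        if self.max_ic50_primary <= 0 or self.consensus_threshold <= 0:
            raise ValueError("IC50 thresholds must be positive")
        if self.consensus_min_support < 1:
            raise ValueError("consensus support must be >= 1")
        if self.min_fold_change <= 0:
            raise ValueError("fold-change threshold must be positive")


@dataclass
class NeoantigenCandidate:
    """A variant's best peptide register with per-criterion filter flags."""

    variant_id: str
    gene: str
    substitution: str
    pair: PeptidePair
    allele: str
    mt_ic50: float
    wt_ic50: float
    fold_change: float
    criterion_flags: tuple[bool, bool, bool, bool, bool, bool]
    fpkm: float | None = None
    fpkm_missing: bool = False

    @property
    def passed(self) -> bool:
        return all(self.criterion_flags)


def apply_filters(
    variant: SomaticVariant,
    fpkm: float | None,
    pair: PeptidePair,
    binding: BestBinding,
    thresholds: FilterThresholds = FilterThresholds(),
) -> NeoantigenCandidate:
    """Evaluate all six criteria on one variant/peptide/binding triple.

    Boundary semantics follow the filter definition: depth, VAF and the
    two IC50 criteria are inclusive; FPKM and fold change are strict.  A
    missing expression record fails criterion 3 and is flagged and logged
    rather than raised.
    """
    t = thresholds
    depth_ok = variant.dna_depth >= t.min_depth and (
        not t.require_rna or variant.rna_depth >= t.min_depth
    )
    vaf_ok = variant.dna_vaf >= t.min_vaf and (
        not t.require_rna or variant.rna_vaf >= t.min_vaf
    )
    fpkm_missing = fpkm is None
    if fpkm_missing:
        logger.warning(
            "no expression record for gene %s (variant %s); criterion 3 fails",
            variant.gene,
            variant.id,
        )
        fpkm_ok = False
    else:
        fpkm_ok = fpkm > t.min_fpkm
    primary_ok = binding.mt_ic50 <= t.max_ic50_primary
    consensus_ok = consensus_vote(
        list(binding.consensus_ic50s.values()),
        threshold=t.consensus_threshold,
        min_support=t.consensus_min_support,
    )
    fc = binding.fold_change
    fc_ok = fc > t.min_fold_change
    return NeoantigenCandidate(
        variant_id=variant.id,
        gene=variant.gene,
        substitution=variant.substitution.notation,
        pair=pair,
        allele=binding.allele,
        mt_ic50=binding.mt_ic50,
        wt_ic50=binding.wt_ic50,
        fold_change=fc,
        criterion_flags=(depth_ok, vaf_ok, fpkm_ok, primary_ok, consensus_ok, fc_ok),
        fpkm=fpkm,
        fpkm_missing=fpkm_missing,
    )


def rank_candidates(
    candidates: Sequence[NeoantigenCandidate],
) -> list[NeoantigenCandidate]:
    """Order passing candidates by descending WT/MT fold change.

    Ties break on lower MT IC50, then lexicographic MT peptide; the sort
    is deterministic and invariant to input permutation.
    """
    return sorted(
        candidates,
        key=lambda c: (-c.fold_change, c.mt_ic50, c.pair.mt_seq),
    )


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_report(
    ranked: Sequence[NeoantigenCandidate], top_n: int | None = None
) -> pd.DataFrame:
    """Summary table of ranked candidates, one row per candidate.

    IC50s are reported at three decimals and fold changes at two
    (round-half-up).  ``top_n`` limits the number of rows; fewer
    candidates than ``top_n`` yield fewer rows, never padding.
    """
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        ranked = ranked[:top_n]
    rows = [
        {
            "rank": i,
            "gene": c.gene,
            "substitution": c.substitution,
            "allele": c.allele,
            "mt_peptide": c.pair.mt_seq,
            "mt_ic50_nM": _round_half_up(c.mt_ic50, 3),
            "wt_peptide": c.pair.wt_seq,
            "wt_ic50_nM": _round_half_up(c.wt_ic50, 3),
            "fold_change": _round_half_up(c.fold_change, 2),
        }
        for i, c in enumerate(ranked, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "gene",
            "substitution",
            "allele",
            "mt_peptide",
            "mt_ic50_nM",
            "wt_peptide",
            "wt_ic50_nM",
            "fold_change",
        ],
    )


def flags_table(candidates: Sequence[NeoantigenCandidate]) -> pd.DataFrame:
    """Long-form per-criterion flags, one row per (candidate, criterion)."""
    rows = []
    for c in candidates:
        for name, flag in zip(CRITERION_NAMES, c.criterion_flags):
            rows.append(
                {
                    "variant_id": c.variant_id,
                    "gene": c.gene,
                    "criterion": name,
                    "passed": bool(flag),
                }
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "gene", "criterion", "passed"]
    )


@dataclass
class PipelineResult:
    """Outcome of the full prioritization: candidates, ranking, funnel."""

    candidates: list[NeoantigenCandidate]
    passing: list[NeoantigenCandidate] = field(default_factory=list)
    funnel: dict[str, int] = field(default_factory=dict)

    @property
    def passing_ids(self) -> set[str]:
        return {c.variant_id for c in self.passing}


def run_pipeline(
    variants: Sequence[SomaticVariant],
    expression: Mapping[str, float],
    proteome: Mapping[str, str],
    alleles: Sequence[str],
    panel: PredictorPanel,
    source: PredictionSource,
    thresholds: FilterThresholds = FilterThresholds(),
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> PipelineResult:
    """Full prioritization: enumerate, predict, filter, rank.

    For each missense variant, all 8-12-mer MT/WT registers are evaluated
    on every patient allele; the register minimizing the primary MT IC50
    (ties: enumeration order, i.e. shorter then earlier windows) becomes
    the variant's candidate, which then faces the six criteria.  Variants
    that are not missense or whose gene lacks a protein sequence are
    dropped from the funnel with a log message.
    """
    candidates: list[NeoantigenCandidate] = []
    n_missense = 0
    for variant in variants:
        if variant.codon_change.kind != "missense":
            logger.info("variant %s is %s; dropped", variant.id, variant.codon_change.kind)
            continue
        n_missense += 1
        seq = proteome.get(variant.gene)
        if seq is None:
            logger.warning("no protein sequence for gene %s; dropped", variant.gene)
            continue
        pairs = enumerate_windows(seq, variant.substitution, lengths)
        best_pair, best_binding = min(
            ((pair, best_allele_binding(pair, alleles, panel, source)) for pair in pairs),
            key=lambda pb: pb[1].mt_ic50,
        )
        candidates.append(
            apply_filters(
                variant,
                expression.get(variant.gene),
                best_pair,
                best_binding,
                thresholds,
            )
        )
    passing = rank_candidates([c for c in candidates if c.passed])
    funnel = {
        "variants": len(variants),
        "missense": n_missense,
        "evaluated": len(candidates),
        "candidates": len(passing),
    }
    return PipelineResult(candidates=candidates, passing=passing, funnel=funnel)
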