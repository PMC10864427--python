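"""Peptide-HLA binding predictions: predictor interface, consensus, fold change.

Real pipelines call external predictors (NetMHC, MHCflurry, MHCnuggets,
SMM, SMMPMBEC, Pickpocket); this module defines the uniform interface
those adapters satisfy, a deterministic built-in toy predictor for offline
work, the "3 of 5 algorithms <= 500 nM" consensus vote, and the
WT/MT IC50 fold change (agretopicity) used for ranking.

A *prediction source* resolves ``(peptide, allele, predictor)`` triples to
IC50 values in nM.  ``DictSource`` is a table-backed source (the TSV cache
dialect), ``ToyPredictorSource`` computes values on the fly from hashed
position weights.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import pandas as pd

from neoprior.peptides import PeptidePair
from neoprior.variants import AMINO_ACIDS

HLA_PATTERN = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2}$")

#: IC50 (nM) of a peptide with zero predicted binding signal.
IC50_CEILING = 50000.0

DEFAULT_PRIMARY = "NetMHC"
DEFAULT_CONSENSUS = ("MHCflurry", "MHCnuggetsI", "SMM", "SMMPMBEC", "Pickpocket")


class MissingPredictionError(KeyError):
    """A (peptide, allele, predictor) triple could not be resolved."""


def validate_allele(allele: str) -> str:
    if not HLA_PATTERN.match(allele):
        raise ValueError(
            f"allele {allele!r} does not match the HLA-A*11:01 style pattern"
        )
    return allele


@dataclass(frozen=True)
class BindingPrediction:
    """One predicted IC50 (nM) for a peptide-allele-predictor triple."""

    peptide: str
    allele: str
    predictor: str
    ic50: float

    def __post_init__(self) -> None:
        validate_allele(self.allele)
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")


@dataclass(frozen=True)
class PredictorPanel:
    """The predictor roster: one primary plus a consensus set.

    The primary predictor supplies the IC50s used for the hard <= 500 nM
    filter and the WT/MT fold change; the consensus predictors vote
    independently ("at least 3 of 5 <= 500 nM").
    """

    primary: str = DEFAULT_PRIMARY
    consensus: tuple[str, ...] = DEFAULT_CONSENSUS

    def __post_init__(self) -> None:
        if self.primary in self.consensus:
            raise ValueError("primary predictor must not sit on the consensus panel")
        if len(set(self.consensus)) != len(self.consensus):
            raise ValueError("consensus predictors must be distinct")
        if not self.consensus:
            raise ValueError("consensus panel must not be empty")

    @property
    def all_predictors(self) -> tuple[str, ...]:
        return (self.primary, *self.consensus)


class PredictionSource(Protocol):
    """Anything that resolves (peptide, allele, predictor) to an IC50 in nM."""

    def ic50(self, peptide: str, allele: str, predictor: str) -> float: ...


WeightSource = Callable[[str, int, str], float]


def hashed_weights(predictor: str) -> WeightSource:
    """Deterministic pseudo-random weights w(allele, position, aa) in [0, 1].

    Each predictor name seeds its own weight table via BLAKE2 hashing, so
    distinct toy predictors disagree with each other yet are stable across
    processes and runs.
    """

    def weight(allele: str, position: int, aa: str) -> float:
        key = f"{predictor}|{allele}|{position}|{aa}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        return int.from_bytes(digest, "big") / 2**64

    return weight


def toy_predict(peptide: str, allele: str, weight_source: WeightSource) -> float:
    """Deterministic toy IC50: 50000^(1 - mean positional weight), in nM.

    The mean of w(allele, position, aa) over peptide positions plays the
    role of a binding score in [0, 1]; a perfect score gives 1 nM, a zero
    score the 50000 nM ceiling.  Strictly decreasing in the score.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = sorted(set(peptide) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"non-canonical residue(s) {''.join(bad)} in {peptide!r}")
    score = sum(
        weight_source(allele, i, aa) for i, aa in enumerate(peptide, start=1)
    ) / len(peptide)
    return IC50_CEILING ** (1.0 - score)


class ToyPredictorSource:
    """Prediction source backed by toy predictors, one weight table per name."""

    def __init__(self, predictors: Sequence[str]):
        self._weights = {name: hashed_weights(name) for name in predictors}

    def ic50(self, peptide: str, allele: str, predictor: str) -> float:
        try:
            weights = self._weights[predictor]
        except KeyError:
            raise MissingPredictionError(
                f"no toy predictor named {predictor!r}"
            ) from None
        return toy_predict(peptide, allele, weights)


class DictSource:
    """Table-backed prediction source, optionally with a default IC50.

    Without a default, an unknown triple raises
    :class:`MissingPredictionError` naming the triple.
    """

    def __init__(
        self,
        table: Mapping[tuple[str, str, str], float],
        default: float | None = None,
    ):
        self.table = dict(table)
        if default is not None and default <= 0:
            raise ValueError("default IC50 must be positive")
        self.default = default

    def ic50(self, peptide: str, allele: str, predictor: str) -> float:
        key = (peptide, allele, predictor)
        value = self.table.get(key, self.default)
        if value is None:
            raise MissingPredictionError(
                f"no prediction for peptide={peptide} allele={allele} "
                f"predictor={predictor}"
            )
        return value


def read_prediction_cache(path: str) -> dict[tuple[str, str, str], float]:
    """Read the ``peptide<TAB>allele<TAB>predictor<TAB>ic50_nM`` cache."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "predictor", "ic50_nM"}
    if not required <= set(df.columns):
        raise ValueError(f"prediction cache {path} needs columns {sorted(required)}")
    return {
        (row.peptide, row.allele, row.predictor): float(row.ic50_nM)
        for row in df.itertuples()
    }


def write_prediction_cache(
    table: Mapping[tuple[str, str, str], float], path: str
) -> None:
    rows = [
        {"peptide": p, "allele": a, "predictor": pr, "ic50_nM": v}
        for (p, a, pr), v in sorted(table.items())
    ]
    pd.DataFrame(
        rows, columns=["peptide", "allele", "predictor", "ic50_nM"]
    ).to_csv(path, sep="\t", index=False)


def consensus_vote(
    ic50s: Sequence[float], threshold: float = 500.0, min_support: int = 3
) -> bool:
    """True iff at least ``min_support`` IC50s are <= threshold (inclusive)."""
    if len(ic50s) == 0:
        raise ValueError("consensus vote needs at least one IC50")
    if any(x <= 0 for x in ic50s):
        raise ValueError("IC50 values must be positive")
    return sum(x <= threshold for x in ic50s) >= min_support


def fold_change(ic50_wt: float, ic50_mt: float) -> float:
    """Agretopicity: IC50(WT) / IC50(MT); > 1 means the mutant binds better."""
    if ic50_wt <= 0 or ic50_mt <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_wt / ic50_mt


@dataclass(frozen=True)
class BestBinding:
    """Binding summary of one peptide pair on its best patient allele."""

    allele: str
    mt_ic50: float
    wt_ic50: float
    consensus_ic50s: dict[str, float] = field(hash=False)

    @property
    def fold_change(self) -> float:
        return fold_change(self.wt_ic50, self.mt_ic50)


def best_allele_binding(
    pair: PeptidePair,
    alleles: Sequence[str],
    panel: PredictorPanel,
    source: PredictionSource,
) -> BestBinding:
    """Evaluate the MT peptide on every patient allele and keep the best.

    The best allele minimizes the primary-predictor MT IC50 (ties broken
    by lexicographically smaller allele name).  The WT IC50 and the
    consensus-panel MT IC50s are then computed for that same allele and
    register.
    """
    if not alleles:
        raise ValueError("at least one patient allele is required")
    for allele in alleles:
        validate_allele(allele)
    best = min(
        sorted(set(alleles)),
        key=lambda a: (source.ic50(pair.mt_seq, a, panel.primary), a),
    )
    mt = source.ic50(pair.mt_seq, best, panel.primary)
    wt = source.ic50(pair.wt_seq, best, panel.primary)
    consensus = {
        name: source.ic50(pair.mt_seq, best, name) for name in panel.consensus
    }
    return BestBinding(allele=best, mt_ic50=mt, wt_ic50=wt, consensus_ic50s=consensus)
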