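"""Synthetic inputs with planted ground truth for the whole pipeline.

Real neoantigen discovery starts from tumor sequencing that cannot ship
with a desk-scale package, so every input the pipeline consumes —
proteome, somatic variants with DNA/RNA support, expression table,
binding-prediction oracle, peptide-HLA structure frames, MM/GBSA energy
series and assay plates — is generated here with known ground truth.

A simulated cohort plants two kinds of variants: *passers* constructed to
clear all six filter criteria with margin, and *decoys* violating exactly
one assigned criterion while clearing the other five with margin.  The
central property downstream code is tested against: the pipeline must
recover exactly the planted passers, and each decoy must fail only its
assigned criterion.

Every generator is a pure function of its arguments including the seed.
Per-component substreams are derived from one master seed keyed by the
component name, so adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from neoprior.binding import DictSource, PredictorPanel
from neoprior.peptides import enumerate_windows
from neoprior.prioritize import FilterThresholds
from neoprior.variants import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    SomaticVariant,
    _codons_for,
    read_expression,
    translate_codon,
)

MIN_PROTEIN_LENGTH = 13  # shortest protein for which every 8-12-mer window exists

DEFAULT_ALLELES = ("HLA-A*11:01", "HLA-A*24:02")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream keyed by component name under one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> dict[str, str]:
    """Random proteome: uniform i.i.d. residues over the 20-letter alphabet.

    Returns ``{gene_id: sequence}`` with gene ids ``SYNG0001`` ...; output
    is identical for identical arguments.
    """
    if n_proteins < 1:
        raise ValueError("at least one protein must be requested")
    lo, hi = length_range
    if lo < MIN_PROTEIN_LENGTH:
        raise ValueError(
            f"minimum protein length is {MIN_PROTEIN_LENGTH} (so that all "
            "8-12-mer windows exist around interior positions)"
        )
    if hi < lo:
        raise ValueError("length range upper bound precedes lower bound")
    rng = substream(seed, "proteome")
    letters = np.array(list(AMINO_ACIDS))
    proteome: dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteome[f"SYNG{i + 1:04d}"] = "".join(rng.choice(letters, size=length))
    return proteome


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``planted_pass`` lists variant ids guaranteed to survive all six
    filters; ``planted_fail`` maps each decoy id to the single criterion
    index (1-6) it violates.
    """

    planted_pass: tuple[str, ...]
    planted_fail: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.planted_pass) & set(self.planted_fail)
        if overlap:
            raise ValueError(f"ids planted both ways: {sorted(overlap)}")
        bad = {k: v for k, v in self.planted_fail.items() if v not in range(1, 7)}
        if bad:
            raise ValueError(f"criterion indices outside 1..6: {bad}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_pass": list(self.planted_pass),
                    "planted_fail": self.planted_fail,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            planted_pass=tuple(data["planted_pass"]),
            planted_fail={k: int(v) for k, v in data["planted_fail"].items()},
            seed=int(data["seed"]),
        )


@dataclass(frozen=True)
class CohortMargins:
    """How far planted variants sit from each threshold.

    Passers clear every criterion by these margins (depth at
    ``depth_factor`` x threshold, VAF at threshold + ``vaf_margin``, FPKM
    at ``fpkm_factor`` x threshold, primary MT IC50 at ``ic50_fraction``
    of the cutoff, WT IC50 at ``wt_fold`` x MT); decoys violate their one
    criterion equally decisively.  ``weak_ic50`` is the oracle's answer
    for every peptide that was not deliberately planted.
    """

    depth_factor: float = 2.0
    vaf_margin: float = 0.2
    fpkm_factor: float = 10.0
    ic50_fraction: float = 0.5
    wt_fold: float = 4.0
    weak_ic50: float = 5000.0


@dataclass(frozen=True)
class HotRegister:
    """The deliberately strong MT/WT register planted for one variant."""

    mt_seq: str
    wt_seq: str
    allele: str


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the ground truth."""

    variants: list[SomaticVariant]
    expression: dict[str, float]
    source: DictSource
    truth: CohortTruth
    proteome: dict[str, str]
    alleles: tuple[str, ...]
    panel: PredictorPanel
    hot: dict[str, HotRegister] = field(default_factory=dict)


def _pick_snv_codon(rng: np.random.Generator, wt_aa: str) -> tuple[str, str, int, str]:
    """Random (codon_ref, codon_alt, changed index, mt_aa) single-base edit.

    The edit always yields a different, non-stop amino acid; every
    standard amino acid admits at least one such edit.
    """
    codons = _codons_for(wt_aa)
    for j in rng.permutation(len(codons)):
        codon = codons[int(j)]
        edits = []
        for i in range(3):
            for b in NUCLEOTIDES:
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                aa = translate_codon(alt)
                if aa not in ("*", wt_aa):
                    edits.append((codon, alt, i, aa))
        if edits:
            return edits[int(rng.integers(len(edits)))]
    raise RuntimeError(f"no missense single-base edit exists for {wt_aa}")


def simulate_cohort(
    proteome: dict[str, str],
    n_pass: int,
    n_fail_per_criterion: int,
    thresholds: FilterThresholds = FilterThresholds(),
    margins: CohortMargins = CohortMargins(),
    seed: int = 0,
    alleles: tuple[str, ...] = DEFAULT_ALLELES,
    panel: PredictorPanel = PredictorPanel(),
) -> SimulatedCohort:
    """Plant a cohort of passing variants and single-criterion decoys.

    One variant per protein; each variant gets one deliberately strong
    8-12-mer register (the *hot* register) on one patient allele, and the
    binding oracle answers ``margins.weak_ic50`` for everything else, so
    the hot register is always the variant's best.  Decoys cycle through
    criteria 1-6, ``n_fail_per_criterion`` each.
    """
    rng = substream(seed, "cohort")
    n_total = n_pass + 6 * n_fail_per_criterion
    usable = [
        g for g, s in proteome.items() if len(s) >= 2 * MIN_PROTEIN_LENGTH - 1
    ]
    if len(usable) < n_total:
        raise ValueError(
            f"proteome has {len(usable)} usable proteins but "
            f"{n_total} variants were requested"
        )
    genes = list(rng.choice(usable, size=n_total, replace=False))

    t, m = thresholds, margins
    plan: list[int] = [0] * n_pass  # 0 = passer; 1..6 = violated criterion
    for criterion in range(1, 7):
        plan.extend([criterion] * n_fail_per_criterion)

    variants: list[SomaticVariant] = []
    expression: dict[str, float] = {}
    table: dict[tuple[str, str, str], float] = {}
    hot: dict[str, HotRegister] = {}
    planted_pass: list[str] = []
    planted_fail: dict[str, int] = {}

    def put(peptide: str, allele: str, predictor: str, ic50: float) -> None:
        key = (peptide, allele, predictor)
        if key in table and table[key] != ic50:
            raise RuntimeError(f"oracle collision on {key}")
        table[key] = ic50

    for idx, (gene, criterion) in enumerate(zip(genes, plan)):
        vid = f"var{idx + 1:04d}"
        protein = proteome[gene]
        L = len(protein)
        # interior position: every 8-12-mer register around it exists
        pos = int(rng.integers(MIN_PROTEIN_LENGTH, L - MIN_PROTEIN_LENGTH + 2))
        wt_aa = protein[pos - 1]
        codon_ref, codon_alt, _, mt_aa = _pick_snv_codon(rng, wt_aa)

        depth = int(round(t.min_depth * m.depth_factor))
        vaf = min(1.0, t.min_vaf + m.vaf_margin)
        if criterion == 1:
            depth = max(1, t.min_depth // 2)
        if criterion == 2:
            vaf = max(0.05, t.min_vaf - m.vaf_margin)
        alt = int(round(vaf * depth))

        fpkm = t.min_fpkm * (0.1 if criterion == 3 else m.fpkm_factor)
        expression[gene] = fpkm

        variant = SomaticVariant(
            id=vid,
            gene=gene,
            transcript=f"{gene}-201",
            codon_ref=codon_ref,
            codon_alt=codon_alt,
            protein_pos=pos,
            dna_depth=depth,
            dna_alt=alt,
            rna_depth=depth,
            rna_alt=alt,
        )
        variants.append(variant)

        # hot register: one random 8-12-mer window covering the substitution
        pairs = enumerate_windows(protein, variant.substitution)
        pair = pairs[int(rng.integers(len(pairs)))]
        allele = alleles[int(rng.integers(len(alleles)))]
        hot[vid] = HotRegister(mt_seq=pair.mt_seq, wt_seq=pair.wt_seq, allele=allele)

        if criterion == 4:
            mt_ic50 = t.max_ic50_primary * float(rng.uniform(2.0, 4.0))
        elif criterion == 6:
            mt_ic50 = float(rng.uniform(100.0, t.max_ic50_primary * 0.8))
        else:
            mt_ic50 = float(rng.uniform(10.0, t.max_ic50_primary * m.ic50_fraction))
        if criterion == 6:
            wt_ic50 = mt_ic50 * 0.5  # fold change decisively below 1
        else:
            wt_ic50 = mt_ic50 * float(rng.uniform(m.wt_fold, 50.0))
        put(pair.mt_seq, allele, panel.primary, round(mt_ic50, 3))
        put(pair.wt_seq, allele, panel.primary, round(wt_ic50, 3))

        n_cons = len(panel.consensus)
        n_low = (
            t.consensus_min_support - 1 if criterion == 5 else n_cons - 1
        )
        low_slots = set(rng.choice(n_cons, size=n_low, replace=False).tolist())
        for slot, name in enumerate(panel.consensus):
            if slot in low_slots:
                value = float(rng.uniform(50.0, t.consensus_threshold * 0.5))
            else:
                value = m.weak_ic50
            put(pair.mt_seq, allele, name, round(value, 3))

        if criterion == 0:
            planted_pass.append(vid)
        else:
            planted_fail[vid] = criterion

    truth = CohortTruth(
        planted_pass=tuple(planted_pass), planted_fail=planted_fail, seed=seed
    )
    source = DictSource(table, default=m.weak_ic50)
    return SimulatedCohort(
        variants=variants,
        expression=expression,
        source=source,
        truth=truth,
        proteome=proteome,
        alleles=tuple(alleles),
        panel=panel,
        hot=hot,
    )


def simulate_energy_series(
    n_frames: int,
    mean_dg: float = -30.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    total_ns: float = 100.0,
):
    """Per-frame MM/GBSA components with a planted mean binding energy.

    Timestamps span 0 to ``total_ns`` uniformly; the receptor and ligand
    components are constant and the complex component carries Gaussian
    noise, so per-frame dG = complex - receptor - ligand has expectation
    ``mean_dg`` (exactly ``mean_dg`` everywhere when ``noise_sd`` is 0).
    """
    from neoprior.structure import EnergySeries

    if n_frames < 2:
        raise ValueError("need at least two frames")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = substream(seed, "energy")
    time_ns = np.linspace(0.0, total_ns, n_frames)
    g_receptor = np.full(n_frames, -1500.0)
    g_ligand = np.full(n_frames, -200.0)
    noise = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    g_complex = g_receptor + g_ligand + mean_dg + noise
    return EnergySeries(
        time_ns=time_ns,
        g_complex=g_complex,
        g_receptor=g_receptor,
        g_ligand=g_ligand,
    )


def simulate_structure(
    n_peptide_res: int = 9,
    n_receptor_res: int = 30,
    seed: int = 0,
    with_hydrogens: bool = True,
):
    """Toy peptide-receptor complex frame (chains ``P`` and ``A``).

    The peptide lies extended along x with ~3.8 A Calpha spacing — the
    pose a class I groove enforces — and the receptor chain scatters
    backbone atoms in a slab a few angstroms above it, so contacts and
    hydrogen bonds exist without any force field.  Intended for
    exercising the structural metrics, not for biology.
    """
    from biotite.structure import AtomArray

    rng = substream(seed, "structure")
    names = ["N", "H", "CA", "C", "O"] if with_hydrogens else ["N", "CA", "C", "O"]
    elements = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O"}
    offsets = {
        "N": np.array([-1.2, 0.8, 0.0]),
        "H": np.array([-1.2, 1.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.8, 0.0]),
        "O": np.array([1.2, 2.0, 0.0]),
    }
    rows: list[tuple[str, int, str, str, np.ndarray]] = []
    for i in range(n_peptide_res):
        ca = np.array([3.8 * i, 0.0, 0.0])
        for name in names:
            rows.append(("P", i + 1, "ALA", name, ca + offsets[name]))
    x_hi = 3.8 * (n_peptide_res - 1) + 5.0
    for i in range(n_receptor_res):
        ca = np.array(
            [
                rng.uniform(-5.0, x_hi),
                rng.uniform(2.5, 9.0),
                rng.uniform(-4.0, 4.0),
            ]
        )
        for name in names:
            rows.append(("A", i + 1, "GLY", name, ca + 0.6 * offsets[name]))

    atoms = AtomArray(len(rows))
    atoms.coord = np.array([r[4] for r in rows])
    atoms.chain_id = np.array([r[0] for r in rows])
    atoms.res_id = np.array([r[1] for r in rows])
    atoms.res_name = np.array([r[2] for r in rows])
    atoms.atom_name = np.array([r[3] for r in rows])
    atoms.element = np.array([elements[r[3]] for r in rows])
    return atoms


def simulate_lysis_plate(
    n_donors: int = 3,
    true_lysis: dict[str, float] | None = None,
    et_ratios: tuple[int, ...] = (20, 40),
    n_replicates: int = 3,
    od_target: float = 1.0,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-form MTS plate: OD490 readings with planted lysis fractions.

    Conditions default to a strongly killing mutant peptide (MT, 40%
    lysis at 20:1), its wildtype counterpart (WT, 10%) and unpulsed
    T cells (UP, 5%); effect scales linearly with the E:T ratio (capped
    at 95%).  ``TA`` rows carry the target-alone OD.
    """
    if true_lysis is None:
        true_lysis = {"MT": 0.40, "WT": 0.10, "UP": 0.05}
    rng = substream(seed, "lysis-plate")
    rows = []
    for d in range(1, n_donors + 1):
        donor = f"donor{d}"
        for rep in range(1, n_replicates + 1):
            od = max(0.01, od_target + rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "donor": donor,
                    "condition": "TA",
                    "et_ratio": "NA",
                    "replicate": rep,
                    "value": round(od, 4),
                }
            )
        for condition, lysis20 in true_lysis.items():
            for ratio in et_ratios:
                lysis = min(0.95, lysis20 * ratio / et_ratios[0])
                for rep in range(1, n_replicates + 1):
                    od = od_target * (1.0 - lysis) + rng.normal(0.0, noise_sd)
                    rows.append(
                        {
                            "donor": donor,
                            "condition": condition,
                            "et_ratio": f"{ratio}:1",
                            "replicate": rep,
                            "value": round(max(0.01, od), 4),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["donor", "condition", "et_ratio", "replicate", "value"]
    )


# ---------------------------------------------------------------------------
# on-disk round trip

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write a cohort as FASTA + VCF + TSVs + JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in cohort.proteome.items()
    ]
    SeqIO.write(records, str(outdir / "proteome.fasta"), "fasta")

    _write_vcf(cohort.variants, outdir / "variants.vcf")

    pd.DataFrame(
        sorted(cohort.expression.items()), columns=["gene_id", "fpkm"]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)

    from neoprior.binding import write_prediction_cache

    write_prediction_cache(cohort.source.table, str(outdir / "predictions.tsv"))
    (outdir / "alleles.txt").write_text("\n".join(cohort.alleles) + "\n")
    cohort.truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(
        json.dumps(
            {
                "alleles": list(cohort.alleles),
                "panel": {
                    "primary": cohort.panel.primary,
                    "consensus": list(cohort.panel.consensus),
                },
                "default_ic50": cohort.source.default,
            },
            indent=2,
        )
    )


def _write_vcf(variants: list[SomaticVariant], path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=536870912>")
    header.add_line(
        '##INFO=<ID=PSUB,Number=1,Type=String,Description="Protein substitution: '
        'gene|transcript|notation|codon_ref|codon_alt">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_sample("TUMOR_DNA")
    header.add_sample("TUMOR_RNA")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, v in enumerate(variants):
            diff = [
                j for j in range(3) if v.codon_ref[j] != v.codon_alt[j]
            ][0]
            rec = vcf.new_record(
                contig="1",
                start=1000 * (i + 1),
                alleles=(v.codon_ref[diff], v.codon_alt[diff]),
                id=v.id,
            )
            rec.info["PSUB"] = (
                f"{v.gene}|{v.transcript}|{v.substitution.notation}"
                f"|{v.codon_ref}|{v.codon_alt}"
            )
            for sample, depth, alt in (
                ("TUMOR_DNA", v.dna_depth, v.dna_alt),
                ("TUMOR_RNA", v.rna_depth, v.rna_alt),
            ):
                rec.samples[sample]["DP"] = depth
                rec.samples[sample]["AD"] = (depth - alt, alt)
            vcf.write(rec)


def load_cohort_inputs(outdir: str | Path):
    """Load the files written by :func:`write_cohort` for a pipeline run.

    Returns ``(variants, expression, proteome, alleles, panel, source,
    truth)``.
    """
    from neoprior.binding import read_prediction_cache
    from neoprior.variants import parse_variants

    outdir = Path(outdir)
    proteome = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(outdir / "proteome.fasta"), "fasta")
    }
    variants = parse_variants(str(outdir / "variants.vcf")).variants
    expression = read_expression(str(outdir / "expression.tsv"))
    config = json.loads((outdir / "config.json").read_text())
    panel = PredictorPanel(
        primary=config["panel"]["primary"],
        consensus=tuple(config["panel"]["consensus"]),
    )
    source = DictSource(
        read_prediction_cache(str(outdir / "predictions.tsv")),
        default=config.get("default_ic50"),
    )
    truth = CohortTruth.from_json(outdir / "truth.json")
    return (
        variants,
        expression,
        proteome,
        tuple(config["alleles"]),
        panel,
        source,
        truth,
    )
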