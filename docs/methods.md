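# Methods

## Scope and model

`neoprior` prioritizes annotated somatic missense variants into candidate
neoantigens and provides the validation-side computations (structural
metrics on peptide–HLA models, assay summary statistics). It deliberately
begins *after* read alignment, somatic calling and effect annotation: its
variant inputs already carry the reference/alternate codon, the protein
substitution and per-sample depths. Binding predictors are likewise
treated as external oracles behind a uniform interface; the package never
re-implements or retrains them.

## Filtering and ranking

A candidate is one variant's best peptide register: among all 8–12-mer
windows covering the substituted residue, scored on every patient HLA
class I allele with the primary predictor, the (register, allele) pair
minimizing the MT IC50. All registers are enumerated (the pVAC-Seq
convention), not one per length. Ties among alleles resolve to the
lexicographically smaller allele name; ties among registers to the
enumeration order (shorter windows, then earlier starts). Deterministic
tie-breaking keeps golden tests and reruns stable.

The six criteria are evaluated independently — no short-circuiting — so a
report always shows every failure reason. Boundary semantics follow the
printed inequalities: depth and VAF are inclusive (≥), the two IC50
criteria inclusive (≤), FPKM and fold change strict (>). A VAF of exactly
0.40 passes; an FPKM of exactly 1 fails. The depth and VAF cutoffs apply
to both the tumor DNA and tumor RNA samples; `FilterThresholds(require_rna=False)`
relaxes them to DNA only, since the joint reading of "DNA/RNA" is the
stricter of the two plausible interpretations. VAF is computed as
alternate reads over total depth (the AD alt count over DP), matching the
depth criterion's denominator at multi-allelic sites. A missing expression
record fails criterion 3 with an explicit "missing" flag rather than
raising, so one unannotated gene cannot abort a cohort run.

Ranking is by descending WT/MT fold change with ties broken by lower MT
IC50 and then lexicographic MT peptide. Report tables round IC50s to three
decimals and fold changes to two, using round-half-up; published tables of
this kind mix rounding and truncation, so comparisons against printed
fold changes should allow ±0.02.

Which algorithm's IC50 feeds criterion 4 and the fold change is a genuine
open choice; the package uses the primary predictor (NetMHC by name in the
default panel) because criterion 4 names it, and exposes the panel so a
median-across-panel variant can be swapped in. The consensus vote
(criterion 5) is evaluated on the best register/allele only.

## The toy predictor

Offline mode replaces all six external predictors with
`toy_predict(peptide, allele, w)`: the mean over peptide positions of a
weight w(allele, position, aa) ∈ [0, 1] acts as a binding score s, and
IC50 = 50000^(1−s) nM. The map is strictly decreasing in s and spans
[1, 50000] nM, the working range of real predictors. Default weights are
BLAKE2 hashes of (predictor, allele, position, aa), giving each predictor
name its own deterministic, process-independent weight table; tests can
inject explicit weight functions. The toy predictor is plumbing with
realistic ranges, not a binding model.

## Synthetic cohorts and what they show

`simulate_cohort` plants two classes of variants on a uniform-composition
random proteome (the simplest exchangeable null; no real proteome model is
implied):

* **passers** clear every criterion with margin — depth at 2× the cutoff,
  VAF at cutoff + 0.2, FPKM at 10× the cutoff, primary MT IC50 at or below
  half the cutoff, WT IC50 at ≥ 4× MT, and 4 of 5 consensus predictors
  below cutoff;
* **decoys** violate exactly one assigned criterion equally decisively
  (half the depth cutoff; VAF at cutoff − 0.2; FPKM at a tenth of the
  cutoff; primary IC50 at 2–4× the cutoff; only 2 of 5 consensus
  predictors low; WT at half the MT IC50) while clearing the other five
  with the passers' margins.

Each variant gets one deliberately strong ("hot") register on one patient
allele; the binding oracle answers a weak 5000 nM for every other triple,
so the hot register is provably the argmin. Margins are parameters
(`CohortMargins`), so boundary behavior is tested separately from
recovery. The central property — the pipeline returns exactly the planted
passers and each decoy fails only its criterion — holds by construction
for any seed; passing it demonstrates the filter logic is wired correctly,
*not* that the pipeline would reach any particular yield on real tumors.
Real data adds everything the generator omits: sequencing noise, allele
bias, multi-allelic sites, annotation errors, correlated predictor errors
and real binding motifs. Cohort sizes are free parameters (the tests use
20 passers + 5 decoys per criterion; the small fixture 5 + 1) chosen to
exercise every code path in seconds.

Randomness uses one master seed with per-component substreams keyed by a
CRC-32 of the component name, so adding a generator never perturbs the
output of another.

## Structural metrics

* **Anchor distance**: Cα–Cα distance between peptide positions 2 and 9
  (positions count residues in chain order, 1-based). The peptide chain is
  auto-detected as the shortest chain of 8–12 residues unless named.
* **Contacts**: inter-chain atom pairs within 4.5 Å (inclusive), heavy
  atoms only by default. 4.5 Å heavy-atom is the community convention; the
  cutoff is a parameter.
* **Hydrogen bonds**: donor N/O with a covalent hydrogen (≤ 1.3 Å, same
  chain), acceptor N/O, D···A ≤ 3.5 Å and D–H···A angle ≥ 120°; each
  donor–acceptor pair counts once. Structures stripped of hydrogens raise
  with a pointer to the distance-only fallback (polar–polar pairs within
  the distance cutoff), which over-counts but needs no protons.
* **MM/GBSA window**: per-frame ΔG = G_complex − G_receptor − G_ligand;
  mean, sample SD (ddof = 1) and frame count over a closed time window,
  default [80, 100] ns — "from 80 to 100" read inclusively at both ends.
  The package evaluates no force field; energy components come from an
  upstream MD/MM-GBSA run as a TSV. Published ΔG values therefore cannot
  be recomputed here and are not targets; the synthetic series only
  validates the windowing arithmetic.

All metrics are invariant under rigid rotation and translation, and
contact counts are monotone in the cutoff (both property-tested).

## Assay statistics

`percent_lysis` returns values outside [0, 100] as-is with a warning —
clipping would hide wells where the co-culture outgrew the target. SEM is
sample SD / √n, undefined (NaN, flagged) at n = 1. `compare_groups` uses a
pooled-variance two-sided t test for two groups and one-way ANOVA with
Tukey HSD for more; the Tukey–Kramer form handles unbalanced designs, and
with two groups the ANOVA F equals t² exactly (tested to 1e-9). α = 0.05
throughout. The module is unit-agnostic: OD, spot counts and percentage
frequencies all pass through the same summaries.

## Numerical and interface choices

* IC50s are nM everywhere; fold change is the dimensionless WT/MT ratio.
* Protein positions, peptide offsets and VCF coordinates are 1-based.
* The VCF dialect carries `AD`/`DP` per sample (samples `TUMOR_DNA`,
  `TUMOR_RNA`) and a pipe-separated protein annotation
  (`gene|transcript|E274K|GAG|AAG`) under a configurable INFO key. When
  the annotation names a substitution, the codon translation must agree;
  disagreement is a hard error, because a silently wrong annotation would
  corrupt every downstream peptide.
* Prediction caches, expression tables, peptide tables and plates are
  plain TSV; structures are PDB; truth/config are JSON.

## Known limitations

Single-residue substitutions only — no indels, frameshifts, fusions or
splice-derived neoepitopes, and no clonality, proteasomal-processing or
TAP modeling (RNA VAF proxies mutant-allele expression). The toy predictor
carries no binding motif information, so synthetic IC50s are exchangeable
across peptides. H-bond detection assumes explicit or inferable protons
and standard element labels. Percentile-rank scoring and HLA class II are
out of scope.
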