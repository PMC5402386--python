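# Methods

This note documents the models implemented in `resmutscan`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Mutation-likelihood model

A mutational signature is a probability distribution over the 96
pyrimidine-context single-base substitutions (`A[C>T]G` etc.). Catalogs
are read in COSMIC layout (context rows × signature columns); each
column must sum to 1 within 1e-3 or parsing fails naming the signature.
Exposure profiles give per-cancer-type signature weights; they are used
as supplied (not renormalised) with a warning if their sum exceeds 1.05,
so likelihoods are comparable only under a consistent weighting
convention.

**Context extension.** Likelihood evaluation needs all 192 contexts
because flanks are read on the coding strand. For unbiased signatures the
purine-context probability equals that of its reverse-complement
pyrimidine context. Signatures with strong transcriptional strand bias
(default set {4, 7, 11, 22, 24, 29}, configurable) have purine contexts
set to zero, with no renormalisation — the pyrimidine half still sums
to 1. The zeroing rule is applied uniformly to the whole biased set; a
different per-signature rule can be supplied by pre-extending signatures
before likelihood evaluation.

**Missense enumeration.** For each protein position, all nine single-base
substitutions of the codon are translated through the standard codon
table; synonymous and stop-gained changes are discarded and substitutions
producing the same amino acid are grouped into one mutation with its
causal SNV set. Codons at CDS edges lack a flank; those SNVs carry an `N`
flank, contribute zero likelihood, and trigger a warning.

**Ranking and enrichment.** Landscapes sort by likelihood descending with
ties broken by (protein position asc, alt amino acid asc), so the order
is permutation-invariant. Each entry carries the dominant substitution
class — the pyrimidine-normalised class of the causal SNV contributing
the most likelihood. Class enrichment among the top *i* entries uses the
classical 2×2 odds ratio `[a/(i−a)] / [b/((N−i)−b)]`; when any cell is
zero a Haldane–Anscombe +0.5 is added to all four cells (keeps top-rank
scans finite); a class absent from the whole landscape returns a result
flagged undefined rather than raising.

## Structures and mutant models

PDB files are parsed with gemmi. Alternate locations keep blank/'A'
altlocs, highest occupancy on duplicated names. Waters are retained
separately for water-bridge detection. The binding site is every protein
residue with ≥1 heavy atom within the cutoff (default 9.5 Å) of any
ligand heavy atom — heavy atoms only, because hydrogens are absent from
most crystal depositions and their presence would make site membership
deposition-dependent.

Mutant models come from a pluggable backend. The default `graft` backend
keeps the backbone fixed and replaces the side chain with an idealised
stick: CB at the tetrahedral position implied by N/CA/C, further heavy
atoms stepping outward along the CA→CB direction with a small alternating
perpendicular offset. It never moves any atom of any other residue, which
makes WT/MT feature deltas attributable to the mutation alone and keeps
model building dependency-free and deterministic. An `external` backend
shells out to a user-supplied modelling command for engines of the
comparative-modelling class. Structure↔CDS mapping uses a user-supplied
residue-number offset; residues whose mapped codon disagrees with the
structure are skipped and reported, never fatal.

Grafted side chains are sticks, not rotamer-quality geometry: aromatic
rings of grafted residues are non-planar, so π-stacking involving a
*mutant* aromatic side chain is generally not detected. Fingerprint tests
therefore use explicitly constructed ring geometry.

## Feature extraction

All geometric thresholds are module constants: hydrogen bond ≤3.2 Å
(N/O heavy-atom pairs; carbon contacts never qualify), salt bridge
≤4.0 Å (ASP/GLU carboxylate O vs LYS/ARG cationic N), disulfide SG–SG in
[1.8, 2.2] Å, halogen bond ≤4.0 Å with C–X⋯A angle ≥140°, π-stacking
centroid ≤5.5 Å with planes parallel within 30° or perpendicular within
60–90°, π-cation ≤6.0 Å, water bridge both polar distances ≤3.6 Å,
hydrophobic C–C ≤4.0 Å between apolar carbons.

Surface areas use an in-house Shrake–Rupley integrator: 960
Fibonacci-sphere points per atom, probe 1.4 Å, van der Waals radii by
element, ligand and waters excluded from the protein surface calculation.
RSA divides residue SASA by the Tien (2013) theoretical maxima. Because
the point set is fixed in the laboratory frame, SASA is invariant under
rigid motion only to within the sampling resolution (≲2 % relative);
every other feature is exactly invariant.

Half-sphere exposure counts CA neighbours within 13 Å split by the
CA→CB axis (pseudo-CB from backbone geometry for glycine). Environment
shells are annular — (0,1], (1,2], …, (5,6] Å by nearest heavy-atom
distance — rather than cumulative, to avoid redundant encodings; the
±5-residue sequence window flags amino-acid presence and records
truncation at chain ends. Secondary structure uses a Ramachandran
torsion-region rule (helix: φ∈(−120,−30), ψ∈(−80,−5); strand: φ<−40 or
φ>160 with ψ>90 or ψ<−160; otherwise coil), chosen over a backbone
H-bond-pattern assigner because it is exact on ideal fixture geometry and
well-defined on graft-built mutants; the assigner is pluggable. WT/MT
superposition uses Kabsch least squares over shared heavy atoms matched
by (chain, resnum, atom name); the refined RMSD iteratively rejects pairs
deviating more than two standard deviations above the mean until
convergence.

The stability feature is an explicit surrogate, not an external
predictor: `ddG = burial · (0.6·ΔKD/9.0 − 1.8·|ΔV|/167.7)` kcal/mol,
where burial = 1 − RSA(WT), ΔKD is the Kyte–Doolittle hydropathy change
(alt − ref, scale span 9.0) and |ΔV| the absolute residue-volume change
(max span 167.7 Å³). Burying added hydrophobicity stabilises; volume
mismatch destabilises. The sign gives the STABLE/UNSTABLE category and a
failed computation yields UNKNOWN, preserved as a distinct category.
Conservation is the mean pairwise BLOSUM62 score of the non-gap alignment
column (self-score at depth 1, undefined on all-gap columns); alignment
construction is the caller's responsibility.

Ligand typing is connectivity-based: bonds inferred from covalent radii
(×1.25), aromatic rings as planar (SVD residual ≤0.15 Å) 5/6-cycles of
C/N/O/S, charged groups by pattern (phosphate, carboxylate, guanidine,
tertiary/quaternary amine).

**Schemas.** The registry is the source of truth for feature order and
length. `aa-v1` (234 features) adds half-sphere exposure, protein
salt-bridge counts and disulfide presence; `lig-v1` (234) drops those and
adds the five interaction-fingerprint families. The wild-type affinity is
encoded as log10(nM) plus a measure-type code (Ki/Kd/IC50). Features that
cannot be computed take a 0 sentinel with a parallel `*_known` indicator
so tree models can split on missingness; vectors never contain NaN.

## Classifier and resistance score

Fold changes are drop-oriented (MT/WT value of Kd, Ki or IC50; >1 is
weaker binding). Bands: SRES ≥5; RES [1.2, 5); NEU the open interval
(1/1.2, 1.2); ISEN ≤1/1.2 — the 1.2 boundaries are assigned outward
because the resistance and sensitivity bands are closed at 1.2 while the
neutral band is open. Training sets drop multi-mutant rows, label from
the fold change, and down-sample the over-represented SRES/RES classes
uniformly at random (seeded) to a cap of 180 while NEU and ISEN keep
their natural sizes; every removal is logged in the construction report.

The forest uses 1000 trees, 20 candidate features per split (clipped to
the feature count), unlimited depth, fixed seed. Evaluation is stratified
10-fold cross-validation; per-class one-vs-rest AUC is computed from
pooled out-of-fold probabilities, mean AUC is the unweighted (macro)
class mean, Cohen's κ and the confusion matrix come from pooled
out-of-fold hard predictions. Classes smaller than k reduce k with a
warning rather than failing.

Predictions are tree-vote fractions summing to 1; exact argmax ties break
by the fixed order SRES > RES > NEU > ISEN and are flagged. The
resistance score weights class confidences by the per-class CV
*precision* (the per-class quantity quoted alongside the score's
definition; recall weighting is available via configuration), giving
RS ∈ [−max P, +max P], linear in each confidence. NRS min–max rescales RS
within one experiment (one landscape scoring, or one whole sensitivity
map); an all-equal batch maps to zeros with a degeneracy flag. A
two-feature affinity-only baseline (externally predicted WT/MT
affinities, same forest and CV protocol) is provided for comparison and
reports per-instance WT/MT predicted-affinity fold changes and how many
exceed 1.2 in either direction.

## Screening

Candidate records require a measured affinity; records flagged
`docked` (extended-set) must additionally satisfy IC50 ≤ 100 nM, while
co-crystal and manual records are exempt. Poses are consumed, never
generated; the record keeps a hook naming the docking engine. The map
normalises NRS over all scored cells (one experiment per map), so adding
a compound rescales but never reorders existing cells. Targetability
thresholds (NRS ≤0.3 / ≥0.7 for ≥80 % of a column) are package defaults
exposed in the function signature — the grouping is qualitative in
origin; columns with under 50 % scored cells are undetermined.

## Synthetic data

The generator produces every input format the pipeline consumes, all
seeded and byte-reproducible. Signature catalogs are gamma-normalised
draws rounded so each column sums to 1 at the printed precision; one
signature id sits in the strand-biased set to exercise the zeroing path.
Toy complexes are extended chains with idealised backbones, grafted side
chains and a scripted ligand; the expected binding site is recorded from
an independent brute-force distance computation at generation time. A
boundary set places atom pairs exactly at 9.4/9.6, 3.19/3.21, 3.9/4.1 and
2.0/2.3 Å so every detector's flip is testable to ±0.01 Å.

Training tables plant the class signal *physically*: the mutant ligand
pose is rigidly translated away from (or towards) the protein by a
class-dependent offset (SRES +2.0, RES +1.0, NEU 0, ISEN −0.7 Å) scaled
by `signal_strength`, plus Gaussian noise (σ = 0.15 Å on the offset,
0.05 Å atom jitter). This perturbs the ligand-distance and hydrogen-bond
features the classifier consumes, so feature extraction — not just the
forest — is on the test path. Fold changes are drawn strictly inside each
class's affinity band, so relabelling recovers the intended classes
exactly; wild-type affinities are class-independent to avoid leakage.
Double-mutant decoy rows (exact count configurable) exercise the
single-mutation filter.

What this does *not* emulate: realistic kinase folds, rotamer-quality
side chains, realistic COSMIC signature shapes, correlated real-data
features, covalent inhibitors, or docking-pose error. Passing tests
demonstrate the correctness of the statistics, the geometry detectors and
the learning machinery under controlled conditions — not real-data
accuracy, which depends on external structure and signature resources.

## Problem sizes and determinism

The test suite and the acceptance script use a balanced planted design of
180/180/70/180 instances on a 10-residue template complex — large enough
for stable stratified 10-fold CV of the NEU class, small enough that the
full pipeline (structure generation, feature extraction, two 1000-tree
cross-validations) completes in a few minutes on one core. All
randomness flows from explicit seeds; re-running any generator or
training step with the same seed reproduces outputs exactly
(byte-identical files, identical forests).

## Known limitations

- Likelihood values depend on the supplied exposure weighting convention;
  absolute numbers are not comparable across differently normalised
  exposure sources.
- Only the uniform purine-zeroing rule is built in for strand-biased
  signatures; finer per-signature bias rules must be supplied externally.
- The graft backend does not remodel backbones, loops, or rotamers, and
  grafted aromatic rings are not planar.
- The stability surrogate is a two-term physical heuristic, not a trained
  ΔΔG predictor; its value lies in giving the forest a monotone
  burial/volume/hydropathy signal with an honest UNKNOWN path.
- The model scope is single point mutations and non-covalent reversible
  inhibitors; multi-mutants, covalent binders and resistance mechanisms
  outside the binding site are out of scope.
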