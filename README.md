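# resmutscan

Prospective prediction of drug-resistance point mutations in the binding
sites of small-molecule cancer-therapy targets.

Acquired resistance to targeted therapies — e.g. the EGFR gatekeeper
mutation T790M under gefitinib treatment, or ERK2 P58L/S/T under VTX-11e —
is frequently driven by single point mutations in the drug binding site.
`resmutscan` is for computational biologists and structure-based drug
designers who want to rank, *before they are observed in the clinic*, which
binding-site mutations are both likely to arise in a given cancer type and
likely to disrupt inhibitor binding, and which alternative compounds would
remain active against them.

## The model

**Mutation likelihood.** Each trinucleotide mutational signature *s*
assigns a probability *P<sub>s</sub>(snv)* to every context substitution
(e.g. `A[C>T]G`); a cancer type *c* weights signatures by exposures
*W<sub>s</sub>*. Because several nucleotide substitutions can produce the
same amino-acid change, the likelihood of an amino-acid mutation *m* is

&nbsp;&nbsp;&nbsp;&nbsp;*L(m) = Σ<sub>snv ∈ M(m)</sub> Σ<sub>s</sub>
W<sub>s</sub> · P<sub>s</sub>(snv)*

where *M(m)* is the set of single-nucleotide substitutions that yield *m*
through the codon table. Signature catalogs list the 96 pyrimidine
contexts; they are extended to all 192 by reverse-complement symmetry,
except for strand-biased signatures (4, 7, 11, 22, 24, 29 by default),
whose purine contexts are zeroed. Enrichment of a substitution class among
the top-*i* ranked mutations is a classical 2×2 odds ratio with
Haldane–Anscombe correction.

**Resistance phenotype.** The drug binding site is every residue with an
atom within 9.5 Å of the co-crystallised ligand. For each SNV-reachable
missense mutation a mutant model is built (backbone-preserving side-chain
graft by default; external engines pluggable) and a feature vector is
extracted: binding-site and residue surface areas (in-house Shrake–Rupley),
relative solvent accessibility, half-sphere exposure, hydrogen bonding to
the drug (≤3.2 Å), concentric-shell and sequence-window environment
encodings, secondary structure, a stability-change surrogate, BLOSUM62
conservation, WT/MT superposition RMSD, CA–ligand distances,
charge/hydropathy changes, salt bridges (≤4.0 Å), disulfides
(1.8–2.2 Å), and protein–ligand interaction fingerprints (halogen bonds,
π-stacking, π-cation, water bridges, hydrophobic contacts). A random
forest (1000 trees, 20 candidate features per split, unlimited depth)
assigns confidences *S<sub>x</sub>* to four phenotypes defined by the
measured affinity fold change: SRES (≥5-fold drop), RES (1.2–5-fold drop),
NEU (within ±1.2-fold), ISEN (≥1.2-fold gain). The Resistance Score weighs
them by the per-class cross-validation precisions *P<sub>x</sub>*:

&nbsp;&nbsp;&nbsp;&nbsp;*RS = S<sub>SRES</sub>P<sub>SRES</sub> +
S<sub>RES</sub>P<sub>RES</sub> − S<sub>NEU</sub>P<sub>NEU</sub> −
S<sub>ISEN</sub>P<sub>ISEN</sub>*

and the normalised RS (NRS) min–max rescales RS within one experiment.
Screening every candidate compound against every mutation yields a
sensitivity map whose columns classify mutations as hardly/easily
targetable or targetable.

## Worked example

Everything below runs on synthetic inputs generated by the package itself:

```sh
resmutscan simulate --preset full --seed 7 --out demo
resmutscan likelihood \
    --catalog demo/signatures/signatures.tsv \
    --exposure demo/signatures/exposure_alpha.tsv \
    --cds demo/complex/cds.fasta --positions 2-11 \
    --out demo/landscape.tsv
resmutscan site --pdb demo/complex/complex_wt.pdb --ligand LIG \
    --out demo/site.tsv
resmutscan train --table demo/training/training.csv --schema aa-v1 \
    --seed 17 --out demo/model.joblib
```

which prints

```
wrote 61 ranked mutations to demo/landscape.tsv
6 residues within 9.5 A of LIG
CV mean AUC 0.996  kappa 0.972
saved model (aa-v1, seed 17) to demo/model.joblib
```

The landscape TSV ranks each reachable amino-acid change by its
exposure-weighted likelihood and reports its dominant substitution class;
the site table lists the residues within the 9.5 Å shell; the training
report shows the cross-validated performance of the four-class classifier
on the demo table, whose class signal is planted geometrically (the mutant
ligand pose shifts by a class-dependent offset), hence the near-perfect
AUC at full signal strength.

In Python, the resistance-score arithmetic on a prediction with
confidences (0.4, 0.3, 0.1, 0.2) and class precisions
(0.63, 0.50, 0.48, 0.59) for (SRES, RES, NEU, ISEN):

```python
>>> from resmutscan import ClassScores, ClassPrecisions, resistance_score
>>> s = ClassScores({"SRES": .4, "RES": .3, "NEU": .1, "ISEN": .2})
>>> p = ClassPrecisions({"SRES": .63, "RES": .50, "NEU": .48, "ISEN": .59})
>>> resistance_score(s, p)
0.236
```

## Layout

- `resmutscan.sigcontext` — signature catalogs, context extension, missense
  enumeration, likelihoods, ranked landscapes, enrichment odds ratios
- `resmutscan.structmut` — complex loading, binding sites, mutant models,
  per-residue score export to B-factors
- `resmutscan.featex` / `resmutscan.schema` — feature families and the
  aa-v1 / lig-v1 schema registry
- `resmutscan.respred` — phenotype labelling, training, cross-validation,
  RS/NRS
- `resmutscan.screen` — candidate curation, sensitivity maps, targetability
- `resmutscan.fixtures` — seeded synthetic inputs for the whole pipeline

See `docs/methods.md` for modelling details, parameter choices and
limitations.
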