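"""Trinucleotide-signature mutation likelihoods for drug-target residues.

A mutational signature assigns a probability to each of the 96
pyrimidine-context single-base substitutions (e.g. ``A[C>T]G``).  For a
given cancer type, signatures act with different contributions (exposures
``W``).  The likelihood of an amino-acid mutation is the exposure-weighted
sum of the context probabilities of every single-nucleotide substitution
that produces it:

    L(m) = sum_{snv in M(m)} sum_{s in signatures} W_s * P_s(snv)

Signature catalogs list only the 96 pyrimidine-reference contexts; before
likelihood evaluation each signature is extended to all 192 contexts.  For
signatures without transcriptional strand bias the purine-context
probability equals that of its reverse-complement pyrimidine context; for
strand-biased signatures (COSMIC 4, 7, 11, 22, 24 and 29 by default) the
purine contexts are set to zero.

Enrichment of a substitution class among the most likely mutations is
quantified with a classical 2x2 odds ratio over a ranked landscape, with a
Haldane-Anscombe +0.5 correction when any cell is empty.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._aa_data import PURINES, PYRIMIDINES, revcomp

#: Signatures with documented transcriptional strand bias; their
#: purine-context probabilities are zeroed on extension.
DEFAULT_BIASED_SIGNATURES = frozenset(
    {"Signature 4", "Signature 7", "Signature 11", "Signature 22",
     "Signature 24", "Signature 29", "4", "7", "11", "22", "24", "29"}
)

_CONTEXT_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")

SUBSTITUTION_CLASSES_PYR = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class CatalogError(ValueError):
    """Malformed or non-normalised signature catalog."""


def context_key(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def parse_context(key: str) -> tuple[str, str, str, str]:
    m = _CONTEXT_RE.match(key.strip())
    if not m:
        raise CatalogError(f"malformed context string: {key!r}")
    five, ref, alt, three = m.groups()
    if ref == alt:
        raise CatalogError(f"context with identical ref/alt base: {key!r}")
    return five, ref, alt, three


def revcomp_context(key: str) -> str:
    """Reverse-complement a context key onto the opposite strand."""
    five, ref, alt, three = parse_context(key)
    return context_key(
        revcomp(three), revcomp(ref)[0], revcomp(alt)[0], revcomp(five)
    )


def collapse_to_pyrimidine(subst: str) -> str:
    """Normalise a substitution class (e.g. ``G>A``) to its pyrimidine form."""
    ref, alt = subst.split(">")
    if ref in PURINES:
        return f"{revcomp(ref)}>{revcomp(alt)}"
    return subst


@dataclass
class MutationalSignature:
    """Per-context substitution probabilities of one mutational process."""

    id: str
    probs: dict[str, float]
    strand_biased: bool = False

    @property
    def extended(self) -> bool:
        return len(self.probs) == 192

    def validate(self, tol: float = 1e-3) -> None:
        if any(p < 0 for p in self.probs.values()):
            raise CatalogError(f"signature {self.id}: negative probability")
        pyr = [p for k, p in self.probs.items()
               if parse_context(k)[1] in PYRIMIDINES]
        if len(pyr) != 96:
            raise CatalogError(
                f"signature {self.id}: expected 96 pyrimidine contexts, "
                f"found {len(pyr)}"
            )
        total = sum(pyr)
        if abs(total - 1.0) > tol:
            raise CatalogError(
                f"signature {self.id}: pyrimidine-context probabilities sum "
                f"to {total:.6f}, expected 1 +/- {tol:g}"
            )


@dataclass
class ExposureProfile:
    """Signature contributions (W) for one cancer type."""

    cancer_type: str
    weights: dict[str, float]

    def validate(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"{self.cancer_type}: negative exposure weight")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError(f"{self.cancer_type}: all exposure weights zero")
        if sum(self.weights.values()) > 1.05:
            warnings.warn(
                f"{self.cancer_type}: exposure weights sum to "
                f"{sum(self.weights.values()):.3f} (> 1.05)",
                stacklevel=2,
            )


@dataclass
class CodingSequence:
    """In-frame coding sequence of the target gene."""

    gene: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length not divisible by 3")
        prot = str(Seq(self.seq).translate())
        if "*" in prot[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon in CDS")

    @classmethod
    def from_fasta(cls, path, gene: str | None = None) -> "CodingSequence":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(gene or rec.id, str(rec.seq))

    @property
    def protein_length(self) -> int:
        prot = str(Seq(self.seq).translate())
        return len(prot.rstrip("*"))

    @property
    def protein_seq(self) -> str:
        return str(Seq(self.seq).translate()).rstrip("*")

    def codon(self, i: int) -> str:
        """Codon for 1-based protein position ``i``."""
        if not 1 <= i <= self.protein_length:
            raise IndexError(f"protein position {i} out of range")
        return self.seq[(i - 1) * 3: i * 3]


@dataclass(frozen=True)
class SnvInContext:
    """One nucleotide substitution with its flanking bases (coding strand)."""

    codon_position: int  # 1-3 within the codon
    ref_base: str
    alt_base: str
    fiveprime: str
    threeprime: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("SNV with identical ref/alt base")

    @property
    def key(self) -> str:
        return context_key(self.fiveprime, self.ref_base, self.alt_base,
                           self.threeprime)

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class AminoAcidMutation:
    """A protein change together with every SNV that can cause it."""

    protein_position: int
    ref_aa: str
    alt_aa: str
    causal_snvs: tuple[SnvInContext, ...]

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("mutation with identical ref/alt amino acid")
        if self.alt_aa == "*":
            raise ValueError("stop-gained changes are excluded")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.protein_position}{self.alt_aa}"


@dataclass
class RankedLandscape:
    """Mutations ordered by likelihood, with dominant substitution class."""

    entries: list[tuple[AminoAcidMutation, float, str]] = field(
        default_factory=list
    )

    @property
    def N(self) -> int:
        return len(self.entries)


@dataclass
class OddsRatioResult:
    value: float
    corrected: bool = False
    undefined: bool = False


# ---------------------------------------------------------------------------
# catalog / exposure parsing


def parse_signature_catalog(path) -> list[MutationalSignature]:
    """Read a COSMIC-layout signature TSV (context rows x signature columns)."""
    df = pd.read_csv(path, sep="\t")
    ctx_col = df.columns[0]
    contexts = [c.strip() for c in df[ctx_col].astype(str)]
    for c in contexts:
        five, ref, _, _ = parse_context(c)
        if ref not in PYRIMIDINES:
            raise CatalogError(f"catalog context not pyrimidine-based: {c!r}")
    sigs = []
    for col in df.columns[1:]:
        probs = dict(zip(contexts, df[col].astype(float)))
        sig = MutationalSignature(id=str(col), probs=probs)
        sig.validate()
        sigs.append(sig)
    return sigs


def parse_exposure_profile(path, cancer_type: str | None = None) -> ExposureProfile:
    """Read a two-column (signature_id, weight) TSV for one cancer type."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["signature_id", "weight"])
    # tolerate a header row
    try:
        float(df.iloc[0]["weight"])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    weights = {str(r.signature_id): float(r.weight) for r in df.itertuples()}
    prof = ExposureProfile(cancer_type or "unknown", weights)
    prof.validate()
    return prof


def extend_to_full_context(
    sig: MutationalSignature,
    biased_ids: frozenset[str] | set[str] = DEFAULT_BIASED_SIGNATURES,
) -> MutationalSignature:
    """Extend 96 pyrimidine-context probabilities to all 192 contexts.

    Non-biased signatures get each purine context from its
    reverse-complement pyrimidine context.  Strand-biased signatures have
    purine contexts set to zero (no renormalisation).
    """
    if sig.extended:
        return sig
    if len(sig.probs) != 96:
        raise CatalogError(
            f"signature {sig.id}: expected 96 contexts before extension"
        )
    biased = sig.strand_biased or sig.id in biased_ids
    probs = dict(sig.probs)
    for key, p in sig.probs.items():
        probs[revcomp_context(key)] = 0.0 if biased else p
    return MutationalSignature(id=sig.id, probs=probs, strand_biased=biased)


def load_catalog(path, biased_ids=DEFAULT_BIASED_SIGNATURES
                 ) -> list[MutationalSignature]:
    """Parse and extend a signature catalog in one step."""
    return [extend_to_full_context(s, biased_ids)
            for s in parse_signature_catalog(path)]


# ---------------------------------------------------------------------------
# mutation enumeration

_BASES = "ACGT"


def enumerate_missense_snvs(
    cds: CodingSequence, positions: list[int]
) -> list[AminoAcidMutation]:
    """All missense changes reachable by one nucleotide substitution.

    Synonymous and stop-gained substitutions are excluded.  Substitutions
    producing the same amino-acid change are grouped into one
    :class:`AminoAcidMutation`.  Codons at the ends of the CDS lack one
    flanking base; those SNVs carry an ``N`` flank (and contribute zero
    likelihood downstream).
    """
    out: list[AminoAcidMutation] = []
    n = len(cds.seq)
    for pos in positions:
        codon = cds.codon(pos)  # raises IndexError if out of range
        ref_aa = str(Seq(codon).translate())
        by_alt: dict[str, list[SnvInContext]] = {}
        for cpos in range(3):
            idx = (pos - 1) * 3 + cpos
            ref = cds.seq[idx]
            five = cds.seq[idx - 1] if idx > 0 else "N"
            three = cds.seq[idx + 1] if idx + 1 < n else "N"
            if "N" in (five, three):
                warnings.warn(
                    f"position {pos}: CDS-edge codon, using 'N' flank",
                    stacklevel=2,
                )
            for alt in _BASES:
                if alt == ref:
                    continue
                new_codon = codon[:cpos] + alt + codon[cpos + 1:]
                alt_aa = str(Seq(new_codon).translate())
                if alt_aa == ref_aa or alt_aa == "*":
                    continue
                by_alt.setdefault(alt_aa, []).append(
                    SnvInContext(cpos + 1, ref, alt, five, three)
                )
        for alt_aa in sorted(by_alt):
            out.append(AminoAcidMutation(pos, ref_aa, alt_aa,
                                         tuple(by_alt[alt_aa])))
    return out


# ---------------------------------------------------------------------------
# likelihood


def _check_catalog(exposure: ExposureProfile,
                   catalog: dict[str, MutationalSignature]) -> None:
    for sid, w in exposure.weights.items():
        if w == 0:
            continue
        if sid not in catalog:
            raise KeyError(
                f"exposure references signature {sid!r} absent from catalog"
            )
        if not catalog[sid].extended:
            raise ValueError(
                f"signature {sid} not extended to 192 contexts"
            )


def mutation_likelihood(
    m: AminoAcidMutation,
    exposure: ExposureProfile,
    catalog: list[MutationalSignature],
) -> float:
    """Exposure-weighted likelihood of an amino-acid mutation.

    ``L = sum_snv sum_sig W_sig * P_sig(context)``.  SNVs with an ``N``
    flank (CDS edges) contribute zero.
    """
    by_id = {s.id: s for s in catalog}
    _check_catalog(exposure, by_id)
    total = 0.0
    for snv in m.causal_snvs:
        if "N" in (snv.fiveprime, snv.threeprime):
            continue
        for sid, w in exposure.weights.items():
            if w == 0:
                continue
            total += w * by_id[sid].probs.get(snv.key, 0.0)
    return total


def snv_contributions(
    m: AminoAcidMutation,
    exposure: ExposureProfile,
    catalog: list[MutationalSignature],
) -> dict[SnvInContext, float]:
    """Per-SNV share of the mutation likelihood."""
    by_id = {s.id: s for s in catalog}
    _check_catalog(exposure, by_id)
    out = {}
    for snv in m.causal_snvs:
        if "N" in (snv.fiveprime, snv.threeprime):
            out[snv] = 0.0
            continue
        out[snv] = sum(
            w * by_id[sid].probs.get(snv.key, 0.0)
            for sid, w in exposure.weights.items() if w > 0
        )
    return out


def dominant_substitution(
    m: AminoAcidMutation,
    exposure: ExposureProfile,
    catalog: list[MutationalSignature],
) -> str:
    """Pyrimidine-normalised class of the highest-contributing causal SNV."""
    contrib = snv_contributions(m, exposure, catalog)
    best = max(
        contrib.items(),
        key=lambda kv: (kv[1], collapse_to_pyrimidine(kv[0].substitution)),
    )
    return collapse_to_pyrimidine(best[0].substitution)


def rank_landscape(
    mutations: list[tuple[AminoAcidMutation, float, str]]
    | list[tuple[AminoAcidMutation, float]],
) -> RankedLandscape:
    """Order (mutation, likelihood[, class]) tuples into a landscape.

    Sorted by likelihood descending; ties broken by (protein position asc,
    alt amino acid asc) so the ordering is permutation-invariant.
    """
    if not mutations:
        raise ValueError("empty mutation list")
    entries = []
    for tup in mutations:
        m, L = tup[0], tup[1]
        cls = tup[2] if len(tup) > 2 else ""
        entries.append((m, float(L), cls))
    entries.sort(key=lambda e: (-e[1], e[0].protein_position, e[0].alt_aa))
    return RankedLandscape(entries=entries)


def build_landscape(
    mutations: list[AminoAcidMutation],
    exposure: ExposureProfile,
    catalog: list[MutationalSignature],
) -> RankedLandscape:
    """Likelihood-ranked landscape with dominant substitution classes."""
    scored = [
        (m,
         mutation_likelihood(m, exposure, catalog),
         dominant_substitution(m, exposure, catalog))
        for m in mutations
    ]
    return rank_landscape(scored)


def enrichment_odds_ratio(
    land: RankedLandscape, subst_class: str, i: int
) -> OddsRatioResult:
    """Odds ratio of a substitution class among the top ``i`` mutations.

    With ``a`` occurrences in ranks 1..i and ``b`` in ranks i+1..N:
    ``OR = [a/(i-a)] / [b/((N-i)-b)]``.  A +0.5 correction is applied to
    all four cells when any cell is zero; a class absent from the whole
    landscape yields a flagged undefined result.
    """
    N = land.N
    if not 0 < i < N:
        raise ValueError(f"cut rank i={i} must satisfy 0 < i < N={N}")
    target = collapse_to_pyrimidine(subst_class)
    classes = [collapse_to_pyrimidine(c) if c else "" for _, _, c in land.entries]
    a = sum(1 for c in classes[:i] if c == target)
    b = sum(1 for c in classes[i:] if c == target)
    if a + b == 0:
        return OddsRatioResult(float("nan"), undefined=True)
    cells = [a, i - a, b, (N - i) - b]
    corrected = any(c == 0 for c in cells)
    if corrected:
        cells = [c + 0.5 for c in cells]
    a_, c_, b_, d_ = cells
    return OddsRatioResult((a_ / c_) / (b_ / d_), corrected=corrected)


def landscape_to_frame(land: RankedLandscape) -> pd.DataFrame:
    """Tabular (position, ref_aa, alt_aa, likelihood, rank, class) view."""
    rows = [
        {
            "position": m.protein_position,
            "ref_aa": m.ref_aa,
            "alt_aa": m.alt_aa,
            "likelihood": L,
            "rank": r + 1,
            "dominant_substitution": cls,
        }
        for r, (m, L, cls) in enumerate(land.entries)
    ]
    return pd.DataFrame(rows)
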