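"""Feature schemas and feature-vector assembly.

The schema registry is the single source of truth for feature ordering and
vector lengths.  ``aa-v1`` is the amino-acid-centred schema; ``lig-v1`` is
the ligand-centred one (interaction fingerprint added; half-sphere
exposure, protein salt-bridge counts and disulfide detection dropped).
Features that can be missing carry a parallel ``*_known`` indicator and a
zero sentinel so tree models can split on missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import featex
from ._aa_data import AA1
from .sigcontext import AminoAcidMutation
from .structmut import BindingSite, ComplexModel, define_binding_site

MEASURE_CODES = {"Ki": 0.0, "Kd": 1.0, "IC50": 2.0}
_DDG_CAT = {"UNSTABLE": -1.0, "UNKNOWN": 0.0, "STABLE": 1.0}


@dataclass(frozen=True)
class FeatureSchema:
    name: str
    features: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)

    def index(self, feature: str) -> int:
        return self.features.index(feature)


def _core_features() -> list[str]:
    names = [
        "site_area_wt", "site_area_mt", "site_area_dabs",
        "res_sasa_wt", "res_sasa_mt", "res_sasa_dabs",
        "rsa_wt", "rsa_mt", "rsa_dabs", "rsa_known",
    ]
    names += [f"mut_{aa}" for aa in AA1]
    names += ["hb_present", "hb_dist", "hb_backbone"]
    names += [f"shell{k}_{aa}" for k in range(1, 7) for aa in AA1]
    names += [f"seqwin_{aa}" for aa in AA1] + ["seqwin_truncated"]
    names += [f"ss_{tag}_{s}" for tag in ("wt", "mt") for s in "HEC"]
    names += ["ddg_value", "ddg_cat", "ddg_known"]
    names += ["cons_score", "cons_known"]
    names += ["rmsd_raw", "rmsd_refined"]
    names += [f"ligdist_{s}_{t}" for t in ("wt", "mt", "dabs")
              for s in ("min", "max", "mean")]
    names += ["ligdist_known"]
    names += [f"charge_{aa}" for aa in AA1] + ["dhydro"]
    names += ["aff_log10_nM", "aff_measure"]
    names += ["ligsb_present", "ligsb_dist", "ligsb_group"]
    return names


_AA_ONLY = [
    "hse_up_wt", "hse_down_wt", "hse_up_mt", "hse_down_mt",
    "hse_up_dabs", "hse_down_dabs", "hse_known",
    "psb_count_wt", "psb_count_mt", "psb_count_dabs",
    "ss_bond_present",
]

_LIG_ONLY = [
    "xb_present", "xb_dist",
    "pistack_present", "pistack_dist",
    "pication_present", "pication_dist",
    "wb_present", "wb_dist",
    "hydroph_present", "hydroph_dist",
    "fp_known",
]

SCHEMAS: dict[str, FeatureSchema] = {
    "aa-v1": FeatureSchema("aa-v1", tuple(_core_features() + _AA_ONLY)),
    "lig-v1": FeatureSchema("lig-v1", tuple(_core_features() + _LIG_ONLY)),
}


def get_schema(name: str) -> FeatureSchema:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise KeyError(
            f"unknown schema {name!r}; available: {sorted(SCHEMAS)}"
        ) from None


@dataclass
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError(
                f"vector length {len(self.values)} != schema "
                f"{self.schema.name} length {len(self.schema)}"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature vector contains NaN")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema.features, map(float, self.values)))


def assemble_feature_vector(
    parts: dict[str, float],
    schema: FeatureSchema,
    wt_affinity_nM: float,
    measure: str = "IC50",
) -> FeatureVector:
    """Order computed feature parts into a schema-conformant vector.

    The wild-type affinity is encoded as log10(nM) plus a measure-type
    code (Ki=0, Kd=1, IC50=2).  Features absent from ``parts`` take the
    zero sentinel with provenance ``unknown``.
    """
    if wt_affinity_nM <= 0:
        raise ValueError("wild-type affinity must be positive (nM)")
    if measure not in MEASURE_CODES:
        raise ValueError(f"unknown affinity measure {measure!r}")
    parts = dict(parts)
    parts["aff_log10_nM"] = math.log10(wt_affinity_nM)
    parts["aff_measure"] = MEASURE_CODES[measure]
    values = np.zeros(len(schema))
    provenance = {}
    for i, name in enumerate(schema.features):
        if name in parts:
            values[i] = float(parts[name])
            provenance[name] = "computed"
        else:
            provenance[name] = "unknown"
    return FeatureVector(schema, values, provenance)


def extract_pair_features(
    wt: ComplexModel,
    mt: ComplexModel,
    mutation: AminoAcidMutation,
    schema: FeatureSchema | str,
    wt_affinity_nM: float,
    measure: str = "IC50",
    site: BindingSite | None = None,
    alignment: list[str] | None = None,
    chain: str | None = None,
    offset: int = 0,
) -> FeatureVector:
    """Compute every schema feature for one WT/MT complex pair.

    ``offset`` maps the mutation's protein position onto structure residue
    numbers.  The binding site defaults to the WT 9.5-A site.  Deltas are
    absolute WT/MT differences throughout.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    pos = mutation.protein_position + offset
    if site is None:
        site = define_binding_site(wt)
    parts: dict[str, float] = {}

    parts.update(
        featex.surface_accessibility_features(wt, mt, site, pos, chain)
    )
    parts.update(featex.mutation_vector(mutation.ref_aa, mutation.alt_aa))
    parts.update(featex.hydrogen_bond_features(mt, pos, chain))
    parts.update(featex.environment_encodings(mt, pos, chain))
    for tag, model in (("wt", wt), ("mt", mt)):
        label, ok = featex.secondary_structure(model, pos, chain)
        for s in "HEC":
            parts[f"ss_{tag}_{s}"] = float(label == s and ok) if s != "C" \
                else float(label == "C")
    ddg, cat = featex.stability_change(
        wt, mutation, rsa_wt=parts.get("rsa_wt") if parts.get("rsa_known")
        else None, chain=chain,
    )
    parts["ddg_value"] = ddg if ddg is not None else 0.0
    parts["ddg_cat"] = _DDG_CAT["UNKNOWN" if ddg is None else cat]
    parts["ddg_known"] = float(ddg is not None)
    cons = None
    if alignment is not None:
        cons = featex.conservation_score(
            alignment, mutation.protein_position - 1
        )
    parts["cons_score"] = cons if cons is not None else 0.0
    parts["cons_known"] = float(cons is not None)
    raw, refined = featex.alignment_rmsd(wt, mt)
    parts["rmsd_raw"] = raw
    parts["rmsd_refined"] = refined
    ld_wt = featex.ligand_distance_features(wt, pos, chain)
    ld_mt = featex.ligand_distance_features(mt, pos, chain)
    if ld_wt and ld_mt:
        for s in ("min", "max", "mean"):
            parts[f"ligdist_{s}_wt"] = ld_wt[s]
            parts[f"ligdist_{s}_mt"] = ld_mt[s]
            parts[f"ligdist_{s}_dabs"] = abs(ld_wt[s] - ld_mt[s])
        parts["ligdist_known"] = 1.0
    else:
        parts["ligdist_known"] = 0.0
    parts.update(
        featex.charge_hydrophobicity_features(mutation.ref_aa, mutation.alt_aa)
    )
    sb = featex.salt_bridge_features(mt, pos, chain)
    parts["ligsb_present"] = sb["ligsb_present"]
    parts["ligsb_dist"] = sb["ligsb_dist"]
    parts["ligsb_group"] = sb["ligsb_group"]

    if schema.name.startswith("aa"):
        hse_wt = featex.half_sphere_exposure(wt, pos, chain)
        hse_mt = featex.half_sphere_exposure(mt, pos, chain)
        if hse_wt and hse_mt:
            parts["hse_up_wt"], parts["hse_down_wt"] = map(float, hse_wt)
            parts["hse_up_mt"], parts["hse_down_mt"] = map(float, hse_mt)
            parts["hse_up_dabs"] = abs(hse_wt[0] - hse_mt[0])
            parts["hse_down_dabs"] = abs(hse_wt[1] - hse_mt[1])
            parts["hse_known"] = 1.0
        else:
            parts["hse_known"] = 0.0
        sb_wt = featex.salt_bridge_features(wt, pos, chain)
        parts["psb_count_wt"] = sb_wt["psb_count"]
        parts["psb_count_mt"] = sb["psb_count"]
        parts["psb_count_dabs"] = abs(sb_wt["psb_count"] - sb["psb_count"])
        parts["ss_bond_present"] = float(featex.disulfide_check(mt, pos, chain))
    else:
        fp = featex.ligand_interaction_fingerprint(mt, pos, chain)
        for key, stem in (("halogen", "xb"), ("pistack", "pistack"),
                          ("pication", "pication"), ("water_bridge", "wb"),
                          ("hydrophobic", "hydroph")):
            parts[f"{stem}_present"] = float(fp.present(key))
            parts[f"{stem}_dist"] = fp.distance(key)
        parts["fp_known"] = float(fp.known)

    return assemble_feature_vector(parts, schema, wt_affinity_nM, measure)
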