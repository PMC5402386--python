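"""Compound screening: mutation x compound sensitivity maps.

Candidate compounds (co-crystallised poses, docked poses or manual
additions) are screened against every binding-site mutation with the
ligand-schema classifier.  All cells of one map form a single
normalisation experiment, so the global maximum Resistance Score maps to
NRS 1.0 and the minimum to 0.0.  Mutations are then grouped by
targetability: *hardly targetable* (almost all compounds predicted
resistant), *easily targetable* (almost all predicted sensitive) and
*targetable* (mixed profile).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .respred import ClassifierModel, ClassPrecisions, predict_scores, resistance_score
from .schema import extract_pair_features
from .sigcontext import AminoAcidMutation
from .structmut import ComplexModel, build_mutant_model, define_binding_site, load_complex

IC50_CUTOFF_NM = 100.0


@dataclass
class CompoundRecord:
    id: str
    source: str  # cocrystal | docked | manual
    pose_path: str
    affinity_nM: float
    measure: str = "IC50"
    ligand_id: str = "LIG"
    docking_engine: str | None = None


@dataclass
class SensitivityMap:
    compounds: list[str]
    mutations: list[str]
    nrs: np.ndarray  # compounds x mutations
    rs: np.ndarray
    classes: np.ndarray  # dtype=object
    missing: np.ndarray  # bool mask

    def column(self, mutation: str) -> np.ndarray:
        return self.nrs[:, self.mutations.index(mutation)]


def load_candidates(
    affinity_table: str | Path,
    poses_dir: str | Path | None = None,
    ic50_cutoff_nM: float = IC50_CUTOFF_NM,
) -> tuple[list[CompoundRecord], list[tuple[str, str]]]:
    """Load candidate compounds from an affinity TSV + pose directory.

    TSV columns: compound_id, affinity_nM, measure, source [, pose,
    ligand_id].  Records without a measured affinity are rejected; docked
    (extended-set) records must satisfy the IC50 cutoff; co-crystal and
    manual records are exempt.  Unresolvable poses are dropped and logged.
    """
    df = pd.read_csv(affinity_table, sep="\t")
    records: list[CompoundRecord] = []
    dropped: list[tuple[str, str]] = []
    for row in df.itertuples():
        cid = str(row.compound_id)
        if pd.isna(row.affinity_nM):
            dropped.append((cid, "no measured affinity"))
            continue
        aff = float(row.affinity_nM)
        source = str(row.source)
        if source == "docked" and aff > ic50_cutoff_nM:
            dropped.append((cid, f"affinity {aff} nM above cutoff"))
            continue
        pose = str(getattr(row, "pose", f"{cid}.pdb"))
        if poses_dir is not None:
            pose = str(Path(poses_dir) / pose)
        if not Path(pose).exists():
            dropped.append((cid, "pose file missing"))
            continue
        records.append(CompoundRecord(
            id=cid, source=source, pose_path=pose, affinity_nM=aff,
            measure=str(getattr(row, "measure", "IC50")),
            ligand_id=str(getattr(row, "ligand_id", "LIG")),
        ))
    return records, dropped


def screen_compounds(
    candidates: list[CompoundRecord],
    mutations: list[AminoAcidMutation],
    model: ClassifierModel,
    target: ComplexModel,
    precisions: ClassPrecisions,
    offset: int = 0,
    chain: str | None = None,
) -> SensitivityMap:
    """Score every compound x mutation pair into a sensitivity map.

    For each pair the mutant model is built (graft backend), lig-schema
    features are extracted against the compound's pose, and the RS is
    computed; NRS is normalised over the complete map.  Failed cells are
    flagged missing, not fatal.
    """
    if not candidates or not mutations:
        raise ValueError("need at least one compound and one mutation")
    nc, nm = len(candidates), len(mutations)
    rs = np.zeros((nc, nm))
    classes = np.empty((nc, nm), dtype=object)
    missing = np.zeros((nc, nm), dtype=bool)
    for ci, comp in enumerate(candidates):
        try:
            complex_model = load_complex(comp.pose_path, comp.ligand_id)
        except (OSError, KeyError, ValueError):
            missing[ci, :] = True
            continue
        site = define_binding_site(complex_model)
        for mi, mut in enumerate(mutations):
            try:
                mt = build_mutant_model(complex_model, mut, offset=offset,
                                        chain=chain)
                fv = extract_pair_features(
                    complex_model, mt.structure, mut, model.schema,
                    wt_affinity_nM=comp.affinity_nM, measure=comp.measure,
                    site=site, chain=chain, offset=offset,
                )
                sc = predict_scores(model, fv)
            except (KeyError, ValueError):
                missing[ci, mi] = True
                continue
            rs[ci, mi] = resistance_score(sc, precisions)
            classes[ci, mi] = sc.predicted_class
    ok = ~missing
    if not ok.any():
        raise ValueError("every cell of the sensitivity map failed")
    lo, hi = rs[ok].min(), rs[ok].max()
    nrs = np.zeros_like(rs)
    if hi > lo:
        nrs[ok] = (rs[ok] - lo) / (hi - lo)
    return SensitivityMap(
        compounds=[c.id for c in candidates],
        mutations=[str(m) for m in mutations],
        nrs=nrs, rs=rs, classes=classes, missing=missing,
    )


def classify_targetability(
    smap: SensitivityMap,
    low: float = 0.3,
    high: float = 0.7,
    frac: float = 0.8,
    min_coverage: float = 0.5,
) -> dict[str, str]:
    """Group mutations by how many compounds remain predicted-sensitive.

    hardly-targetable: >= ``frac`` of a mutation's cells have NRS >=
    ``high``; easily-targetable: >= ``frac`` have NRS <= ``low``;
    otherwise targetable.  Columns with under ``min_coverage`` scored
    cells are undetermined.
    """
    groups = {}
    for mi, mut in enumerate(smap.mutations):
        ok = ~smap.missing[:, mi]
        if ok.mean() < min_coverage:
            groups[mut] = "undetermined"
            continue
        vals = smap.nrs[ok, mi]
        if (vals >= high).mean() >= frac:
            groups[mut] = "hardly-targetable"
        elif (vals <= low).mean() >= frac:
            groups[mut] = "easily-targetable"
        else:
            groups[mut] = "targetable"
    return groups


def map_to_frame(smap: SensitivityMap) -> pd.DataFrame:
    return pd.DataFrame(smap.nrs, index=smap.compounds,
                        columns=smap.mutations)


def export_map(smap: SensitivityMap, path: str | Path, fmt: str = "tsv") -> None:
    """Write the map as TSV (NRS matrix), JSON (with classes) or PNG."""
    if not smap.compounds or not smap.mutations:
        raise ValueError("empty sensitivity map")
    path = Path(path)
    if fmt == "tsv":
        map_to_frame(smap).to_csv(path, sep="\t", index_label="compound")
    elif fmt == "json":
        payload = {
            "compounds": smap.compounds,
            "mutations": smap.mutations,
            "nrs": smap.nrs.tolist(),
            "rs": smap.rs.tolist(),
            "classes": [[c if c is not None else None for c in row]
                        for row in smap.classes.tolist()],
            "missing": smap.missing.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "png":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * len(smap.mutations)),
                     max(3, 0.4 * len(smap.compounds)))
        )
        im = ax.imshow(smap.nrs, cmap="RdYlGn_r", vmin=0, vmax=1,
                       aspect="auto")
        ax.set_xticks(range(len(smap.mutations)), smap.mutations,
                      rotation=90, fontsize=6)
        ax.set_yticks(range(len(smap.compounds)), smap.compounds, fontsize=6)
        fig.colorbar(im, label="NRS")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_map(path: str | Path, fmt: str = "tsv") -> SensitivityMap:
    """Round-trip loader for exported maps (TSV keeps NRS only)."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        nrs = df.to_numpy()
        return SensitivityMap(
            compounds=list(df.index), mutations=list(df.columns),
            nrs=nrs, rs=np.zeros_like(nrs),
            classes=np.empty(nrs.shape, dtype=object),
            missing=np.zeros(nrs.shape, dtype=bool),
        )
    if fmt == "json":
        payload = json.loads(path.read_text())
        return SensitivityMap(
            compounds=payload["compounds"], mutations=payload["mutations"],
            nrs=np.array(payload["nrs"]), rs=np.array(payload["rs"]),
            classes=np.array(payload["classes"], dtype=object),
            missing=np.array(payload["missing"], dtype=bool),
        )
    raise ValueError(f"unknown format {fmt!r}")
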