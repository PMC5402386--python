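"""Self-contained synthetic inputs for the whole pipeline.

Everything the other modules consume can be generated here from a seed:
signature catalogs and exposure profiles in COSMIC layout, matched toy
CDS + protein-ligand complex pairs with scripted geometry (including
boundary fixtures that sit exactly on the geometric detector cutoffs),
Platinum-style training tables with a planted, physically expressed class
signal, and candidate compound poses with an affinity table.

The planted signal lives in real geometry: the mutant ligand pose is
translated away from (or towards) the protein by a class-dependent offset
scaled by ``signal_strength``, which perturbs the ligand-distance and
hydrogen-bond features that the classifiers consume.  At strength zero
the classes are geometrically indistinguishable.

Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa_data import AA_1TO3, SIDECHAIN_ATOMS
from .sigcontext import context_key
from .structmut import Atom, ComplexModel, Residue, _graft_sidechain, write_complex

_BASES = "ACGT"
_PYR_CONTEXTS = [
    context_key(f, r, a, t)
    for r in "CT" for a in _BASES if a != r
    for f in _BASES for t in _BASES
]

# one fixed codon per amino acid for CDS back-translation
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACG", "V": "GTT", "W": "TGG", "Y": "TAT",
}

CLASS_OFFSETS = {"SRES": 2.0, "RES": 1.0, "NEU": 0.0, "ISEN": -0.7}
GEOM_NOISE_SD = 0.15


@dataclass
class FixtureBundle:
    seed: int
    catalog: Path | None = None
    exposures: dict[str, Path] = field(default_factory=dict)
    cds_fasta: Path | None = None
    complex_pdb: Path | None = None
    boundary_pdbs: dict[str, Path] = field(default_factory=dict)
    site_resnums: list[int] = field(default_factory=list)
    training_table: Path | None = None
    candidate_dir: Path | None = None
    affinity_table: Path | None = None


# ---------------------------------------------------------------------------
# signatures


def make_toy_signature_catalog(
    n_signatures: int, seed: int, out_dir: str | Path
) -> FixtureBundle:
    """COSMIC-layout catalog TSV + two exposure profiles.

    Each signature's 96 probabilities are Dirichlet-ish draws rounded to 8
    decimals and adjusted to sum exactly to 1.  The last signature is
    flagged strand-biased (id ``Signature 7``-style analog lives at id
    ``7``) to exercise the purine-zeroing path.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cols = {}
    ids = [str(i + 1) for i in range(n_signatures)]
    if n_signatures > 1 and "7" not in ids:
        ids[-1] = "7"  # guarantee one biased id
    for sid in ids:
        raw = rng.gamma(0.5, size=96)
        p = raw / raw.sum()
        p = np.round(p, 8)
        p[np.argmax(p)] += round(1.0 - p.sum(), 8)
        cols[sid] = p
    df = pd.DataFrame({"Somatic Mutation Type": _PYR_CONTEXTS, **cols})
    catalog = out / "signatures.tsv"
    df.to_csv(catalog, sep="\t", index=False, float_format="%.8f")
    bundle = FixtureBundle(seed=seed, catalog=catalog)
    for name in ("alpha", "beta"):
        w = rng.dirichlet(np.ones(n_signatures))
        path = out / f"exposure_{name}.tsv"
        lines = [f"{sid}\t{wi:.8f}" for sid, wi in zip(ids, np.round(w, 8))]
        path.write_text("\n".join(lines) + "\n")
        bundle.exposures[name] = path
    return bundle


# ---------------------------------------------------------------------------
# toy complexes


def _backbone(resnum: int, chain: str, aa1: str, x0: float) -> Residue:
    res = Residue(chain, resnum, AA_1TO3[aa1], [
        Atom("N", "N", np.array([x0, 0.0, 0.0])),
        Atom("CA", "C", np.array([x0 + 1.2, 0.9, 0.0])),
        Atom("C", "C", np.array([x0 + 2.5, 0.4, 0.0])),
        Atom("O", "O", np.array([x0 + 2.5, -0.8, 0.3])),
    ])
    if SIDECHAIN_ATOMS[aa1]:
        res = _graft_sidechain(res, aa1)
    return res


def build_toy_chain(sequence: str, chain: str = "A",
                    spacing: float = 3.5) -> list[Residue]:
    """Extended chain with idealised backbone and grafted side chains."""
    return [
        _backbone(i + 1, chain, aa, i * spacing)
        for i, aa in enumerate(sequence)
    ]


def _ligand_near(residues: list[Residue], anchor: int,
                 n_atoms: int) -> Residue:
    """Ligand block above the anchor residue, with one O hydrogen-bonded
    (3.0 A) to the anchor's backbone O."""
    anchor_res = residues[anchor]
    o = anchor_res.atom("O")
    ca = anchor_res.atom("CA")
    up = np.array([0.0, -1.0, 0.5])
    up /= np.linalg.norm(up)
    atoms = [Atom("O1", "O", o.pos + 3.0 * up)]
    base = ca.pos + np.array([0.0, -4.5, 2.5])
    for i in range(max(0, n_atoms - 1)):
        dx = 1.4 * (i % 2)
        dz = 1.4 * (i // 2)
        atoms.append(Atom(f"C{i + 1}", "C", base + np.array([dx, 0.0, dz])))
    return Residue("A", 900, "LIG", atoms, het=True)


def make_toy_complex(
    n_residues: int, ligand_atoms: int, seed: int, out_dir: str | Path
) -> FixtureBundle:
    """Matched WT complex PDB + in-frame CDS FASTA + boundary fixtures.

    The ligand sits above the middle of the chain; the expected binding
    site is recorded from an all-pairs distance computation done here,
    independent of the site-definition code under test.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    # deterministic sequence; keep a THR at the anchor so its ACG codon
    # exercises the classic gatekeeper-style A[C>T]G context
    aas = "".join(rng.choice(list("ACDEFGHIKLMNQRSVWY"))
                  for _ in range(n_residues))
    anchor = n_residues // 2
    seq = aas[:anchor] + "T" + aas[anchor + 1:]
    residues = build_toy_chain(seq)
    ligand = _ligand_near(residues, anchor, ligand_atoms)
    model = ComplexModel(residues, ligand, source="toy")
    pdb = out / "complex_wt.pdb"
    write_complex(model, pdb)
    # independent brute-force site
    lig = ligand.heavy_coords()
    site = []
    for r in residues:
        d = np.sqrt(((r.heavy_coords()[:, None, :] - lig[None, :, :]) ** 2)
                    .sum(axis=2)).min()
        if d <= 9.5:
            site.append(r.resnum)
    cds = "".join(_CODON_OF[a] for a in seq) + "TAA"
    fasta = out / "cds.fasta"
    fasta.write_text(f">toygene\n{cds}\n")
    bundle = FixtureBundle(seed=seed, complex_pdb=pdb, cds_fasta=fasta,
                           site_resnums=site)
    bundle.boundary_pdbs = make_boundary_set(out)
    return bundle


def _micro_complex(probe_res: list[Residue], lig_atoms: list[Atom]
                   ) -> ComplexModel:
    return ComplexModel(probe_res, Residue("A", 900, "LIG", lig_atoms,
                                           het=True))


def make_boundary_set(out_dir: str | Path) -> dict[str, Path]:
    """Micro-complexes that sit exactly on the detector cutoffs.

    site_9p4/9p6: closest residue atom at 9.4/9.6 A from the ligand;
    hbond_3p19/3p21: SER OG to ligand O; salt_3p9/4p1: ASP OD1 to LYS NZ;
    ssbond_2p0/2p3: CYS SG-SG.
    """
    out = Path(out_dir)
    paths: dict[str, Path] = {}

    def put(name: str, model: ComplexModel) -> None:
        p = out / f"{name}.pdb"
        write_complex(model, p)
        paths[name] = p

    far = Atom("C9", "C", np.array([500.0, 0.0, 0.0]))
    for tag, d in (("site_9p4", 9.4), ("site_9p6", 9.6)):
        res = _backbone(1, "A", "A", 0.0)
        cb = res.atom("CB")
        lig_o = Atom("O1", "O", cb.pos + np.array([0.0, d, 0.0]))
        put(tag, _micro_complex([res], [lig_o]))
    for tag, d in (("hbond_3p19", 3.19), ("hbond_3p21", 3.21)):
        res = _backbone(1, "A", "S", 0.0)
        og = res.atom("OG")
        lig_o = Atom("O1", "O", og.pos + np.array([0.0, d, 0.0]))
        put(tag, _micro_complex([res], [lig_o]))
    for tag, d in (("salt_3p9", 3.9), ("salt_4p1", 4.1)):
        asp = _backbone(1, "A", "D", 0.0)
        lys = _backbone(2, "A", "K", 30.0)
        od1 = asp.atom("OD1")
        od2 = asp.atom("OD2")
        # NZ on the OD2->OD1 axis so only the scripted pair is in range
        axis = od1.pos - od2.pos
        axis /= np.linalg.norm(axis)
        lys.atom("NZ").pos = od1.pos + d * axis
        put(tag, _micro_complex([asp, lys], [far]))
    for tag, d in (("ssbond_2p0", 2.0), ("ssbond_2p3", 2.3)):
        c1 = _backbone(1, "A", "C", 0.0)
        c2 = _backbone(2, "A", "C", 30.0)
        sg1 = c1.atom("SG")
        c2.atom("SG").pos = sg1.pos + np.array([0.0, d, 0.0])
        put(tag, _micro_complex([c1, c2], [far]))
    return paths


# ---------------------------------------------------------------------------
# training tables


_TEMPLATE_SEQ = "GKDLTSERYM"
_TEMPLATE_ANCHOR = 4  # 0-based; residue 5 (T)


def _template_complex(rng: np.random.Generator) -> ComplexModel:
    residues = build_toy_chain(_TEMPLATE_SEQ)
    ligand = _ligand_near(residues, _TEMPLATE_ANCHOR, 4)
    model = ComplexModel(residues, ligand, source="template")
    for r in residues + [ligand]:
        for a in r.atoms:
            a.pos = a.pos + rng.normal(0.0, 0.05, size=3)
    return model


def _fold_change_for(label: str, rng: np.random.Generator) -> float:
    if label == "SRES":
        return float(rng.uniform(5.0, 20.0))
    if label == "RES":
        return float(rng.uniform(1.25, 4.8))
    if label == "NEU":
        return float(rng.uniform(1.0 / 1.19, 1.19))
    return float(1.0 / rng.uniform(1.25, 10.0))


def make_toy_training_table(
    n_per_class: dict[str, int] | int,
    signal_strength: float,
    seed: int,
    out_dir: str | Path,
    n_decoys: int = 5,
) -> FixtureBundle:
    """Platinum-style training CSV + WT/MT structures with planted signal.

    Per instance the mutant ligand pose is rigidly translated away from
    the protein by ``CLASS_OFFSETS[label] * signal_strength`` (plus
    Gaussian noise of 0.15 A), and the mutated residue's side chain is
    rebuilt by the graft backend.  Fold changes are drawn inside each
    class's affinity band, so relabelling from the fold change recovers
    the intended class exactly.  ``n_decoys`` double-mutant rows exercise
    the single-mutation filter.
    """
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in
                       ("SRES", "RES", "NEU", "ISEN")}
    if min(n_per_class.values()) < 10:
        raise ValueError("need at least 10 instances per class")
    out = Path(out_dir)
    structs = out / "structs"
    structs.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    mut_pos = _TEMPLATE_ANCHOR + 1  # 1-based, in the binding site
    ref_aa = _TEMPLATE_SEQ[_TEMPLATE_ANCHOR]
    alt_choices = [a for a in "ACDEFGHIKLMNPQRSVWY" if a != ref_aa]
    rows = []
    idx = 0
    for label, n in n_per_class.items():
        for _ in range(n):
            idx += 1
            inst = f"inst{idx:04d}"
            wt = _template_complex(rng)
            alt = str(rng.choice(alt_choices))
            mt = _mutant_with_offset(
                wt, mut_pos, alt,
                CLASS_OFFSETS[label] * signal_strength
                + rng.normal(0.0, GEOM_NOISE_SD), rng)
            wt_path = structs / f"{inst}_wt.pdb"
            mt_path = structs / f"{inst}_mt.pdb"
            write_complex(wt, wt_path)
            write_complex(mt, mt_path)
            fold = _fold_change_for(label, rng)
            aff_wt = float(rng.lognormal(np.log(50.0), 0.5))
            rows.append({
                "id": inst, "protein": "TOY1",
                "mutation": f"{ref_aa}{mut_pos}{alt}",
                "n_mutations": 1,
                "wt_structure": str(wt_path.relative_to(out)),
                "mt_structure": str(mt_path.relative_to(out)),
                "affinity_wt": round(aff_wt, 4),
                "affinity_mt": round(aff_wt * fold, 4),
                "measure": str(rng.choice(["Ki", "Kd", "IC50"])),
                "ligand_id": "LIG",
            })
    for j in range(n_decoys):
        idx += 1
        base = dict(rows[j % len(rows)])
        base.update(id=f"decoy{j:02d}", n_mutations=2)
        rows.append(base)
    table = out / "training.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return FixtureBundle(seed=seed, training_table=table)


def _mutant_with_offset(
    wt: ComplexModel, pos: int, alt_aa: str, dy: float,
    rng: np.random.Generator,
) -> ComplexModel:
    import copy

    mt = copy.deepcopy(wt)
    target = mt.residue(pos)
    mt.residues[mt.residues.index(target)] = _graft_sidechain(target, alt_aa)
    shift = np.array([0.0, -dy, 0.0])  # ligand sits at negative y: -dy moves away
    for a in mt.ligand.atoms:
        a.pos = a.pos + shift
    return mt


# ---------------------------------------------------------------------------
# candidate compounds


def make_candidate_set(
    n_compounds: int, seed: int, out_dir: str | Path
) -> FixtureBundle:
    """Candidate poses + affinity TSV exercising every curation rule.

    Generated compounds reuse the template complex with per-compound
    ligand perturbations.  The table includes one record without a
    measured affinity and one docked record above the IC50 cutoff, both
    of which loaders must drop.
    """
    out = Path(out_dir)
    poses = out / "poses"
    poses.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    sources = ["cocrystal", "docked", "manual"]
    for i in range(n_compounds):
        cid = f"CPD{i + 1:03d}"
        model = _template_complex(rng)
        for a in model.ligand.atoms:
            a.pos = a.pos + rng.normal(0.0, 0.3, size=3)
        write_complex(model, poses / f"{cid}.pdb")
        rows.append({
            "compound_id": cid,
            "affinity_nM": round(float(rng.uniform(1.0, 90.0)), 2),
            "measure": "IC50",
            "source": sources[i % len(sources)],
            "pose": f"{cid}.pdb",
            "ligand_id": "LIG",
        })
    # curation decoys
    model = _template_complex(rng)
    write_complex(model, poses / "NOAFF.pdb")
    rows.append({"compound_id": "NOAFF", "affinity_nM": np.nan,
                 "measure": "IC50", "source": "manual",
                 "pose": "NOAFF.pdb", "ligand_id": "LIG"})
    write_complex(model, poses / "WEAK.pdb")
    rows.append({"compound_id": "WEAK", "affinity_nM": 500.0,
                 "measure": "IC50", "source": "docked",
                 "pose": "WEAK.pdb", "ligand_id": "LIG"})
    table = out / "affinities.tsv"
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
    return FixtureBundle(seed=seed, candidate_dir=poses,
                         affinity_table=table)


def make_full_bundle(seed: int, out_dir: str | Path,
                     signal_strength: float = 1.0) -> FixtureBundle:
    """Everything at once, under one seed."""
    out = Path(out_dir)
    sig = make_toy_signature_catalog(4, seed, out / "signatures")
    cx = make_toy_complex(12, 5, seed + 1, out / "complex")
    tr = make_toy_training_table(12, signal_strength, seed + 2,
                                 out / "training")
    cand = make_candidate_set(3, seed + 3, out / "candidates")
    return FixtureBundle(
        seed=seed,
        catalog=sig.catalog, exposures=sig.exposures,
        cds_fasta=cx.cds_fasta, complex_pdb=cx.complex_pdb,
        boundary_pdbs=cx.boundary_pdbs, site_resnums=cx.site_resnums,
        training_table=tr.training_table,
        candidate_dir=cand.candidate_dir,
        affinity_table=cand.affinity_table,
    )
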