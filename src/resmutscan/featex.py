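"""Structural and sequence features for wild-type/mutant complex pairs.

Each feature family describes one aspect of how a point mutation perturbs a
protein-ligand complex: surface burial, hydrogen bonding to the drug,
local structural and sequence environment, stability, conservation,
geometry change, charge/hydrophobicity and protein-ligand interaction
fingerprints.  Two schema variants exist:

* ``aa-v1`` - the amino-acid-centred set (adds half-sphere exposure,
  protein-protein salt-bridge counts and disulfide detection);
* ``lig-v1`` - the ligand-centred set (adds the interaction fingerprint:
  halogen bonds, pi-stacking, pi-cation, water bridges, hydrophobic
  contacts) and drops the aa-only items.

Geometric detector thresholds (configurable via module constants):
hydrogen bond donor-acceptor <= 3.2 A; salt bridge <= 4.0 A; disulfide
SG-SG in [1.8, 2.2] A; halogen bond <= 4.0 A with C-X...A angle >= 140
degrees; pi-stacking centroid <= 5.5 A with ring planes parallel within
30 degrees or perpendicular (60-90); pi-cation centroid-cation <= 6.0 A;
water bridge both polar distances <= 3.6 A; hydrophobic C-C <= 4.0 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

from ._aa_data import (
    AA1,
    AROMATIC_RINGS,
    CATION_ATOMS,
    CHARGE,
    HALOGENS,
    HYDROPATHY,
    MAX_ASA,
    VDW_DEFAULT,
    VDW_RADII,
    VOLUME,
)
from .sigcontext import AminoAcidMutation
from .structmut import Atom, BindingSite, ComplexModel, Residue

HBOND_CUTOFF = 3.2
SALT_BRIDGE_CUTOFF = 4.0
DISULFIDE_RANGE = (1.8, 2.2)
HALOGEN_CUTOFF = 4.0
HALOGEN_MIN_ANGLE = 140.0
PISTACK_CUTOFF = 5.5
PISTACK_PARALLEL_MAX = 30.0
PISTACK_TSHAPE_RANGE = (60.0, 90.0)
PICATION_CUTOFF = 6.0
WATER_BRIDGE_CUTOFF = 3.6
HYDROPHOBIC_CUTOFF = 4.0
HSE_RADIUS = 13.0
SASA_POINTS = 960
SASA_PROBE = 1.4

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# covalent radii (A) for distance-based bond perception
_COV_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
              "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39}


# ---------------------------------------------------------------------------
# solvent accessibility


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str],
    n_points: int = SASA_POINTS,
    probe: float = SASA_PROBE,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Classic point-sampling integration: test points on each solvent-
    expanded atomic sphere are flagged buried when inside any neighbour's
    expanded sphere.
    """
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    radii = np.array(
        [VDW_RADII.get(e.upper(), VDW_DEFAULT) + probe for e in elements]
    )
    sphere = _fibonacci_sphere(n_points)
    areas = np.zeros(n)
    # neighbour prefilter
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        cutoff = (radii[i] + radii.max()) ** 2
        nbr = np.where((d2[i] <= cutoff) & (np.arange(n) != i))[0]
        pts = coords[i] + radii[i] * sphere
        if nbr.size:
            dist2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (dist2 <= radii[nbr][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return areas


def _protein_sasa(model: ComplexModel) -> dict[tuple[str, int], float]:
    """SASA per protein residue (ligand and waters excluded)."""
    coords, elements, owner = [], [], []
    for r in model.residues:
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            coords.append(a.pos)
            elements.append(a.element)
            owner.append(r.key)
    areas = shrake_rupley_sasa(np.array(coords), elements)
    out: dict[tuple[str, int], float] = {}
    for key, area in zip(owner, areas):
        out[key] = out.get(key, 0.0) + area
    return out


def surface_accessibility_features(
    wt: ComplexModel,
    mt: ComplexModel,
    site: BindingSite,
    pos: int,
    chain: str | None = None,
) -> dict[str, float]:
    """Binding-site surface area, residue SASA and RSA for WT/MT + |deltas|."""
    out: dict[str, float] = {}
    site_keys = {r.key for r in site.residues}
    for tag, model in (("wt", wt), ("mt", mt)):
        per_res = _protein_sasa(model)
        res = model.residue(pos, chain)
        out[f"site_area_{tag}"] = sum(
            v for k, v in per_res.items() if k in site_keys
        )
        out[f"res_sasa_{tag}"] = per_res.get(res.key, 0.0)
        max_asa = MAX_ASA.get(res.aa1 or "", None)
        if max_asa:
            out[f"rsa_{tag}"] = out[f"res_sasa_{tag}"] / max_asa
            out[f"rsa_{tag}_known"] = 1.0
        else:
            out[f"rsa_{tag}"] = 0.0
            out[f"rsa_{tag}_known"] = 0.0
    for stem in ("site_area", "res_sasa", "rsa"):
        out[f"{stem}_dabs"] = abs(out[f"{stem}_wt"] - out[f"{stem}_mt"])
    out["rsa_known"] = min(out.pop("rsa_wt_known"), out.pop("rsa_mt_known"))
    return out


# ---------------------------------------------------------------------------
# half-sphere exposure


def _pseudo_cb(res: Residue) -> np.ndarray | None:
    cb = res.atom("CB")
    if cb is not None:
        return cb.pos
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        return None
    u = n.pos - ca.pos
    v = c.pos - ca.pos
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-8 or nv < 1e-8:
        return None
    d = -(u / nu + v / nv)
    nd = np.linalg.norm(d)
    if nd < 1e-8:
        return None
    return ca.pos + 1.53 * d / nd


def half_sphere_exposure(
    model: ComplexModel, pos: int, chain: str | None = None,
    radius: float = HSE_RADIUS,
) -> tuple[int, int] | None:
    """CA-neighbour counts in the CB-facing ('up') and opposite hemispheres."""
    res = model.residue(pos, chain)
    ca = res.atom("CA")
    cb = _pseudo_cb(res)
    if ca is None or cb is None:
        return None
    axis = cb - ca.pos
    na = np.linalg.norm(axis)
    if na < 1e-8:
        return None
    axis /= na
    up = down = 0
    for other in model.residues:
        if other.key == res.key:
            continue
        oca = other.atom("CA")
        if oca is None:
            continue
        v = oca.pos - ca.pos
        if np.linalg.norm(v) > radius:
            continue
        if np.dot(axis, v) > 0:
            up += 1
        else:
            down += 1
    return up, down


# ---------------------------------------------------------------------------
# hydrogen bond


def _polar_atoms(res: Residue) -> list[Atom]:
    return [a for a in res.atoms if a.element.upper() in ("N", "O")]


def hydrogen_bond_features(
    model: ComplexModel, pos: int, chain: str | None = None,
    cutoff: float = HBOND_CUTOFF,
) -> dict[str, float]:
    """Residue-ligand hydrogen bond presence, closest distance and type.

    Presence requires a donor/acceptor heavy-atom (N/O) pair within the
    cutoff; ``hb_backbone`` is 1 when the protein partner is a backbone
    N or O.
    """
    res = model.residue(pos, chain)
    best = None
    for pa in _polar_atoms(res):
        for la in _polar_atoms(model.ligand):
            d = float(np.linalg.norm(pa.pos - la.pos))
            if best is None or d < best[0]:
                best = (d, pa)
    if best is None:
        return {"hb_present": 0.0, "hb_dist": 0.0, "hb_backbone": 0.0}
    d, pa = best
    present = d <= cutoff
    return {
        "hb_present": float(present),
        "hb_dist": d if present else 0.0,
        "hb_backbone": float(pa.name in ("N", "O")) if present else 0.0,
    }


# ---------------------------------------------------------------------------
# environment encodings


def environment_encodings(
    model: ComplexModel, pos: int, chain: str | None = None,
    window: int = 5,
) -> dict[str, float]:
    """Concentric-shell, sequence-window and mutation-type encodings.

    Six annular shells (0,1], (1,2], ..., (5,6] A around the mutated
    residue flag amino-acid presence by nearest heavy-atom distance; the
    +/-``window`` sequence neighbourhood flags composition.
    """
    res = model.residue(pos, chain)
    ref = res.heavy_coords()
    out = {f"shell{k}_{aa}": 0.0 for k in range(1, 7) for aa in AA1}
    for other in model.residues:
        if other.key == res.key or other.aa1 is None:
            continue
        coords = other.heavy_coords()
        if coords.size == 0 or ref.size == 0:
            continue
        d = np.sqrt(
            ((coords[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if d <= 6.0:
            shell = max(1, int(math.ceil(d)))
            out[f"shell{shell}_{other.aa1}"] = 1.0
    idx = model.residues.index(res)
    for aa in AA1:
        out[f"seqwin_{aa}"] = 0.0
    lo = max(0, idx - window)
    hi = min(len(model.residues), idx + window + 1)
    truncated = (idx - lo != window) or (hi - idx - 1 != window)
    for other in model.residues[lo:hi]:
        if other.key != res.key and other.aa1 is not None:
            out[f"seqwin_{other.aa1}"] = 1.0
    out["seqwin_truncated"] = float(truncated)
    return out


def mutation_vector(ref_aa: str, alt_aa: str) -> dict[str, float]:
    """-1 at the wild-type amino acid, +1 at the mutant, 0 elsewhere."""
    out = {f"mut_{aa}": 0.0 for aa in AA1}
    out[f"mut_{ref_aa}"] = -1.0
    out[f"mut_{alt_aa}"] = 1.0
    return out


# ---------------------------------------------------------------------------
# secondary structure


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def secondary_structure(
    model: ComplexModel, pos: int, chain: str | None = None
) -> tuple[str, bool]:
    """Three-state label (H/E/C) from backbone phi/psi torsions.

    Helix: phi in (-120, -30) and psi in (-80, -5).  Strand: phi < -40 or
    phi > 160, with psi > 90 or psi < -160 (covers ideal beta and fully
    extended geometry).  Everything else, chain termini and incomplete
    backbones are coil; the second return value flags whether the torsions
    were computable.
    """
    res = model.residue(pos, chain)
    idx = model.residues.index(res)
    if idx == 0 or idx == len(model.residues) - 1:
        return "C", False
    prev, nxt = model.residues[idx - 1], model.residues[idx + 1]
    atoms = [prev.atom("C"), res.atom("N"), res.atom("CA"), res.atom("C"),
             nxt.atom("N")]
    if any(a is None for a in atoms):
        return "C", False
    phi = _dihedral(atoms[0].pos, atoms[1].pos, atoms[2].pos, atoms[3].pos)
    psi = _dihedral(atoms[1].pos, atoms[2].pos, atoms[3].pos, atoms[4].pos)
    if -120 < phi < -30 and -80 < psi < -5:
        return "H", True
    if (phi < -40 or phi > 160) and (psi > 90 or psi < -160):
        return "E", True
    return "C", True


# ---------------------------------------------------------------------------
# stability surrogate


def stability_change(
    wt: ComplexModel,
    mutation: AminoAcidMutation,
    rsa_wt: float | None = None,
    chain: str | None = None,
    backend=None,
) -> tuple[float | None, str]:
    """Folding stability change (ddG, kcal/mol) plus its sign category.

    The default surrogate scores the mutated site's burial against the
    hydropathy gain and the side-chain volume mismatch:

        ddG = burial * (0.6 * dKD / 9.0  -  1.8 * |dV| / 167.7)

    where burial = 1 - RSA(WT), dKD is the Kyte-Doolittle hydropathy
    difference (alt - ref) and |dV| the absolute residue-volume change.
    Burying extra hydrophobicity stabilises; volume mismatch destabilises.
    A pluggable ``backend(wt, mutation)`` may return a ddG instead; a
    backend failure or missing RSA yields the UNKNOWN category.
    """
    if backend is not None:
        try:
            val = backend(wt, mutation)
        except Exception:
            return None, "UNKNOWN"
        if val is None:
            return None, "UNKNOWN"
        return float(val), _ddg_category(float(val))
    if rsa_wt is None:
        try:
            per_res = _protein_sasa(wt)
            res = wt.residue(mutation.protein_position, chain)
            max_asa = MAX_ASA.get(res.aa1 or "")
            if not max_asa:
                return None, "UNKNOWN"
            rsa_wt = per_res.get(res.key, 0.0) / max_asa
        except (KeyError, ValueError):
            return None, "UNKNOWN"
    burial = float(np.clip(1.0 - rsa_wt, 0.0, 1.0))
    dkd = HYDROPATHY[mutation.alt_aa] - HYDROPATHY[mutation.ref_aa]
    dv = abs(VOLUME[mutation.alt_aa] - VOLUME[mutation.ref_aa])
    ddg = burial * (0.6 * dkd / 9.0 - 1.8 * dv / 167.7)
    return ddg, _ddg_category(ddg)


def _ddg_category(ddg: float) -> str:
    if ddg < 0:
        return "UNSTABLE"
    if ddg > 0:
        return "STABLE"
    return "STABLE"


# ---------------------------------------------------------------------------
# conservation


def conservation_score(alignment: list[str], column: int) -> float | None:
    """Mean pairwise BLOSUM62 score of a multiple-alignment column.

    ``column`` is 0-based.  Gaps are excluded; with a single non-gap
    residue the self-substitution score is returned; an all-gap column
    yields ``None``.
    """
    if not alignment:
        return None
    if column >= len(alignment[0]) or column < 0:
        raise IndexError(f"column {column} outside alignment width")
    residues = [s[column].upper() for s in alignment
                if s[column].upper() in AA1]
    if not residues:
        return None
    if len(residues) == 1:
        return float(_BLOSUM62[residues[0], residues[0]])
    total = 0.0
    npairs = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            total += float(_BLOSUM62[residues[i], residues[j]])
            npairs += 1
    return total / npairs


# ---------------------------------------------------------------------------
# structural alignment RMSD


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares superposition RMSD of P onto Q + per-pair deviations."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    P1 = P0 @ R.T
    dev = np.linalg.norm(P1 - Q0, axis=1)
    return float(np.sqrt((dev ** 2).mean())), dev


def alignment_rmsd(
    wt: ComplexModel, mt: ComplexModel, max_cycles: int = 10
) -> tuple[float, float]:
    """Raw and refined heavy-atom RMSD between WT and mutant structures.

    Shared atoms are matched by (chain, residue number, atom name).  The
    refined value iteratively rejects pairs deviating more than two
    standard deviations above the mean deviation, re-superposing until no
    pair is rejected (or fewer than three pairs remain).
    """
    wt_atoms = {(r.chain, r.resnum, a.name): a.pos
                for r in wt.residues for a in r.atoms if not a.is_hydrogen}
    shared = [
        (wt_atoms[(r.chain, r.resnum, a.name)], a.pos)
        for r in mt.residues for a in r.atoms
        if not a.is_hydrogen and (r.chain, r.resnum, a.name) in wt_atoms
    ]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared heavy atoms")
    P = np.array([s[1] for s in shared])
    Q = np.array([s[0] for s in shared])
    raw, dev = _kabsch_rmsd(P, Q)
    refined = raw
    for _ in range(max_cycles):
        thr = dev.mean() + 2.0 * dev.std()
        keep = dev <= thr
        if keep.all() or keep.sum() < 3:
            break
        P, Q = P[keep], Q[keep]
        refined, dev = _kabsch_rmsd(P, Q)
    return raw, refined


# ---------------------------------------------------------------------------
# ligand distances


def ligand_distance_features(
    model: ComplexModel, pos: int, chain: str | None = None
) -> dict[str, float] | None:
    """Min/max/mean distance from the residue CA to all ligand heavy atoms."""
    res = model.residue(pos, chain)
    ca = res.atom("CA")
    lig = model.ligand.heavy_coords()
    if ca is None or lig.size == 0:
        return None
    d = np.linalg.norm(lig - ca.pos, axis=1)
    return {"min": float(d.min()), "max": float(d.max()),
            "mean": float(d.mean())}


# ---------------------------------------------------------------------------
# charge / hydrophobicity


def charge_hydrophobicity_features(ref_aa: str, alt_aa: str) -> dict[str, float]:
    """Charge-annotated mutation vector and hydropathy delta."""
    out = {f"charge_{aa}": 0.0 for aa in AA1}
    out[f"charge_{ref_aa}"] = CHARGE.get(ref_aa, 0.0)
    out[f"charge_{alt_aa}"] = CHARGE.get(alt_aa, 0.0)
    out["dhydro"] = HYDROPATHY[alt_aa] - HYDROPATHY[ref_aa]
    return out


# ---------------------------------------------------------------------------
# salt bridges & disulfide


_ANION_ATOMS = {"D": ["OD1", "OD2"], "E": ["OE1", "OE2"]}
_CATION_SB_ATOMS = {"K": ["NZ"], "R": ["NH1", "NH2", "NE"]}


def _residue_sb_atoms(res: Residue) -> tuple[list[Atom], list[Atom]]:
    anions = [res.atom(n) for n in _ANION_ATOMS.get(res.aa1 or "", [])]
    cations = [res.atom(n) for n in _CATION_SB_ATOMS.get(res.aa1 or "", [])]
    return ([a for a in anions if a], [a for a in cations if a])


def salt_bridge_features(
    model: ComplexModel, pos: int, chain: str | None = None,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    ligand_groups: list[dict] | None = None,
) -> dict[str, float]:
    """Protein-protein salt-bridge count and protein-ligand presence.

    A protein salt bridge pairs an ASP/GLU carboxylate oxygen with a
    LYS/ARG cationic nitrogen at <= 4.0 A.  The ligand bridge pairs the
    residue's charged group with an oppositely charged ligand group (see
    :func:`ligand_charged_groups`); the group class is encoded as
    phosphate=0, carboxylate=1, guanidine=2, tert-amine=3, quart-amine=4
    (-1 when absent).
    """
    res = model.residue(pos, chain)
    an, cat = _residue_sb_atoms(res)
    count = 0
    for other in model.residues:
        if other.key == res.key:
            continue
        oan, ocat = _residue_sb_atoms(other)
        for a in an:
            for b in ocat:
                if np.linalg.norm(a.pos - b.pos) <= cutoff:
                    count += 1
        for a in cat:
            for b in oan:
                if np.linalg.norm(a.pos - b.pos) <= cutoff:
                    count += 1
    out = {"psb_count": float(count),
           "ligsb_present": 0.0, "ligsb_dist": 0.0, "ligsb_group": -1.0}
    if ligand_groups is None:
        ligand_groups = ligand_charged_groups(model.ligand)
    group_code = {"phosphate": 0, "carboxylate": 1, "guanidine": 2,
                  "tert-amine": 3, "quart-amine": 4}
    best = None
    for g in ligand_groups:
        partners = cat if g["charge"] < 0 else an
        for a in partners:
            for gp in g["coords"]:
                d = float(np.linalg.norm(a.pos - gp))
                if d <= cutoff and (best is None or d < best[0]):
                    best = (d, g["kind"])
    if best:
        out.update(ligsb_present=1.0, ligsb_dist=best[0],
                   ligsb_group=float(group_code[best[1]]))
    return out


def disulfide_check(
    model: ComplexModel, pos: int, chain: str | None = None,
    window: tuple[float, float] = DISULFIDE_RANGE,
) -> bool:
    """True iff the residue is CYS with an SG-SG pair inside the window."""
    res = model.residue(pos, chain)
    if res.aa1 != "C":
        return False
    sg = res.atom("SG")
    if sg is None:
        return False
    lo, hi = window
    for other in model.residues:
        if other.key == res.key or other.aa1 != "C":
            continue
        osg = other.atom("SG")
        if osg is None:
            continue
        if lo <= np.linalg.norm(sg.pos - osg.pos) <= hi:
            return True
    return False


# ---------------------------------------------------------------------------
# ligand typing


def ligand_bonds(ligand: Residue, scale: float = 1.25) -> list[tuple[int, int]]:
    """Distance-inferred covalent bonds between ligand heavy atoms."""
    atoms = [a for a in ligand.atoms if not a.is_hydrogen]
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = _COV_RADII.get(atoms[i].element.upper(), 0.77)
            rj = _COV_RADII.get(atoms[j].element.upper(), 0.77)
            if np.linalg.norm(atoms[i].pos - atoms[j].pos) <= scale * (ri + rj):
                bonds.append((i, j))
    return bonds


def ligand_aromatic_rings(
    ligand: Residue, planarity_tol: float = 0.15
) -> list[np.ndarray]:
    """Planar 5/6-membered C/N/O/S cycles; returns member-coordinate arrays."""
    atoms = [a for a in ligand.atoms if not a.is_hydrogen]
    g = nx.Graph(ligand_bonds(ligand))
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if any(atoms[i].element.upper() not in ("C", "N", "O", "S")
               for i in cycle):
            continue
        coords = np.array([atoms[i].pos for i in cycle])
        centered = coords - coords.mean(axis=0)
        _, s, _ = np.linalg.svd(centered)
        if s[-1] / math.sqrt(len(cycle)) <= planarity_tol:
            rings.append(coords)
    return rings


def ligand_charged_groups(ligand: Residue) -> list[dict]:
    """Charged functional groups perceived from ligand connectivity.

    phosphate (P with >=3 O), carboxylate (C with 2 terminal O), guanidine
    (C with 3 N), tert-amine (N with 3 bonds), quart-amine (N with 4).
    """
    atoms = [a for a in ligand.atoms if not a.is_hydrogen]
    g = nx.Graph(ligand_bonds(ligand))
    groups = []
    for i, a in enumerate(atoms):
        nbrs = [atoms[j] for j in g.neighbors(i)] if i in g else []
        el = a.element.upper()
        n_o = sum(1 for b in nbrs if b.element.upper() == "O")
        n_n = sum(1 for b in nbrs if b.element.upper() == "N")
        coords = [a.pos] + [b.pos for b in nbrs]
        if el == "P" and n_o >= 3:
            groups.append({"kind": "phosphate", "charge": -1, "coords": coords})
        elif el == "C" and n_o == 2 and n_n == 0:
            groups.append({"kind": "carboxylate", "charge": -1,
                           "coords": coords})
        elif el == "C" and n_n == 3:
            groups.append({"kind": "guanidine", "charge": 1, "coords": coords})
        elif el == "N" and len(nbrs) == 4:
            groups.append({"kind": "quart-amine", "charge": 1,
                           "coords": coords})
        elif el == "N" and len(nbrs) == 3 and all(
                b.element.upper() == "C" for b in nbrs):
            groups.append({"kind": "tert-amine", "charge": 1,
                           "coords": coords})
    return groups


# ---------------------------------------------------------------------------
# interaction fingerprint


@dataclass
class InteractionFingerprint:
    """Per-type residue-ligand interaction detections."""

    entries: dict[str, dict] = field(default_factory=dict)
    known: bool = True

    def present(self, kind: str) -> bool:
        return self.entries.get(kind, {}).get("present", False)

    def distance(self, kind: str) -> float:
        return self.entries.get(kind, {}).get("distance", 0.0)


def _residue_rings(res: Residue) -> list[np.ndarray]:
    rings = []
    for names in AROMATIC_RINGS.get(res.aa1 or "", []):
        atoms = [res.atom(n) for n in names]
        if all(a is not None for a in atoms):
            rings.append(np.array([a.pos for a in atoms]))
    return rings


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def ligand_interaction_fingerprint(
    model: ComplexModel, pos: int, chain: str | None = None
) -> InteractionFingerprint:
    """Halogen-bond, pi-stacking, pi-cation, water-bridge and hydrophobic
    detections between one residue and the ligand."""
    res = model.residue(pos, chain)
    lig = model.ligand
    atoms = [a for a in lig.atoms if not a.is_hydrogen]
    fp = InteractionFingerprint()
    bonds = ligand_bonds(lig)
    g = nx.Graph(bonds)

    # halogen bonds: ligand C-X ... residue O/N/S acceptor
    best = None
    acceptors = [a for a in res.atoms if a.element.upper() in ("O", "N", "S")]
    for i, a in enumerate(atoms):
        if a.element.upper() not in HALOGENS or i not in g:
            continue
        carbons = [atoms[j] for j in g.neighbors(i)
                   if atoms[j].element.upper() == "C"]
        for acc in acceptors:
            d = float(np.linalg.norm(a.pos - acc.pos))
            if d > HALOGEN_CUTOFF:
                continue
            for cat in carbons:
                v1 = cat.pos - a.pos
                v2 = acc.pos - a.pos
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                if ang >= HALOGEN_MIN_ANGLE and (best is None or d < best[0]):
                    best = (d, a.name, acc.name)
    fp.entries["halogen"] = (
        {"present": True, "distance": best[0], "groups": best[1:]}
        if best else {"present": False}
    )

    # pi-stacking
    best = None
    lig_rings = ligand_aromatic_rings(lig)
    for rr in _residue_rings(res):
        rn = _ring_normal(rr)
        rc = rr.mean(axis=0)
        for lr in lig_rings:
            lc = lr.mean(axis=0)
            d = float(np.linalg.norm(rc - lc))
            if d > PISTACK_CUTOFF:
                continue
            ln = _ring_normal(lr)
            cosang = abs(float(np.dot(rn, ln)))
            ang = math.degrees(math.acos(np.clip(cosang, 0, 1)))
            parallel = ang <= PISTACK_PARALLEL_MAX
            tshape = PISTACK_TSHAPE_RANGE[0] <= ang <= PISTACK_TSHAPE_RANGE[1]
            if (parallel or tshape) and (best is None or d < best[0]):
                best = (d, "parallel" if parallel else "t-shaped")
    fp.entries["pistack"] = (
        {"present": True, "distance": best[0], "groups": (best[1],)}
        if best else {"present": False}
    )

    # pi-cation: residue ring vs ligand cation, or ligand ring vs residue cation
    best = None
    lig_cations = [g_["coords"][0] for g_ in ligand_charged_groups(lig)
                   if g_["charge"] > 0]
    for rr in _residue_rings(res):
        rc = rr.mean(axis=0)
        for cpos in lig_cations:
            d = float(np.linalg.norm(rc - cpos))
            if d <= PICATION_CUTOFF and (best is None or d < best[0]):
                best = (d,)
    res_cations = [res.atom(n) for n in CATION_ATOMS.get(res.aa1 or "", [])]
    for lr in lig_rings:
        lc = lr.mean(axis=0)
        for a in res_cations:
            if a is None:
                continue
            d = float(np.linalg.norm(lc - a.pos))
            if d <= PICATION_CUTOFF and (best is None or d < best[0]):
                best = (d,)
    fp.entries["pication"] = (
        {"present": True, "distance": best[0]} if best else {"present": False}
    )

    # water bridge
    best = None
    res_polar = _polar_atoms(res)
    lig_polar = _polar_atoms(lig)
    for w in model.waters:
        wo = next((a for a in w.atoms if a.element.upper() == "O"), None)
        if wo is None:
            continue
        d_res = min((float(np.linalg.norm(wo.pos - a.pos))
                     for a in res_polar), default=np.inf)
        d_lig = min((float(np.linalg.norm(wo.pos - a.pos))
                     for a in lig_polar), default=np.inf)
        if d_res <= WATER_BRIDGE_CUTOFF and d_lig <= WATER_BRIDGE_CUTOFF:
            score = max(d_res, d_lig)
            if best is None or score < best[0]:
                best = (score,)
    fp.entries["water_bridge"] = (
        {"present": True, "distance": best[0]} if best else {"present": False}
    )

    # hydrophobic contacts: residue side-chain carbons vs apolar ligand carbons
    best = None
    side_c = [a for a in res.atoms
              if a.element.upper() == "C" and a.name not in ("CA", "C")]
    apolar = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "C":
            continue
        nbrs = [atoms[j] for j in g.neighbors(i)] if i in g else []
        if not any(b.element.upper() in ("N", "O") for b in nbrs):
            apolar.append(a)
    for a in side_c:
        for b in apolar:
            d = float(np.linalg.norm(a.pos - b.pos))
            if d <= HYDROPHOBIC_CUTOFF and (best is None or d < best[0]):
                best = (d,)
    fp.entries["hydrophobic"] = (
        {"present": True, "distance": best[0]} if best else {"present": False}
    )
    return fp
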