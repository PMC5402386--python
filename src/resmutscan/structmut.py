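"""Protein-ligand complexes, binding sites and mutant model building.

The drug binding site is the set of residues with at least one heavy atom
within a fixed cutoff (default 9.5 A) of any heavy atom of the
co-crystallised ligand.  Mutant structural models are produced by a
pluggable backend; the default ``graft`` backend keeps the backbone fixed
and replaces the side chain with an idealised stick geometry, which keeps
every other atom of the complex untouched and is fully deterministic.
"""

from __future__ import annotations

import copy
import subprocess
from dataclasses import dataclass, field

import gemmi
import numpy as np

from ._aa_data import (
    AA_1TO3,
    AA_3TO1,
    BACKBONE_ATOMS,
    SIDECHAIN_ATOMS,
)
from .sigcontext import AminoAcidMutation, CodingSequence, enumerate_missense_snvs

WATER_NAMES = {"HOH", "WAT", "DOD"}

DEFAULT_SITE_CUTOFF = 9.5


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    chain: str
    resnum: int
    name: str  # 3-letter (protein) or het code
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def aa1(self) -> str | None:
        return AA_3TO1.get(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.pos for a in self.atoms if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.resnum)


@dataclass
class ComplexModel:
    """A protein with one named ligand and (optionally) crystal waters."""

    residues: list[Residue]
    ligand: Residue
    waters: list[Residue] = field(default_factory=list)
    source: str = ""

    def residue(self, resnum: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.resnum == resnum and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"residue {chain or ''}{resnum} not in model")

    @property
    def sequence(self) -> str:
        return "".join(r.aa1 or "X" for r in self.residues)


@dataclass
class BindingSite:
    residues: list[Residue]
    cutoff: float = DEFAULT_SITE_CUTOFF

    @property
    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]


@dataclass
class MutantModel:
    spec: AminoAcidMutation
    structure: ComplexModel
    backend: str = "graft"


class LigandNotFoundError(KeyError):
    pass


# ---------------------------------------------------------------------------
# I/O


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep blank/'A' altlocs; highest occupancy wins duplicated names."""
    chosen: dict[str, gemmi.Atom] = {}
    for a in res:
        alt = a.altloc if a.altloc not in ("\x00",) else ""
        if alt not in ("", "A"):
            continue
        prev = chosen.get(a.name)
        if prev is None or a.occ > prev.occ:
            chosen[a.name] = a
    return list(chosen.values())


def load_complex(path, ligand_id: str) -> ComplexModel:
    """Parse a PDB file into a :class:`ComplexModel`.

    Protein residues, the named heteroatom group and waters are separated;
    other het groups are ignored but reported if ``ligand_id`` is absent.
    """
    st = gemmi.read_structure(str(path))
    residues: list[Residue] = []
    waters: list[Residue] = []
    ligand_parts: list[Residue] = []
    het_seen: set[str] = set()
    for chain in st[0]:
        for res in chain:
            atoms = [
                Atom(a.name, a.element.name.upper(),
                     np.array([a.pos.x, a.pos.y, a.pos.z]), a.occ, a.b_iso)
                for a in _pick_altloc(res)
            ]
            rr = Residue(chain.name, res.seqid.num, res.name, atoms)
            if res.name in WATER_NAMES:
                waters.append(rr)
            elif res.name in AA_3TO1 and res.het_flag != "H":
                residues.append(rr)
            else:
                het_seen.add(res.name)
                if res.name == ligand_id:
                    rr.het = True
                    ligand_parts.append(rr)
    if not ligand_parts:
        raise LigandNotFoundError(
            f"ligand {ligand_id!r} not found in {path}; heteroatom groups "
            f"present: {sorted(het_seen) or 'none'}"
        )
    ligand = ligand_parts[0]
    for extra in ligand_parts[1:]:
        ligand.atoms.extend(extra.atoms)
    for r in residues + [ligand] + waters:
        for a in r.atoms:
            if not np.all(np.isfinite(a.pos)):
                raise ValueError(f"non-finite coordinates in {path}")
    return ComplexModel(residues, ligand, waters, source=str(path))


def to_gemmi(model: ComplexModel) -> gemmi.Structure:
    st = gemmi.Structure()
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(res: Residue, het: bool) -> None:
        ch = chains.setdefault(res.chain, gemmi.Chain(res.chain))
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.resnum, " ")
        gr.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*map(float, a.pos))
            ga.occ = float(a.occ)
            ga.b_iso = float(a.b)
            gr.add_atom(ga)
        ch.add_residue(gr)

    for r in model.residues:
        add(r, het=False)
    add(model.ligand, het=True)
    for w in model.waters:
        add(w, het=True)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    return st


def write_complex(model: ComplexModel, path) -> None:
    to_gemmi(model).write_pdb(str(path))


# ---------------------------------------------------------------------------
# binding site


def define_binding_site(
    model: ComplexModel, cutoff: float = DEFAULT_SITE_CUTOFF
) -> BindingSite:
    """Residues with >=1 heavy atom within ``cutoff`` A of a ligand heavy atom."""
    lig = model.ligand.heavy_coords()
    if lig.size == 0:
        raise ValueError("ligand has no heavy atoms")
    members = []
    for res in model.residues:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= cutoff * cutoff:
            members.append(res)
    return BindingSite(members, cutoff)


def enumerate_binding_site_mutants(
    site: BindingSite,
    cds: CodingSequence,
    offset: int = 0,
) -> tuple[list[AminoAcidMutation], list[tuple[int, str]]]:
    """Missense SNV-reachable mutations over the binding-site residues.

    ``offset`` maps structure residue numbers to CDS protein positions
    (``protein_position = resnum - offset``).  Residues whose mapped codon
    does not translate to the structure's amino-acid type are skipped and
    reported rather than fatal.
    """
    mutations: list[AminoAcidMutation] = []
    skipped: list[tuple[int, str]] = []
    for res in site.residues:
        pos = res.resnum - offset
        if not 1 <= pos <= cds.protein_length:
            skipped.append((res.resnum, "outside CDS"))
            continue
        if res.aa1 != cds.protein_seq[pos - 1]:
            skipped.append(
                (res.resnum,
                 f"structure {res.aa1} vs CDS {cds.protein_seq[pos - 1]}")
            )
            continue
        mutations.extend(enumerate_missense_snvs(cds, [pos]))
    return mutations, skipped


# ---------------------------------------------------------------------------
# mutant model building


def _graft_sidechain(res: Residue, alt_aa: str) -> Residue:
    """Replace a side chain with an idealised stick geometry.

    CB sits at the tetrahedral position implied by N/CA/C; further heavy
    atoms extend outward along the CA->CB direction with a small
    alternating perpendicular offset.  Backbone atoms are untouched.
    """
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {res.resnum}: incomplete backbone")
    new = Residue(res.chain, res.resnum, AA_1TO3[alt_aa],
                  [copy.deepcopy(res.atom(x)) for x in BACKBONE_ATOMS
                   if res.atom(x) is not None])
    names = SIDECHAIN_ATOMS[alt_aa]
    if not names:
        return new
    # tetrahedral CB direction: opposite the N/C bisector, tilted off-plane
    u = n.pos - ca.pos
    v = c.pos - ca.pos
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    perp = np.cross(u, v)
    nb, npp = np.linalg.norm(bisector), np.linalg.norm(perp)
    if nb < 1e-8 or npp < 1e-8:
        raise ValueError(f"residue {res.resnum}: degenerate backbone geometry")
    d = bisector / nb * np.cos(np.deg2rad(54.75)) + perp / npp * np.sin(
        np.deg2rad(54.75))
    d /= np.linalg.norm(d)
    side = np.cross(d, perp / npp)
    side /= np.linalg.norm(side)
    cb = ca.pos + 1.53 * d
    for i, name in enumerate(names):
        if i == 0:
            pos = cb
        else:
            pos = cb + 1.4 * i * d + 0.45 * (i % 2) * side
        new.atoms.append(Atom(name, name[0], pos))
    return new


def build_mutant_model(
    model: ComplexModel,
    spec: AminoAcidMutation,
    backend: str = "graft",
    offset: int = 0,
    chain: str | None = None,
    external_command: list[str] | None = None,
) -> MutantModel:
    """Build a single-point mutant structure.

    ``graft`` (default) is the in-house backbone-preserving backend;
    ``external`` shells out to a user-supplied modelling command taking
    ``WT.pdb POS ALT OUT.pdb`` arguments.
    """
    resnum = spec.protein_position + offset
    res = model.residue(resnum, chain)
    if res.aa1 != spec.ref_aa:
        raise ValueError(
            f"residue {resnum} is {res.aa1}, spec expects {spec.ref_aa}"
        )
    if res.aa1 == spec.alt_aa:
        raise ValueError(f"{spec}: not a mutation (alt equals structure type)")
    if backend == "graft":
        mutated = copy.deepcopy(model)
        target = mutated.residue(resnum, chain)
        new = _graft_sidechain(target, spec.alt_aa)
        mutated.residues[mutated.residues.index(target)] = new
        return MutantModel(spec, mutated, backend="graft")
    if backend == "external":
        if not external_command:
            raise ValueError("external backend requires a command template")
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as td:
            wt = Path(td) / "wt.pdb"
            out = Path(td) / "mt.pdb"
            write_complex(model, wt)
            cmd = external_command + [
                str(wt), str(spec.protein_position), spec.alt_aa, str(out)
            ]
            try:
                subprocess.run(cmd, check=True, capture_output=True)
            except (OSError, subprocess.CalledProcessError) as exc:
                raise RuntimeError(
                    f"external modelling backend failed for {spec}: {exc}"
                ) from exc
            mutated = load_complex(out, model.ligand.name)
        return MutantModel(spec, mutated, backend="external")
    raise ValueError(f"unknown modelling backend {backend!r}")


# ---------------------------------------------------------------------------
# score export


def export_residue_scores_to_bfactor(
    model: ComplexModel, scores: dict[int, float] | dict[tuple[str, int], float],
    path,
) -> None:
    """Write the model with per-residue scores in the B-factor column.

    Scores may be keyed by residue number or (chain, resnum); unscored
    residues (and ligand/waters) get 0.00.  Values are clipped to the PDB
    field range [-9.99, 999.99].
    """
    out = copy.deepcopy(model)
    for r in out.residues + [out.ligand] + out.waters:
        val = scores.get(r.resnum)
        if val is None:
            val = scores.get((r.chain, r.resnum), 0.0)
        val = float(np.clip(val, -9.99, 999.99))
        for a in r.atoms:
            a.b = val
    write_complex(out, path)
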