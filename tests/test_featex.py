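"""Feature extraction: geometry detectors, encodings and assembly."""

import math

import numpy as np
import pytest

from resmutscan import featex as fx
from resmutscan import schema as sch
from resmutscan._aa_data import AA1, HYDROPATHY, VDW_RADII
from resmutscan.fixtures import build_toy_chain, _ligand_near
from resmutscan.sigcontext import AminoAcidMutation, SnvInContext
from resmutscan.structmut import (
    Atom,
    BindingSite,
    ComplexModel,
    Residue,
    build_mutant_model,
    define_binding_site,
)


def _mut(pos, ref, alt):
    return AminoAcidMutation(pos, ref, alt,
                             (SnvInContext(1, "A", "C", "N", "N"),))


def _single_atom_complex(element="C", lig_dist=50.0):
    res = Residue("A", 1, "ALA", [Atom("CA", element, np.zeros(3))])
    lig = Residue("A", 900, "LIG",
                  [Atom("C1", "C", np.array([lig_dist, 0.0, 0.0]))], het=True)
    return ComplexModel([res], lig)


def _grid_sasa_oracle(coords, elements, probe=1.4, n_theta=140):
    """Independent latitude-band surface integrator (not point sampling)."""
    radii = np.array([VDW_RADII.get(e.upper(), 1.7) + probe
                      for e in elements])
    total = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        acc = 0.0
        for t in range(n_theta):
            theta = math.pi * (t + 0.5) / n_theta
            band = 2 * math.pi * r * r * math.sin(theta) * (math.pi / n_theta)
            n_phi = max(8, int(2 * n_theta * math.sin(theta)))
            exposed = 0
            for p in range(n_phi):
                phi = 2 * math.pi * (p + 0.5) / n_phi
                pt = c + r * np.array([
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                    math.cos(theta)])
                buried = any(
                    np.linalg.norm(pt - coords[j]) <= radii[j]
                    for j in range(len(coords)) if j != i)
                if not buried:
                    exposed += 1
            acc += band * exposed / n_phi
        total[i] = acc
    return total


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        area = fx.shrake_rupley_sasa(np.zeros((1, 3)), ["C"])
        assert area[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2,
                                        rel=1e-9)

    def test_two_atom_union_matches_band_integrator(self, rng):
        coords = np.array([[0.0, 0.0, 0.0], [2.2, 0.4, -0.3],
                           [1.0, 1.8, 0.9]])
        elements = ["C", "N", "O"]
        got = fx.shrake_rupley_sasa(coords, elements)
        oracle = _grid_sasa_oracle(coords, elements)
        assert np.allclose(got, oracle, rtol=0.02)

    def test_isolated_alanine_matches_band_integrator(self):
        res = build_toy_chain("A")[0]
        coords = np.array([a.pos for a in res.atoms])
        elements = [a.element for a in res.atoms]
        got = fx.shrake_rupley_sasa(coords, elements)
        oracle = _grid_sasa_oracle(coords, elements)
        assert got.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_buried_residue_rsa_near_zero(self):
        # central atom fully enclosed by a shell of atoms
        shell = fx._fibonacci_sphere(60) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = fx.shrake_rupley_sasa(coords, ["C"] * len(coords))
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_identity_pair_zero_deltas(self, toy_complex):
        site = define_binding_site(toy_complex)
        pos = site.resnums[0]
        out = fx.surface_accessibility_features(
            toy_complex, toy_complex, site, pos)
        assert out["site_area_dabs"] == 0.0
        assert out["res_sasa_dabs"] == 0.0
        assert out["rsa_dabs"] == 0.0


class TestHalfSphereExposure:
    def test_isolated_residue_zero(self):
        model = ComplexModel(build_toy_chain("A"),
                             Residue("A", 900, "LIG",
                                     [Atom("C1", "C", np.full(3, 99.0))],
                                     het=True))
        assert fx.half_sphere_exposure(model, 1) == (0, 0)

    def test_hand_geometry_partition(self):
        # neighbours placed explicitly on both sides of the CA->CB axis
        res = Residue("A", 2, "ALA", [
            Atom("N", "N", np.array([-1.2, -0.9, 0.0])),
            Atom("CA", "C", np.zeros(3)),
            Atom("C", "C", np.array([1.3, -0.5, 0.0])),
            Atom("CB", "C", np.array([0.0, 1.5, 0.0])),
        ])
        up_nbr = Residue("A", 1, "GLY",
                         [Atom("CA", "C", np.array([0.0, 5.0, 0.0]))])
        dn_nbr = Residue("A", 3, "GLY",
                         [Atom("CA", "C", np.array([0.0, -5.0, 0.0]))])
        far = Residue("A", 4, "GLY",
                      [Atom("CA", "C", np.array([0.0, 20.0, 0.0]))])
        model = ComplexModel(
            [up_nbr, res, dn_nbr, far],
            Residue("A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))],
                    het=True))
        assert fx.half_sphere_exposure(model, 2) == (1, 1)

    def test_glycine_pseudo_cb_finite(self):
        chain = build_toy_chain("GAG")
        model = ComplexModel(chain, Residue(
            "A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))], het=True))
        res = fx.half_sphere_exposure(model, 1)
        assert res is not None and all(isinstance(x, int) for x in res)


class TestHydrogenBond:
    def test_boundary_flip(self, complex_bundle):
        from resmutscan.structmut import load_complex

        inc = load_complex(complex_bundle.boundary_pdbs["hbond_3p19"], "LIG")
        out = load_complex(complex_bundle.boundary_pdbs["hbond_3p21"], "LIG")
        assert fx.hydrogen_bond_features(inc, 1)["hb_present"] == 1.0
        assert fx.hydrogen_bond_features(out, 1)["hb_present"] == 0.0

    def test_carbon_contact_not_a_bond(self):
        res = Residue("A", 1, "ALA", [Atom("CB", "C", np.zeros(3))])
        lig = Residue("A", 900, "LIG",
                      [Atom("C1", "C", np.array([2.9, 0.0, 0.0]))], het=True)
        out = fx.hydrogen_bond_features(ComplexModel([res], lig), 1)
        assert out["hb_present"] == 0.0

    def test_closest_pair_reported(self):
        res = Residue("A", 1, "SER", [
            Atom("N", "N", np.zeros(3)),
            Atom("OG", "O", np.array([0.0, 5.0, 0.0])),
        ])
        lig = Residue("A", 900, "LIG", [
            Atom("O1", "O", np.array([3.1, 0.0, 0.0])),
            Atom("O2", "O", np.array([0.0, 7.9, 0.0])),
        ], het=True)
        out = fx.hydrogen_bond_features(ComplexModel([res], lig), 1)
        assert out["hb_dist"] == pytest.approx(2.9)  # OG-O2 pair
        assert out["hb_backbone"] == 0.0


class TestEnvironment:
    def test_isolated_residue_zero_shells(self):
        model = ComplexModel(build_toy_chain("A"), Residue(
            "A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))], het=True))
        out = fx.environment_encodings(model, 1)
        assert all(out[f"shell{k}_{aa}"] == 0.0
                   for k in range(1, 7) for aa in AA1)

    def test_neighbour_binned_in_correct_shell(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])
        nbr = Residue("A", 2, "VAL",
                      [Atom("CA", "C", np.array([2.5, 0.0, 0.0]))])
        model = ComplexModel([res, nbr], Residue(
            "A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))], het=True))
        out = fx.environment_encodings(model, 1)
        assert out["shell3_V"] == 1.0
        assert sum(out[f"shell{k}_V"] for k in range(1, 7)) == 1.0

    def test_sequence_window_truncation_flagged(self):
        chain = build_toy_chain("AVLIKD")
        model = ComplexModel(chain, Residue(
            "A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))], het=True))
        out = fx.environment_encodings(model, 2)
        assert out["seqwin_truncated"] == 1.0
        assert out["seqwin_V"] == 0.0  # V is the mutated position itself
        assert out["seqwin_A"] == 1.0 and out["seqwin_D"] == 1.0

    def test_mutation_vector_encoding(self):
        out = fx.mutation_vector("L", "M")
        assert out["mut_L"] == -1.0 and out["mut_M"] == 1.0
        assert sum(v != 0 for v in out.values()) == 2


def _chain_from_torsions(n, phi, psi):
    """NeRF-style chain builder from ideal backbone internal coordinates."""
    def place(a, b, c, bond, angle, torsion):
        ab = b - a
        bc = c - b
        bc_n = bc / np.linalg.norm(bc)
        n_vec = np.cross(ab, bc)
        n_vec /= np.linalg.norm(n_vec)
        m = np.cross(n_vec, bc_n)
        ang = math.radians(angle)
        tor = math.radians(torsion)
        d = np.array([-bond * math.cos(ang),
                      bond * math.sin(ang) * math.cos(tor),
                      bond * math.sin(ang) * math.sin(tor)])
        return c + d[0] * bc_n + d[1] * m + d[2] * n_vec

    # seed atoms
    atoms = [np.array([0.0, 0.0, 0.0]),            # N1
             np.array([1.458, 0.0, 0.0]),          # CA1
             None]                                  # C1 set below
    atoms[2] = place(np.array([0.0, 1.0, 0.0]), atoms[0], atoms[1],
                     1.525, 111.0, phi)
    coords = [("N", atoms[0]), ("CA", atoms[1]), ("C", atoms[2])]
    for i in range(1, n):
        n_i = place(coords[-3][1], coords[-2][1], coords[-1][1],
                    1.329, 117.0, psi)
        ca_i = place(coords[-2][1], coords[-1][1], n_i, 1.458, 121.0, 180.0)
        c_i = place(coords[-1][1], n_i, ca_i, 1.525, 111.0, phi)
        coords += [("N", n_i), ("CA", ca_i), ("C", c_i)]
    residues = []
    for i in range(n):
        names = coords[3 * i: 3 * i + 3]
        residues.append(Residue("A", i + 1, "ALA", [
            Atom(nm, nm[0], pos) for nm, pos in names]))
    return ComplexModel(residues, Residue(
        "A", 900, "LIG", [Atom("C1", "C", np.full(3, 99.0))], het=True))


class TestSecondaryStructure:
    def test_ideal_alpha_helix(self):
        model = _chain_from_torsions(5, phi=-57.0, psi=-47.0)
        label, known = fx.secondary_structure(model, 3)
        assert (label, known) == ("H", True)

    def test_ideal_beta_strand(self):
        model = _chain_from_torsions(5, phi=-139.0, psi=135.0)
        label, known = fx.secondary_structure(model, 3)
        assert (label, known) == ("E", True)

    def test_short_fragment_is_coil_unknown(self):
        model = _chain_from_torsions(2, phi=-57.0, psi=-47.0)
        label, known = fx.secondary_structure(model, 2)
        assert (label, known) == ("C", False)


class TestStability:
    def test_sign_categories(self):
        assert fx._ddg_category(-1.3) == "UNSTABLE"
        assert fx._ddg_category(0.2) == "STABLE"

    def test_backend_failure_unknown(self, toy_complex):
        val, cat = fx.stability_change(
            toy_complex, _mut(5, "T", "M"), backend=lambda *a: None)
        assert val is None and cat == "UNKNOWN"

    def test_surrogate_buried_hydrophilic_to_hydrophobic_stabilises(
            self, toy_complex):
        val, cat = fx.stability_change(toy_complex, _mut(5, "T", "I"),
                                       rsa_wt=0.0)
        # same-volume-ish gain in hydropathy at full burial
        assert val is not None
        manual = 1.0 * (0.6 * (HYDROPATHY["I"] - HYDROPATHY["T"]) / 9.0
                        - 1.8 * abs(166.7 - 116.1) / 167.7)
        assert val == pytest.approx(manual)


class TestConservation:
    def test_identity_column(self):
        assert fx.conservation_score(["LLL", "LAA"], 0) == 4.0

    def test_two_sequence_column(self):
        assert fx.conservation_score(["L", "M"], 0) == 2.0

    def test_random_column_matches_nested_loop(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        col = [str(rng.choice(list(AA1))) for _ in range(5)]
        expected = np.mean([
            blosum[col[i], col[j]]
            for i in range(5) for j in range(i + 1, 5)])
        got = fx.conservation_score(["".join(col)[i] for i in range(5)], 0)
        assert got == pytest.approx(float(expected))

    def test_all_gap_column(self):
        assert fx.conservation_score(["-", "-"], 0) is None


class TestAlignmentRmsd:
    def test_identical_structures(self, toy_complex):
        raw, refined = fx.alignment_rmsd(toy_complex, toy_complex)
        assert raw == pytest.approx(0.0, abs=1e-9)
        assert refined == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_complex, rng):
        import copy

        from scipy.spatial.transform import Rotation

        moved = copy.deepcopy(toy_complex)
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        for r in moved.residues + [moved.ligand]:
            for a in r.atoms:
                a.pos = R @ a.pos + t
        raw, refined = fx.alignment_rmsd(toy_complex, moved)
        assert raw == pytest.approx(0.0, abs=1e-8)

    def test_outlier_rejection_reduces_rmsd(self, toy_complex):
        import copy

        moved = copy.deepcopy(toy_complex)
        moved.residues[0].atoms[0].pos = \
            moved.residues[0].atoms[0].pos + np.array([8.0, 0.0, 0.0])
        raw, refined = fx.alignment_rmsd(toy_complex, moved)
        assert refined < raw

    def test_too_few_atoms(self):
        a = ComplexModel(
            [Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])],
            Residue("A", 900, "LIG", [Atom("C1", "C", np.ones(3))], het=True))
        with pytest.raises(ValueError, match="3 shared"):
            fx.alignment_rmsd(a, a)


class TestLigandDistances:
    def test_single_atom_ligand(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])
        lig = Residue("A", 900, "LIG",
                      [Atom("C1", "C", np.array([5.0, 0.0, 0.0]))], het=True)
        out = fx.ligand_distance_features(ComplexModel([res], lig), 1)
        assert (out["min"], out["max"], out["mean"]) == (5.0, 5.0, 5.0)

    def test_two_atom_arithmetic(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])
        lig = Residue("A", 900, "LIG", [
            Atom("C1", "C", np.array([4.0, 0.0, 0.0])),
            Atom("C2", "C", np.array([0.0, 8.0, 0.0]))], het=True)
        out = fx.ligand_distance_features(ComplexModel([res], lig), 1)
        assert (out["min"], out["max"], out["mean"]) == (4.0, 8.0, 6.0)

    def test_matches_brute_force(self, rng):
        from conftest import random_toy_complex

        model = random_toy_complex(rng)
        pos = model.residues[2].resnum
        ca = model.residues[2].atom("CA").pos
        d = [float(np.linalg.norm(a.pos - ca))
             for a in model.ligand.atoms if not a.is_hydrogen]
        out = fx.ligand_distance_features(model, pos)
        assert out["min"] == pytest.approx(min(d))
        assert out["max"] == pytest.approx(max(d))
        assert out["mean"] == pytest.approx(sum(d) / len(d))


class TestChargeHydrophobicity:
    def test_charge_reversal(self):
        out = fx.charge_hydrophobicity_features("D", "K")
        assert out["charge_D"] == -1.0 and out["charge_K"] == 1.0

    def test_hydropathy_delta_from_table(self):
        out = fx.charge_hydrophobicity_features("I", "L")
        assert out["dhydro"] == pytest.approx(HYDROPATHY["L"] - HYDROPATHY["I"])


class TestSaltBridgesAndDisulfide:
    def test_boundary_flip(self, complex_bundle):
        from resmutscan.structmut import load_complex

        inc = load_complex(complex_bundle.boundary_pdbs["salt_3p9"], "LIG")
        out = load_complex(complex_bundle.boundary_pdbs["salt_4p1"], "LIG")
        assert fx.salt_bridge_features(inc, 1)["psb_count"] == 1.0
        assert fx.salt_bridge_features(out, 1)["psb_count"] == 0.0

    def test_neutral_residue_zero(self, toy_complex):
        pos = next(r.resnum for r in toy_complex.residues
                   if r.aa1 not in "DEKR")
        assert fx.salt_bridge_features(toy_complex, pos)["psb_count"] == 0.0

    def test_ligand_carboxylate_near_arginine(self):
        arg = build_toy_chain("R")[0]
        nh1 = arg.atom("NH1")
        # carboxylate: C bonded to two terminal O, anion near the guanidine
        c = nh1.pos + np.array([0.0, 3.0, 0.0])
        lig = Residue("A", 900, "LIG", [
            Atom("C1", "C", c),
            Atom("O1", "O", c + np.array([1.25, 0.0, 0.0])),
            Atom("O2", "O", c + np.array([-0.6, 1.1, 0.0])),
        ], het=True)
        out = fx.salt_bridge_features(ComplexModel([arg], lig), 1)
        assert out["ligsb_present"] == 1.0
        assert out["ligsb_group"] == 1.0  # carboxylate code

    def test_disulfide_window(self, complex_bundle):
        from resmutscan.structmut import load_complex

        inc = load_complex(complex_bundle.boundary_pdbs["ssbond_2p0"], "LIG")
        out = load_complex(complex_bundle.boundary_pdbs["ssbond_2p3"], "LIG")
        assert fx.disulfide_check(inc, 1) is True
        assert fx.disulfide_check(out, 1) is False

    def test_non_cysteine_never_bonded(self, toy_complex):
        pos = next(r.resnum for r in toy_complex.residues if r.aa1 != "C")
        assert fx.disulfide_check(toy_complex, pos) is False


def _hexagon(center, radius=1.4, normal_axis=2):
    pts = []
    for k in range(6):
        ang = math.pi * k / 3
        p = np.array(center, dtype=float)
        axes = [i for i in range(3) if i != normal_axis]
        p[axes[0]] += radius * math.cos(ang)
        p[axes[1]] += radius * math.sin(ang)
        pts.append(p)
    return pts


class TestInteractionFingerprint:
    def _phe_with_ring(self):
        res = build_toy_chain("F")[0]
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        for name, p in zip(ring_names, _hexagon([0.0, 5.0, 0.0])):
            res.atom(name).pos = p
        return res

    def test_parallel_pi_stacking_detected(self):
        res = self._phe_with_ring()
        lig = Residue("A", 900, "LIG", [
            Atom(f"C{i+1}", "C", p)
            for i, p in enumerate(_hexagon([0.0, 5.0, 4.0]))], het=True)
        fp = fx.ligand_interaction_fingerprint(ComplexModel([res], lig), 1)
        assert fp.present("pistack")
        assert fp.distance("pistack") == pytest.approx(4.0, abs=1e-6)

    def test_distant_ring_not_stacked(self):
        res = self._phe_with_ring()
        lig = Residue("A", 900, "LIG", [
            Atom(f"C{i+1}", "C", p)
            for i, p in enumerate(_hexagon([0.0, 5.0, 7.0]))], het=True)
        fp = fx.ligand_interaction_fingerprint(ComplexModel([res], lig), 1)
        assert not fp.present("pistack")

    def test_halogen_bond_angle_and_distance_rule(self):
        res = Residue("A", 1, "ALA", [Atom("O", "O", np.zeros(3))])
        lig = Residue("A", 900, "LIG", [
            Atom("CL1", "CL", np.array([3.2, 0.0, 0.0])),
            Atom("C1", "C", np.array([4.9, 0.0, 0.0])),  # C-Cl...O at 180
        ], het=True)
        fp = fx.ligand_interaction_fingerprint(ComplexModel([res], lig), 1)
        assert fp.present("halogen")
        assert fp.distance("halogen") == pytest.approx(3.2)
        # bent geometry fails the angle rule
        lig2 = Residue("A", 900, "LIG", [
            Atom("CL1", "CL", np.array([3.2, 0.0, 0.0])),
            Atom("C1", "C", np.array([3.2, 1.7, 0.0])),  # ~90 degrees
        ], het=True)
        fp2 = fx.ligand_interaction_fingerprint(ComplexModel([res], lig2), 1)
        assert not fp2.present("halogen")

    def test_pi_cation_lysine_over_ligand_ring(self):
        lys = build_toy_chain("K")[0]
        ring_center = lys.atom("NZ").pos + np.array([0.0, 4.0, 0.0])
        lig = Residue("A", 900, "LIG", [
            Atom(f"C{i+1}", "C", p)
            for i, p in enumerate(_hexagon(ring_center))], het=True)
        fp = fx.ligand_interaction_fingerprint(ComplexModel([lys], lig), 1)
        assert fp.present("pication")

    def test_water_bridge(self):
        ser = build_toy_chain("S")[0]
        og = ser.atom("OG")
        w_pos = og.pos + np.array([0.0, 3.0, 0.0])
        lig = Residue("A", 900, "LIG", [
            Atom("O1", "O", w_pos + np.array([0.0, 3.0, 0.0]))], het=True)
        water = Residue("A", 500, "HOH", [Atom("O", "O", w_pos)])
        model = ComplexModel([ser], lig, waters=[water])
        fp = fx.ligand_interaction_fingerprint(model, 1)
        assert fp.present("water_bridge")

    def test_hydrophobic_contact(self):
        leu = build_toy_chain("L")[0]
        cd1 = leu.atom("CD1")
        lig = Residue("A", 900, "LIG", [
            Atom("C1", "C", cd1.pos + np.array([0.0, 3.5, 0.0]))], het=True)
        fp = fx.ligand_interaction_fingerprint(ComplexModel([leu], lig), 1)
        assert fp.present("hydrophobic")


class TestAssembly:
    def test_schema_lengths_and_membership(self):
        aa = sch.get_schema("aa-v1")
        lig = sch.get_schema("lig-v1")
        assert len(set(aa.features)) == len(aa)
        assert len(set(lig.features)) == len(lig)
        for f in ("hse_up_wt", "psb_count_wt", "ss_bond_present"):
            assert f in aa.features and f not in lig.features
        for f in ("xb_present", "pistack_present", "wb_present",
                  "hydroph_present", "pication_present"):
            assert f in lig.features and f not in aa.features
        shared = set(aa.features) & set(lig.features)
        assert "hb_present" in shared and "aff_log10_nM" in shared

    def test_vector_conforms_and_deterministic(self, toy_complex):
        site = define_binding_site(toy_complex)
        pos = site.resnums[1]
        res = toy_complex.residue(pos)
        mut = _mut(pos, res.aa1, "A" if res.aa1 != "A" else "V")
        mt = build_mutant_model(toy_complex, mut).structure
        fv1 = sch.extract_pair_features(
            toy_complex, mt, mut, "aa-v1", wt_affinity_nM=50.0, site=site)
        fv2 = sch.extract_pair_features(
            toy_complex, mt, mut, "aa-v1", wt_affinity_nM=50.0, site=site)
        assert len(fv1.values) == len(sch.get_schema("aa-v1"))
        assert np.array_equal(fv1.values, fv2.values)
        assert not np.isnan(fv1.values).any()

    def test_affinity_encoding_and_errors(self):
        schema = sch.get_schema("aa-v1")
        fv = sch.assemble_feature_vector({}, schema, 1000.0, "Kd")
        d = fv.as_dict()
        assert d["aff_log10_nM"] == pytest.approx(3.0)
        assert d["aff_measure"] == 1.0
        assert fv.provenance["hb_present"] == "unknown"
        with pytest.raises(ValueError):
            sch.assemble_feature_vector({}, schema, -1.0, "Kd")
        with pytest.raises(ValueError):
            sch.assemble_feature_vector({}, schema, 1.0, "EC50")

    def test_rigid_motion_near_invariance(self, toy_complex):
        import copy

        from scipy.spatial.transform import Rotation

        site = define_binding_site(toy_complex)
        pos = site.resnums[1]
        res = toy_complex.residue(pos)
        mut = _mut(pos, res.aa1, "A" if res.aa1 != "A" else "V")
        mt = build_mutant_model(toy_complex, mut).structure
        fv = sch.extract_pair_features(
            toy_complex, mt, mut, "lig-v1", wt_affinity_nM=50.0, site=site)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([11.0, -7.0, 4.0])
        wt2, mt2 = copy.deepcopy(toy_complex), copy.deepcopy(mt)
        for model in (wt2, mt2):
            for r in model.residues + [model.ligand] + model.waters:
                for a in r.atoms:
                    a.pos = R @ a.pos + t
        site2 = define_binding_site(wt2)
        fv2 = sch.extract_pair_features(
            wt2, mt2, mut, "lig-v1", wt_affinity_nM=50.0, site=site2)
        # SASA point sampling is orientation-dependent; allow small slack
        assert np.allclose(fv.values, fv2.values, rtol=0.05, atol=2.0)
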