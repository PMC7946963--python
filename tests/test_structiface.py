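"""Structure geometry: SASA oracles, interfaces, H-bonds, superposition."""

import math

import numpy as np
import pytest

from firtool.structiface import (
    StructureModel,
    buried_surface,
    hydrogen_bonds,
    pocket_contacts,
    read_structure,
    salt_bridges,
    sasa,
    superpose,
)
from firtool.synth import gen_toy_structure

R_C = 1.70 + 1.4  # expanded carbon radius at the default probe


def two_sphere_sasa(r1: float, r2: float, d: float) -> float:
    """Closed-form SASA of two intersecting spheres (spherical caps)."""
    if d >= r1 + r2:
        return 4 * math.pi * (r1 * r1 + r2 * r2)
    total = 0.0
    for ra, rb in ((r1, r2), (r2, r1)):
        a = (d * d + ra * ra - rb * rb) / (2 * d)
        h = ra - a  # buried cap height on sphere a
        total += 4 * math.pi * ra * ra - 2 * math.pi * ra * h
    return total


class TestRead:
    def test_two_atom_fixture(self):
        pdb, _ = gen_toy_structure("sphere_pair", separation=5.0)
        m = read_structure(pdb)
        assert len(m) == 2
        np.testing.assert_allclose(m.coords[1], [5.0, 0.0, 0.0])
        assert m.atoms[0].element == "C"
        assert m.chains() == ["A", "B"]

    def test_altloc_highest_occupancy_kept(self):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00           C\n"
            "END\n"
        )
        m = read_structure(pdb)
        assert len(m) == 1
        np.testing.assert_allclose(m.coords[0], [1.0, 0.0, 0.0])

    def test_altloc_tie_keeps_A(self):
        pdb = (
            "ATOM      1  CA BALA A   1       1.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50 10.00           C\n"
            "END\n"
        )
        m = read_structure(pdb)
        assert len(m) == 1
        np.testing.assert_allclose(m.coords[0], [0.0, 0.0, 0.0])

    def test_waters_dropped_by_default(self):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00 10.00           O\n"
            "END\n"
        )
        assert len(read_structure(pdb)) == 1
        assert len(read_structure(pdb, keep_waters=True)) == 2


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        pdb, truth = gen_toy_structure("sphere_pair", separation=100.0)
        m = read_structure(pdb)
        areas, total = sasa(m, m.select(chain="A"))
        assert total == pytest.approx(4 * math.pi * R_C**2, rel=1e-9)
        assert total == pytest.approx(truth["isolated_sasa"], rel=1e-9)

    def test_far_apart_atoms_additive(self):
        pdb, truth = gen_toy_structure("sphere_pair", separation=100.0)
        m = read_structure(pdb)
        _, total = sasa(m)
        assert total == pytest.approx(2 * truth["isolated_sasa"], rel=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_cap_oracle(self, d):
        pdb, _ = gen_toy_structure("sphere_pair", separation=d)
        m = read_structure(pdb)
        _, total = sasa(m, points_per_atom=3840)
        assert total == pytest.approx(two_sphere_sasa(R_C, R_C, d), rel=0.01)

    def test_occlusion_never_increases_per_atom_area(self):
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        a_only, _ = sasa(m, m.select(chain="A"))
        both_sel = np.concatenate([m.select(chain="A"), m.select(chain="B")])
        ab, _ = sasa(m, both_sel)
        n = len(a_only)
        assert np.all(ab[:n] <= a_only + 1e-9)

    def test_matches_independent_reference_implementation(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        ours, total = sasa(m, points_per_atom=3840)

        arr = biotite_struc.AtomArray(len(m))
        arr.coord = m.coords.astype(np.float32)
        for i, a in enumerate(m.atoms):
            arr.chain_id[i] = a.chain
            arr.res_id[i] = a.resnum
            arr.res_name[i] = a.resname
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        radii = np.array([1.70 if a.element == "C" else 1.55 if a.element == "N" else 1.52
                          for a in m.atoms])
        ref = biotite_struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                                 point_number=3840)
        assert total == pytest.approx(float(ref.sum()), rel=0.02)

    def test_unknown_element_raises(self):
        from firtool.structiface import Atom

        m = StructureModel([Atom("A", 1, "", "UNK", "XX", "XX", (0.0, 0.0, 0.0))])
        with pytest.raises(KeyError, match="XX"):
            sasa(m)


class TestBuriedSurface:
    def test_far_apart_chains_zero(self):
        pdb, _ = gen_toy_structure("sphere_pair", separation=100.0)
        m = read_structure(pdb)
        rep = buried_surface(m, m.select(chain="A"), m.select(chain="B"))
        assert rep.bsa_sum == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_decomposition_sums(self):
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        sa, sb = m.select(chain="A"), m.select(chain="B")
        rep_ab = buried_surface(m, sa, sb)
        rep_ba = buried_surface(m, sb, sa)
        assert rep_ab.bsa_sum == pytest.approx(rep_ba.bsa_sum, rel=1e-12)
        assert rep_ab.bsa_half == pytest.approx(rep_ab.bsa_sum / 2)
        assert rep_ab.bsa_sum > 0
        assert sum(rep_ab.per_residue.values()) == pytest.approx(rep_ab.bsa_sum, rel=1e-9)

    def test_rigid_motion_invariance(self):
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        th = 0.9
        R = np.array([
            [math.cos(th), -math.sin(th), 0.0],
            [math.sin(th), math.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ])
        m2 = m.transformed(R, np.array([10.0, -4.0, 2.0]))
        rep1 = buried_surface(m, m.select(chain="A"), m.select(chain="B"))
        rep2 = buried_surface(m2, m2.select(chain="A"), m2.select(chain="B"))
        # the deterministic point set is not rotated with the body, so
        # agreement is to quadrature accuracy, not machine precision
        assert rep2.bsa_sum == pytest.approx(rep1.bsa_sum, rel=0.02)

    def test_overlapping_selections_rejected(self):
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        sel = m.select(chain="A")
        with pytest.raises(ValueError):
            buried_surface(m, sel, sel)


class TestHydrogenBonds:
    def test_ideal_antiparallel_ladder(self):
        pdb, truth = gen_toy_structure("beta_pair", n_pairs=5)
        m = read_structure(pdb)
        hb = hydrogen_bonds(m, m.select(chain="A"), m.select(chain="B"))
        assert len(hb) == truth["n_hbonds"] == 10
        assert all(h.hbond_class == "backbone-backbone" for h in hb)
        assert all(h.distance == pytest.approx(2.9, abs=1e-6) for h in hb)
        got = {
            ((h.donor.chain, h.donor.resnum, h.donor.name),
             (h.acceptor.chain, h.acceptor.resnum, h.acceptor.name))
            for h in hb
        }
        assert got == {tuple(p) for p in truth["pairs"]}

    def test_zero_cutoff_empty(self):
        pdb, _ = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        assert hydrogen_bonds(m, m.select(chain="A"), m.select(chain="B"), d_max=1e-6) == []

    def test_rigid_motion_invariance(self):
        pdb, truth = gen_toy_structure("beta_pair")
        m = read_structure(pdb)
        th = -1.2
        R = np.array([
            [1.0, 0.0, 0.0],
            [0.0, math.cos(th), -math.sin(th)],
            [0.0, math.sin(th), math.cos(th)],
        ])
        m2 = m.transformed(R, np.array([-3.0, 7.0, 1.0]))
        hb = hydrogen_bonds(m2, m2.select(chain="A"), m2.select(chain="B"))
        assert len(hb) == truth["n_hbonds"]


class TestSaltBridges:
    @staticmethod
    def _pair_pdb(d: float) -> str:
        return (
            f"ATOM      1  NZ  LYS A   1       0.000   0.000   0.000  1.00 10.00           N\n"
            f"ATOM      2  OD1 ASP B   1       {d:.3f}   0.000   0.000  1.00 10.00           O\n"
            "END\n"
        )

    def test_lys_asp_pair_within_cutoff(self):
        m = read_structure(self._pair_pdb(3.0))
        bridges = salt_bridges(m, m.select(chain="A"), m.select(chain="B"))
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.0)

    def test_pair_beyond_cutoff(self):
        m = read_structure(self._pair_pdb(5.0))
        assert salt_bridges(m, m.select(chain="A"), m.select(chain="B")) == []

    def test_phosphate_oxygen_is_anion(self):
        pdb = (
            "ATOM      1  NH1 ARG A   1       0.000   0.000   0.000  1.00 10.00           N\n"
            "ATOM      2  O1P SEP B   1       3.500   0.000   0.000  1.00 10.00           O\n"
            "END\n"
        )
        m = read_structure(pdb)
        bridges = salt_bridges(m, m.select(chain="A"), m.select(chain="B"))
        assert len(bridges) == 1
        assert bridges[0].anion.resname == "SEP"


class TestSuperpose:
    def test_identical_coordinates(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        rmsd, R, t = superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rotated_translated_copy(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(20, 3))
        th = 1.1
        R = np.array([
            [math.cos(th), 0.0, math.sin(th)],
            [0.0, 1.0, 0.0],
            [-math.sin(th), 0.0, math.cos(th)],
        ])
        Q = P @ R.T + np.array([4.0, 5.0, 6.0])
        rmsd, Rf, tf = superpose(P, Q)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(Q @ Rf.T + tf, P, atol=1e-9)

    def test_idempotent_after_applying_transform(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(15, 3))
        Q = P + rng.normal(scale=0.3, size=P.shape)
        rmsd1, R, t = superpose(P, Q)
        Q2 = Q @ R.T + t
        rmsd2, _, _ = superpose(P, Q2)
        assert rmsd2 == pytest.approx(rmsd1, rel=1e-9)

    def test_perturbation_rmsd_scaling(self):
        # after optimal superposition, RMSD of an isotropically perturbed
        # copy approaches sigma * sqrt(3) for many atoms
        rng = np.random.default_rng(4)
        sigma = 0.5
        P = rng.normal(scale=10.0, size=(2000, 3))
        Q = P + rng.normal(scale=sigma, size=P.shape)
        rmsd, _, _ = superpose(P, Q)
        assert rmsd == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_degenerate_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPocketContacts:
    def test_claw_mock_planted_contacts(self):
        pdb, truth = gen_toy_structure("claw_mock")
        m = read_structure(pdb)
        contacts = pocket_contacts(m, m.select(chain="B"))
        assert contacts == truth["contacts"]
        assert ("B", 112, "") not in contacts  # spacer residue is far away

    def test_distant_peptide_empty(self):
        pdb, _ = gen_toy_structure("claw_mock")
        m = read_structure(pdb)
        m2 = m.transformed(np.eye(3), np.zeros(3))
        far = StructureModel(
            [a if a.chain != "B" else type(a)(
                a.chain, a.resnum, a.icode, a.resname, a.name, a.element,
                (a.pos[0] + 100.0, a.pos[1], a.pos[2])) for a in m2.atoms]
        )
        assert pocket_contacts(far, far.select(chain="B")) == {}
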