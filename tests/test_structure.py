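"""Structure metrics: PDB input, Kabsch/RMSD, SS, SASA, YRB patches."""

import numpy as np
import pytest

from qtykit import (
    ProteinRecord,
    TMSegment,
    Topology,
    apply_qty,
    assign_ss,
    compare_models,
    helical_ratio,
    hydrophobic_patch_fraction,
    kabsch_superpose,
    polar_point,
    read_pdb,
    rmsd_full,
    rmsd_tm,
    sasa_shrake_rupley,
    yrb_classify,
)
from qtykit.structure import (
    Atom,
    Residue,
    StructureModel,
    sphere_points,
    thread_sequence,
)
from qtykit.synth import (
    SynthSpec,
    make_helix_bundle_model,
    make_membrane_protein,
    perturb_structure,
)

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.000   1.000   0.500  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2      12.800   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       5.000   5.000   5.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


def ideal_helix(n, rise=1.5, twist=100.0, radius=2.3):
    j = np.arange(n)
    ang = np.deg2rad(twist) * j
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * j]
    )


def ca_model(coords, seq=None, model_id="m"):
    seq = seq or "A" * len(coords)
    residues = tuple(
        Residue(i + 1, seq[i], tuple(coords[i])) for i in range(len(coords))
    )
    return StructureModel(model_id, residues)


class TestReadPdb:
    def test_minimal_fixture(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINI_PDB)
        model = read_pdb(p)
        assert len(model) == 2
        assert model.sequence() == "AG"
        np.testing.assert_allclose(
            model.ca_coords()[0], [1.458, 0.0, 0.0], atol=1e-3
        )
        assert len(model.atoms) == 4  # N, CA, CB, CA

    def test_only_model_1_parsed(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(TWO_MODEL_PDB)
        model = read_pdb(p)
        assert len(model) == 2
        np.testing.assert_allclose(model.ca_coords()[0], [0, 0, 0])

    def test_altloc_a_kept(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_pdb(p)
        assert len(model) == 2
        assert len(model.atoms) == 2  # altloc B dropped
        np.testing.assert_allclose(model.ca_coords()[0], [0, 0, 0])

    def test_no_ca_error(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\nEND\n"
        )
        with pytest.raises(ValueError, match="no CA"):
            read_pdb(p)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()


class TestKabsch:
    def test_identical_sets_rmsd_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        rot = random_rotation(rng)
        b = a @ rot.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            rot, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-9
        )

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="degenerate"):
            kabsch_superpose(a, a + 1.0)

    def test_agrees_with_euler_grid_oracle(self):
        """Kabsch matches brute-force minimization over rotations on
        random 4-point problems (the independent oracle)."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        grid = np.deg2rad(
            np.stack(
                np.meshgrid(
                    np.arange(0, 360, 8.0),
                    np.arange(0, 180, 8.0),
                    np.arange(0, 360, 8.0),
                    indexing="ij",
                ),
                axis=-1,
            ).reshape(-1, 3)
        )
        mats = Rotation.from_euler("zyz", grid).as_matrix()
        for _ in range(25):
            a = rng.normal(size=(4, 3))
            b = rng.normal(size=(4, 3))
            a0 = a - a.mean(axis=0)
            b0 = b - b.mean(axis=0)

            def cost_angles(angles):
                rot = Rotation.from_euler("zyz", angles).as_matrix()
                return float(np.mean(np.sum((b0 @ rot.T - a0) ** 2, axis=1)))

            fitted = np.einsum("kij,nj->kni", mats, b0)
            costs = np.mean(np.sum((fitted - a0) ** 2, axis=2), axis=1)
            best = grid[int(np.argmin(costs))]
            res = minimize(cost_angles, best, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            oracle = np.sqrt(res.fun)
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(oracle, abs=1e-3)


class TestRmsdTm:
    def test_loop_only_perturbation(self, bundle_pair):
        record, topo, native, perturbed = bundle_pair
        assert rmsd_tm(native, perturbed, topo) == pytest.approx(0, abs=1e-9)
        assert rmsd_full(native, perturbed) > 0.1

    def test_identical_models_both_zero(self, bundle_pair):
        _, topo, native, _ = bundle_pair
        assert rmsd_full(native, native) == pytest.approx(0, abs=1e-8)
        assert rmsd_tm(native, native, topo) == pytest.approx(0, abs=1e-8)

    def test_tm_noise_matches_independent_superposition(self, bundle_pair):
        """TM-restricted RMSD equals an independent superposition (scipy
        align_vectors) computed on the same sampled TM coordinates."""
        from scipy.spatial.transform import Rotation

        record, topo, native, _ = bundle_pair
        noisy = perturb_structure(native, 0.1, region="tm", seed=5,
                                  topo=topo)
        ours = rmsd_tm(native, noisy, topo)
        mask = topo.tm_mask(len(native))
        a = native.ca_coords()[mask]
        b = noisy.ca_coords()[mask]
        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)
        _, rssd = Rotation.align_vectors(a0, b0)
        oracle = rssd / np.sqrt(len(a0))
        assert ours == pytest.approx(oracle, abs=1e-9)
        # superposition can only shrink the raw displacement RMS
        raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert 0 < ours <= raw + 1e-12

    def test_too_few_tm_residues_error(self, bundle_pair):
        _, _, native, perturbed = bundle_pair
        tiny = Topology(native.id, (TMSegment(1, 2),))
        with pytest.raises(ValueError):
            rmsd_tm(native, perturbed, tiny)


class TestAssignSS:
    def test_ideal_helix_mostly_h(self):
        model = ca_model(ideal_helix(20))
        ss = assign_ss(model)
        assert ss.count("H") >= 16

    def test_extended_chain_no_h(self):
        coords = np.column_stack(
            [3.8 * np.arange(20.0), np.zeros(20), np.zeros(20)]
        )
        ss = assign_ss(ca_model(coords))
        assert ss.count("H") == 0

    def test_helix_loop_helix_blocks_match_spans(self):
        spec = SynthSpec(n_tm=(2, 2))
        record, topo = make_membrane_protein(spec, seed=21)
        model = make_helix_bundle_model(record, topo)
        ss = assign_ss(model)
        h_idx = {i for i, c in enumerate(ss) if c == "H"}
        tm_idx = set()
        for seg in topo.segments:
            tm_idx.update(range(seg.start - 1, seg.end))
        # H blocks coincide with the generated helix spans within 1 residue
        near_tm = set()
        for seg in topo.segments:
            near_tm.update(range(seg.start - 2, seg.end + 1))
        assert h_idx <= near_tm
        for seg in topo.segments:
            core = set(range(seg.start, seg.end - 1))  # span minus 1 per end
            assert core <= h_idx

    def test_chain_break_warns_and_splits(self):
        helix = ideal_helix(12)
        far = ideal_helix(12) + np.array([50.0, 0, 0])
        model = ca_model(np.vstack([helix, far]))
        with pytest.warns(UserWarning, match="chain break"):
            ss = assign_ss(model)
        assert len(ss) == 24

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            assign_ss(ca_model(ideal_helix(4)))


class TestHelicalRatioAndPolar:
    def test_ratio_examples(self):
        assert helical_ratio("HHHHCC") == pytest.approx(4 / 6)
        assert helical_ratio("CCCC") == 0.0

    def test_concatenation_is_weighted_mean(self):
        a, b = "HHHC", "CCCCCC"
        combined = helical_ratio(a + b)
        expected = (4 * helical_ratio(a) + 6 * helical_ratio(b)) / 10
        assert combined == pytest.approx(expected)

    def test_polar_point_cases(self):
        assert polar_point(0.0, 0.5, 0.5, 8.0) == (0.0, 0.0, "upper")
        r, ang, hemi = polar_point(1.0, 0.5, 0.25, 5.0)
        assert ang == pytest.approx(45.0)
        assert hemi == "lower"
        assert polar_point(1.0, 0.0, 1.0, 7.0)[1] == 180.0
        assert polar_point(1.0, 0.0, 1.0, 7.0)[2] == "upper"  # tie -> upper


def single_atom_model(radius=1.7):
    return StructureModel(
        "one",
        (Residue(1, "A", (0.0, 0.0, 0.0)),),
        (Atom(1, "CA", "C", 0, (0.0, 0.0, 0.0), radius),),
    )


class TestSasa:
    def test_single_sphere_analytic(self):
        areas = sasa_shrake_rupley(single_atom_model())
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=5e-3)

    def test_two_distant_atoms_no_occlusion(self):
        model = StructureModel(
            "two",
            (Residue(1, "A", (0, 0, 0)), Residue(2, "A", (100, 0, 0))),
            (
                Atom(1, "CA", "C", 0, (0.0, 0.0, 0.0), 1.7),
                Atom(2, "CA", "N", 1, (100.0, 0.0, 0.0), 1.55),
            ),
        )
        areas = sasa_shrake_rupley(model)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=5e-3)
        assert areas[1] == pytest.approx(4 * np.pi * 2.95**2, rel=5e-3)

    def test_caged_atom_zero(self):
        cage = 2.0 * sphere_points(80)
        residues = [Residue(1, "A", (0.0, 0.0, 0.0))]
        atoms = [Atom(1, "CA", "C", 0, (0.0, 0.0, 0.0), 1.7)]
        for i, xyz in enumerate(cage):
            atoms.append(
                Atom(i + 2, "CB", "C", 0, tuple(xyz), 1.7)
            )
        model = StructureModel("cage", tuple(residues), tuple(atoms))
        areas = sasa_shrake_rupley(model)
        assert areas[0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in [6.5, 5.0, 4.0, 3.0, 2.5, 2.0]:
            model = StructureModel(
                "pair",
                (Residue(1, "A", (0, 0, 0)), Residue(2, "A", (d, 0, 0))),
                (
                    Atom(1, "CA", "C", 0, (0.0, 0.0, 0.0), 1.7),
                    Atom(2, "CA", "C", 1, (float(d), 0.0, 0.0), 1.7),
                ),
            )
            area = sasa_shrake_rupley(model)[0]
            assert area <= prev + 1e-9
            prev = area

    def test_point_count_validation(self):
        with pytest.raises(ValueError):
            sasa_shrake_rupley(single_atom_model(), n_points=10)


def full_atom_residue(res3_atoms, aa, rid=1, offset=(0.0, 0.0, 0.0)):
    residues = (Residue(rid, aa, tuple(offset)),)
    atoms = tuple(
        Atom(i + 1, name, name[0], 0,
             (offset[0] + 0.5 * i, offset[1], offset[2]), 1.7)
        for i, name in enumerate(res3_atoms)
    )
    return StructureModel(f"res{aa}", residues, atoms)


class TestYrb:
    def test_rule_table_classes(self):
        model = full_atom_residue(["N", "CA", "CB", "C", "O"], "A")
        classes = yrb_classify(model, reduced=False)
        assert classes == ["none", "none", "yellow", "none", "red"]
        # terminal O of the last residue counts as C-terminal oxygen

    def test_lys_nz_blue_asp_od1_red(self):
        lys = full_atom_residue(["CA", "CB", "CG", "CD", "CE", "NZ"], "K")
        assert yrb_classify(lys, reduced=False)[-1] == "blue"
        asp = full_atom_residue(["CA", "CB", "CG", "OD1", "OD2"], "D")
        assert yrb_classify(asp, reduced=False)[3:] == ["red", "red"]

    def test_backbone_o_not_red_when_not_terminal(self):
        model = StructureModel(
            "bb",
            (Residue(1, "A", (0, 0, 0)), Residue(2, "A", (3.8, 0, 0))),
            (
                Atom(1, "CA", "C", 0, (0.0, 0.0, 0.0), 1.7),
                Atom(2, "O", "O", 0, (1.0, 0.0, 0.0), 1.52),
                Atom(3, "CA", "C", 1, (3.8, 0.0, 0.0), 1.7),
            ),
        )
        classes = yrb_classify(model, reduced=False)
        assert classes[1] == "none"

    def test_unknown_atom_warns_none(self):
        model = full_atom_residue(["CA", "XX9"], "A")
        with pytest.warns(UserWarning, match="unknown atom"):
            classes = yrb_classify(model, reduced=False)
        assert classes[1] == "none"


class TestHydrophobicPatch:
    def test_all_carbon_toy_is_one(self):
        # lone Leu side-chain carbons: every atom yellow
        model = full_atom_residue(["CB", "CG", "CD1", "CD2"], "L")
        assert hydrophobic_patch_fraction(model) == pytest.approx(1.0)

    def test_polylys_less_hydrophobic_than_polyleu(self):
        def poly(aa):
            coords = np.column_stack(
                [3.8 * np.arange(8.0), np.zeros(8), np.zeros(8)]
            )
            residues = tuple(
                Residue(i + 1, aa, tuple(coords[i])) for i in range(8)
            )
            atoms = []
            serial = 1
            for i in range(8):
                atoms.append(Atom(serial, "CA", "C", i, tuple(coords[i]),
                                  1.7))
                serial += 1
                cb = coords[i] + np.array([0.0, 1.53, 0.0])
                atoms.append(Atom(serial, "CB", "C", i, tuple(cb), 1.7))
                serial += 1
            return StructureModel(f"poly{aa}", residues, tuple(atoms))

        assert hydrophobic_patch_fraction(
            poly("K")
        ) < hydrophobic_patch_fraction(poly("L"))

    def test_qty_variant_reduces_patch_fraction(self, bundle_pair):
        record, topo, native, _ = bundle_pair
        design = apply_qty(record, topo)
        variant = thread_sequence(native, design.variant_sequence)
        assert hydrophobic_patch_fraction(
            variant
        ) < hydrophobic_patch_fraction(native)


class TestCompareModels:
    def test_full_pipeline_consistency(self, bundle_pair):
        record, topo, native, perturbed = bundle_pair
        metrics = compare_models(native, perturbed, topo, pi_native=8.5)
        assert metrics.rmsd_tm == pytest.approx(0.0, abs=1e-9)
        assert metrics.rmsd_full > 0
        assert metrics.radius == metrics.rmsd_full
        assert metrics.polar_angle_deg == pytest.approx(
            min(180.0, abs(metrics.delta_rh) * 180.0)
        )
        assert metrics.hemisphere == "upper"
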