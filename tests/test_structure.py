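"""Superposition, ensemble statistics, SASA and buried surface areas.

Brute-force oracles used here: a two-stage rotation-grid search for the
Kabsch minimum, an independently coded pairwise RMSD (scipy Rotation), and
dense-point numerical integration for SASA on overlapping spheres.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from nmrbind import structure as st
from nmrbind import synthetic as syn
from tests.conftest import make_atomset


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def grid_search_rmsd(mobile, reference):
    """Exhaustive rotation search: coarse 10-deg Euler grid refined to a
    1-deg local grid around the best coarse cell."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def best_over(angles_z1, angles_y, angles_z2):
        best = np.inf
        grid = [(a, b, c) for a in angles_z1 for b in angles_y for c in angles_z2]
        rots = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        for R in rots:
            r = np.sqrt(np.mean(np.sum((mc @ R.T - rc) ** 2, axis=1)))
            if r < best:
                best, bestR = r, R
        return best, bestR

    coarse = np.arange(0, 360, 10)
    coarse_y = np.arange(0, 181, 10)
    best, R = best_over(coarse, coarse_y, coarse)
    e = Rotation.from_matrix(R).as_euler("zyz", degrees=True)
    fine = [np.arange(c - 10, c + 10.5, 1.0) for c in e]
    best2, _ = best_over(fine[0], fine[1], fine[2])
    return min(best, best2)


class TestSuperpose:
    def test_identity_on_self(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = st.superpose(coords, coords)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        coords = np.random.default_rng(1).normal(size=(5, 3))
        _, _, rmsd = st.superpose(coords + [5.0, 0.0, 0.0], coords)
        assert rmsd < 1e-12

    def test_transform_reproduces_reported_rmsd(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        R, t, rmsd = st.superpose(a, b)
        fitted = st.apply_transform(a, R, t)
        recomputed = np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1)))
        assert abs(recomputed - rmsd) < 1e-9

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_rotation_grid_search_on_4_atom_cases(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(scale=3.0, size=(4, 3))
        reference = rng.normal(scale=3.0, size=(4, 3))
        _, _, kabsch = st.superpose(mobile, reference)
        grid = grid_search_rmsd(mobile, reference)
        assert kabsch <= grid + 1e-9  # Kabsch is the global optimum
        assert abs(kabsch - grid) < 0.01

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            st.superpose(line, line)

    def test_too_few_pairs_rejected(self):
        two = np.zeros((2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            st.superpose(two, two)


class TestEnsembleRMSD:
    def _jittered(self, seed=0, n_models=5, sigma=0.5):
        spec = syn.GeneratorSpec(
            seed=seed, n_residues=20, n_models=n_models,
            core_range=(1, 20), sigma_core=sigma, sigma_tail=sigma,
        )
        return syn.make_ensemble(spec)[0]

    def test_identical_models_give_zero(self):
        ens = self._jittered(sigma=0.0)
        for mode in ("pairwise_mean", "to_mean_structure"):
            out = st.ensemble_rmsd(ens, mode=mode)
            assert out["mean"] < 1e-12 and out["sd"] < 1e-12

    def test_translated_models_give_zero(self):
        ens = self._jittered(sigma=0.0)
        coords = ens.coords.copy()
        for i in range(coords.shape[0]):
            coords[i] += np.array([i * 10.0, 0.0, 0.0])
        ens2 = st.Ensemble(atoms=ens.atoms, coords=coords)
        assert st.ensemble_rmsd(ens2)["mean"] < 1e-12

    def test_pairwise_matches_brute_force_oracle(self):
        """Independent oracle: scipy Rotation.align_vectors per model pair."""
        ens = self._jittered(seed=7)
        mask = ens.select("backbone")
        X = ens.coords[:, mask, :]
        vals = []
        for i in range(len(X)):
            for j in range(i + 1, len(X)):
                a = X[j] - X[j].mean(axis=0)
                b = X[i] - X[i].mean(axis=0)
                rot, rssd = Rotation.align_vectors(b, a)
                vals.append(rssd / np.sqrt(len(a)))
        ours = st.ensemble_rmsd(ens, mode="pairwise_mean")
        assert abs(ours["mean"] - np.mean(vals)) < 1e-9

    def test_rigid_transform_invariance(self):
        ens = self._jittered(seed=9)
        base = st.ensemble_rmsd(ens)["mean"]
        coords = ens.coords.copy()
        for i in range(coords.shape[0]):
            R, t = random_rigid(100 + i)
            coords[i] = coords[i] @ R.T + t
        moved = st.Ensemble(atoms=ens.atoms, coords=coords)
        assert abs(st.ensemble_rmsd(moved)["mean"] - base) < 1e-9

    def test_empty_selection_rejected(self):
        ens = self._jittered()
        with pytest.raises(ValueError, match="empty selection"):
            st.ensemble_rmsd(ens, selection="name XX")


class TestOrderedRange:
    def test_rigid_ensemble_returns_full_range(self):
        spec = syn.GeneratorSpec(
            seed=0, n_residues=30, n_models=4, core_range=(1, 30),
            sigma_core=0.05, sigma_tail=0.05,
        )
        ens, _ = syn.make_ensemble(spec)
        assert st.find_ordered_range(ens, cutoff=2.0) == [(1, 30)]

    def test_disordered_tail_excluded(self):
        spec = syn.GeneratorSpec(
            seed=1, n_residues=60, n_models=6, core_range=(1, 50),
            sigma_core=0.1, sigma_tail=10.0,
        )
        ens, _ = syn.make_ensemble(spec)
        ranges = st.find_ordered_range(ens, cutoff=2.0)
        assert ranges == [(1, 50)]

    def test_flexible_internal_loop_splits_ranges(self):
        spec = syn.GeneratorSpec(
            seed=2, n_residues=60, n_models=6, core_range=(1, 60),
            sigma_core=0.1, sigma_tail=0.1,
        )
        ens, _ = syn.make_ensemble(spec)
        coords = ens.coords.copy()
        loop = ens.atoms["residue_number"].between(20, 23).to_numpy()
        rng = np.random.default_rng(3)
        coords[:, loop, :] += rng.normal(0, 10.0, coords[:, loop, :].shape)
        ens2 = st.Ensemble(atoms=ens.atoms, coords=coords)
        assert st.find_ordered_range(ens2, cutoff=2.0) == [(1, 19), (24, 60)]

    def test_all_excluded_suggests_larger_cutoff(self):
        spec = syn.GeneratorSpec(
            seed=4, n_residues=20, n_models=4, core_range=(1, 20),
            sigma_core=8.0, sigma_tail=8.0,
        )
        ens, _ = syn.make_ensemble(spec)
        with pytest.raises(ValueError, match="larger cutoff"):
            st.find_ordered_range(ens, cutoff=0.5)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        spec = syn.GeneratorSpec(seed=0, n_residues=10, n_frames=5,
                                 sigma_core=0.0, sigma_tail=0.0,
                                 core_range=(1, 10))
        traj, _ = syn.make_trajectory(spec)
        assert np.allclose(st.per_residue_rmsf(traj)["rmsf"], 0.0)

    def test_oscillating_atom_closed_form(self):
        """Atom alternating +-d along x about its mean has RMSF exactly d."""
        d = 0.7
        rows = [("A", 1, "ALA", "CA", "C"), ("A", 2, "ALA", "CA", "C")]
        frames = []
        for f in range(6):
            x = d if f % 2 == 0 else -d
            frames.append([[0.0, 0.0, 0.0], [10.0 + x, 0.0, 0.0]])
        traj = st.Trajectory(
            atoms=pd.DataFrame(rows, columns=st.ATOM_COLUMNS),
            coords=np.array(frames), frame_spacing=0.5,
        )
        prof = st.per_residue_rmsf(traj, selection="name CA")
        assert np.allclose(prof["rmsf"], [0.0, d])

    def test_planted_mobile_segment_has_max_rmsf(self):
        spec = syn.GeneratorSpec(
            seed=5, n_residues=40, n_frames=10, core_range=(1, 30),
            sigma_core=0.1, sigma_tail=3.0,
        )
        traj, truth = syn.make_trajectory(spec)
        prof = st.per_residue_rmsf(traj)
        top = prof.sort_values("rmsf").iloc[-1]["residue_number"]
        assert top > 30  # in the planted high-mobility tail


def dense_grid_sasa(centers, radii, probe, n_points=10**6, seed=0):
    """Numerical SASA oracle: random points on each expanded sphere."""
    rng = np.random.default_rng(seed)
    areas = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        R = r + probe
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = c + R * v
        exposed = np.ones(n_points, dtype=bool)
        for j, (cj, rj) in enumerate(zip(centers, radii)):
            if j == i:
                continue
            exposed &= np.sum((pts - cj) ** 2, axis=1) > (rj + probe) ** 2
        areas.append(4 * np.pi * R**2 * exposed.mean())
    return np.array(areas)


class TestSASA:
    def test_isolated_carbon_matches_analytic_sphere(self):
        model = make_atomset([("A", 1, "ALA", "CA", "C")], [[0, 0, 0]])
        areas, per_res = st.sasa(model, probe=1.4, n_points=960)
        analytic = 4 * np.pi * 3.10**2
        assert abs(areas[0] - analytic) / analytic < 0.005
        assert per_res.loc[0, "sasa"] == areas[0]

    def test_distant_atoms_are_additive(self):
        model = make_atomset(
            [("A", 1, "ALA", "CA", "C"), ("A", 2, "ALA", "CA", "C")],
            [[0, 0, 0], [100.0, 0, 0]],
        )
        areas, _ = st.sasa(model)
        assert np.allclose(areas, 4 * np.pi * 3.10**2, rtol=1e-12)

    def test_overlapping_spheres_match_dense_grid_oracle(self):
        centers = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        model = make_atomset(
            [("A", 1, "ALA", "CA", "C"), ("A", 1, "ALA", "CB", "C")], centers
        )
        areas, _ = st.sasa(model, probe=1.4, n_points=960)
        oracle = dense_grid_sasa(centers, np.array([1.70, 1.70]), 1.4)
        assert np.all(np.abs(areas - oracle) / oracle < 0.01)

    def test_overlapping_spheres_match_spherical_cap_closed_form(self):
        # same configuration, but exact: exposed area = 4 pi R^2 - cap area,
        # cap height h = R - (d^2) / (2 d) ... for equal radii h = R - d/2
        centers = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        model = make_atomset(
            [("A", 1, "ALA", "CA", "C"), ("A", 1, "ALA", "CB", "C")], centers
        )
        areas, _ = st.sasa(model, probe=1.4, n_points=960)
        R, d = 3.10, 2.0
        cap = 2 * np.pi * R * (R - d / 2)
        exact = 4 * np.pi * R**2 - cap
        assert np.all(np.abs(areas - exact) / exact < 0.01)

    def test_unknown_element_is_hard_error(self):
        model = make_atomset([("A", 1, "UNK", "XX", "ZZ")], [[0, 0, 0]])
        with pytest.raises(ValueError, match="no vdW radius"):
            st.sasa(model)

    def test_sasa_monotone_as_components_approach(self):
        areas = []
        for d in (8.0, 6.0, 4.0, 3.0, 2.0):
            model = make_atomset(
                [("A", 1, "ALA", "CA", "C"), ("B", 1, "ALA", "CA", "C")],
                [[0, 0, 0], [d, 0, 0]],
            )
            a, _ = st.sasa(model)
            areas.append(a.sum())
        assert all(x >= y - 1e-9 for x, y in zip(areas, areas[1:]))


class TestBSA:
    def _dimer(self, d):
        return make_atomset(
            [("A", 1, "ALA", "CA", "C"), ("B", 1, "ALA", "CA", "C")],
            [[0, 0, 0], [d, 0, 0]],
        )

    def test_separated_components_bury_nothing(self):
        model = self._dimer(100.0)
        out = st.buried_surface_area(
            model, model.select("chain A"), model.select("chain B")
        )
        assert np.allclose(out["per_residue"]["bsa"], 0.0, atol=1e-9)
        assert out["interface_area"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_dimer_buries_equally(self):
        model = self._dimer(2.5)
        out = st.buried_surface_area(
            model, model.select("chain A"), model.select("chain B")
        )
        bsa = out["per_residue"].set_index("chain")["bsa"]
        assert bsa["A"] == pytest.approx(bsa["B"], rel=1e-6)
        assert bsa["A"] > 10.0

    def test_pocket_fixture_matches_grid_oracle(self):
        """3-atom pocket + 1-atom ligand: per-atom BSA against the dense
        numerical oracle."""
        centers = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [1.5, 2.5, 0], [1.5, 1.0, 2.5]]
        )
        rows = [
            ("A", 1, "ALA", "CA", "C"), ("A", 2, "ALA", "CA", "C"),
            ("A", 3, "ALA", "CA", "C"), ("B", 9, "ALA", "CA", "C"),
        ]
        model = make_atomset(rows, centers)
        out = st.buried_surface_area(
            model, model.select("chain A"), model.select("chain B"),
        )
        radii = np.full(4, 1.70)
        sasa_complex = dense_grid_sasa(centers, radii, 1.4, n_points=200_000)
        sasa_a = dense_grid_sasa(centers[:3], radii[:3], 1.4, n_points=200_000)
        sasa_b = dense_grid_sasa(centers[3:], radii[3:], 1.4, n_points=200_000)
        oracle = np.concatenate([sasa_a - sasa_complex[:3], sasa_b - sasa_complex[3:]])
        got = out["per_residue"].sort_values(["chain", "residue_number"])["bsa"]
        # ~1% of a ~120 A^2 sphere: covers lattice + Monte Carlo error
        assert np.allclose(got, oracle, atol=1.5)

    def test_bsa_conservation_identity(self):
        """SASA(A) + SASA(B) - SASA(AB) equals the summed per-residue BSA."""
        rng = np.random.default_rng(12)
        rows, coords = [], []
        for i in range(6):
            rows.append(("A", i + 1, "ALA", "CA", "C"))
            coords.append(rng.uniform(0, 6, 3))
        for i in range(6):
            rows.append(("B", i + 1, "ALA", "CA", "C"))
            coords.append(rng.uniform(3, 9, 3))
        model = make_atomset(rows, np.array(coords))
        ga, gb = model.select("chain A"), model.select("chain B")
        out = st.buried_surface_area(model, ga, gb)
        a_tot = st.sasa(model.subset(ga))[0].sum()
        b_tot = st.sasa(model.subset(gb))[0].sum()
        ab_tot = st.sasa(model)[0].sum()
        delta = a_tot + b_tot - ab_tot
        assert abs(delta - out["per_residue"]["bsa"].sum()) <= 1e-6 * max(delta, 1.0)

    def test_overlapping_partition_rejected(self):
        model = self._dimer(3.0)
        both = np.ones(2, dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            st.buried_surface_area(model, both, both)


class TestRelativeSASA:
    def test_exposed_residue_near_unity_buried_near_zero(self):
        # a lone glycine N/CA/C triad is maximally exposed; caging it with a
        # shell of neighbors drives the fraction toward zero
        rows = [("A", 1, "GLY", "N", "N"), ("A", 1, "GLY", "CA", "C"),
                ("A", 1, "GLY", "C", "C"), ("A", 1, "GLY", "O", "O")]
        coords = [[-1.4, 0.9, 0], [0, 0, 0], [1.4, 0.9, 0], [2.4, 0.2, 0]]
        free = make_atomset(rows, coords)
        frac_free = st.relative_sasa(free).loc[0, "rel_sasa"]
        assert frac_free > 0.7

        shell_rows, shell_coords = list(rows), list(coords)
        golden = st._fibonacci_sphere(60) * 4.5
        for i, p in enumerate(golden):
            shell_rows.append(("A", 2 + i, "ALA", "CA", "C"))
            shell_coords.append((np.array([0.8, 0.5, 0.0]) + p).tolist())
        caged = make_atomset(shell_rows, np.array(shell_coords))
        frac_caged = st.relative_sasa(caged).set_index("residue_number").loc[1, "rel_sasa"]
        assert frac_caged < 0.1

    def test_fraction_is_sasa_over_reference(self):
        rows = [("A", 5, "THR", "CA", "C")]
        model = make_atomset(rows, [[0, 0, 0]])
        _, per_res = st.sasa(model)
        frac = st.relative_sasa(model).loc[0, "rel_sasa"]
        assert frac == pytest.approx(per_res.loc[0, "sasa"] / st.MAX_SASA["THR"])

    def test_unknown_residue_excluded_with_warning(self):
        rows = [("A", 1, "XYZ", "CA", "C"), ("A", 2, "ALA", "CA", "C")]
        model = make_atomset(rows, [[0, 0, 0], [50.0, 0, 0]])
        with pytest.warns(UserWarning, match="XYZ"):
            out = st.relative_sasa(model)
        assert out["residue_name"].tolist() == ["ALA"]


class TestPDBIO:
    def test_single_and_multi_model_roundtrip(self, tmp_path):
        spec = syn.GeneratorSpec(seed=6, n_residues=8, n_models=3,
                                 core_range=(1, 8), sigma_core=0.3,
                                 sigma_tail=0.3)
        ens, _ = syn.make_ensemble(spec)
        p = tmp_path / "ens.pdb"
        st.write_models(ens, p)
        back = st.read_models(p)
        assert back.n_models == 3
        assert len(back.atoms) == len(ens.atoms)
        assert np.abs(back.coords - ens.coords).max() < 1e-3  # PDB precision
        assert back.atoms["atom_name"].tolist() == ens.atoms["atom_name"].tolist()

    def test_twenty_model_file(self, tmp_path):
        spec = syn.GeneratorSpec(seed=7, n_residues=5, n_models=20,
                                 core_range=(1, 5), sigma_core=0.2,
                                 sigma_tail=0.2)
        ens, _ = syn.make_ensemble(spec)
        p = tmp_path / "ens20.pdb"
        st.write_models(ens, p)
        assert st.read_models(p).n_models == 20

    def test_roster_mismatch_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(ValueError, match="atoms"):
            st.read_models(p)


class TestSelect:
    def test_selection_grammar(self):
        rows = [
            ("A", 1, "ALA", "N", "N"), ("A", 1, "ALA", "CA", "C"),
            ("A", 2, "GLY", "CA", "C"), ("B", 5, "ALA", "CA", "C"),
        ]
        atoms = pd.DataFrame(rows, columns=st.ATOM_COLUMNS)
        assert st.select(atoms, "chain A").sum() == 3
        assert st.select(atoms, "chain A and resi 1").sum() == 2
        assert st.select(atoms, "name N,CA").sum() == 4
        assert st.select(atoms, "backbone and resi 1-2").sum() == 3
        assert st.select(atoms, "all").sum() == 4
        with pytest.raises(ValueError, match="unknown selection"):
            st.select(atoms, "bogus thing")
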