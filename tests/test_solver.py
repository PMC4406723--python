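import numpy as np
import pytest

from headforge import solver as slv
from headforge.grids import LabelVolume
from headforge.phantom import TISSUE_LABELS, default_head_spec, generate_label_phantom
from headforge.pipeline import DEFAULT_CONDUCTIVITY_TABLE


def bar_montage():
    return slv.ElectrodeMontage([
        slv.Electrode("A", 1.0, kind="face", axis=0, side=0),
        slv.Electrode("B", 0.0, kind="face", axis=0, side=-1),
    ])


@pytest.fixture(scope="module")
def head_setup():
    lab = generate_label_phantom(default_head_spec((28, 28, 28), (5.0, 5.0, 5.0)))
    sigma = np.zeros(lab.shape)
    for l, s in DEFAULT_CONDUCTIVITY_TABLE.items():
        sigma[lab.labels == l] = s
    return lab, sigma


class TestVoxelSolver:
    def test_parallel_plate_uniform_field(self):
        grid = (20, 8, 8)
        sol = slv.solve_voxel(np.full(grid, 2.0), bar_montage(), (1, 1, 1))
        L = 19e-3  # Dirichlet at voxel centres: 19 voxel gaps of 1 mm
        e = sol.e_magnitude()[sol.domain]
        assert np.allclose(e, 1.0 / L, rtol=1e-6)
        # current = sigma * A / L
        expected_i = 2.0 * 64e-6 / L
        assert sol.electrode_currents["A"] == pytest.approx(expected_i, rel=1e-6)
        assert sol.current_balance() <= 1e-6

    def test_two_layer_series(self):
        grid = (20, 6, 6)
        sigma = np.full(grid, 1.0)
        sigma[10:] = 3.0
        sol = slv.solve_voxel(sigma, bar_montage(), (1, 1, 1))
        e1 = sol.E[5, 3, 3, 0]
        e2 = sol.E[15, 3, 3, 0]
        assert e1 / e2 == pytest.approx(3.0, rel=1e-6)
        # series resistance: 9.5 mm of each sigma plus harmonic interface
        area = 36e-6
        r = (9.5e-3 / 1.0 + 9.5e-3 / 3.0) / area  # centre-to-centre path
        assert sol.electrode_currents["A"] == pytest.approx(1.0 / r, rel=1e-4)

    def test_sigma_scaling_linearity(self):
        grid = (12, 6, 6)
        rng = np.random.default_rng(0)
        sigma = rng.uniform(0.5, 2.0, grid)
        a = slv.solve_voxel(sigma, bar_montage(), (1, 1, 1))
        b = slv.solve_voxel(3.0 * sigma, bar_montage(), (1, 1, 1))
        dom = a.domain
        assert np.allclose(b.phi[dom], a.phi[dom], atol=1e-7)
        assert np.allclose(b.J[dom], 3.0 * a.J[dom], rtol=1e-5, atol=1e-10)

    def test_maximum_principle(self, head_setup):
        lab, sigma = head_setup
        sol = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("fpz_cz"),
                              lab.spacing)
        phi = sol.phi[sol.domain]
        assert phi.min() >= 0.0 - 1e-9
        assert phi.max() <= 1.0 + 1e-9

    def test_current_conservation_head(self, head_setup):
        lab, sigma = head_setup
        sol = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("fpz_cz"),
                              lab.spacing)
        assert sol.current_balance() <= 1e-6
        assert sol.residual <= 1e-8

    def test_face_aligned_two_layer_exact(self):
        # with the interface on a voxel face, harmonic-mean FV reproduces
        # the 1-D series circuit exactly at any resolution
        n = 10
        grid = (n, 4, 4)
        h = 2.0
        sigma = np.full(grid, 1.0)
        sigma[n // 2:] = 3.0
        sol = slv.solve_voxel(sigma, bar_montage(), (h, 1.0, 1.0))
        area = 16e-6
        l_half = (n / 2 - 0.5) * h * 1e-3
        r = (l_half / 1.0 + l_half / 3.0) / area
        assert sol.electrode_currents["A"] == pytest.approx(1.0 / r, rel=1e-8)

    def test_grid_refinement_convergence(self):
        # interface at 7.3 mm (never on a voxel face): the snapping error
        # decreases monotonically under x2 and x4 refinement
        errs = []
        for n in (10, 20, 40):
            grid = (n, 4, 4)
            h = 20.0 / n
            centers = (np.arange(n) + 0.5) * h
            sigma = np.where(centers < 7.3, 1.0, 3.0)[:, None, None] * np.ones(grid)
            sol = slv.solve_voxel(sigma, bar_montage(), (h, 1.0, 1.0))
            area = 16e-6
            l1 = (7.3 - h / 2) * 1e-3
            l2 = (20.0 - h / 2 - 7.3) * 1e-3
            i_exact = area / (l1 / 1.0 + l2 / 3.0)
            errs.append(abs(sol.electrode_currents["A"] - i_exact) / i_exact)
        assert errs[0] > errs[1] > errs[2]

    def test_disconnected_electrodes_error(self):
        grid = (10, 4, 4)
        sigma = np.full(grid, 1.0)
        sigma[5] = 0.0  # insulating wall
        with pytest.raises(ValueError, match="connected"):
            slv.solve_voxel(sigma, bar_montage(), (1, 1, 1))

    def test_diagonal_tensor_supported(self):
        grid = (12, 6, 6)
        sigma = np.zeros(grid + (3,))
        sigma[...] = [2.0, 1.0, 1.0]
        sol = slv.solve_voxel(sigma, bar_montage(), (1, 1, 1))
        L = 11e-3
        assert np.allclose(sol.J[5, 3, 3], [2.0 / L, 0, 0], atol=1e-6 / L)


class TestFEM:
    def test_homogeneous_bar_matches_closed_form(self):
        grid = (20, 8, 8)
        sig = np.zeros(grid + (3, 3))
        sig[...] = 2.0 * np.eye(3)
        sol = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
        L = 20e-3  # face electrodes fix the outer lattice planes
        e = sol.e_magnitude()[sol.domain]
        assert np.allclose(e, 1.0 / L, rtol=1e-6)
        assert sol.electrode_currents["A"] == pytest.approx(2.0 * 64e-6 / L,
                                                            rel=1e-6)

    def test_cross_solver_agreement(self):
        # matched conduction gap: voxel solver with n voxels has a
        # (n-1)-voxel centre-to-centre gap; FEM with n-1 voxels spans the
        # same distance between its outer lattice planes
        n = 16
        vox = slv.solve_voxel(np.full((n, 6, 6), 1.5), bar_montage(), (1, 1, 1))
        sig = np.zeros((n - 1, 6, 6) + (3, 3))
        sig[...] = 1.5 * np.eye(3)
        fem = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
        ev = vox.e_magnitude()[vox.domain]
        ef = fem.e_magnitude()[fem.domain]
        assert np.allclose(ev.mean(), ef.mean(), rtol=1e-6)
        assert np.allclose(ev, ev.mean(), rtol=1e-6)
        assert np.allclose(ef, ef.mean(), rtol=1e-6)

    def test_anisotropic_homogeneous_closed_form(self):
        grid = (16, 8, 8)
        sig = np.zeros(grid + (3, 3))
        sig[...] = np.diag([1.0, 2.5, 4.0])
        sol = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
        L = 16e-3
        j = sol.J[sol.domain]
        assert np.allclose(j[:, 0], 1.0 / L, rtol=1e-6)
        assert np.allclose(j[:, 1:], 0.0, atol=1e-6 / L)

    def test_full_tensor_rotation_equivariance(self):
        # rotating conductivity and geometry together preserves |E| stats:
        # swap x and y axes entirely
        grid = (10, 10, 6)
        t = np.array([[1.0, 0.3, 0.0], [0.3, 2.0, 0.0], [0.0, 0.0, 1.5]])
        sig = np.zeros(grid + (3, 3))
        sig[...] = t
        sol_a = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
        perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        t_rot = perm @ t @ perm.T
        sig_b = np.zeros((10, 10, 6) + (3, 3))
        sig_b[...] = t_rot
        montage_y = slv.ElectrodeMontage([
            slv.Electrode("A", 1.0, kind="face", axis=1, side=0),
            slv.Electrode("B", 0.0, kind="face", axis=1, side=-1),
        ])
        sol_b = slv.solve_fem(sig_b, montage_y, (1, 1, 1))
        ea = np.sort(sol_a.e_magnitude()[sol_a.domain])
        eb = np.sort(sol_b.e_magnitude()[sol_b.domain])
        assert np.allclose(ea, eb, rtol=1e-9)

    def test_non_spd_tensor_rejected(self):
        grid = (6, 4, 4)
        sig = np.zeros(grid + (3, 3))
        sig[...] = np.diag([1.0, -0.5, 1.0])
        with pytest.raises(ValueError):
            slv.solve_fem(sig, bar_montage(), (1, 1, 1))

    def test_current_balance(self):
        grid = (10, 6, 6)
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 2.0, grid)
        sig = vals[..., None, None] * np.eye(3)
        sol = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
        assert sol.current_balance() <= 1e-6


class TestMontages:
    def test_presets(self):
        for name in ("fpz_cz", "cz_ring"):
            m = slv.ElectrodeMontage.preset(name)
            assert len({e.potential for e in m.electrodes}) >= 2

    def test_montage_json_roundtrip(self, tmp_path):
        m = slv.ElectrodeMontage.preset("cz_ring")
        m.to_json(tmp_path / "m.json")
        m2 = slv.ElectrodeMontage.from_json(tmp_path / "m.json")
        assert [e.name for e in m2.electrodes] == [e.name for e in m.electrodes]

    def test_overlapping_electrodes_rejected(self, head_setup):
        lab, sigma = head_setup
        m = slv.ElectrodeMontage([
            slv.Electrode("A", 1.0, direction=(0, 0, 1), radius_deg=40.0),
            slv.Electrode("B", 0.0, direction=(0.05, 0, 1), radius_deg=40.0),
        ])
        with pytest.raises(ValueError, match="overlap"):
            slv.solve_voxel(sigma, m, lab.spacing)

    def test_compare_montages_identical_solutions(self, head_setup):
        lab, sigma = head_setup
        sol = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("fpz_cz"),
                              lab.spacing)
        eye = lab.mask(TISSUE_LABELS["eye_left"]) | lab.mask(
            TISSUE_LABELS["eye_right"])
        rep = slv.compare_montages(sol, sol, eye)
        for q in ("E", "J"):
            for v in rep["ratio_a_over_b"][q].values():
                assert v == pytest.approx(1.0)

    def test_doubling_potential_doubles_field(self, head_setup):
        lab, sigma = head_setup
        m1 = slv.ElectrodeMontage.preset("fpz_cz", amplitude=1.0)
        m2 = slv.ElectrodeMontage.preset("fpz_cz", amplitude=2.0)
        a = slv.solve_voxel(sigma, m1, lab.spacing)
        b = slv.solve_voxel(sigma, m2, lab.spacing)
        dom = a.domain
        ea = a.e_magnitude()[dom]
        eb = b.e_magnitude()[dom]
        assert np.median(eb) == pytest.approx(2.0 * np.median(ea), rel=1e-6)

    def test_frontal_montage_higher_eye_current(self, head_setup):
        lab, sigma = head_setup
        frontal = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("fpz_cz"),
                                  lab.spacing)
        ring = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("cz_ring"),
                               lab.spacing)
        eye = lab.mask(TISSUE_LABELS["eye_left"]) | lab.mask(
            TISSUE_LABELS["eye_right"])
        rep = slv.compare_montages(frontal, ring, eye)
        assert rep["ratio_a_over_b"]["J"]["p50"] > 1.0

    def test_empty_region_errors(self, head_setup):
        lab, sigma = head_setup
        sol = slv.solve_voxel(sigma, slv.ElectrodeMontage.preset("fpz_cz"),
                              lab.spacing)
        with pytest.raises(ValueError):
            slv.compare_montages(sol, sol, np.zeros(lab.shape, dtype=bool))


class TestScalarVsTensor:
    def test_isotropic_consistency_ratio_one(self, head_setup):
        lab, _ = head_setup
        grid = lab.shape
        tensors = np.zeros(grid + (3, 3))
        for l, s in DEFAULT_CONDUCTIVITY_TABLE.items():
            tensors[lab.labels == l] = s * np.eye(3)
        brain = np.isin(lab.labels, [TISSUE_LABELS[k]
                                     for k in ("wm", "gm", "csf", "ventricles")])
        rep = slv.scalar_vs_tensor_study(
            lab, DEFAULT_CONDUCTIVITY_TABLE, tensors,
            slv.ElectrodeMontage.preset("fpz_cz"), brain)
        assert rep["ratio_tensor_over_scalar"] == pytest.approx(1.0, abs=1e-3)

    def test_anisotropic_wm_changes_ratio(self, head_setup):
        lab, _ = head_setup
        grid = lab.shape
        tensors = np.zeros(grid + (3, 3))
        for l, s in DEFAULT_CONDUCTIVITY_TABLE.items():
            tensors[lab.labels == l] = s * np.eye(3)
        # trace-preserving anisotropy in WM along x
        wm = lab.mask(TISSUE_LABELS["wm"])
        s_wm = DEFAULT_CONDUCTIVITY_TABLE[TISSUE_LABELS["wm"]]
        tensors[wm] = s_wm * np.diag([2.0, 0.5, 0.5])
        brain = np.isin(lab.labels, [TISSUE_LABELS[k]
                                     for k in ("wm", "gm", "csf", "ventricles")])
        rep = slv.scalar_vs_tensor_study(
            lab, DEFAULT_CONDUCTIVITY_TABLE, tensors,
            slv.ElectrodeMontage.preset("fpz_cz"), brain)
        assert rep["ratio_tensor_over_scalar"] != pytest.approx(1.0, abs=1e-3)
        assert rep["direction"] in ("weaker", "stronger")

    def test_lower_cap_monotone_current(self):
        # 1-D-like homogeneous bar: smaller cap -> smaller current
        grid = (14, 5, 5)
        currents = []
        for cap in (2.0, 1.0, 0.5):
            sig = np.zeros(grid + (3, 3))
            sig[...] = min(3.0, cap) * np.eye(3)
            sol = slv.solve_fem(sig, bar_montage(), (1, 1, 1))
            currents.append(sol.electrode_currents["A"])
        assert currents[0] > currents[1] > currents[2]
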