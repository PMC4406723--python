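import numpy as np
import pytest

from headforge import dti
from headforge.phantom import (
    DiffusionProtocol,
    PhantomSpec,
    RaterModel,
    TISSUE_LABELS,
    TissueDef,
    default_head_spec,
    default_contrast_means,
    generate_label_phantom,
    make_tensor_field,
    render_contrast,
    simulate_rater,
    synth_dwi,
)

from conftest import make_sphere_mask


def sphere_spec(radius=5.0, grid=32, spacing=1.0):
    c = (grid - 1) * spacing / 2.0
    return PhantomSpec(
        (grid,) * 3, (spacing,) * 3,
        [TissueDef(1, "ball",
                   {"kind": "ellipsoid", "center": [c] * 3, "radii": [radius] * 3})],
    )


class TestGenerateLabelPhantom:
    def test_sphere_voxel_count_matches_brute_force(self):
        # oracle: scan all 32^3 voxel centres
        spec = sphere_spec()
        vol = generate_label_phantom(spec)
        c = 31 / 2.0
        oracle = make_sphere_mask((32, 32, 32), (c, c, c), 5.0)
        assert vol.mask(1).sum() == oracle.sum()
        assert np.array_equal(vol.mask(1), oracle)

    def test_empty_tissue_defs_all_background(self):
        vol = generate_label_phantom(PhantomSpec((8, 8, 8), (1, 1, 1), []))
        assert np.all(vol.labels == 0)

    def test_deterministic(self):
        spec = default_head_spec((24, 24, 24), (4, 4, 4), seed=7)
        a = generate_label_phantom(spec)
        b = generate_label_phantom(spec)
        assert np.array_equal(a.labels, b.labels)

    def test_every_voxel_single_label(self, head_labels_32):
        assert head_labels_32.labels.min() >= 0

    def test_required_tissues_present(self, head_labels_32):
        present = set(head_labels_32.present_labels().tolist())
        for name in ("skin", "skull_outer", "diploe", "skull_inner",
                     "csf", "gm", "wm", "ventricles"):
            assert TISSUE_LABELS[name] in present

    def test_geometry_exceeding_grid_names_tissue(self):
        spec = PhantomSpec(
            (16, 16, 16), (1, 1, 1),
            [TissueDef(3, "huge",
                       {"kind": "ellipsoid", "center": [8] * 3, "radii": [40] * 3})],
        )
        with pytest.raises(ValueError, match="huge"):
            generate_label_phantom(spec)

    def test_duplicate_labels_rejected(self):
        defs = [
            TissueDef(1, "a", {"kind": "ellipsoid", "center": [8] * 3, "radii": [2] * 3}),
            TissueDef(1, "b", {"kind": "ellipsoid", "center": [8] * 3, "radii": [3] * 3}),
        ]
        with pytest.raises(ValueError):
            PhantomSpec((16, 16, 16), (1, 1, 1), defs)

    def test_cylinder_geometry(self):
        spec = PhantomSpec(
            (16, 16, 16), (1, 1, 1),
            [TissueDef(1, "rod", {"kind": "cylinder", "center": [7.5] * 3,
                                  "axis": [0, 0, 1], "radius": 3.0,
                                  "half_length": 5.0})],
        )
        vol = generate_label_phantom(spec)
        # brute force
        idx = np.indices((16, 16, 16), dtype=float)
        inplane = (idx[0] - 7.5) ** 2 + (idx[1] - 7.5) ** 2 <= 9.0
        along = np.abs(idx[2] - 7.5) <= 5.0
        assert np.array_equal(vol.mask(1), inplane & along)

    def test_spec_json_roundtrip(self, tmp_path):
        spec = default_head_spec((16, 16, 16), (4, 4, 4), seed=3)
        spec.to_json(tmp_path / "spec.json")
        spec2 = PhantomSpec.from_json(tmp_path / "spec.json")
        a = generate_label_phantom(spec)
        b = generate_label_phantom(spec2)
        assert np.array_equal(a.labels, b.labels)


class TestRenderContrast:
    def test_noiseless_piecewise_constant(self, head_labels_32):
        means = default_contrast_means()["t1"]
        img = render_contrast(head_labels_32, means, 0.0, 0.0)
        for label in head_labels_32.present_labels():
            vals = img.values[head_labels_32.labels == label]
            assert np.allclose(vals, means[int(label)])

    def test_noise_sd_matches_sigma(self):
        # law-of-large-numbers check on >= 1e4 voxels of one tissue
        lab = generate_label_phantom(PhantomSpec((30, 30, 30), (1, 1, 1), []))
        img = render_contrast(lab, {0: 100.0}, noise_sigma=5.0, seed=11)
        sd = img.values.std()
        assert abs(sd - 5.0) / 5.0 < 0.05

    def test_missing_label_errors(self, head_labels_32):
        with pytest.raises(ValueError, match="missing"):
            render_contrast(head_labels_32, {0: 1.0}, 0.0, 0.0)

    def test_two_contrasts_label_consistent(self, head_labels_32):
        m = default_contrast_means()
        t1 = render_contrast(head_labels_32, m["t1"], 0.0, 0.0)
        t2 = render_contrast(head_labels_32, m["t2"], 0.0, 0.0)
        wm = head_labels_32.mask(TISSUE_LABELS["wm"])
        assert np.allclose(t1.values[wm], m["t1"][TISSUE_LABELS["wm"]])
        assert np.allclose(t2.values[wm], m["t2"][TISSUE_LABELS["wm"]])

    def test_deterministic(self, head_labels_32):
        means = default_contrast_means()["t1"]
        a = render_contrast(head_labels_32, means, 2.0, 0.1, seed=5)
        b = render_contrast(head_labels_32, means, 2.0, 0.1, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_bias_bounded(self, head_labels_32):
        means = default_contrast_means()["t1"]
        img = render_contrast(head_labels_32, means, 0.0, 0.2, seed=2)
        wm = head_labels_32.mask(TISSUE_LABELS["wm"])
        mean = means[TISSUE_LABELS["wm"]]
        assert np.all(img.values[wm] >= 0.8 * mean - 1e-9)
        assert np.all(img.values[wm] <= 1.2 * mean + 1e-9)


class TestSimulateRater:
    def test_perfect_rater_identity(self, head_labels_32):
        truth = head_labels_32.mask(TISSUE_LABELS["wm"])
        out = simulate_rater(truth, RaterModel(1.0, 1.0, seed=0))
        assert np.array_equal(out, truth)

    def test_binomial_expectation(self):
        truth = np.zeros((10, 10, 100), dtype=bool)
        truth.flat[:1000] = True
        out = simulate_rater(truth, RaterModel(0.9, 0.95, seed=3))
        hits = int((out & truth).sum())
        # 1000 fg kept w.p. 0.9 -> 900 +- 3*sqrt(1000*0.9*0.1)
        assert abs(hits - 900) <= 3 * np.sqrt(1000 * 0.9 * 0.1)
        false_pos = int((out & ~truth).sum())
        nb = truth.size - 1000
        assert abs(false_pos - 0.05 * nb) <= 3 * np.sqrt(nb * 0.05 * 0.95)

    def test_expected_dice_formula(self):
        # E[D] ~ 2 p F / (p F + F + (1-q) B) for mode-A raters
        p, q = 0.9, 0.95
        truth = np.zeros((20, 20, 25), dtype=bool)
        truth.flat[:2000] = True
        F = 2000
        B = truth.size - F
        expected = 2 * p * F / (p * F + F + (1 - q) * B)
        dices = []
        for s in range(20):
            out = simulate_rater(truth, RaterModel(p, q, seed=s))
            inter = (out & truth).sum()
            dices.append(2 * inter / (out.sum() + F))
        assert abs(np.mean(dices) - expected) < 0.02

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError):
            simulate_rater(np.zeros((4, 4, 4), dtype=bool), RaterModel(0.9, 0.9))

    def test_jitter_mode_deterministic(self, head_labels_32):
        truth = head_labels_32.mask(TISSUE_LABELS["gm"])
        m = RaterModel(0.95, 0.99, boundary_jitter_mm=2.0, seed=9)
        a = simulate_rater(truth, m, head_labels_32.spacing)
        b = simulate_rater(truth, m, head_labels_32.spacing)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, truth)  # jitter + flips change the mask

    def test_label_conservation(self, head_labels_32):
        before = head_labels_32.labels.copy()
        truth = head_labels_32.mask(TISSUE_LABELS["wm"])
        simulate_rater(truth, RaterModel(0.8, 0.8, seed=1))
        assert np.array_equal(head_labels_32.labels, before)


class TestTensorFieldGeneration:
    def test_gm_isotropic_fa_zero(self, head_labels_32):
        tf = make_tensor_field(head_labels_32)
        gm = head_labels_32.mask(TISSUE_LABELS["gm"])
        assert np.allclose(dti.fa(tf.tensors[gm]), 0.0, atol=1e-12)

    def test_wm_fa_matches_formula(self, head_labels_32):
        tf = make_tensor_field(head_labels_32)
        wm = head_labels_32.mask(TISSUE_LABELS["wm"])
        lam = np.array([1.4e-3, 0.35e-3, 0.35e-3])
        mean = lam.mean()
        expected = np.sqrt(1.5) * np.linalg.norm(lam - mean) / np.linalg.norm(lam)
        got = dti.fa(tf.tensors[wm])
        assert np.allclose(got, expected, atol=1e-10)

    def test_wm_principal_direction_follows_fibers(self, head_labels_32):
        lab = head_labels_32
        tf = make_tensor_field(lab)
        wm = lab.mask(TISSUE_LABELS["wm"])
        idx = np.argwhere(wm)
        pts = idx * lab.spacing
        center = (np.asarray(lab.shape) - 1) * lab.spacing / 2.0
        axis = np.array([0.0, 1.0, 0.0])
        w, v = np.linalg.eigh(tf.tensors[wm])
        e1 = v[..., -1]  # largest eigenvalue
        rel = pts - center
        tang = np.cross(np.broadcast_to(axis, rel.shape), rel)
        norms = np.linalg.norm(tang, axis=1)
        ok = norms > 1e-6
        cos = np.abs(np.einsum("ij,ij->i", e1[ok], tang[ok] / norms[ok, None]))
        assert np.all(cos > 0.999)

    def test_all_tensors_spd(self, head_labels_32):
        tf = make_tensor_field(head_labels_32)
        w = np.linalg.eigvalsh(tf.tensors[tf.mask])
        assert np.all(w > 0)

    def test_invalid_diffusivities_error(self, head_labels_32):
        with pytest.raises(ValueError):
            make_tensor_field(head_labels_32, {"gm": -1.0})


class TestSynthDwi:
    def test_b0_returns_s0(self, head_labels_32):
        tf = make_tensor_field(head_labels_32)
        prot = DiffusionProtocol.standard(8)
        sig = synth_dwi(tf, prot, s0=500.0)
        assert np.allclose(sig[..., 0], 500.0)

    def test_isotropic_closed_form(self):
        lab = generate_label_phantom(default_head_spec((16, 16, 16), (4, 4, 4)))
        tf = make_tensor_field(lab)
        prot = DiffusionProtocol.standard(8, b=800.0)
        sig = synth_dwi(tf, prot, s0=1000.0)
        gm = lab.mask(TISSUE_LABELS["gm"])
        expected = 1000.0 * np.exp(-800.0 * 0.8e-3)
        assert np.allclose(sig[gm][:, 1:], expected, rtol=1e-12)

    def test_underdetermined_protocol_rejected(self):
        bvals = [0.0, 800, 800, 800]
        bvecs = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        with pytest.raises(ValueError):
            DiffusionProtocol(bvals, bvecs)

    def test_protocol_fsl_roundtrip(self, tmp_path):
        prot = DiffusionProtocol.standard(12)
        prot.to_fsl(tmp_path / "bvals", tmp_path / "bvecs")
        prot2 = DiffusionProtocol.from_fsl(tmp_path / "bvals", tmp_path / "bvecs")
        assert np.allclose(prot.bvals, prot2.bvals)
        assert np.allclose(prot.bvecs, prot2.bvecs, atol=1e-7)
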