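"""Diffusion tensor reconstruction and anisotropic conductivity mapping.

Log-linear least-squares tensor fitting (7 unknowns per voxel), fractional
anisotropy, tissue masking, the linear diffusivity-to-conductivity map
with eigenvalue capping, and resampling of tensor fields onto solver
grids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import LabelVolume
from .phantom import DiffusionProtocol, TensorField

__all__ = [
    "fit_tensor",
    "fa",
    "mask_tensors",
    "map_conductivity",
    "sample_to_grid",
    "DEFAULT_CONDUCTIVITY_SCALE",
    "CONDUCTIVITY_CAP",
]

# Linear sigma = k * D coefficient (S*s/mm^3) from the standard effective-
# medium literature; configurable because published values vary.
DEFAULT_CONDUCTIVITY_SCALE = 0.844
# Conductivity eigenvalues are capped at the CSF value.
CONDUCTIVITY_CAP = 1.8  # S/m

EIG_FLOOR = 1e-6  # mm^2/s


def fit_tensor(
    dwi: np.ndarray,
    protocol: DiffusionProtocol,
    spacing,
    origin=(0.0, 0.0, 0.0),
    mask: np.ndarray | None = None,
) -> TensorField:
    """Per-voxel least-squares fit of ln S = ln S0 − b gᵀ D g.

    ``dwi`` has the measurement axis last.  Voxels with non-positive
    signal anywhere are dropped from the mask.  Negative eigenvalues are
    clamped to a small positive floor (conditioning), which keeps every
    fitted tensor positive definite.
    """
    dwi = np.asarray(dwi, dtype=float)
    grid_shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & np.all(dwi > 0, axis=-1)

    design = protocol.design_matrix()
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("rank-deficient design matrix: protocol invalid")
    pinv = np.linalg.pinv(design)

    tensors = np.zeros(grid_shape + (3, 3))
    s0 = np.zeros(grid_shape)
    sel = dwi[mask]
    if sel.size:
        beta = np.log(sel) @ pinv.T  # (n_voxels, 7)
        s0[mask] = np.exp(beta[:, 0])
        six = beta[:, 1:]
        t = TensorField.from_six(six)
        # clamp negative eigenvalues (noise) to the floor
        w, v = np.linalg.eigh(t)
        if np.any(w < EIG_FLOOR):
            w = np.maximum(w, EIG_FLOOR)
            t = np.einsum("nij,nj,nkj->nik", v, w, v)
        tensors[mask] = t
    return TensorField(
        tensors, mask, np.asarray(spacing, float), np.asarray(origin, float), s0=s0
    )


def fa(tensor: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of one or many symmetric 3x3 tensors.

    FA = sqrt(3/2) * ||λ − λ̄|| / ||λ||; the zero tensor maps to 0.
    """
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    w = np.linalg.eigvalsh(t)
    mean = w.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(w - mean, axis=-1)
    den = np.linalg.norm(w, axis=-1)
    out = np.where(den > 0, np.sqrt(1.5) * num / np.maximum(den, 1e-300), 0.0)
    return float(out[0]) if single else out


def mask_tensors(field: TensorField, labels: LabelVolume, keep_labels) -> TensorField:
    """Restrict the validity mask to voxels whose label is in ``keep_labels``."""
    if labels.shape != field.grid_shape:
        raise ValueError("label grid must match tensor grid")
    keep = np.isin(labels.labels, list(keep_labels))
    out = field.copy()
    out.mask = field.mask & keep
    if not out.mask.any():
        import warnings

        warnings.warn("mask_tensors produced an empty tensor field", stacklevel=2)
    return out


def map_conductivity(
    field: TensorField,
    labels: LabelVolume,
    fallback: dict[int, float],
    scale_k: float = DEFAULT_CONDUCTIVITY_SCALE,
    cap: float = CONDUCTIVITY_CAP,
) -> TensorField:
    """σ = k·D eigenvalue-wise with the eigenvectors preserved.

    Eigenvalues are clipped into (ε, cap]; voxels outside the DTI mask
    get an isotropic tensor from the per-tissue ``fallback`` table
    (label → S/m).  Fallback values are capped too.
    """
    if scale_k <= 0 or cap <= 0:
        raise ValueError("scale_k and cap must be positive")
    present = np.unique(labels.labels[~field.mask])
    missing = [int(l) for l in present if int(l) not in fallback]
    if missing:
        raise ValueError(f"no fallback conductivity for labels {missing}")

    eps = 1e-9
    out = np.zeros(field.grid_shape + (3, 3))
    w, v = np.linalg.eigh(field.tensors[field.mask])
    w = np.clip(scale_k * w, eps, cap)
    out[field.mask] = np.einsum("nij,nj,nkj->nik", v, w, v)
    eye = np.eye(3)
    for label, sigma in fallback.items():
        sel = (labels.labels == label) & ~field.mask
        if sel.any():
            out[sel] = min(max(float(sigma), 0.0), cap) * eye
    return TensorField(
        out, np.ones(field.grid_shape, dtype=bool), field.spacing, field.origin
    )


def sample_to_grid(
    field: TensorField,
    points_mm: np.ndarray,
    fallback_sigma: float = 0.0,
    cap: float | None = None,
) -> np.ndarray:
    """Tensor at each query point by component-wise trilinear interpolation,
    then re-symmetrisation and optional eigenvalue re-clipping.

    Points outside the source grid get an isotropic ``fallback_sigma``
    tensor.  Returns an ``(n, 3, 3)`` array.
    """
    pts = np.asarray(points_mm, dtype=float).reshape(-1, 3)
    vox = (pts - field.origin[None, :]) / field.spacing[None, :]
    n = np.asarray(field.grid_shape, dtype=float)
    inside = np.all((vox >= 0) & (vox <= n[None, :] - 1), axis=1)

    six_src = field.six_components()
    six = np.zeros((pts.shape[0], 6))
    coords = vox[inside].T
    for c in range(6):
        six[inside, c] = ndimage.map_coordinates(
            six_src[..., c], coords, order=1, mode="nearest"
        )
    out = TensorField.from_six(six)
    out[~inside] = fallback_sigma * np.eye(3)
    out = 0.5 * (out + np.swapaxes(out, -1, -2))
    if cap is not None:
        w, v = np.linalg.eigh(out)
        w = np.clip(w, 1e-9, cap)
        out = np.einsum("nij,nj,nkj->nik", v, w, v)
    return out
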