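"""12-DOF affine registration maximising normalised mutual information.

The transform maps moving-image world coordinates (mm) to fixed-image
world coordinates as ``T · R · Sh · Sc`` (translation, rotation, shear,
scale — applied right to left).  NMI follows Studholme's dialect
``(H(A) + H(B)) / H(A, B)``, computed on a joint histogram over the
valid overlap with bin ranges set by the 1st–99th intensity percentiles.
Optimisation is a coarse-to-fine pyramid with a derivative-free (Powell)
search per level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .grids import ScalarImage

__all__ = ["AffineTransform", "JointHistogram", "resample", "nmi", "register_affine"]


def _rot_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform:
    """12-parameter affine: (tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz).

    Translations in mm, rotations in radians (R = Rz·Ry·Rx), scales
    dimensionless, shears as upper-triangular unit factors.  The 4x4
    homogeneous matrix composes as T·R·Sh·Sc.
    """

    params: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], float)
    )

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float).reshape(12)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        t = self.params[0:3]
        R = _rot_matrix(*self.params[3:6])
        s = self.params[6:9]
        hxy, hxz, hyz = self.params[9:12]
        Sh = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        M = np.eye(4)
        M[:3, :3] = R @ Sh @ np.diag(s)
        M[:3, 3] = t
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "AffineTransform":
        """Recover the 12 parameters from a homogeneous matrix via QR
        decomposition (orthogonal rotation times upper-triangular
        shear·scale with positive diagonal)."""
        M = np.asarray(M, dtype=float)
        A = M[:3, :3]
        Q, U = np.linalg.qr(A)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q = Q * signs[None, :]
        U = U * signs[:, None]
        if np.linalg.det(Q) < 0:  # keep a proper rotation
            Q[:, 2] *= -1
            U[2, :] *= -1
        sy = np.clip(-Q[2, 0], -1.0, 1.0)
        ry = np.arcsin(sy)
        if abs(Q[2, 0]) < 1.0 - 1e-12:
            rx = np.arctan2(Q[2, 1], Q[2, 2])
            rz = np.arctan2(Q[1, 0], Q[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-Q[1, 2], Q[1, 1])
            rz = 0.0
        s = np.diag(U).copy()
        hxy = U[0, 1] / U[1, 1]
        hxz = U[0, 2] / U[2, 2]
        hyz = U[1, 2] / U[2, 2]
        params = np.array(
            [M[0, 3], M[1, 3], M[2, 3], rx, ry, rz, s[0], s[1], s[2], hxy, hxz, hyz]
        )
        return cls(params)

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map (…, 3) mm points through the transform."""
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform.from_matrix(self.matrix @ other.matrix)

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = {
            "params": self.params.tolist(),
            "matrix": self.matrix.tolist(),
            "units": "mm",
            "convention": "voxel-center; matrix = T*R*Sh*Sc",
        }
        if metadata:
            payload["metadata"] = metadata
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["params"]))


@dataclass
class JointHistogram:
    counts: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def entropies(self) -> tuple[float, float, float]:
        p = self.counts / self.counts.sum()
        pa = p.sum(axis=1)
        pb = p.sum(axis=0)

        def H(x):
            x = x[x > 0]
            return float(-np.sum(x * np.log(x)))

        return H(pa), H(pb), H(p.ravel())


def resample(
    img: ScalarImage,
    spacing_mm=None,
    transform: AffineTransform | None = None,
    interp: str = "linear",
    shape: tuple[int, int, int] | None = None,
    origin_mm=None,
) -> ScalarImage:
    """Resample ``img`` onto a new grid through ``transform``.

    The output grid (``shape``/``spacing_mm``/``origin_mm``, defaulting
    to the input's geometry) lives in fixed space; each output voxel
    centre is mapped through ``transform⁻¹`` into the input image.
    Out-of-field samples are marked invalid.
    """
    if interp not in ("nearest", "linear"):
        raise ValueError("interp must be 'nearest' or 'linear'")
    order = 0 if interp == "nearest" else 1
    spacing = img.spacing if spacing_mm is None else np.asarray(spacing_mm, float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    origin = img.origin if origin_mm is None else np.asarray(origin_mm, float).reshape(3)
    if shape is None:
        extent = (np.asarray(img.shape) - 1) * img.spacing
        shape = tuple(np.maximum(1, np.round(extent / spacing).astype(int) + 1))
    transform = transform or AffineTransform.identity()
    Minv = transform.inverse_matrix()

    idx = np.indices(shape, dtype=float)
    world = np.stack([origin[a] + spacing[a] * idx[a] for a in range(3)])
    src_mm = np.einsum("ab,b...->a...", Minv[:3, :3], world) + Minv[:3, 3].reshape(3, 1, 1, 1)
    src_vox = (src_mm - img.origin.reshape(3, 1, 1, 1)) / img.spacing.reshape(3, 1, 1, 1)

    n = np.asarray(img.shape, dtype=float).reshape(3, 1, 1, 1)
    inside = np.all((src_vox >= 0) & (src_vox <= n - 1), axis=0)
    values = ndimage.map_coordinates(img.values, src_vox, order=order, mode="nearest")
    valid = inside
    if img.valid is not None:
        vsamp = ndimage.map_coordinates(
            img.valid.astype(float), src_vox, order=0, mode="constant", cval=0.0
        )
        valid = valid & (vsamp > 0.5)
    return ScalarImage(values, spacing, origin, valid=valid)


def joint_histogram(a: ScalarImage, b: ScalarImage, bins: int = 64) -> JointHistogram:
    """Joint histogram over the valid overlap; bin ranges span each
    image's 1st–99th percentiles (outliers clipped into end bins)."""
    if a.shape != b.shape:
        raise ValueError("images must share a grid; resample first")
    overlap = a.valid_mask() & b.valid_mask()
    if not overlap.any():
        raise ValueError("empty valid overlap")
    va = a.values[overlap]
    vb = b.values[overlap]

    def edges(v):
        lo, hi = np.percentile(v, [1.0, 99.0])
        if hi <= lo:
            hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)

    ea, eb = edges(va), edges(vb)
    ia = np.clip(np.searchsorted(ea, va, side="right") - 1, 0, bins - 1)
    ib = np.clip(np.searchsorted(eb, vb, side="right") - 1, 0, bins - 1)
    counts = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    return JointHistogram(counts, ea, eb)


def nmi(a: ScalarImage, b: ScalarImage, bins: int = 64) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B) in [1, 2]."""
    hist = joint_histogram(a, b, bins=bins)
    ha, hb, hab = hist.entropies()
    if hab == 0.0:
        return 2.0  # both images constant on the overlap: perfectly dependent
    return (ha + hb) / hab


def _downsample(img: ScalarImage, factor: int, presmooth: float = 1.0) -> ScalarImage:
    """Anti-aliased decimation plus a mild extra blur.

    The extra blur (``presmooth`` voxels, applied at every level including
    full resolution) regularises the NMI landscape: without it the optimum
    of piecewise-constant renderings is measurably displaced by linear-
    interpolation histogram artefacts.
    """
    sig = np.sqrt((0.5 * factor) ** 2 + presmooth**2) if factor > 1 else presmooth
    sm = ndimage.gaussian_filter(img.values, sigma=sig, mode="nearest") if sig > 0 \
        else img.values
    vals = sm[::factor, ::factor, ::factor]
    valid = None if img.valid is None else img.valid[::factor, ::factor, ::factor]
    return ScalarImage(vals, img.spacing * factor, img.origin.copy(), valid=valid)


class _NmiCost:
    """Cached NMI cost for one pyramid level.

    The fixed image's bin indices, the output-grid world coordinates and
    both images' bin edges are precomputed; each evaluation is a matrix
    multiply, one trilinear sampling pass and a joint bincount.
    """

    def __init__(self, fixed: ScalarImage, moving: ScalarImage, bins: int,
                 max_samples: int = 8000, seed: int = 0, order: int = 1):
        self.bins = bins
        self.moving = moving
        self.order = order
        # cubic sampling needs the spline prefilter applied once up front
        self.mv_coeffs = (moving.values if order == 1 else
                          ndimage.spline_filter(moving.values, order=order))
        fixed_valid = fixed.valid_mask().ravel()
        idx = np.indices(fixed.shape, dtype=float).reshape(3, -1)
        world = fixed.origin[:, None] + fixed.spacing[:, None] * idx
        va = fixed.values.ravel()

        def edges(v):
            lo, hi = np.percentile(v, [1.0, 99.0])
            if hi <= lo:
                hi = lo + 1.0
            return np.linspace(lo, hi, bins + 1)

        self.edges_a = edges(va[fixed_valid])
        # deterministic random subset of valid fixed voxels: histogram
        # estimation needs far fewer samples than the full grid
        valid_idx = np.flatnonzero(fixed_valid)
        if valid_idx.size > max_samples:
            sel = np.random.default_rng(seed).choice(
                valid_idx, size=max_samples, replace=False)
        else:
            sel = valid_idx
        self.world = np.ascontiguousarray(world[:, sel])
        # linear Parzen bin coordinates for the (static) fixed side
        lo_a = self.edges_a[0]
        wid_a = self.edges_a[1] - lo_a
        fa = np.clip(va[sel] / wid_a - lo_a / wid_a - 0.5, 0.0, bins - 1.0)
        self.ia0 = np.minimum(fa.astype(np.int64), bins - 2)
        self.wa1 = fa - self.ia0
        mv_valid = moving.valid_mask()
        self.edges_b = edges(moving.values[mv_valid])
        self.mv_shape = np.asarray(moving.shape, dtype=float)

    def __call__(self, transform: AffineTransform) -> float:
        Minv = transform.inverse_matrix()
        src_mm = Minv[:3, :3] @ self.world + Minv[:3, 3][:, None]
        src_vox = (src_mm - self.moving.origin[:, None]) / self.moving.spacing[:, None]
        ok = np.all(
            (src_vox >= 0) & (src_vox <= self.mv_shape[:, None] - 1), axis=0)
        if not ok.any():
            return -1.0
        samples = ndimage.map_coordinates(
            self.mv_coeffs, src_vox[:, ok], order=self.order,
            prefilter=False, mode="nearest")
        # linear Parzen window on both axes: each sample spreads over a 2x2
        # bin patch, making the cost smooth under small motions (hard
        # assignment creates plateaus and biased optima otherwise)
        lo = self.edges_b[0]
        width = self.edges_b[1] - lo
        fb = np.clip((samples - lo) / width - 0.5, 0.0, self.bins - 1.0)
        ib0 = np.minimum(fb.astype(np.int64), self.bins - 2)
        wb1 = fb - ib0
        ia0 = self.ia0[ok]
        wa1 = self.wa1[ok]
        base = ia0 * self.bins + ib0
        nb2 = self.bins * self.bins
        joint = (
            np.bincount(base, weights=(1 - wa1) * (1 - wb1), minlength=nb2)
            + np.bincount(base + 1, weights=(1 - wa1) * wb1, minlength=nb2)
            + np.bincount(base + self.bins, weights=wa1 * (1 - wb1), minlength=nb2)
            + np.bincount(base + self.bins + 1, weights=wa1 * wb1, minlength=nb2)
        )
        joint /= joint.sum()
        pa = joint.reshape(self.bins, self.bins).sum(axis=1)
        pb = joint.reshape(self.bins, self.bins).sum(axis=0)

        def H(x):
            x = x[x > 0]
            return -np.sum(x * np.log(x))

        hab = H(joint)
        if hab == 0.0:
            return -2.0
        val = (H(pa) + H(pb)) / hab
        if not np.isfinite(val):
            raise RuntimeError("non-finite NMI during search")
        return -float(val)


def register_affine(
    moving: ScalarImage,
    fixed: ScalarImage,
    bins: int = 32,
    levels: tuple[int, ...] = (4, 2, 1),
    bounds_mm: float = 10.0,
    bounds_rot: float = 0.35,
    multistart: int = 0,
    seed: int = 0,
    dof: int = 12,
) -> AffineTransform:
    """Estimate the 12-DOF transform mapping ``moving`` into ``fixed``.

    Coarse-to-fine pyramid (default ×4, ×2, ×1 downsampling) with a
    Powell search per level.  ``multistart`` adds seeded random restarts
    of the translation/rotation block at the coarsest level.  ``dof``
    may be 6 (rigid), 9 (+scale) or 12 (full affine).
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9 or 12")
    rng = np.random.default_rng(seed)
    x = AffineTransform.identity().params.copy()
    # search scales per parameter block: mm, rad, scale, shear
    step = np.array([2.0] * 3 + [0.1] * 3 + [0.05] * 3 + [0.05] * 3)

    # anchor rotation/scale/shear at the fixed-image centre so the
    # parameters are decoupled (a small rotation no longer drags the
    # far corner of the volume)
    center = fixed.origin + (np.asarray(fixed.shape) - 1) * fixed.spacing / 2.0
    C = np.eye(4)
    C[:3, 3] = center
    Cinv = np.eye(4)
    Cinv[:3, 3] = -center

    def anchored(params: np.ndarray) -> AffineTransform:
        return AffineTransform.from_matrix(C @ AffineTransform(params).matrix @ Cinv)

    def cost_at_level(fx, mv, max_samples=8000, order=1):
        engine = _NmiCost(fx, mv, bins, max_samples=max_samples, seed=seed,
                          order=order)

        def cost(p):
            params = x.copy()
            params[:len(p)] = p
            return engine(anchored(params))

        return cost

    def run_powell(cost, x0, ndof, xtol, maxfev, step_scale=1.0):
        return optimize.minimize(
            cost,
            x0[:ndof],
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-8, "maxfev": maxfev,
                     "direc": np.diag(step[:ndof] * step_scale)},
        )

    for li, f in enumerate(levels):
        fx = _downsample(fixed, f)
        mv = _downsample(moving, f)
        coarsest = li == 0
        finest = f == 1
        # the finest level sets the final sub-voxel accuracy: use a larger
        # sample budget there to keep histogram noise from displacing the
        # optimum
        cost = cost_at_level(fx, mv, max_samples=32000 if finest else 8000)
        if coarsest:
            # deterministic global translation sweep, then a rigid Powell:
            # rotation/scale are left at identity where the data are too
            # blurred to constrain them
            grid_pts = np.arange(-bounds_mm, bounds_mm + 1e-9, 2.0)
            best = (np.inf, x[:3].copy())
            for dx in grid_pts:
                for dy in grid_pts:
                    for dz in grid_pts:
                        p = x.copy()
                        p[:3] = (dx, dy, dz)
                        c = cost(p)
                        if c < best[0]:
                            best = (c, np.array([dx, dy, dz]))
            x[:3] = best[1]
            # optional seeded rigid multistart around the sweep optimum
            starts = [x[:6].copy()]
            for _ in range(multistart):
                pert = x[:6].copy()
                pert[3:6] += rng.uniform(-bounds_rot, bounds_rot, 3)
                starts.append(pert)
            best6 = None
            for s in starts:
                r = run_powell(cost, s, 6, 1e-3 * f, 1500)
                if best6 is None or r.fun < best6.fun:
                    best6 = r
            x[:6] = best6.x
            continue
        scale = 0.25 if finest else 0.5
        xtol = 1e-4 if finest else 1e-3 * f
        maxfev = 2500 if finest else 2000
        res = run_powell(cost, x.copy(), dof, xtol, maxfev, scale)
        x[:dof] = res.x
        if finest:
            # cubic-interpolation polish: the linear-interpolation cost has
            # shallow spurious optima ~0.5 voxel wide; switching to cubic
            # sampling reshapes them and lets a short small-step restart
            # slide into the true basin
            cost3 = cost_at_level(fx, mv, max_samples=16000, order=3)
            res = run_powell(cost3, x.copy(), dof, 1e-5, 1500, 0.15)
            x[:dof] = res.x
    return anchored(x)
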