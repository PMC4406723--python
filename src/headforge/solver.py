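"""Quasi-electrostatic forward solvers for transcranial stimulation.

Solves ∇·(σ∇φ) = 0 with Dirichlet electrode patches and zero-flux outer
boundaries, at stimulation frequencies low enough that permittivity is
negligible (purely real σ).  Two discretisations are provided, mirroring
the voxel/unstructured split of production tools:

- ``solve_voxel``: 7-point finite-volume scheme on the voxel grid with
  harmonic-mean face conductances; scalar or diagonal-tensor σ.
- ``solve_fem``: structured 6-tetrahedra-per-voxel P1 finite elements
  supporting full symmetric conductivity tensors.

Both produce a :class:`FieldSolution` with potential, E, J, the relative
residual and per-electrode currents (which must balance to ~0).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, splu

__all__ = [
    "Electrode",
    "ElectrodeMontage",
    "FieldSolution",
    "solve_voxel",
    "solve_fem",
    "compare_montages",
    "scalar_vs_tensor_study",
]

STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class Electrode:
    """A Dirichlet surface patch.

    kind "patch": angular cap on the outer conductive surface, defined by
    a ``direction`` unit vector from the head centroid and an angular
    ``radius_deg``.  kind "face": an entire grid face (``axis``, ``side``)
    — used for analytic bar/plate problems.
    """

    name: str
    potential: float
    kind: str = "patch"
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_deg: float = 20.0
    axis: int = 0
    side: int = 0  # 0 = low face, -1 = high face


# Approximate 10-20-like directions on the phantom scalp:
# x anterior, y left, z superior; polar angle from +z.
def _dir(theta_deg: float, azimuth_deg: float) -> tuple[float, float, float]:
    th = np.radians(theta_deg)
    az = np.radians(azimuth_deg)
    return (float(np.sin(th) * np.cos(az)), float(np.sin(th) * np.sin(az)),
            float(np.cos(th)))


TEN_TWENTY = {
    "Cz": _dir(0, 0),
    "Fz": _dir(36, 0),
    "Pz": _dir(36, 180),
    "C3": _dir(36, 90),
    "C4": _dir(36, -90),
    "Fpz": _dir(72, 0),
}


@dataclass
class ElectrodeMontage:
    electrodes: list[Electrode]

    def __post_init__(self):
        if len(self.electrodes) < 2:
            raise ValueError("montage needs >= 2 electrodes")
        if len({e.potential for e in self.electrodes}) < 2:
            raise ValueError("montage needs >= 2 distinct potentials")

    @classmethod
    def preset(cls, name: str, amplitude: float = 1.0) -> "ElectrodeMontage":
        """'fpz_cz': two large patches; 'cz_ring': Cz vs Fz/C3/C4/Pz."""
        if name == "fpz_cz":
            return cls([
                Electrode("Fpz", +amplitude, direction=TEN_TWENTY["Fpz"],
                          radius_deg=25.0),
                Electrode("Cz", 0.0, direction=TEN_TWENTY["Cz"], radius_deg=25.0),
            ])
        if name == "cz_ring":
            ring = [Electrode(n, 0.0, direction=TEN_TWENTY[n], radius_deg=12.0)
                    for n in ("Fz", "C3", "C4", "Pz")]
            return cls([Electrode("Cz", +amplitude, direction=TEN_TWENTY["Cz"],
                                  radius_deg=12.0)] + ring)
        raise ValueError(f"unknown preset {name!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([
            {"name": e.name, "potential": e.potential, "kind": e.kind,
             "direction": list(e.direction), "radius_deg": e.radius_deg,
             "axis": e.axis, "side": e.side}
            for e in self.electrodes
        ], indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeMontage":
        items = json.loads(Path(path).read_text())
        return cls([Electrode(
            i["name"], i["potential"], i.get("kind", "patch"),
            tuple(i.get("direction", (0, 0, 1))), i.get("radius_deg", 20.0),
            i.get("axis", 0), i.get("side", 0)) for i in items])


@dataclass
class FieldSolution:
    phi: np.ndarray                  # potential (V); NaN outside the domain
    E: np.ndarray                    # (…, 3) V/m
    J: np.ndarray                    # (…, 3) A/m^2
    domain: np.ndarray               # conductive-voxel mask
    residual: float
    electrode_currents: dict[str, float]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def e_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)

    def j_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.J, axis=-1)

    def current_balance(self) -> float:
        vals = np.array(list(self.electrode_currents.values()))
        denom = np.sum(np.abs(vals))
        return float(abs(vals.sum()) / denom) if denom > 0 else 0.0


def _electrode_voxel_masks(montage, domain: np.ndarray, spacing) -> dict[str, np.ndarray]:
    spacing = np.asarray(spacing, dtype=float)
    surface = domain & ~ndimage.binary_erosion(domain, structure=STRUCT_6,
                                               border_value=0)
    idx = np.argwhere(domain)
    centroid = idx.mean(axis=0) * spacing
    masks = {}
    for e in montage.electrodes:
        m = np.zeros(domain.shape, dtype=bool)
        if e.kind == "face":
            sl = [slice(None)] * 3
            sl[e.axis] = e.side
            face = np.zeros(domain.shape, dtype=bool)
            face[tuple(sl)] = True
            m = face & domain
        elif e.kind == "patch":
            d = np.asarray(e.direction, dtype=float)
            d = d / np.linalg.norm(d)
            sidx = np.argwhere(surface)
            rel = sidx * spacing - centroid
            rn = np.linalg.norm(rel, axis=1)
            ok = rn > 0
            cosang = np.zeros(len(rel))
            cosang[ok] = (rel[ok] @ d) / rn[ok]
            sel = cosang >= np.cos(np.radians(e.radius_deg))
            m[tuple(sidx[sel].T)] = True
        else:
            raise ValueError(f"unknown electrode kind {e.kind!r}")
        if not m.any():
            raise ValueError(f"electrode {e.name!r} covers no conductive voxels")
        masks[e.name] = m
    names = list(masks)
    for a, b in itertools.combinations(names, 2):
        if (masks[a] & masks[b]).any():
            raise ValueError(f"electrodes {a!r} and {b!r} overlap")
    return masks


def _check_connected(domain, masks):
    comps, _ = ndimage.label(domain, structure=STRUCT_6)
    ids = [set(np.unique(comps[m])) - {0} for m in masks.values()]
    if not set.intersection(*ids):
        raise ValueError("electrodes are not connected through conductive tissue")


def _gradient_in_domain(phi: np.ndarray, domain: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel gradient using central differences where both neighbours
    are in the domain, one-sided otherwise (exact for linear fields)."""
    g = np.zeros(phi.shape + (3,))
    for a in range(3):
        h = spacing[a]
        fwd = np.roll(phi, -1, axis=a)
        bwd = np.roll(phi, 1, axis=a)
        dfwd = np.roll(domain, -1, axis=a)
        dbwd = np.roll(domain, 1, axis=a)
        # roll wraps; kill wrapped entries
        sl = [slice(None)] * 3
        sl[a] = -1
        dfwd[tuple(sl)] = False
        sl[a] = 0
        dbwd[tuple(sl)] = False
        both = dfwd & dbwd & domain
        fonly = dfwd & ~dbwd & domain
        bonly = ~dfwd & dbwd & domain
        comp = np.zeros_like(phi)
        comp[both] = (fwd[both] - bwd[both]) / (2 * h)
        comp[fonly] = (fwd[fonly] - phi[fonly]) / h
        comp[bonly] = (phi[bonly] - bwd[bonly]) / h
        g[..., a] = comp
    return g


def _solve_linear(A: sparse.csr_matrix, b: np.ndarray, tol: float):
    """CG with Jacobi preconditioning; sparse-LU fallback on stagnation."""
    d = A.diagonal()
    M = sparse.diags(1.0 / np.maximum(d, 1e-300))
    x, info = cg(A, b, rtol=tol * 1e-2, atol=0.0, maxiter=20000, M=M)
    bn = np.linalg.norm(b)
    res = np.linalg.norm(A @ x - b) / bn if bn > 0 else 0.0
    if info != 0 or res > tol:
        x = splu(A.tocsc()).solve(b)
        res = np.linalg.norm(A @ x - b) / bn if bn > 0 else 0.0
        if res > tol:
            raise RuntimeError(f"linear solve failed to converge: residual {res:.3e}")
    return x, float(res)


def solve_voxel(
    sigma: np.ndarray,
    montage: ElectrodeMontage,
    spacing_mm=(1.0, 1.0, 1.0),
    tol: float = 1e-8,
) -> FieldSolution:
    """Finite-volume solve on the voxel grid.

    ``sigma`` is a scalar S/m per voxel (shape ``grid``) or a diagonal
    tensor per voxel (shape ``grid + (3,)``); full tensors must use
    :func:`solve_fem`.  Face conductance is the harmonic mean of the two
    adjacent voxel conductivities times face area over centre distance.
    Voxels with σ = 0 are excluded from the domain.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 3:
        sig = np.repeat(sigma[..., None], 3, axis=-1)
    elif sigma.ndim == 4 and sigma.shape[-1] == 3:
        sig = sigma
    else:
        raise ValueError("sigma must be scalar-per-voxel or diagonal-per-voxel")
    if np.any(sig < 0):
        raise ValueError("conductivities must be >= 0")
    grid = sig.shape[:3]
    spacing = np.asarray(spacing_mm, dtype=float) * 1e-3  # mm -> m
    domain = np.any(sig > 0, axis=-1)
    masks = _electrode_voxel_masks(montage, domain, spacing)
    _check_connected(domain, masks)

    index = -np.ones(grid, dtype=np.int64)
    dom_idx = np.argwhere(domain)
    n = len(dom_idx)
    index[domain] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for a in range(3):
        area = spacing[(a + 1) % 3] * spacing[(a + 2) % 3]
        h = spacing[a]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, grid[a] - 1)
        sl_hi[a] = slice(1, grid[a])
        s1 = sig[tuple(sl_lo)][..., a]
        s2 = sig[tuple(sl_hi)][..., a]
        num = 2.0 * s1 * s2
        den = s1 + s2
        g = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0) * area / h
        d1 = domain[tuple(sl_lo)]
        d2 = domain[tuple(sl_hi)]
        both = d1 & d2 & (g > 0)
        i1 = index[tuple(sl_lo)][both]
        i2 = index[tuple(sl_hi)][both]
        gg = g[both]
        rows.extend([i1, i2])
        cols.extend([i2, i1])
        vals.extend([-gg, -gg])
        np.add.at(diag, i1, gg)
        np.add.at(diag, i2, gg)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    fixed_val = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    for e in montage.electrodes:
        ids = index[masks[e.name]]
        fixed[ids] = True
        fixed_val[ids] = e.potential
    free = ~fixed
    A_ff = A[free][:, free]
    b = -A[free][:, fixed] @ fixed_val[fixed]
    x_free, res = _solve_linear(A_ff.tocsr(), b, tol)
    x = fixed_val.copy()
    x[free] = x_free

    phi = np.full(grid, np.nan)
    phi[domain] = x
    phi_filled = np.where(domain, phi, 0.0)
    E = -_gradient_in_domain(phi_filled, domain, spacing)
    J = sig * E
    E[~domain] = 0.0
    J[~domain] = 0.0

    r_full = A @ x  # nodal net currents; nonzero only at Dirichlet nodes
    currents = {}
    for e in montage.electrodes:
        ids = index[masks[e.name]]
        currents[e.name] = float(r_full[ids].sum())

    return FieldSolution(phi, E, J, domain, res, currents,
                         np.asarray(spacing_mm, dtype=float))


# ---------------------------------------------------------------------------
# FEM on structured tetrahedra

# Kuhn triangulation of the unit cube: 6 tets along vertex-ordering paths
_KUHN_PERMS = list(itertools.permutations(range(3)))


def _tet_corner_offsets():
    """(6, 4, 3) integer corner offsets of the Kuhn tetrahedra."""
    tets = []
    for perm in _KUHN_PERMS:
        c = np.zeros(3, dtype=int)
        corners = [c.copy()]
        for axis in perm:
            c = c.copy()
            c[axis] = 1
            corners.append(c)
        tets.append(corners)
    return np.array(tets)


def _p1_gradients(corners_mm: np.ndarray):
    """Volume and constant shape-function gradients of one tetrahedron."""
    p = corners_mm
    T = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
    vol = abs(np.linalg.det(T)) / 6.0
    Tinv = np.linalg.inv(T)
    g = np.zeros((4, 3))
    g[1:, :] = Tinv
    g[0, :] = -Tinv.sum(axis=0)
    return vol, g


def solve_fem(
    sigma_tensors: np.ndarray,
    montage: ElectrodeMontage,
    spacing_mm=(1.0, 1.0, 1.0),
    tol: float = 1e-8,
) -> FieldSolution:
    """P1 FEM solve with full symmetric conductivity tensors.

    Each conductive voxel is split into 6 structured tetrahedra; σ is
    taken constant per voxel (sampled at the centroid).  Electrode
    patches fix the potential on all corner nodes of their voxels.
    """
    sig = np.asarray(sigma_tensors, dtype=float)
    if sig.ndim != 5 or sig.shape[-2:] != (3, 3):
        raise ValueError("sigma_tensors must have shape grid + (3, 3)")
    if not np.allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-12):
        raise ValueError("conductivity tensors must be symmetric")
    grid = sig.shape[:3]
    spacing = np.asarray(spacing_mm, dtype=float) * 1e-3
    tr = np.trace(sig, axis1=-2, axis2=-1)
    domain = tr > 0
    w = np.linalg.eigvalsh(sig[domain])
    if np.any(w < -1e-12):
        raise ValueError("conductivity tensors must be positive semi-definite")
    masks = _electrode_voxel_masks(montage, domain, spacing)
    _check_connected(domain, masks)

    nx, ny, nz = grid
    node_shape = (nx + 1, ny + 1, nz + 1)

    def node_id(i, j, k):
        return (i * node_shape[1] + j) * node_shape[2] + k

    vox = np.argwhere(domain)
    nv = len(vox)
    offsets = _tet_corner_offsets()                     # (6, 4, 3)
    geom = [
        _p1_gradients(off * spacing[None, :]) for off in offsets
    ]

    sig_dom = sig[domain]                               # (nv, 3, 3)
    total = 6 * nv * 16
    rows = np.empty(total, dtype=np.int64)
    cols = np.empty(total, dtype=np.int64)
    vals = np.empty(total)
    pos = 0
    corner_ids_all = []
    for t in range(6):
        off = offsets[t]                                # (4, 3)
        corners = vox[:, None, :] + off[None, :, :]     # (nv, 4, 3)
        ids = node_id(corners[..., 0], corners[..., 1], corners[..., 2])
        corner_ids_all.append(ids)
        volume, G = geom[t]
        # element stiffness: vol * G σ G^T, per voxel
        Ke = volume * np.einsum("ia,nab,jb->nij", G, sig_dom, G)
        rr = np.repeat(ids, 4, axis=1)                  # (nv, 16)
        cc = np.tile(ids, (1, 4))
        m = 16 * nv
        rows[pos:pos + m] = rr.ravel()
        cols[pos:pos + m] = cc.ravel()
        vals[pos:pos + m] = Ke.reshape(nv, 16).ravel()
        pos += m

    used_nodes = np.unique(np.concatenate([ids.ravel() for ids in corner_ids_all]))
    remap = -np.ones(np.prod(node_shape), dtype=np.int64)
    remap[used_nodes] = np.arange(used_nodes.size)
    nn = used_nodes.size
    A = sparse.coo_matrix((vals, (remap[rows], remap[cols])), shape=(nn, nn)).tocsr()

    fixed = np.zeros(nn, dtype=bool)
    fixed_val = np.zeros(nn)
    electrode_nodes: dict[str, np.ndarray] = {}
    for e in montage.electrodes:
        ev = np.argwhere(masks[e.name])
        if e.kind == "face":
            # fix only the outer lattice plane so the conductive gap is the
            # full bar length (exact parallel-plate closed forms)
            corners = ev[:, None, :] + np.array(
                list(itertools.product((0, 1), repeat=3)))[None, :, :]
            plane = 0 if e.side == 0 else grid[e.axis]
            sel = corners[..., e.axis] == plane
            corners = corners[sel]
        else:
            corners = (ev[:, None, :] + np.array(
                list(itertools.product((0, 1), repeat=3)))[None, :, :]).reshape(-1, 3)
        ids = np.unique(remap[node_id(corners[:, 0], corners[:, 1], corners[:, 2])])
        ids = ids[ids >= 0]
        electrode_nodes[e.name] = ids
        fixed[ids] = True
        fixed_val[ids] = e.potential
    free = ~fixed
    A_ff = A[free][:, free]
    b = -A[free][:, fixed] @ fixed_val[fixed]
    x_free, res = _solve_linear(A_ff.tocsr(), b, tol)
    x = fixed_val.copy()
    x[free] = x_free

    # per-voxel E: mean of the 6 constant element fields (equal volumes)
    E_vox = np.zeros((nv, 3))
    for t in range(6):
        ids = remap[corner_ids_all[t]]                  # (nv, 4)
        phi_e = x[ids]
        _, G = geom[t]
        E_vox += -(phi_e @ G)
    E_vox /= 6.0
    J_vox = np.einsum("nab,nb->na", sig_dom, E_vox)

    phi_nodes = np.full(np.prod(node_shape), np.nan)
    phi_nodes[used_nodes] = x
    phi_node_grid = phi_nodes.reshape(node_shape)
    # voxel-centre potential: mean of the 8 corners
    phi_grid = np.full(grid, np.nan)
    corner_sum = np.zeros(nv)
    for off in itertools.product((0, 1), repeat=3):
        ids = node_id(vox[:, 0] + off[0], vox[:, 1] + off[1], vox[:, 2] + off[2])
        corner_sum += phi_nodes[ids]
    phi_grid[domain] = corner_sum / 8.0

    E = np.zeros(grid + (3,))
    J = np.zeros(grid + (3,))
    E[domain] = E_vox
    J[domain] = J_vox

    r_full = A @ x
    currents = {
        e.name: float(r_full[electrode_nodes[e.name]].sum())
        for e in montage.electrodes
    }

    sol = FieldSolution(phi_grid, E, J, domain, res, currents,
                        np.asarray(spacing_mm, dtype=float))
    sol.phi_nodes = phi_node_grid  # node-lattice potential, for diagnostics
    return sol


def compare_montages(
    solution_a: FieldSolution,
    solution_b: FieldSolution,
    region_mask: np.ndarray,
    percentiles=(50, 75, 95, 99),
) -> dict:
    """Median/percentile |E| and |J| inside a region for two solutions,
    plus their ratios (a / b)."""
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    if solution_a.phi.shape != solution_b.phi.shape:
        raise ValueError("solutions live on different grids")

    def summarize(sol):
        sel = region & sol.domain
        e = sol.e_magnitude()[sel]
        j = sol.j_magnitude()[sel]
        return {
            "E": {f"p{p}": float(np.percentile(e, p)) for p in percentiles},
            "J": {f"p{p}": float(np.percentile(j, p)) for p in percentiles},
        }

    sa = summarize(solution_a)
    sb = summarize(solution_b)
    ratios = {
        q: {k: (sa[q][k] / sb[q][k] if sb[q][k] > 0 else float("inf"))
            for k in sa[q]}
        for q in ("E", "J")
    }
    return {"a": sa, "b": sb, "ratio_a_over_b": ratios}


def scalar_vs_tensor_study(
    labels,
    scalar_table: dict[int, float],
    tensor_map,
    montage: ElectrodeMontage,
    brain_mask: np.ndarray,
    tol: float = 1e-8,
) -> dict:
    """Same montage solved with per-tissue scalar σ and with a tensor map;
    reports the tensor/scalar ratio of median brain |E|.

    Both runs use the FEM solver so the comparison isolates the material
    model, not the discretisation.
    """
    lab = labels.labels
    present = np.unique(lab)
    missing = [int(l) for l in present if int(l) != 0 and int(l) not in scalar_table]
    if missing:
        raise ValueError(f"scalar table missing labels {missing}")
    grid = lab.shape
    scalar_sig = np.zeros(grid + (3, 3))
    eye = np.eye(3)
    for l, s in scalar_table.items():
        scalar_sig[lab == l] = s * eye
    tensors = tensor_map.tensors if hasattr(tensor_map, "tensors") else np.asarray(tensor_map)

    sol_scalar = solve_fem(scalar_sig, montage, labels.spacing, tol)
    sol_tensor = solve_fem(tensors, montage, labels.spacing, tol)
    brain = np.asarray(brain_mask, dtype=bool)
    sel_s = brain & sol_scalar.domain
    sel_t = brain & sol_tensor.domain
    med_s = float(np.median(sol_scalar.e_magnitude()[sel_s]))
    med_t = float(np.median(sol_tensor.e_magnitude()[sel_t]))
    ratio = med_t / med_s if med_s > 0 else float("inf")
    return {
        "median_brain_E_scalar": med_s,
        "median_brain_E_tensor": med_t,
        "ratio_tensor_over_scalar": ratio,
        "direction": "weaker" if ratio < 1 else ("stronger" if ratio > 1 else "equal"),
        "scalar_solution": sol_scalar,
        "tensor_solution": sol_tensor,
    }
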