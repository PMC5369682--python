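"""Point-distribution shape model with per-landmark intensity profiles.

The model is a classical active shape model over the three healthy eye
structures jointly (sclera/cornea shell, vitreous humor, lens): generalized
Procrustes alignment of corresponded landmark sets, PCA of the aligned
coordinates, and per-landmark statistics of intensity profiles sampled along
outward surface normals in both channels.  Tumors are never part of the
geometry, but training on pathological cases folds tumor appearance into
the profile statistics — this is what distinguishes a pathological model
(PM) from a healthy model (HM) built by the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import STRUCTURES, PhantomCase
from .volume import (
    CHANNEL_NAMES,
    LABEL_LENS,
    LABEL_SCLERA,
    LABEL_VH,
    EyeLabelMap,
    MultiChannelVolume,
)

STRUCTURE_CODES = {"sclera": LABEL_SCLERA, "vh": LABEL_VH, "lens": LABEL_LENS}


# ---------------------------------------------------------------------------
# similarity alignment

def similarity_align(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Umeyama least-squares similarity transform mapping src onto dst.

    Returns ``(scale, rotation, translation)`` with
    ``dst ≈ scale * src @ rotation.T + translation``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = (sc**2).sum() / len(src)
        scale = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return scale, R, t


def generalized_procrustes(
    shapes: np.ndarray, with_scale: bool = True, max_iter: int = 10, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively align ``(n, L, 3)`` shapes to their evolving mean.

    The mean keeps the mm scale of the data (its centroid size is the
    average of the training centroid sizes), so model coordinates remain
    interpretable distances.
    """
    shapes = np.asarray(shapes, dtype=float)
    aligned = shapes - shapes.mean(axis=1, keepdims=True)
    size0 = np.mean([np.linalg.norm(s) for s in aligned])
    # iterate against a unit-size mean, then rescale the whole configuration
    # so the average centroid size is preserved — this makes re-alignment of
    # an already-aligned set an exact identity (fixed point)
    mean = aligned[0] / np.linalg.norm(aligned[0])
    for _ in range(max_iter):
        for i in range(len(aligned)):
            s, R, t = similarity_align(aligned[i], mean, with_scale)
            aligned[i] = s * aligned[i] @ R.T + t
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    factor = size0 / np.mean([np.linalg.norm(s) for s in aligned])
    return aligned * factor, mean * factor


# ---------------------------------------------------------------------------
# model container

@dataclass
class ShapeModel:
    """Joint PCA shape model + per-landmark profile statistics."""

    mean_shape: np.ndarray  # (L, 3) mm, Procrustes frame
    modes: np.ndarray  # (M, 3L) orthonormal rows
    eigenvalues: np.ndarray  # (M,) descending
    profile_mean: np.ndarray  # (L, k, n_channels)
    profile_var: np.ndarray  # (L, k, n_channels)
    structure_slices: dict[str, tuple[int, int]]
    faces: dict[str, np.ndarray]
    profile_k: int
    profile_spacing_mm: float
    variance_kept: float
    n_train: int

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def shape_from_coefficients(self, b: np.ndarray) -> np.ndarray:
        flat = self.mean_shape.reshape(-1) + (
            self.modes.T @ np.asarray(b, dtype=float) if self.n_modes else 0.0
        )
        return flat.reshape(-1, 3)

    def clamp(self, b: np.ndarray) -> np.ndarray:
        lim = 3.0 * np.sqrt(np.maximum(self.eigenvalues, 0.0))
        return np.clip(b, -lim, lim)

    def structure_vertices(self, shape: np.ndarray, name: str) -> np.ndarray:
        a, b = self.structure_slices[name]
        return shape[a:b]

    def meshes_from_shape(self, shape: np.ndarray) -> dict[str, trimesh.Trimesh]:
        return {
            name: trimesh.Trimesh(
                self.structure_vertices(shape, name), self.faces[name], process=False
            )
            for name in self.structure_slices
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.attrs["profile_k"] = self.profile_k
            f.attrs["profile_spacing_mm"] = self.profile_spacing_mm
            f.attrs["variance_kept"] = self.variance_kept
            f.attrs["n_train"] = self.n_train
            f.create_dataset("mean_shape", data=self.mean_shape)
            f.create_dataset("modes", data=self.modes)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("profile_mean", data=self.profile_mean)
            f.create_dataset("profile_var", data=self.profile_var)
            for name, (a, b) in self.structure_slices.items():
                g = f.create_group(f"structures/{name}")
                g.attrs["start"], g.attrs["end"] = a, b
                g.create_dataset("faces", data=self.faces[name])

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with h5py.File(path, "r") as f:
            slices, faces = {}, {}
            for name, g in f["structures"].items():
                slices[name] = (int(g.attrs["start"]), int(g.attrs["end"]))
                faces[name] = g["faces"][()]
            return cls(
                mean_shape=f["mean_shape"][()],
                modes=f["modes"][()],
                eigenvalues=f["eigenvalues"][()],
                profile_mean=f["profile_mean"][()],
                profile_var=f["profile_var"][()],
                structure_slices=slices,
                faces=faces,
                profile_k=int(f.attrs["profile_k"]),
                profile_spacing_mm=float(f.attrs["profile_spacing_mm"]),
                variance_kept=float(f.attrs["variance_kept"]),
                n_train=int(f.attrs["n_train"]),
            )


@dataclass
class ShapeFit:
    """Result of fitting a shape model to a volume."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    coefficients: np.ndarray
    meshes: dict[str, trimesh.Trimesh]
    converged: bool
    iterations: int

    @property
    def vertices(self) -> np.ndarray:
        return np.concatenate([m.vertices for m in self.meshes.values()])


# ---------------------------------------------------------------------------
# profile sampling

def sample_profiles(
    volume: MultiChannelVolume,
    vertices: np.ndarray,
    normals: np.ndarray,
    k: int,
    s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample k intensity samples spaced s mm along each vertex normal.

    Returns ``(profiles, out_of_grid)`` with profiles of shape
    ``(L, k, n_channels)``; samples outside the grid are replicate-padded
    and flagged per landmark.
    """
    offsets = (np.arange(k) - (k - 1) / 2.0) * s
    pos = vertices[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = (pos - volume.origin) / volume.spacing  # (L, k, 3)
    shape = np.asarray(volume.shape)
    oob = np.any((coords < 0) | (coords > shape - 1), axis=(1, 2))
    cc = coords.reshape(-1, 3).T
    profiles = np.stack(
        [
            ndimage.map_coordinates(volume.channels[ch], cc, order=1, mode="nearest").reshape(
                len(vertices), k
            )
            for ch in CHANNEL_NAMES
        ],
        axis=-1,
    )
    return profiles, oob


def _case_vertices_normals(case: PhantomCase) -> tuple[np.ndarray, np.ndarray, dict, dict]:
    verts, norms = [], []
    slices, faces = {}, {}
    start = 0
    for name in STRUCTURES:
        mesh = case.meshes[name]
        v = np.asarray(mesh.vertices, dtype=float)
        verts.append(v)
        norms.append(np.asarray(mesh.vertex_normals, dtype=float))
        slices[name] = (start, start + len(v))
        faces[name] = np.asarray(mesh.faces)
        start += len(v)
    return np.concatenate(verts), np.concatenate(norms), slices, faces


# ---------------------------------------------------------------------------
# model building

def build_shape_model(
    cases: list[PhantomCase],
    variance_kept: float = 0.95,
    k: int = 7,
    s: float = 0.75,
) -> ShapeModel:
    """Build the point-distribution model from topology-matched cases.

    Profiles are sampled from each case's own (possibly pathological)
    volume, so tumor appearance enters the intensity statistics even though
    tumors contribute no landmarks.
    """
    if not cases:
        raise ValueError("need at least one training case")
    extent = np.min([np.asarray(c.volume.shape) * c.volume.spacing for c in cases])
    if k * s > extent:
        raise ValueError("profile length k*s exceeds the grid extent")

    all_verts, all_norms, slices, faces = [], [], None, None
    for case in cases:
        v, n, sl, fc = _case_vertices_normals(case)
        if slices is None:
            slices, faces = sl, fc
        elif sl != slices or any(
            not np.array_equal(fc[name], faces[name]) for name in faces
        ):
            raise ValueError("mesh topology mismatch across training cases")
        all_verts.append(v)
        all_norms.append(n)
    shapes = np.stack(all_verts)  # (n, L, 3)

    if len(cases) == 1:
        mean = shapes[0] - shapes[0].mean(axis=0)
        modes = np.zeros((0, mean.size))
        eigenvalues = np.zeros(0)
    else:
        aligned, _ = generalized_procrustes(shapes)
        # PCA about the sample mean of the aligned shapes: guarantees rank
        # ≤ n-1 and exact reconstruction of training shapes with all modes
        mean = aligned.mean(axis=0)
        data = aligned.reshape(len(cases), -1) - mean.reshape(-1)
        U, S, Vt = np.linalg.svd(data, full_matrices=False)
        eigenvalues = S**2 / (len(cases) - 1)
        nonzero = eigenvalues > max(1e-12, eigenvalues[0] * 1e-12) if len(eigenvalues) else []
        eigenvalues = eigenvalues[nonzero]
        modes = Vt[nonzero]
        if len(eigenvalues):
            cum = np.cumsum(eigenvalues) / eigenvalues.sum()
            m = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
            modes, eigenvalues = modes[:m], eigenvalues[:m]

    profs = np.stack(
        [
            sample_profiles(case.volume, v, n, k, s)[0]
            for case, v, n in zip(cases, all_verts, all_norms)
        ]
    )  # (n, L, k, ch)
    return ShapeModel(
        mean_shape=mean,
        modes=modes,
        eigenvalues=eigenvalues,
        profile_mean=profs.mean(axis=0),
        profile_var=profs.var(axis=0),
        structure_slices=slices,
        faces=faces,
        profile_k=k,
        profile_spacing_mm=s,
        variance_kept=variance_kept,
        n_train=len(cases),
    )


# ---------------------------------------------------------------------------
# fitting

def fit_shape_model(
    model: ShapeModel,
    volume: MultiChannelVolume,
    init: tuple[float, np.ndarray, np.ndarray] | None = None,
    search_range_mm: float = 3.0,
    search_step_mm: float = 0.25,
    max_iter: int = 50,
    tol: float = 0.05,
) -> ShapeFit:
    """Iterative ASM search: profile matching + constrained model update.

    Per landmark the best Mahalanobis profile match along the normal within
    ``±search_range_mm`` becomes the target; a similarity pose and clamped
    mode coefficients are then refit.  Stops when the mean landmark
    displacement falls below ``tol`` mm or at ``max_iter``.
    """
    if init is None:
        scale, R, t = 1.0, np.eye(3), np.zeros(3)
    else:
        scale, R, t = init
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
    b = np.zeros(model.n_modes)

    offsets = np.arange(-search_range_mm, search_range_mm + 1e-9, search_step_mm)
    load = 1e-3 * float(model.profile_var.mean()) + 1e-6
    inv_var = 1.0 / (model.profile_var + load)
    k, s = model.profile_k, model.profile_spacing_mm

    X_prev = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        x_m = model.shape_from_coefficients(b)
        X = scale * x_m @ R.T + t
        normals = _shape_normals(model, X)

        # candidate positions: (L, n_off, k, 3)
        prof_off = (np.arange(k) - (k - 1) / 2.0) * s
        disp = offsets[None, :, None] + prof_off[None, None, :]
        pos = X[:, None, None, :] + disp[..., None] * normals[:, None, None, :]
        coords = ((pos - volume.origin) / volume.spacing).reshape(-1, 3).T
        cost = np.zeros((model.n_landmarks, len(offsets)))
        for ci, ch in enumerate(CHANNEL_NAMES):
            samples = ndimage.map_coordinates(
                volume.channels[ch], coords, order=1, mode="nearest"
            ).reshape(model.n_landmarks, len(offsets), k)
            diff = samples - model.profile_mean[:, None, :, ci]
            cost += np.sum(diff**2 * inv_var[:, None, :, ci], axis=2)
        best = offsets[np.argmin(cost, axis=1)]
        targets = X + best[:, None] * normals

        scale, R, t = similarity_align(x_m, targets)
        inv_targets = (targets - t) @ R / scale
        if model.n_modes:
            b = model.clamp(model.modes @ (inv_targets - model.mean_shape).reshape(-1))
        X_new = scale * model.shape_from_coefficients(b) @ R.T + t
        if X_prev is not None:
            if float(np.mean(np.linalg.norm(X_new - X_prev, axis=1))) < tol:
                converged = True
                X_prev = X_new
                break
        X_prev = X_new

    final_shape = scale * model.shape_from_coefficients(b) @ R.T + t
    meshes = model.meshes_from_shape(final_shape)
    return ShapeFit(scale, R, t, b, meshes, converged, iterations)


def _shape_normals(model: ShapeModel, shape: np.ndarray) -> np.ndarray:
    out = np.zeros_like(shape)
    for name, (a, b) in model.structure_slices.items():
        mesh = trimesh.Trimesh(shape[a:b], model.faces[name], process=False)
        out[a:b] = mesh.vertex_normals
    return out


# ---------------------------------------------------------------------------
# mesh voxelization

def _voxelize_solid(
    mesh: trimesh.Trimesh,
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
) -> np.ndarray:
    """Boolean solid of a closed mesh on a voxel grid (center-inside test).

    The surface is densely sampled, touched voxels form a closed shell,
    interior voxels come from hole filling, and shell voxels are classified
    by the sign of the offset to the nearest surface sample along its
    normal.
    """
    if not mesh.is_watertight:
        raise ValueError("mesh is not closed; cannot voxelize")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    step = float(spacing.min()) / 2.5

    tri = mesh.triangles  # (F, 3, 3)
    pts, nrm = [], []
    face_normals = np.asarray(mesh.face_normals)
    for f in range(len(tri)):
        a, b, c = tri[f]
        n_sub = max(
            2, int(np.ceil(max(np.linalg.norm(b - a), np.linalg.norm(c - a)) / step)) + 1
        )
        u = np.linspace(0, 1, n_sub)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1.0
        uu, vv = uu[keep], vv[keep]
        p = a[None, :] + uu[:, None] * (b - a)[None, :] + vv[:, None] * (c - a)[None, :]
        pts.append(p)
        nrm.append(np.repeat(face_normals[f][None, :], len(p), axis=0))
    pts = np.concatenate(pts)
    nrm = np.concatenate(nrm)

    idx = np.round((pts - origin) / spacing).astype(int)
    inside_grid = np.all((idx >= 0) & (idx < np.asarray(grid_shape)), axis=1)
    shell = np.zeros(grid_shape, dtype=bool)
    shell[tuple(idx[inside_grid].T)] = True
    filled = ndimage.binary_fill_holes(shell)
    interior = filled & ~shell

    shell_idx = np.array(np.nonzero(shell)).T
    if len(shell_idx):
        centers = origin + shell_idx * spacing
        tree = cKDTree(pts)
        _, nearest = tree.query(centers, workers=-1)
        signed = np.einsum("ij,ij->i", centers - pts[nearest], nrm[nearest])
        inside_shell = signed < 0
        solid = interior.copy()
        solid[tuple(shell_idx[inside_shell].T)] = True
    else:
        solid = interior
    return solid


def mesh_to_labelmap(
    meshes: dict[str, trimesh.Trimesh],
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
) -> EyeLabelMap:
    """Voxelize structure meshes into a label map, innermost structure wins.

    Painting order sclera -> VH -> lens resolves nesting: the VH ball
    overwrites the globe interior leaving the sclera/cornea shell, and the
    lens overwrites the VH.
    """
    data = np.zeros(grid_shape, dtype=np.int16)
    for name in STRUCTURES:
        if name not in meshes:
            continue
        solid = _voxelize_solid(meshes[name], grid_shape, spacing, origin)
        data[solid] = STRUCTURE_CODES[name]
    return EyeLabelMap(data, np.asarray(spacing, float), np.asarray(origin, float))
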