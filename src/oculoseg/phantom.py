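"""Seeded synthetic pathological-eye phantom generator.

Each case emulates the anatomy the segmentation pipeline assumes: a roughly
spherical eye whose sclera/cornea shell encloses the vitreous humor (VH), an
anterior lens ellipsoid fully embedded in the VH, and an endophytic tumor
blob growing from the interior VH boundary into the VH.  The two channels
emulate a gadolinium-enhanced T1w VIBE and a T2w acquisition: the tumor is
brighter than the VH on T1 and darker on T2, so the channels carry
complementary contrast.

World coordinates are mm; the eye center (VH center) sits at the world
origin, i.e. phantoms are born in the canonical frame up to the configured
center offset.  The optic disc landmark is placed 15 degrees off the
posterior pole in the y-x plane, matching the anatomical position of the
optic nerve head; this also makes the three landmarks non-collinear, which
canonical alignment requires.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .volume import (
    LABEL_BACKGROUND,
    LABEL_LENS,
    LABEL_SCLERA,
    LABEL_TUMOR,
    LABEL_VH,
    EyeLabelMap,
    MultiChannelVolume,
)

STRUCTURES = ("sclera", "vh", "lens")  # modeled (healthy) structures, outermost first

#: icosphere subdivision level shared by every mesh -> identical vertex
#: topology and anatomical correspondence of vertex k across cases
ICOSPHERE_SUBDIVISIONS = 3

DEFAULT_TISSUE_MEANS = {
    # label: (T1, T2) in arbitrary units on a 0-200 scale.  Tumor T1 is close
    # to sclera T1 (both enhance with gadolinium); the T2 channel and the
    # location features carry the complementary discrimination.
    LABEL_BACKGROUND: (25.0, 25.0),
    LABEL_SCLERA: (110.0, 60.0),
    LABEL_VH: (60.0, 160.0),
    LABEL_LENS: (90.0, 50.0),
    LABEL_TUMOR: (115.0, 85.0),
}

OPTIC_DISC_ANGLE_DEG = 15.0


class PhantomError(ValueError):
    """Invalid phantom parameterization."""


@dataclass
class PhantomParams:
    """Geometric and intensity parameters of one synthetic eye."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    eye_radius_mm: float = 9.5
    sclera_thickness_mm: float = 2.0
    lens_semiaxes_mm: tuple[float, float, float] = (3.2, 2.0, 3.2)
    tumor_radius_mm: float = 3.5
    #: (polar from +y, azimuth around y) in degrees; seeds the tumor on the VH boundary
    tumor_angle_deg: tuple[float, float] = (120.0, 40.0)
    with_tumor: bool = True
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tissue_means: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    noise_sd: tuple[float, float] = (10.0, 10.0)
    bias_field_amplitude: float = 0.0
    n_tumor_bumps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing_mm must be positive on every axis")
        for name in ("eye_radius_mm", "sclera_thickness_mm", "tumor_radius_mm"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be strictly positive")
        if any(a <= 0 for a in self.lens_semiaxes_mm):
            raise PhantomError("lens semiaxes must be strictly positive")
        if self.tumor_radius_mm >= self.eye_radius_mm:
            raise PhantomError("tumor_radius_mm must be smaller than eye_radius_mm")

    @property
    def inner_radius_mm(self) -> float:
        return self.eye_radius_mm - self.sclera_thickness_mm


@dataclass
class PhantomCase:
    """One synthetic case: volume, ground-truth labels, landmarks, meshes."""

    volume: MultiChannelVolume
    labels: EyeLabelMap
    landmarks: dict[str, np.ndarray]
    meshes: dict[str, trimesh.Trimesh]
    params: PhantomParams

    @property
    def name(self) -> str:
        return f"case_seed{self.params.seed}"


def _unit_from_angles(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Direction at `polar` from +y, rotated `azimuth` around y (x->z)."""
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(ph), np.cos(th), np.sin(th) * np.sin(ph)])


def _world_grid(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    shape = np.asarray(params.grid_shape)
    spacing = np.asarray(params.spacing_mm)
    center = np.asarray(params.center_offset_mm, dtype=float)
    origin = center - (shape - 1) / 2.0 * spacing
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return origin, X, Y, Z


def _lens_center(params: PhantomParams) -> np.ndarray:
    # anterior lens, fully embedded in the VH (0.8 mm clearance to the shell)
    y = params.inner_radius_mm - params.lens_semiaxes_mm[1] - 0.8
    return np.asarray(params.center_offset_mm) + np.array([0.0, y, 0.0])


def _tumor_spheres(params: PhantomParams, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Main tumor sphere seeded on the interior VH boundary plus small bumps."""
    center = np.asarray(params.center_offset_mm, dtype=float)
    u = _unit_from_angles(*params.tumor_angle_deg)
    r = params.tumor_radius_mm
    main = center + (params.inner_radius_mm - r) * u
    spheres = [(main, r)]
    for _ in range(params.n_tumor_bumps):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        spheres.append((main + 0.85 * r * d, 0.3 * r))
    return spheres


def generate_eye(params: PhantomParams) -> PhantomCase:
    """Render one deterministic phantom case from its parameters.

    The label map is the analytic geometry sampled at voxel centers; the
    meshes are icospheres/ellipsoids over the same analytic surfaces, so
    voxelizing a mesh reproduces its label region to within one voxel.
    """
    params = replace(params)  # defensive copy
    shape = np.asarray(params.grid_shape)
    spacing = np.asarray(params.spacing_mm)
    center = np.asarray(params.center_offset_mm, dtype=float)
    half_extent = (shape - 1) / 2.0 * spacing
    if np.any(params.eye_radius_mm + np.abs(center) > half_extent + 1e-9):
        raise PhantomError("grid too small to contain the eye (plus center offset)")

    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0xE7E]))
    origin, X, Y, Z = _world_grid(params)
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2

    labels = np.zeros(tuple(shape), dtype=np.int16)
    labels[r2 <= params.eye_radius_mm**2] = LABEL_SCLERA
    vh = r2 <= params.inner_radius_mm**2
    labels[vh] = LABEL_VH

    lc = _lens_center(params)
    a, b, c = params.lens_semiaxes_mm
    in_lens = ((X - lc[0]) / a) ** 2 + ((Y - lc[1]) / b) ** 2 + ((Z - lc[2]) / c) ** 2 <= 1.0
    labels[in_lens & vh] = LABEL_LENS

    tumor_spheres: list[tuple[np.ndarray, float]] = []
    if params.with_tumor:
        tumor_spheres = _tumor_spheres(params, rng)
        tmask = np.zeros(tuple(shape), dtype=bool)
        for c_s, r_s in tumor_spheres:
            tmask |= (X - c_s[0]) ** 2 + (Y - c_s[1]) ** 2 + (Z - c_s[2]) ** 2 <= r_s**2
        # endophytic: the tumor only replaces vitreous humor, never leaves it
        tmask &= labels == LABEL_VH
        if not tmask.any():
            raise PhantomError("tumor placement left no tumor voxels inside the VH")
        labels[tmask] = LABEL_TUMOR

    channels: dict[str, np.ndarray] = {}
    for ci, cname in enumerate(("T1", "T2")):
        img = np.zeros(tuple(shape), dtype=np.float64)
        for code, means in params.tissue_means.items():
            img[labels == code] = means[ci]
        if params.bias_field_amplitude > 0:
            img *= 1.0 + params.bias_field_amplitude * _smooth_bias(shape, rng)
        sd = params.noise_sd[ci]
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=img.shape)
        channels[cname] = img

    landmarks = {
        "vh_center": center.copy(),
        "lens_center": lc,
        "optic_disc": center + params.inner_radius_mm * _optic_disc_direction(),
    }
    meshes = make_structure_meshes(params)
    volume = MultiChannelVolume(channels, spacing, origin)
    return PhantomCase(volume, EyeLabelMap(labels, spacing, origin), landmarks, meshes, params)


def _optic_disc_direction() -> np.ndarray:
    th = np.deg2rad(OPTIC_DISC_ANGLE_DEG)
    return np.array([np.sin(th), -np.cos(th), 0.0])


def _smooth_bias(shape: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth multiplicative field from low-order cosines."""
    axes = [np.linspace(0, np.pi, n) for n in shape]
    field_ = np.zeros(tuple(shape))
    for k in range(1, 3):
        coeffs = rng.normal(size=3)
        field_ += (
            coeffs[0] * np.cos(k * axes[0])[:, None, None]
            + coeffs[1] * np.cos(k * axes[1])[None, :, None]
            + coeffs[2] * np.cos(k * axes[2])[None, None, :]
        )
    field_ -= field_.mean()
    m = np.max(np.abs(field_))
    return field_ / m if m > 0 else field_


def make_structure_meshes(params: PhantomParams) -> dict[str, trimesh.Trimesh]:
    """Closed surface meshes with shared icosphere topology across cases.

    ``sclera`` is the outer globe surface, ``vh`` the inner shell surface and
    ``lens`` the lens ellipsoid; nesting is resolved innermost-wins when
    voxelizing, which recovers the shell label.
    """
    template = trimesh.creation.icosphere(subdivisions=ICOSPHERE_SUBDIVISIONS, radius=1.0)
    center = np.asarray(params.center_offset_mm, dtype=float)
    meshes = {}
    meshes["sclera"] = trimesh.Trimesh(
        template.vertices * params.eye_radius_mm + center, template.faces.copy(), process=False
    )
    meshes["vh"] = trimesh.Trimesh(
        template.vertices * params.inner_radius_mm + center, template.faces.copy(), process=False
    )
    meshes["lens"] = trimesh.Trimesh(
        template.vertices * np.asarray(params.lens_semiaxes_mm) + _lens_center(params),
        template.faces.copy(),
        process=False,
    )
    return meshes


DEFAULT_JITTER = {
    # uniform ranges a cohort draws per-case parameters from; tumor radii span
    # the sub-voxel-cluster (~1.5 mm) to large (>2000-voxel) regime
    "eye_radius_mm": (8.5, 10.5),
    "sclera_thickness_mm": (1.8, 2.2),
    "lens_scale": (0.88, 1.12),
    "tumor_radius_mm": (1.5, 6.0),
    "tumor_polar_deg": (95.0, 150.0),
    "tumor_azimuth_deg": (0.0, 360.0),
    "center_offset_mm": (-1.5, 1.5),
}


def generate_cohort(
    n: int,
    base: PhantomParams | None = None,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Draw ``n`` phantom cases with per-case parameters from jitter ranges."""
    if n < 2:
        raise PhantomError("a cohort needs at least 2 cases")
    base = base or PhantomParams()
    jit = dict(DEFAULT_JITTER)
    if jitter is not None:
        jit.update(jitter)
    for key, (lo, hi) in jit.items():
        if lo > hi:
            raise PhantomError(f"degenerate jitter range for {key}: {lo} > {hi}")

    ss = np.random.SeedSequence(seed)
    case_seeds = ss.generate_state(n).astype(np.int64)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cases = []
    for i in range(n):
        lens_scale = rng.uniform(*jit["lens_scale"])
        params = replace(
            base,
            eye_radius_mm=rng.uniform(*jit["eye_radius_mm"]),
            sclera_thickness_mm=rng.uniform(*jit["sclera_thickness_mm"]),
            lens_semiaxes_mm=tuple(np.asarray(base.lens_semiaxes_mm) * lens_scale),
            tumor_radius_mm=rng.uniform(*jit["tumor_radius_mm"]),
            tumor_angle_deg=(
                rng.uniform(*jit["tumor_polar_deg"]),
                rng.uniform(*jit["tumor_azimuth_deg"]),
            ),
            center_offset_mm=tuple(rng.uniform(*jit["center_offset_mm"], size=3)),
            seed=int(case_seeds[i]),
        )
        cases.append(generate_eye(params))
    return cases


# ---------------------------------------------------------------------------
# case I/O (NIfTI + CSV + PLY + JSON manifest)

def save_case(case: PhantomCase, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    case.volume.save(directory)
    case.labels.save(directory / "labels.nii.gz")
    with open(directory / "landmarks.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x_mm", "y_mm", "z_mm"])
        for name, p in case.landmarks.items():
            writer.writerow([name, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])
    mesh_dir = directory / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    for name, mesh in case.meshes.items():
        mesh.export(mesh_dir / f"{name}.ply", encoding="ascii")
    manifest = {
        "grid_shape": [int(v) for v in case.params.grid_shape],
        "spacing_mm": list(case.params.spacing_mm),
        "eye_radius_mm": case.params.eye_radius_mm,
        "sclera_thickness_mm": case.params.sclera_thickness_mm,
        "tumor_radius_mm": case.params.tumor_radius_mm,
        "with_tumor": case.params.with_tumor,
        "seed": int(case.params.seed),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_landmarks_csv(path: str | Path) -> dict[str, np.ndarray]:
    landmarks = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            landmarks[row["name"]] = np.array(
                [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
            )
    return landmarks


def load_case(directory: str | Path) -> PhantomCase:
    directory = Path(directory)
    volume = MultiChannelVolume.load(directory)
    labels_path = directory / "labels.nii.gz"
    if labels_path.exists():
        labels = EyeLabelMap.load(labels_path)
    else:
        # unlabeled case (no ground truth): all-background label map
        labels = EyeLabelMap(
            np.zeros(volume.shape, dtype=np.int16), volume.spacing, volume.origin
        )
    landmarks = load_landmarks_csv(directory / "landmarks.csv")
    meshes = {
        name: trimesh.load(directory / "meshes" / f"{name}.ply", process=False)
        for name in STRUCTURES
    }
    manifest = json.loads((directory / "manifest.json").read_text())
    params = PhantomParams(
        grid_shape=tuple(manifest["grid_shape"]),
        spacing_mm=tuple(manifest["spacing_mm"]),
        eye_radius_mm=manifest["eye_radius_mm"],
        sclera_thickness_mm=manifest["sclera_thickness_mm"],
        tumor_radius_mm=manifest["tumor_radius_mm"],
        with_tumor=manifest["with_tumor"],
        seed=manifest["seed"],
    )
    return PhantomCase(volume, labels, landmarks, meshes, params)
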