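"""Per-voxel feature planes for tumor classification.

Two families:

* STD features — raw channel intensities (T1, T2), an anisotropic-diffusion
  filtered T1 (A-T1), the 6-neighbor von-Neumann means of all three, and the
  per-slice SLIC superpixel mean intensities of both channels;
* EPSF (eye patient-specific features) — unsigned Euclidean distances (mm)
  to the lens and VH boundary voxel sets, plus a Gaussian-smoothed
  cross-patient tumor-location prior in [0, 1].

Classification is restricted to the θ-band: the fitted VH plus a band of
width θ mm outside its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.segmentation import slic as skimage_slic

from .volume import LABEL_LENS, LABEL_TUMOR, LABEL_VH, EyeLabelMap, MultiChannelVolume

STD_FEATURE_NAMES = ("t1", "t2", "at1", "nbr_t1", "nbr_t2", "nbr_at1", "slic_t1", "slic_t2")
EPSF_FEATURE_NAMES = ("f_l", "f_vh", "f_t")


@dataclass
class FeatureConfig:
    theta_mm: float = 2.0  # evaluation-band width outside the fitted VH
    prior_sigma_mm: float = 3.0  # tumor-prior Gaussian smoothing
    slic_region_size: int = 10  # nominal superpixel side length in voxels
    slic_regularization: float = 0.1
    diffusion_iterations: int = 10
    diffusion_conductance: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_mm < 0:
            raise ValueError("theta_mm must be non-negative")
        if self.prior_sigma_mm <= 0:
            raise ValueError("prior_sigma_mm must be positive")


@dataclass
class FeatureStack:
    """Named per-voxel feature planes plus the θ-band mask."""

    planes: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: np.ndarray
    feature_order: tuple[str, ...]

    def matrix(self) -> np.ndarray:
        """Masked voxels × features, in `feature_order`."""
        if not self.mask.any():
            return np.zeros((0, len(self.feature_order)))
        return np.stack([self.planes[name][self.mask] for name in self.feature_order], axis=1)

    def save(self, path) -> None:
        """HDF5 export: one dataset per plane, the mask, and the masked
        feature matrix with a column-name attribute."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["feature_order"] = list(self.feature_order)
            f.attrs["spacing"] = self.spacing
            for name, plane in self.planes.items():
                f.create_dataset(f"planes/{name}", data=plane)
            f.create_dataset("mask", data=self.mask.astype(np.uint8))
            m = f.create_dataset("matrix", data=self.matrix())
            m.attrs["columns"] = list(self.feature_order)

    @classmethod
    def load(cls, path) -> "FeatureStack":
        import h5py

        with h5py.File(path, "r") as f:
            order = tuple(str(c) for c in f.attrs["feature_order"])
            planes = {name: f[f"planes/{name}"][()] for name in f["planes"]}
            return cls(planes, f["mask"][()].astype(bool), np.asarray(f.attrs["spacing"]), order)


# ---------------------------------------------------------------------------
# EPSF

def boundary_voxels(region: np.ndarray) -> np.ndarray:
    """Region voxels with at least one non-region face neighbor."""
    if not region.any():
        raise ValueError("empty structure region")
    eroded = ndimage.binary_erosion(
        region, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return region & ~eroded


def distance_to_boundary(region: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Per voxel, min Euclidean distance (mm) to the region's boundary voxel set."""
    b = boundary_voxels(region)
    # exact EDT of the complement of the boundary set, anisotropic spacing
    return ndimage.distance_transform_edt(~b, sampling=np.asarray(spacing, float))


def compute_distance_features(labels: EyeLabelMap) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned distance maps (mm) to the lens and VH boundary voxel sets.

    The VH region is taken as VH plus tumor: an endophytic tumor lies inside
    the anatomical vitreous chamber, whose boundary is what the feature is
    meant to encode.
    """
    lens = labels.data == LABEL_LENS
    vh = (labels.data == LABEL_VH) | (labels.data == LABEL_TUMOR)
    if not lens.any() or not vh.any():
        raise ValueError("empty lens or VH region")
    return (
        distance_to_boundary(lens, labels.spacing),
        distance_to_boundary(vh, labels.spacing),
    )


def compute_tumor_prior(
    masks: list[np.ndarray], spacing: np.ndarray, sigma_mm: float = 3.0
) -> np.ndarray:
    """Voxelwise cohort mean of aligned binary tumor masks, Gaussian-smoothed."""
    if not masks:
        raise ValueError("need at least one training mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks on mismatched grids: {shapes}")
    prior = np.mean([m.astype(float) for m in masks], axis=0)
    if sigma_mm > 0:
        sigma_vox = sigma_mm / np.asarray(spacing, dtype=float)
        prior = ndimage.gaussian_filter(prior, sigma=sigma_vox, mode="reflect")
    return np.clip(prior, 0.0, 1.0)


# ---------------------------------------------------------------------------
# STD

def anisotropic_diffusion(
    channel: np.ndarray,
    spacing: np.ndarray,
    iterations: int = 10,
    conductance: float = 1.0,
) -> np.ndarray:
    """Edge-preserving Perona-Malik-family smoothing of one channel."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(channel.T, dtype=np.float64))
    # run in relative voxel units so the explicit scheme stays stable at
    # sub-millimetre spacing (3D stability bound: time step <= 1/16)
    rel = np.asarray(spacing, dtype=float)
    rel = rel / rel.min()
    img.SetSpacing(tuple(float(s) for s in rel))
    out = sitk.GradientAnisotropicDiffusion(
        img,
        timeStep=0.06,
        conductanceParameter=float(conductance),
        numberOfIterations=int(iterations),
    )
    return sitk.GetArrayFromImage(out).T.copy()


def von_neumann_mean(plane: np.ndarray) -> np.ndarray:
    """Mean of the 6 face neighbors (center excluded), replicate-padded."""
    padded = np.pad(plane, 1, mode="edge")
    acc = np.zeros_like(plane, dtype=float)
    for axis in range(3):
        for shift in (-1, 1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(1 + shift, padded.shape[axis] - 1 + shift)
            acc += padded[tuple(sl)]
    return acc / 6.0


def compute_std_features(
    volume: MultiChannelVolume, config: FeatureConfig | None = None
) -> dict[str, np.ndarray]:
    """The six intensity planes: T1, T2, A-T1 and their 6-neighbor means."""
    config = config or FeatureConfig()
    t1 = np.asarray(volume.channels["T1"], dtype=float)
    t2 = np.asarray(volume.channels["T2"], dtype=float)
    at1 = anisotropic_diffusion(
        t1, volume.spacing, config.diffusion_iterations, config.diffusion_conductance
    )
    return {
        "t1": t1,
        "t2": t2,
        "at1": at1,
        "nbr_t1": von_neumann_mean(t1),
        "nbr_t2": von_neumann_mean(t2),
        "nbr_at1": von_neumann_mean(at1),
    }


def compute_slic_features(
    volume: MultiChannelVolume, config: FeatureConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-axial-slice SLIC oversegmentation; each voxel gets its superpixel's
    mean intensity, per channel.  Both channels drive one joint segmentation
    per slice."""
    config = config or FeatureConfig()
    t1 = np.asarray(volume.channels["T1"], dtype=float)
    t2 = np.asarray(volume.channels["T2"], dtype=float)
    nx, ny, nz = t1.shape
    if min(nx, ny) < config.slic_region_size:
        raise ValueError("slice dimensions smaller than the SLIC region size")
    n_segments = max(1, (nx * ny) // config.slic_region_size**2)
    out1 = np.empty_like(t1)
    out2 = np.empty_like(t2)
    for z in range(nz):
        sl = np.stack([t1[:, :, z], t2[:, :, z]], axis=-1)
        span = sl.max() - sl.min()
        if span <= 0:
            out1[:, :, z] = t1[:, :, z]
            out2[:, :, z] = t2[:, :, z]
            continue
        seg = skimage_slic(
            (sl - sl.min()) / span,
            n_segments=n_segments,
            compactness=config.slic_regularization,
            start_label=0,
            channel_axis=-1,
            enforce_connectivity=True,
            # permissive fragment merging: with a low regularization factor
            # superpixels are irregular and the default merge threshold
            # collapses them into one region
            min_size_factor=0.1,
        )
        index = np.arange(seg.max() + 1)
        out1[:, :, z] = ndimage.mean(t1[:, :, z], seg, index)[seg]
        out2[:, :, z] = ndimage.mean(t2[:, :, z], seg, index)[seg]
    return {"slic_t1": out1, "slic_t2": out2}


# ---------------------------------------------------------------------------
# θ-band mask

def compute_vh_mask(vh_region: np.ndarray, spacing: np.ndarray, theta_mm: float) -> np.ndarray:
    """VH interior plus voxels outside the VH within θ mm of its boundary."""
    if not vh_region.any():
        raise ValueError("empty VH region")
    if theta_mm == 0:
        return vh_region.copy()
    dist_out = ndimage.distance_transform_edt(~vh_region, sampling=np.asarray(spacing, float))
    return vh_region | (dist_out <= theta_mm)


# ---------------------------------------------------------------------------
# assembly

def assemble_features(
    std_planes: dict[str, np.ndarray],
    slic_planes: dict[str, np.ndarray],
    epsf_planes: dict[str, np.ndarray] | None,
    mask: np.ndarray,
    spacing: np.ndarray,
    use_epsf: bool = True,
) -> FeatureStack:
    """Combine planes into a stack with the documented fixed column order."""
    planes = dict(std_planes)
    planes.update(slic_planes)
    order = list(STD_FEATURE_NAMES)
    if use_epsf:
        if epsf_planes is None:
            raise ValueError("use_epsf=True requires EPSF planes")
        planes.update(epsf_planes)
        order += list(EPSF_FEATURE_NAMES)
    grids = {planes[name].shape for name in order} | {mask.shape}
    if len(grids) > 1:
        raise ValueError(f"feature planes on mismatched grids: {grids}")
    return FeatureStack(planes, mask.astype(bool), np.asarray(spacing, float), tuple(order))


def compute_feature_stack(
    volume: MultiChannelVolume,
    structure_labels: EyeLabelMap,
    tumor_prior: np.ndarray | None,
    config: FeatureConfig | None = None,
    use_epsf: bool = True,
    theta_mm: float | None = None,
) -> FeatureStack:
    """Full feature stack for one case given its (fitted or GT) structures."""
    config = config or FeatureConfig()
    theta = config.theta_mm if theta_mm is None else theta_mm
    std = compute_std_features(volume, config)
    slic_planes = compute_slic_features(volume, config)
    vh_region = (structure_labels.data == LABEL_VH) | (structure_labels.data == LABEL_TUMOR)
    mask = compute_vh_mask(vh_region, structure_labels.spacing, theta)
    epsf = None
    if use_epsf:
        f_l, f_vh = compute_distance_features(structure_labels)
        if tumor_prior is None:
            raise ValueError("EPSF features require a tumor prior plane")
        epsf = {"f_l": f_l, "f_vh": f_vh, "f_t": tumor_prior}
    return assemble_features(std, slic_planes, epsf, mask, volume.spacing, use_epsf)
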