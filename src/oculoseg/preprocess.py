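"""Bring cases into a common frame, resolution and intensity scale.

The canonical frame places the vitreous-humor center at the origin with the
lens-VH axis along +y and the optic disc in the y-x half-plane (x > 0).
Channels are resampled with linear interpolation, label maps with nearest
neighbor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import OPTIC_DISC_ANGLE_DEG
from .volume import LABEL_SCLERA, EyeLabelMap, MultiChannelVolume


class LandmarkDetectionError(RuntimeError):
    """No eye-like blob found; caller may supply landmarks from file."""


class RegistrationError(RuntimeError):
    """Rigid registration failed to converge or fields of view are disjoint."""


@dataclass
class RigidTransform:
    """World-space rigid map ``p' = R p + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply `other` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_json(self) -> str:
        return json.dumps(
            {"rotation": self.rotation.ravel().tolist(), "translation": self.translation.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.array(d["rotation"]).reshape(3, 3), np.array(d["translation"]))


def detect_landmarks(volume: MultiChannelVolume) -> dict[str, np.ndarray]:
    """Locate vh_center, lens_center and optic disc from the image channels.

    The VH is the largest T2-bright connected component; the lens is the
    embedded cavity with the lowest mean T1 (the tumor, when present, is a
    second cavity but enhances on T1).  The optic disc position carries no
    intensity signature, so it is placed on the detected globe at the
    anatomical ~15 degrees off the posterior pole, in the plane the package
    uses as its roll reference.
    """
    t2 = volume.channels["T2"]
    t1 = volume.channels["T1"]
    finite_range = float(t2.max() - t2.min())
    if finite_range <= 0:
        raise LandmarkDetectionError("channel has no intensity range")
    thr = threshold_otsu(t2)
    bright = t2 > thr
    lbl, n = ndimage.label(bright)
    if n == 0:
        raise LandmarkDetectionError("no bright blob found")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    blob = lbl == (1 + int(np.argmax(sizes)))
    if blob.sum() < 50:
        raise LandmarkDetectionError("largest bright blob too small to be an eye")
    filled = ndimage.binary_fill_holes(blob)
    vh_center_idx = np.array(ndimage.center_of_mass(filled))
    vh_center = volume.index_to_world(vh_center_idx)

    holes = filled & ~blob
    hlbl, hn = ndimage.label(holes)
    if hn == 0:
        raise LandmarkDetectionError("no lens cavity found inside the eye")
    means = ndimage.mean(t1, hlbl, index=np.arange(1, hn + 1))
    hsizes = ndimage.sum_labels(np.ones_like(hlbl), hlbl, index=np.arange(1, hn + 1))
    means = np.where(hsizes >= 10, means, np.inf)  # ignore speckle holes
    if not np.isfinite(means).any():
        raise LandmarkDetectionError("no lens cavity found inside the eye")
    lens_blob = hlbl == (1 + int(np.argmin(means)))
    lens_center = volume.index_to_world(np.array(ndimage.center_of_mass(lens_blob)))

    # globe radius from the filled-volume equivalent sphere
    voxel_vol = float(np.prod(volume.spacing))
    radius = (3.0 * filled.sum() * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    posterior = vh_center - lens_center
    norm = np.linalg.norm(posterior)
    if norm < 1e-9:
        raise LandmarkDetectionError("lens and VH centers coincide")
    posterior = posterior / norm
    disc_dir = _rotate_towards_x(posterior, np.deg2rad(OPTIC_DISC_ANGLE_DEG))
    optic_disc = vh_center + radius * disc_dir
    return {"vh_center": vh_center, "lens_center": lens_center, "optic_disc": optic_disc}


def _rotate_towards_x(direction: np.ndarray, angle: float) -> np.ndarray:
    """Rotate `direction` by `angle` within the plane spanned with +x."""
    x = np.array([1.0, 0.0, 0.0])
    perp = x - np.dot(x, direction) * direction
    n = np.linalg.norm(perp)
    if n < 1e-9:  # direction parallel to x; use +z as fallback plane
        perp = np.array([0.0, 0.0, 1.0]) - direction * direction[2]
        n = np.linalg.norm(perp)
    perp /= n
    return np.cos(angle) * direction + np.sin(angle) * perp


def canonical_frame(landmarks: dict[str, np.ndarray]) -> RigidTransform:
    """Rigid world map taking the landmark triplet to the canonical frame."""
    vh = np.asarray(landmarks["vh_center"], dtype=float)
    lens = np.asarray(landmarks["lens_center"], dtype=float)
    disc = np.asarray(landmarks["optic_disc"], dtype=float)
    y = lens - vh
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("lens and VH landmarks coincide")
    y = y / ny
    d = disc - vh
    x = d - np.dot(d, y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise ValueError("landmarks are collinear; canonical roll is undefined")
    x = x / nx
    z = np.cross(x, y)
    rot = np.stack([x, y, z])  # rows: canonical axes in world coordinates
    return RigidTransform(rot, -rot @ vh)


def resample_rigid(
    volume: MultiChannelVolume,
    labels: EyeLabelMap | None,
    transform: RigidTransform,
    out_shape: tuple[int, int, int] | None = None,
    out_spacing: np.ndarray | None = None,
) -> tuple[MultiChannelVolume, EyeLabelMap | None]:
    """Resample onto a grid centered on the canonical origin.

    `transform` maps input world -> output world.  Channels use linear,
    labels nearest-neighbor interpolation.
    """
    out_shape = tuple(out_shape or volume.shape)
    spacing = np.asarray(out_spacing if out_spacing is not None else volume.spacing, float)
    out_origin = -(np.asarray(out_shape) - 1) / 2.0 * spacing

    idx = np.indices(out_shape, dtype=float).reshape(3, -1).T
    world_out = out_origin + idx * spacing
    inv = transform.inverse()
    world_in = inv.apply(world_out)
    coords = ((world_in - volume.origin) / volume.spacing).T.reshape(3, *out_shape)

    channels = {
        name: ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
        for name, arr in volume.channels.items()
    }
    out_volume = MultiChannelVolume(channels, spacing, out_origin)
    out_labels = None
    if labels is not None:
        data = ndimage.map_coordinates(labels.data, coords, order=0, mode="constant", cval=0)
        out_labels = EyeLabelMap(data.astype(labels.data.dtype), spacing, out_origin)
    return out_volume, out_labels


def resample_to_spacing(
    volume: MultiChannelVolume,
    labels: EyeLabelMap | None = None,
    spacing_mm: float = 0.5,
) -> tuple[MultiChannelVolume, EyeLabelMap | None]:
    """Resample to a common isotropic resolution (default 0.5 mm).

    The physical extent is preserved; channels are interpolated linearly,
    labels with nearest neighbor.
    """
    new_spacing = np.full(3, float(spacing_mm))
    extent = (np.asarray(volume.shape) - 1) * volume.spacing
    out_shape = tuple((np.floor(extent / new_spacing) + 1).astype(int))
    # identity world map; resample_rigid centers the output grid on the
    # canonical origin, so shift it back over the input's physical center
    out_volume, out_labels = resample_rigid(
        volume, labels,
        RigidTransform(np.eye(3), -(volume.origin + extent / 2.0)),
        out_shape=out_shape, out_spacing=new_spacing,
    )
    shift = volume.origin + extent / 2.0
    out_volume.origin = out_volume.origin + shift
    if out_labels is not None:
        out_labels.origin = out_labels.origin + shift
    return out_volume, out_labels


def align_to_canonical(
    volume: MultiChannelVolume,
    labels: EyeLabelMap | None,
    landmarks: dict[str, np.ndarray],
) -> tuple[MultiChannelVolume, EyeLabelMap | None, RigidTransform]:
    """Map the case into the canonical frame defined by its three landmarks."""
    transform = canonical_frame(landmarks)
    out_volume, out_labels = resample_rigid(volume, labels, transform)
    return out_volume, out_labels, transform


# ---------------------------------------------------------------------------
# rigid inter-channel co-registration

def _to_sitk(arr: np.ndarray, spacing: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def coregister_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing: np.ndarray,
    min_final_metric: float = -0.05,
) -> RigidTransform:
    """Recover the rigid motion aligning `moving` onto `fixed`.

    Mattes mutual information + regular-step gradient descent; works across
    channels with different contrast.  Returns the transform mapping moving
    world points to fixed world points.
    """
    spacing = np.asarray(spacing, dtype=float)
    f_img = _to_sitk(fixed, spacing)
    m_img = _to_sitk(moving, spacing)
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(0.3, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init, inPlace=False)
    try:
        result = reg.Execute(f_img, m_img)
        final_metric = reg.GetMetricValue()
    except RuntimeError as exc:
        raise RegistrationError(f"rigid registration failed: {exc}") from None
    if final_metric > min_final_metric:
        raise RegistrationError(
            f"rigid registration did not converge (final metric {final_metric:.4f})"
        )
    euler = sitk.Euler3DTransform(
        result if not isinstance(result, sitk.CompositeTransform) else result.GetNthTransform(0)
    )
    rot = np.array(euler.GetMatrix()).reshape(3, 3)
    center = np.array(euler.GetCenter())
    trans = np.array(euler.GetTranslation())
    # sitk transform maps fixed-space points into moving space; invert it so
    # the returned transform carries moving onto fixed
    fixed_to_moving = RigidTransform(rot, trans + center - rot @ center)
    return fixed_to_moving.inverse()


# ---------------------------------------------------------------------------
# intensity normalization

@dataclass
class NormalizationMap:
    """Piecewise-linear percentile-landmark intensity map (monotone)."""

    source_landmarks: np.ndarray
    target_landmarks: np.ndarray
    percentiles: tuple[float, ...] = (1.0, 99.0)

    def __post_init__(self) -> None:
        self.source_landmarks = np.asarray(self.source_landmarks, dtype=float)
        self.target_landmarks = np.asarray(self.target_landmarks, dtype=float)
        if np.any(np.diff(self.source_landmarks) <= 0):
            raise ValueError("source landmarks must be strictly increasing")
        if np.any(np.diff(self.target_landmarks) < 0):
            raise ValueError("target landmarks must be non-decreasing")

    @classmethod
    def from_channel(
        cls,
        channel: np.ndarray,
        percentiles: tuple[float, ...] = (1.0, 99.0),
        targets: tuple[float, ...] = (0.0, 100.0),
    ) -> "NormalizationMap":
        src = np.percentile(channel, percentiles)
        if src[-1] - src[0] <= 0:
            raise ValueError("constant-valued channel cannot be normalized")
        return cls(src, np.asarray(targets, dtype=float), tuple(percentiles))

    def apply(self, channel: np.ndarray) -> np.ndarray:
        src, tgt = self.source_landmarks, self.target_landmarks
        # linear extrapolation beyond the outer landmarks keeps the map monotone
        lo_slope = (tgt[1] - tgt[0]) / (src[1] - src[0])
        hi_slope = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
        out = np.interp(channel, src, tgt)
        below = channel < src[0]
        above = channel > src[-1]
        out = np.where(below, tgt[0] + (channel - src[0]) * lo_slope, out)
        out = np.where(above, tgt[-1] + (channel - src[-1]) * hi_slope, out)
        return out


def normalize_intensity(channel: np.ndarray, reference: NormalizationMap) -> np.ndarray:
    """Map the channel so its percentile landmarks hit the reference targets."""
    own = NormalizationMap.from_channel(channel, reference.percentiles, tuple(reference.target_landmarks))
    return own.apply(channel)


# ---------------------------------------------------------------------------
# ROI crop

@dataclass
class CropInfo:
    index_offset: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))

    def to_original_index(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx) + self.index_offset


def crop_roi(
    volume: MultiChannelVolume,
    labels: EyeLabelMap,
    landmarks: dict[str, np.ndarray],
    margin_mm: float = 8.0,
) -> tuple[MultiChannelVolume, EyeLabelMap, CropInfo]:
    """Crop a box centered on vh_center containing the sclera shell + margin.

    The cropped grids keep world coordinates (origin shifts with the crop),
    so index bookkeeping round-trips exactly.
    """
    eye = labels.data == LABEL_SCLERA
    if not eye.any():
        raise ValueError("no sclera voxels; cannot determine the eye extent")
    center_idx = volume.world_to_index(landmarks["vh_center"])
    idx = np.array(np.nonzero(eye))
    half_mm = np.maximum(
        np.abs(idx.min(axis=1) - center_idx), np.abs(idx.max(axis=1) - center_idx)
    ) * volume.spacing + margin_mm
    half_vox = np.ceil(half_mm / volume.spacing).astype(int)
    lo = np.round(center_idx).astype(int) - half_vox
    hi = np.round(center_idx).astype(int) + half_vox + 1
    shape = np.asarray(volume.shape)
    if np.any(lo < 0) or np.any(hi > shape):
        warnings.warn("ROI crop exceeds grid bounds; clamping", stacklevel=2)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    new_origin = volume.origin + lo * volume.spacing
    out_volume = MultiChannelVolume(
        {c: a[sl].copy() for c, a in volume.channels.items()}, volume.spacing.copy(), new_origin
    )
    out_labels = EyeLabelMap(labels.data[sl].copy(), volume.spacing.copy(), new_origin)
    return out_volume, out_labels, CropInfo(lo)
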