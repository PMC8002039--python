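"""Region-of-interest summarization of 4-D volume series.

Stages: isotropic Gaussian smoothing (FWHM in mm), selection of one
activation maximum per region under a binary mask with a minimum pairwise
Euclidean separation, and summarization of a small sphere around each
maximum by its first eigenvariate (first principal temporal component).

Coordinates are world mm; voxel indices are 0-based and mapped through a
diagonal affine (voxel size + origin).  NIfTI I/O goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class VolumeSeries:
    """A (x, y, z, t) voxel array with geometry."""

    data: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.0)
    origin: tuple = (0.0, 0.0, 0.0)
    tr: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError("volume series must be 4-D (x, y, z, t)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, ijk) -> np.ndarray:
        return np.asarray(ijk, float) * np.asarray(self.voxel_size) + np.asarray(
            self.origin
        )

    def mm_to_voxel(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, float) - np.asarray(self.origin)) / np.asarray(
            self.voxel_size
        )

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms((*self.voxel_size, self.tr))
        return img

    @classmethod
    def from_nifti(cls, img_or_path, tr: float | None = None) -> "VolumeSeries":
        img = (
            img_or_path
            if isinstance(img_or_path, nib.Nifti1Image)
            else nib.load(str(img_or_path))
        )
        aff = img.affine
        vox = tuple(np.abs(np.diag(aff)[:3]))
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(
            data=np.asarray(img.get_fdata(), float),
            voxel_size=vox,
            origin=tuple(aff[:3, 3]),
            tr=tr,
        )


@dataclass
class RoiSpec:
    """A labeled sphere in world mm coordinates."""

    label: str
    center: tuple
    radius: float = 4.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        self.center = tuple(float(c) for c in self.center)


def roi_table(rois) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {"label": r.label, "x": r.center[0], "y": r.center[1],
             "z": r.center[2], "radius": r.radius}
            for r in rois
        ]
    )


def gaussian_smooth(vol: VolumeSeries, fwhm: float,
                    renormalize: bool = True) -> VolumeSeries:
    """Per-volume 3-D Gaussian smoothing with FWHM given in mm.

    Per-axis sigma is fwhm/2.3548 mm converted to voxels.  Boundaries are
    zero-padded; with ``renormalize`` the result is divided by the smoothed
    all-ones volume so constants stay constant up to the image edge.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return VolumeSeries(vol.data.copy(), vol.voxel_size, vol.origin, vol.tr)
    sigma_vox = [fwhm / FWHM_TO_SD / v for v in vol.voxel_size]
    out = np.empty_like(vol.data)
    norm = None
    if renormalize:
        ones = np.ones(vol.data.shape[:3])
        norm = gaussian_filter(ones, sigma_vox, mode="constant")
    for t in range(vol.n_volumes):
        sm = gaussian_filter(vol.data[..., t], sigma_vox, mode="constant")
        out[..., t] = sm / norm if renormalize else sm
    return VolumeSeries(out, vol.voxel_size, vol.origin, vol.tr)


def select_maxima(
    stat_map: np.ndarray,
    masks: dict,
    min_separation: float = 8.0,
    voxel_size=(2.0, 2.0, 2.0),
    origin=(0.0, 0.0, 0.0),
    radius: float = 4.0,
) -> list[RoiSpec]:
    """One peak coordinate per region, separated by >= ``min_separation`` mm.

    Regions are processed greedily in the declared (dict) order; each takes
    its highest masked voxel that keeps a Euclidean distance of at least
    ``min_separation`` mm from every already-selected peak, falling back to
    the next-highest voxel on conflict.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be nonnegative")
    stat_map = np.asarray(stat_map, float)
    voxel_size = np.asarray(voxel_size, float)
    origin = np.asarray(origin, float)
    chosen: list[RoiSpec] = []
    for label, mask in masks.items():
        mask = np.asarray(mask, bool)
        if mask.shape != stat_map.shape:
            raise ValueError(f"mask for {label!r} does not match the map shape")
        idx = np.argwhere(mask)
        if idx.size == 0:
            raise ValueError(f"empty mask for region {label!r}")
        vals = stat_map[mask]
        order = np.argsort(vals)[::-1]
        placed = False
        for o in order:
            xyz = idx[o] * voxel_size + origin
            if all(
                np.linalg.norm(xyz - np.asarray(r.center)) >= min_separation
                for r in chosen
            ):
                chosen.append(RoiSpec(label, tuple(xyz), radius))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"no admissible voxel for region {label!r} under the "
                f"{min_separation} mm separation rule"
            )
    return chosen


def sphere_voxels(vol: VolumeSeries, roi: RoiSpec) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ROI sphere."""
    shape = vol.data.shape[:3]
    grid = np.indices(shape).reshape(3, -1).T
    mm = grid * np.asarray(vol.voxel_size) + np.asarray(vol.origin)
    d2 = np.sum((mm - np.asarray(roi.center)) ** 2, axis=1)
    return (d2 <= roi.radius**2).reshape(shape)


def first_eigenvariate(vol: VolumeSeries, roi: RoiSpec) -> np.ndarray:
    """First principal temporal component of the sphere's voxel x time matrix.

    Scaled to the amplitude (root-mean-square) of the mean ROI series, with
    sign chosen so its correlation with the mean series is nonnegative.
    """
    inside = sphere_voxels(vol, roi)
    if not inside.any():
        raise ValueError(f"ROI sphere {roi.label!r} contains no voxels")
    Y = vol.data[inside].T  # time x voxels
    mean_series = Y.mean(axis=1)
    U, S, _ = np.linalg.svd(Y, full_matrices=False)
    e = U[:, 0]
    amp_m = np.sqrt(np.mean(mean_series**2))
    amp_e = np.sqrt(np.mean(e**2))
    if amp_m > 0 and amp_e > 0:
        e = e * (amp_m / amp_e)
    else:
        e = e * S[0] / np.sqrt(Y.shape[1])
    c = e - e.mean()
    m = mean_series - mean_series.mean()
    if float(c @ m) < 0:
        e = -e
    return e
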