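"""Region-based feature extraction from tissue-density volumes.

Turns grey-/white-matter density volumes plus an atlas label volume (e.g. the
116-region AAL parcellation) into the decoding design matrix: per-region mean
densities, 0/1 acquisition-site indicator columns and a +1/-1 gender
regressor, in the canonical block order [GM | WM | site | gender] with
p = 2R + S + 1 columns. The atlas is resliced onto the data grid with
nearest-neighbour interpolation before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .data import Dataset

__all__ = [
    "LabelVolume",
    "RegionFeatureRow",
    "reslice_labels",
    "region_means",
    "build_design_matrix",
    "extract_features",
]


@dataclass
class LabelVolume:
    """Integer atlas parcellation on a voxel grid; label 0 is background."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.allclose(self.voxels, rounded):
                raise ValueError("label volume must contain integer labels")
            self.voxels = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if np.any(self.voxels < 0):
            raise ValueError("labels must be non-negative (0 = background)")

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        unique = np.unique(self.voxels)
        return unique[unique > 0]

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "LabelVolume":
        return cls(voxels=np.asarray(img.dataobj), affine=img.affine)

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.voxels.astype(np.int16), self.affine)


@dataclass
class RegionFeatureRow:
    """Per-subject region-mean features."""

    subject_id: str
    gm_means: np.ndarray
    wm_means: np.ndarray

    def __post_init__(self) -> None:
        self.gm_means = np.asarray(self.gm_means, dtype=float).ravel()
        self.wm_means = np.asarray(self.wm_means, dtype=float).ravel()
        if self.gm_means.shape != self.wm_means.shape:
            raise ValueError("gm_means and wm_means must have equal length")


def _check_invertible(affine: np.ndarray, name: str) -> None:
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{name} affine is singular (not invertible)")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (deterministic NN)."""
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def reslice_labels(labels: LabelVolume, reference) -> LabelVolume:
    """Reslice an atlas onto a reference grid by nearest-neighbour lookup.

    Each reference voxel centre is mapped through the two affines into the
    label volume's voxel space and assigned the label of the nearest voxel
    (half-coordinates round away from zero); positions outside the label
    volume become background.
    """
    if isinstance(reference, LabelVolume):
        ref_shape, ref_affine = reference.voxels.shape, reference.affine
    elif isinstance(reference, nib.spatialimages.SpatialImage):
        ref_shape, ref_affine = reference.shape, reference.affine
    else:  # (shape, affine) pair
        ref_shape, ref_affine = reference
        ref_affine = np.asarray(ref_affine, dtype=float)
    _check_invertible(labels.affine, "label")
    _check_invertible(ref_affine, "reference")
    mapping = np.linalg.inv(labels.affine) @ ref_affine
    grid = np.indices(ref_shape).reshape(3, -1)
    coords = mapping[:3, :3] @ grid + mapping[:3, 3:4]
    idx = _round_half_away(coords)
    shape = np.asarray(labels.voxels.shape)[:, None]
    inside = np.all((idx >= 0) & (idx < shape), axis=0)
    out = np.zeros(grid.shape[1], dtype=labels.voxels.dtype)
    out[inside] = labels.voxels[idx[0, inside], idx[1, inside], idx[2, inside]]
    return LabelVolume(voxels=out.reshape(ref_shape), affine=ref_affine)


def region_means(data, labels: LabelVolume, region_labels=None) -> np.ndarray:
    """Mean of ``data`` voxels within each atlas region, ascending label order.

    ``data`` may be a nibabel image (grid checked against the label affine)
    or a bare array on the label grid. Empty regions yield NaN with a warning;
    downstream fitting refuses NaNs unless imputation is requested.
    """
    if isinstance(data, nib.spatialimages.SpatialImage):
        if not np.allclose(data.affine, labels.affine):
            raise ValueError("data and label volumes are on different grids")
        values = np.asarray(data.dataobj, dtype=float)
    else:
        values = np.asarray(data, dtype=float)
    if values.shape != labels.voxels.shape:
        raise ValueError(
            f"data shape {values.shape} does not match label grid "
            f"{labels.voxels.shape}")
    if region_labels is None:
        region_labels = labels.labels
    region_labels = np.asarray(region_labels)
    flat_labels = labels.voxels.ravel()
    sums = np.bincount(flat_labels, weights=values.ravel())
    counts = np.bincount(flat_labels)
    means = np.full(region_labels.size, np.nan)
    for i, lab in enumerate(region_labels):
        if lab < counts.size and counts[lab] > 0:
            means[i] = sums[lab] / counts[lab]
        else:
            warnings.warn(f"region {lab} is empty; mean set to NaN",
                          stacklevel=2)
    return means


def build_design_matrix(rows, site, gender, *, site_levels=None,
                        gender_levels=None):
    """Assemble the [GM | WM | site | gender] design block.

    Parameters
    ----------
    rows : sequence of RegionFeatureRow
    site : sequence
        Site labels per subject; one 0/1 indicator column per level.
    gender : sequence
        Binary gender labels; coded +1 for the first level and -1 for the
        second (lexicographic order unless ``gender_levels`` is given).
        Numeric +1/-1 input passes through.
    site_levels : sequence or None
        The declared site set. Levels seen here but absent from the data get
        all-zero columns; data levels outside the declared set raise.

    Returns
    -------
    (design, column_roles) : (n, 2R + S + 1) array and role tags.
    """
    rows = list(rows)
    site = np.asarray(site)
    gender = np.asarray(gender)
    n = len(rows)
    if site.shape != (n,) or gender.shape != (n,):
        raise ValueError("rows, site and gender must have equal length")
    gm = np.vstack([r.gm_means for r in rows])
    wm = np.vstack([r.wm_means for r in rows])
    n_regions = gm.shape[1]

    if site_levels is None:
        site_levels = np.unique(site)
    else:
        site_levels = np.asarray(site_levels)
        unseen = set(site) - set(site_levels)
        if unseen:
            raise ValueError(
                f"site level(s) {sorted(map(str, unseen))} not in the "
                "declared site set")
    site_block = (site[:, None] == site_levels[None, :]).astype(float)

    if np.issubdtype(gender.dtype, np.number) and set(np.unique(gender)) <= {-1.0, 1.0}:
        gender_col = gender.astype(float)
    else:
        levels = (np.asarray(gender_levels) if gender_levels is not None
                  else np.unique(gender.astype(str)))
        if levels.size > 2 or levels.size == 0:
            raise ValueError("gender must have at most two levels")
        # a single observed level is the lexicographic first -> coded +1
        gender_col = np.where(gender.astype(str) == str(levels[0]), 1.0, -1.0)

    design = np.hstack([gm, wm, site_block, gender_col[:, None]])
    roles = np.asarray(
        ["gm_region"] * n_regions + ["wm_region"] * n_regions
        + ["site"] * site_levels.size + ["gender"], dtype=object)
    return design, roles


def extract_features(gm_images, wm_images, atlas: LabelVolume, subject_ids,
                     site, gender, ages=None, *, site_levels=None,
                     gender_levels=None) -> Dataset:
    """Full extraction: reslice atlas to the first GM image, average regions
    per subject, and assemble the design matrix as a :class:`Dataset`."""
    gm_images = list(gm_images)
    wm_images = list(wm_images)
    if len(gm_images) != len(wm_images):
        raise ValueError("need one WM image per GM image")
    resliced = reslice_labels(atlas, gm_images[0])
    region_labels = resliced.labels
    rows = []
    for sid, gm_img, wm_img in zip(subject_ids, gm_images, wm_images):
        rows.append(RegionFeatureRow(
            subject_id=str(sid),
            gm_means=region_means(gm_img, resliced, region_labels),
            wm_means=region_means(wm_img, resliced, region_labels)))
    design, roles = build_design_matrix(
        rows, site, gender, site_levels=site_levels,
        gender_levels=gender_levels)
    n = design.shape[0]
    ages = np.full(n, np.nan) if ages is None else np.asarray(ages, float)
    return Dataset(ages=ages, design=design, column_roles=roles,
                   subject_ids=np.asarray(list(subject_ids), dtype=object))
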