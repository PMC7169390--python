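"""3D tumor-mass segmentation and eye-referenced localisation.

Masses are supra-threshold 26-connected components above a minimum size;
the largest one is the primary (injection-site) tumor and all others are
disseminated secondary foci. Each secondary focus is summarised by its
centroid x-coordinate relative to the eye landmark — the 1-D rostro-caudal
position underlying the dispersion (x-variance) readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from zeonco.io import VoxelStack

#: 26-neighbour connectivity structure for 3D component labeling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentedMass:
    """One connected 3D tumor component."""

    mass_id: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    is_primary: bool = False


@dataclass
class LarvaSegmentation:
    """All masses of one larva at one time point, plus the eye landmark."""

    larva_id: str
    timepoint_tag: str
    threshold_used: float
    background: float
    masses: list[SegmentedMass] = field(default_factory=list)
    eye_um: Optional[tuple[float, float, float]] = None

    @property
    def primary(self) -> Optional[SegmentedMass]:
        for m in self.masses:
            if m.is_primary:
                return m
        return None

    @property
    def secondaries(self) -> list[SegmentedMass]:
        return [m for m in self.masses if not m.is_primary]

    @property
    def foci_rel_x(self) -> list[float]:
        """Secondary-mass centroid x minus eye x, in µm (one per focus)."""
        if self.eye_um is None:
            raise ValueError("no eye landmark available for relative positions")
        ex = self.eye_um[2]
        return [m.centroid_um[2] - ex for m in self.secondaries]


def estimate_background(stack: VoxelStack) -> float:
    """Robust background level: the median voxel intensity.

    Tumor and eye signal occupy a small fraction of the field of view, so
    the median is insensitive to them.
    """
    return float(np.median(stack.intensities))


def segment_tumor(
    stack: VoxelStack,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_voxels: int = 30,
    exclude_center_um: Optional[tuple[float, float, float]] = None,
    exclude_radius_um: float = 0.0,
    background: Optional[float] = None,
) -> tuple[list[SegmentedMass], float]:
    """Threshold, label 26-connected components, and size-filter.

    Parameters
    ----------
    method
        "otsu" (parameter-free, full-stack histogram) or "fixed".
    fixed_threshold
        Required when ``method == "fixed"``.
    min_voxels
        Components smaller than this are discarded (noise speckles).
    exclude_center_um, exclude_radius_um
        Optional spherical region (e.g. around the eye landmark, which is
        autofluorescent/bright) zeroed out of the mask before labeling.

    Returns
    -------
    (masses, threshold_used)
        Masses sorted by voxel count, descending; no primary flag yet.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    img = stack.intensities
    if method == "otsu":
        if float(img.max()) == float(img.min()):
            warnings.warn("constant-intensity stack: nothing to segment")
            return [], float(img.max())
        threshold = float(threshold_otsu(img))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    bg = float(np.median(img)) if background is None else float(background)
    if threshold <= bg:
        warnings.warn(
            f"threshold {threshold:.3g} <= background estimate {bg:.3g}; "
            "segmentation likely degenerate"
        )

    mask = img > threshold
    if exclude_center_um is not None and exclude_radius_um > 0:
        vs = stack.voxel_size
        coords = [
            (np.arange(n) * d - c) ** 2
            for n, d, c in zip(mask.shape, vs, exclude_center_um)
        ]
        dist2 = (
            coords[0][:, None, None]
            + coords[1][None, :, None]
            + coords[2][None, None, :]
        )
        mask &= dist2 > exclude_radius_um**2

    labels, n_labels = ndi.label(mask, structure=_STRUCT_26)
    if n_labels == 0:
        return [], threshold
    zz, yy, xx = np.nonzero(mask)
    lab_vals = labels[zz, yy, xx]
    counts = np.bincount(lab_vals, minlength=n_labels + 1)[1:]
    keep = np.flatnonzero(counts >= min_voxels) + 1
    if keep.size == 0:
        return [], threshold
    sums = [
        np.bincount(lab_vals, weights=coord, minlength=n_labels + 1)[1:]
        for coord in (zz, yy, xx)
    ]
    centroids = [
        tuple(s[lab - 1] / counts[lab - 1] for s in sums) for lab in keep
    ]
    slices = ndi.find_objects(labels)
    vs = stack.voxel_size
    vvol = stack.voxel_volume_um3
    masses = []
    for lab, cent in zip(keep, centroids):
        sl = slices[lab - 1]
        masses.append(
            SegmentedMass(
                mass_id=int(lab),
                voxel_count=int(counts[lab - 1]),
                volume_um3=float(counts[lab - 1] * vvol),
                centroid_um=tuple(float(c * d) for c, d in zip(cent, vs)),
                bbox=tuple((s.start, s.stop) for s in sl),  # type: ignore[arg-type]
            )
        )
    masses.sort(key=lambda m: m.voxel_count, reverse=True)
    for i, m in enumerate(masses):
        m.mass_id = i + 1
    return masses, threshold


def classify_primary(
    masses: Sequence[SegmentedMass],
    injection_ref_um: Optional[tuple[float, float, float]] = None,
) -> list[SegmentedMass]:
    """Flag the primary (injection-site) tumor among segmented masses.

    The largest mass is primary; exact size ties are broken by proximity of
    the centroid to the injection reference point. Empty input stays empty.
    """
    out = [
        SegmentedMass(
            m.mass_id, m.voxel_count, m.volume_um3, m.centroid_um, m.bbox, False
        )
        for m in masses
    ]
    if not out:
        return out
    max_count = max(m.voxel_count for m in out)
    candidates = [m for m in out if m.voxel_count == max_count]
    if len(candidates) > 1 and injection_ref_um is not None:
        ref = np.asarray(injection_ref_um)
        candidates.sort(
            key=lambda m: float(np.sum((np.asarray(m.centroid_um) - ref) ** 2))
        )
    candidates[0].is_primary = True
    return out


def locate_eye(
    stack: VoxelStack,
    annotation_um: Optional[tuple[float, float, float]] = None,
    rostral_fraction: float = 0.25,
    min_voxels: int = 10,
) -> tuple[float, float, float]:
    """Eye landmark in µm: a manual annotation, or the brightest compact
    blob in the rostral sub-volume (first ``rostral_fraction`` of the x
    axis) when no annotation is given."""
    extent = tuple(n * d for n, d in zip(stack.shape, stack.voxel_size))
    if annotation_um is not None:
        if any(not (0 <= c <= e) for c, e in zip(annotation_um, extent)):
            raise ValueError(
                f"eye annotation {annotation_um} outside grid extent {extent}"
            )
        return tuple(float(c) for c in annotation_um)  # type: ignore[return-value]

    nx = max(1, int(stack.shape[2] * rostral_fraction))
    sub = stack.intensities[:, :, :nx]
    bg = float(np.median(sub))
    peak = float(sub.max())
    if peak <= bg or (peak - bg) < 1e-9:
        raise ValueError(
            "no detectable eye blob in rostral sub-volume; provide a manual "
            "eye annotation in the plate map"
        )
    # keep only the top of the intensity range: the eye outshines tumor signal
    threshold = bg + 0.75 * (peak - bg)
    mask = sub > threshold
    labels, n = ndi.label(mask, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("no eye blob found; provide a manual annotation")
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_voxels:
        raise ValueError(
            "brightest rostral blob too small to be an eye; provide a manual "
            "annotation"
        )
    cent = ndi.center_of_mass(mask, labels, best)
    return tuple(float(c * d) for c, d in zip(cent, stack.voxel_size))  # type: ignore[return-value]


def segment_larva(
    stack: VoxelStack,
    eye_annotation_um: Optional[tuple[float, float, float]] = None,
    method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_voxels: int = 30,
    eye_exclusion_radius_um: float = 40.0,
    injection_ref_um: Optional[tuple[float, float, float]] = None,
) -> LarvaSegmentation:
    """Full per-stack segmentation: eye, masses, primary call.

    The eye region is excluded from the tumor mask before labeling so the
    bright landmark can never masquerade as a tumor mass.
    """
    eye = locate_eye(stack, annotation_um=eye_annotation_um)
    background = estimate_background(stack)
    masses, threshold = segment_tumor(
        stack,
        method=method,
        fixed_threshold=fixed_threshold,
        min_voxels=min_voxels,
        exclude_center_um=eye,
        exclude_radius_um=eye_exclusion_radius_um,
        background=background,
    )
    masses = classify_primary(masses, injection_ref_um or eye)
    return LarvaSegmentation(
        larva_id=stack.larva_id,
        timepoint_tag=stack.timepoint_tag,
        threshold_used=threshold,
        background=background,
        masses=masses,
        eye_um=eye,
    )
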