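"""Bone segmentation and cortical/cancellous classification.

The in-vivo workflow is automatic recognition followed by manual correction
of misrecognized regions.  Here segmentation is a density threshold keeping
the largest connected component; the cortical compartment is the
boundary-connected high-density shell; manual corrections are replayable
edit records (polygons with a forced label) so the whole chain stays
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw, measure, morphology

__all__ = [
    "BACKGROUND",
    "CORTICAL",
    "CANCELLOUS",
    "ShellParams",
    "BoneMask",
    "RoiEdit",
    "segment_bone",
    "classify_cortical",
    "apply_edits",
    "load_edits",
    "write_label_image",
]

BACKGROUND, CORTICAL, CANCELLOUS = 0, 1, 2
_VALID_LABELS = (BACKGROUND, CORTICAL, CANCELLOUS)


@dataclass(frozen=True)
class ShellParams:
    """Parameters of the cortical-shell classification rule.

    cortical_threshold
        Minimum density (mg/cm^3) for a bone pixel to belong to the shell.
    max_shell_depth_cm
        Maximum depth (cm) of the shell measured inward from the bone
        boundary; limits how far the shell flood can reach.
    halo_fraction
        Bone pixels outside the closed shell (the partial-volume surface
        halo left by blur) are merged into the cortex, but only while they
        amount to less than this fraction of all bone pixels -- a larger
        exterior-reachable set means the ring is genuinely broken.
    """

    cortical_threshold: float = 450.0
    max_shell_depth_cm: float = 0.2
    halo_fraction: float = 0.25


@dataclass
class BoneMask:
    """Per-pixel label map {0 background, 1 cortical, 2 cancellous}.

    ``ring_ok`` is False when the cortical shell does not enclose the
    cancellous compartment (broken ring); such slices are skipped by the
    thickness measurement and flagged downstream.
    """

    labels: np.ndarray
    ring_ok: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("BoneMask labels must be 2-D")

    @property
    def bone(self) -> np.ndarray:
        """Boolean mask of all bone pixels (cortical + cancellous)."""
        return self.labels != BACKGROUND

    @property
    def cortical(self) -> np.ndarray:
        return self.labels == CORTICAL

    @property
    def cancellous(self) -> np.ndarray:
        return self.labels == CANCELLOUS

    @property
    def empty(self) -> bool:
        return not self.bone.any()


@dataclass(frozen=True)
class RoiEdit:
    """One replayable manual correction: force ``label`` inside a polygon.

    The polygon is a sequence of (x, y) vertices in pixel coordinates on
    slice ``slice_index``; later edits override earlier ones.
    """

    slice_index: int
    polygon: tuple[tuple[float, float], ...]
    label: int

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValueError(f"invalid label {self.label}; must be one of {_VALID_LABELS}")
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")


def segment_bone(slice_map: np.ndarray, bone_threshold: float = 160.0) -> np.ndarray:
    """Threshold a density map and keep the largest connected component.

    Returns a boolean mask; an all-False mask means no pixel reached the
    threshold (the slice is excluded downstream).
    """
    if bone_threshold <= 0:
        raise ValueError("bone_threshold must be > 0")
    slice_map = np.asarray(slice_map, dtype=float)
    raw = slice_map >= bone_threshold
    if not raw.any():
        return raw
    lbl = measure.label(raw, connectivity=2)
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    return lbl == counts.argmax()


def _exterior_background(bone: np.ndarray) -> np.ndarray:
    """Background pixels connected to the image border (4-connectivity)."""
    bg = ~bone
    lbl = measure.label(bg, connectivity=1)
    border_ids = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border_ids = border_ids[border_ids != 0]
    return np.isin(lbl, border_ids)


def _enclosure_ok(labels: np.ndarray) -> bool:
    """True when no cancellous pixel can reach the border avoiding cortex."""
    if not (labels == CANCELLOUS).any():
        return True
    return not _exterior_reachable_cancellous(labels).any()


def classify_cortical(
    mask: np.ndarray,
    slice_map: np.ndarray,
    shell: ShellParams = ShellParams(),
    *,
    pixel_spacing: float,
) -> BoneMask:
    """Split a bone mask into cortical shell and cancellous interior.

    Cortical pixels are those reachable from the outer bone boundary
    through bone of density >= ``shell.cortical_threshold``, no deeper than
    ``shell.max_shell_depth_cm`` from the boundary.  Remaining bone is
    cancellous.  ``ring_ok`` is False when the shell fails to enclose the
    interior.
    """
    mask = np.asarray(mask, dtype=bool)
    slice_map = np.asarray(slice_map, dtype=float)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if not mask.any():
        return BoneMask(labels, ring_ok=False)

    exterior = _exterior_background(mask)
    # depth from the outer boundary, in pixels (pixel-center convention)
    depth = ndimage.distance_transform_edt(~exterior)
    max_depth_px = shell.max_shell_depth_cm / pixel_spacing
    candidate = mask & (slice_map >= shell.cortical_threshold) & (depth <= max_depth_px + 0.5)

    cortical = np.zeros_like(mask)
    if candidate.any():
        touching = ndimage.binary_dilation(exterior, structure=np.ones((3, 3))) & candidate
        comp = measure.label(candidate, connectivity=2)
        keep = np.unique(comp[touching])
        keep = keep[keep != 0]
        cortical = np.isin(comp, keep)

    labels[mask] = CANCELLOUS
    labels[cortical] = CORTICAL

    # merge the partial-volume surface halo (sub-threshold bone outside the
    # closed shell) into the cortex; a large exterior-reachable set is a
    # genuinely broken ring and is left for the enclosure flag instead
    outside = _exterior_reachable_cancellous(labels)
    if outside.any() and outside.sum() < shell.halo_fraction * mask.sum():
        labels[outside] = CORTICAL
    return BoneMask(labels, ring_ok=_enclosure_ok(labels))


def _exterior_reachable_cancellous(labels: np.ndarray) -> np.ndarray:
    """Cancellous pixels that can reach the image border avoiding cortex."""
    passable = labels != CORTICAL
    lbl = measure.label(passable, connectivity=2)
    border_ids = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border_ids = border_ids[border_ids != 0]
    return np.isin(lbl, border_ids) & (labels == CANCELLOUS)


def apply_edits(masks: Sequence[BoneMask], edits: Sequence[RoiEdit]) -> list[BoneMask]:
    """Replay manual corrections over a stack of masks, in order.

    All edits are validated first; any out-of-bounds edit raises and the
    input masks are returned unchanged.  Later edits win on overlap.  The
    enclosure invariant is re-validated on every touched slice.
    """
    masks = list(masks)
    for e in edits:
        if not (0 <= e.slice_index < len(masks)):
            raise IndexError(f"edit slice {e.slice_index} outside stack of {len(masks)}")
        shape = masks[e.slice_index].labels.shape
        for x, y in e.polygon:
            if not (0 <= x <= shape[1] and 0 <= y <= shape[0]):
                raise ValueError(
                    f"edit polygon vertex ({x}, {y}) outside slice of shape {shape}"
                )
    out = [BoneMask(m.labels.copy(), ring_ok=m.ring_ok) for m in masks]
    touched = set()
    for e in edits:
        labels = out[e.slice_index].labels
        xs = np.array([p[0] for p in e.polygon], dtype=float)
        ys = np.array([p[1] for p in e.polygon], dtype=float)
        rr, cc = draw.polygon(ys, xs, shape=labels.shape)
        labels[rr, cc] = e.label
        touched.add(e.slice_index)
    for i in touched:
        out[i].ring_ok = _enclosure_ok(out[i].labels)
    return out


def load_edits(path) -> list[RoiEdit]:
    """Read edits from JSON: ``[{"slice": i, "polygon": [[x,y],...], "label": l}]``."""
    entries = json.loads(Path(path).read_text())
    return [
        RoiEdit(
            slice_index=int(e["slice"]),
            polygon=tuple((float(x), float(y)) for x, y in e["polygon"]),
            label=int(e["label"]),
        )
        for e in entries
    ]


def write_label_image(mask: BoneMask, path) -> None:
    """Persist a label map as an 8-bit TIFF."""
    import tifffile

    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def local_thickness_px(cortical: np.ndarray) -> float:
    """Mean local thickness of a binary ring, in pixels.

    Medial-axis rule: thickness at a skeleton pixel is twice its distance
    to the nearest background pixel center.  On curved rings the half-pixel
    boundary offset and the skeleton pixel's own off-center offset cancel
    on average, so the estimate is unbiased for rings two or more pixels
    wide; a one-pixel ring reads about one pixel high.  Returns NaN for an
    empty mask.
    """
    cortical = np.asarray(cortical, dtype=bool)
    if not cortical.any():
        return float("nan")
    # fixed rng: medial_axis breaks skeletonization ties randomly otherwise
    skel, dist = morphology.medial_axis(cortical, return_distance=True, rng=0)
    if not skel.any():
        return float("nan")
    return float(np.mean(2.0 * dist[skel]))
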