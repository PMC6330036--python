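"""Measurement pipeline: segmented stacks -> per-animal morphometry rows."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import moments
from .segment import BoneMask, ShellParams, classify_cortical, segment_bone
from .stack_io import RESULT_COLUMNS, CalibratedStack

__all__ = ["SegmentationConfig", "measure_stack", "measure_study"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    bone_threshold: float = 160.0
    shell: ShellParams = field(default_factory=ShellParams)


def _segment_stack(
    stack: CalibratedStack, seg: SegmentationConfig, indices: Sequence[int]
) -> list[BoneMask | None]:
    masks: list[BoneMask | None] = [None] * stack.n_slices
    for i in indices:
        bone = segment_bone(stack.slices[i], seg.bone_threshold)
        if not bone.any():
            log.warning("slice %d excluded: no pixel above bone threshold", i)
            continue
        masks[i] = classify_cortical(
            bone, stack.slices[i], seg.shell, pixel_spacing=stack.pixel_spacing
        )
    return masks


def measure_stack(
    stack: CalibratedStack,
    seg: SegmentationConfig = SegmentationConfig(),
    vertebrae: Sequence[str] = moments.DEFAULT_VERTEBRAE,
    diagnostics: bool = False,
):
    """Per-animal morphometry of one calibrated stack.

    Segments every labeled slice, computes per-slice moments, and applies
    the L2-L4 averaging conventions: BMD/volume over the whole analysis
    window, moments as the slice average, thickness and dimensions as the
    mean of per-vertebra values.  Returns the morphometry dict, or
    ``(dict, per-slice DataFrame)`` when ``diagnostics`` is set.
    """
    indices = stack.labeled_slices(vertebrae)
    masks = _segment_stack(stack, seg, indices)
    spacing = stack.pixel_spacing

    diag_rows = []
    imins, polars = [], []
    for i in indices:
        m = masks[i]
        if m is None:
            continue
        centroid = moments.compute_centroid(stack.slices[i], m, spacing)
        imin, theta = moments.minimum_cross_sectional_moment(
            stack.slices[i], m, centroid, spacing
        )
        j = moments.polar_moment(stack.slices[i], m, centroid, spacing)
        imins.append(imin)
        polars.append(j)
        if diagnostics:
            diag_rows.append(
                {
                    "slice": i,
                    "S_i": float(m.bone.sum()) * spacing**2,
                    "I_min": imin,
                    "theta_star": theta,
                    "J": j,
                    "ring_ok": m.ring_ok,
                }
            )
    if not imins:
        raise ValueError("every labeled slice was excluded by segmentation")

    bmd, mineral, volume = moments.bmd_and_volume(stack, masks, vertebrae)
    masks_by_vertebra = {
        name: [
            masks[i]
            for i in range(*_incl(stack.vertebra_labels[name]))
            if masks[i] is not None
        ]
        for name in vertebrae
    }
    thickness = moments.mean_cortical_thickness(masks_by_vertebra, spacing, vertebrae)
    heights, widths = {}, {}
    for name in vertebrae:
        heights[name], widths[name] = moments.vertebral_dimensions(stack, masks, name)
    result = {
        "bmd": bmd,
        "mineral_content": mineral,
        "volume": volume,
        "cortical_thickness": thickness,
        "body_height": moments.vertebra_average(heights, vertebrae),
        "body_width": moments.vertebra_average(widths, vertebrae),
        "min_moment": float(np.mean(imins)),
        "polar_moment": float(np.mean(polars)),
    }
    if diagnostics:
        return result, pd.DataFrame(diag_rows)
    return result


def _incl(rng: tuple[int, int]) -> tuple[int, int]:
    return rng[0], rng[1] + 1


def measure_study(
    stacks: Mapping[str, Mapping[int, CalibratedStack]],
    groups: Mapping[str, str],
    seg: SegmentationConfig = SegmentationConfig(),
    vertebrae: Sequence[str] = moments.DEFAULT_VERTEBRAE,
) -> pd.DataFrame:
    """Measure every (subject, day) stack into a StudyTable DataFrame.

    Subjects whose stack fails to measure are skipped with a log message.
    """
    rows = []
    for subject_id in sorted(stacks):
        for day in sorted(stacks[subject_id]):
            try:
                rec = measure_stack(stacks[subject_id][day], seg, vertebrae)
            except (ValueError, KeyError) as exc:
                log.error("subject %s day %s skipped: %s", subject_id, day, exc)
                continue
            rows.append(
                {"subject_id": subject_id, "group": groups[subject_id], "day": day, **rec}
            )
    if not rows:
        raise ValueError("no stack could be measured")
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
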