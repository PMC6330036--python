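"""Calibrated slice-stack and results-table I/O.

A study stack lives on disk as a directory of 16-bit single-channel TIFF
slices plus a ``stack.json`` sidecar holding the linear density calibration
(density = slope * pixel_value + intercept, mg/cm^3), the in-plane pixel
spacing, the inter-slice interval *d*, and inclusive per-vertebra slice
ranges.  Tabular results are plain RFC-4180 CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedStack",
    "read_stack",
    "write_stack",
    "RESULT_COLUMNS",
    "write_results_table",
    "read_results_table",
]

SIDECAR_NAME = "stack.json"

#: stable column order of the per-animal results table (the StudyTable)
RESULT_COLUMNS = (
    "subject_id",
    "group",
    "day",
    "bmd",
    "mineral_content",
    "volume",
    "cortical_thickness",
    "body_height",
    "body_width",
    "min_moment",
    "polar_moment",
)


@dataclass
class CalibratedStack:
    """Ordered per-slice density maps (mg/cm^3) with geometry metadata.

    Parameters
    ----------
    slices
        Array of shape ``(n_slices, rows, cols)``; every slice shares one
        shape.  Values are calibrated densities in mg/cm^3.
    pixel_spacing
        Isotropic in-plane spacing, cm/pixel.
    slice_interval_d
        Inter-slice interval *d*, cm (1 mm in the in-vivo protocol).
    vertebra_labels
        Mapping from vertebra name (e.g. ``"L2"``) to an inclusive
        ``(first_slice, last_slice)`` range.  Ranges must be disjoint and
        within bounds.
    """

    slices: np.ndarray
    pixel_spacing: float
    slice_interval_d: float
    vertebra_labels: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError(
                f"slices must be a (n, rows, cols) array, got ndim={self.slices.ndim}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.slice_interval_d <= 0:
            raise ValueError("slice_interval_d must be > 0")
        self.vertebra_labels = {
            str(k): (int(v[0]), int(v[1])) for k, v in self.vertebra_labels.items()
        }
        self._validate_labels()

    def _validate_labels(self) -> None:
        n = len(self.slices)
        for name, (first, last) in self.vertebra_labels.items():
            if not (0 <= first <= last < n):
                raise ValueError(
                    f"label {name}: slice range ({first}, {last}) outside stack of {n} slices"
                )
        ordered = sorted(self.vertebra_labels.items(), key=lambda kv: kv[1][0])
        for (name_a, (_, last_a)), (name_b, (first_b, _)) in zip(ordered, ordered[1:]):
            if first_b <= last_a:
                raise ValueError(f"{name_a}/{name_b} overlap in vertebra labels")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def labeled_slices(self, vertebrae=None) -> list[int]:
        """Sorted slice indices covered by the given vertebrae (default all)."""
        names = list(self.vertebra_labels) if vertebrae is None else list(vertebrae)
        out: list[int] = []
        for name in names:
            if name not in self.vertebra_labels:
                raise KeyError(f"vertebra {name!r} not labeled in stack")
            first, last = self.vertebra_labels[name]
            out.extend(range(first, last + 1))
        return sorted(out)


def write_stack(
    stack: CalibratedStack,
    path,
    *,
    density_slope: float = 0.05,
    density_intercept: float = -200.0,
) -> None:
    """Write a stack as 16-bit TIFF slices plus the JSON sidecar.

    Densities are quantized to ``round((density - intercept) / slope)`` and
    clipped to the uint16 range, so the round trip is exact to within one
    quantization step (``density_slope`` mg/cm^3).
    """
    if density_slope <= 0:
        raise ValueError("density_slope must be > 0")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(stack.slices):
        raw = np.clip(np.rint((sl - density_intercept) / density_slope), 0, 65535)
        tifffile.imwrite(path / f"slice_{i:03d}.tif", raw.astype(np.uint16))
    sidecar = {
        "pixel_spacing_cm": stack.pixel_spacing,
        "slice_interval_cm": stack.slice_interval_d,
        "density_slope": density_slope,
        "density_intercept": density_intercept,
        "vertebra_labels": [
            {"name": name, "first_slice": first, "last_slice": last}
            for name, (first, last) in stack.vertebra_labels.items()
        ],
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))


def read_stack(path) -> CalibratedStack:
    """Read a stack directory back into calibrated densities."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.is_file():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    slope = float(meta["density_slope"])
    intercept = float(meta["density_intercept"])
    files = sorted(path.glob("slice_*.tif"))
    if not files:
        raise FileNotFoundError(f"no slice_*.tif files in {path}")
    slices = []
    shape = None
    for f in files:
        raw = tifffile.imread(f)
        if shape is None:
            shape = raw.shape
        elif raw.shape != shape:
            raise ValueError(
                f"inconsistent slice dimensions in {f.name}: {raw.shape} vs {shape}"
            )
        slices.append(raw.astype(float) * slope + intercept)
    labels = {
        e["name"]: (int(e["first_slice"]), int(e["last_slice"]))
        for e in meta.get("vertebra_labels", [])
    }
    return CalibratedStack(
        slices=np.stack(slices),
        pixel_spacing=float(meta["pixel_spacing_cm"]),
        slice_interval_d=float(meta["slice_interval_cm"]),
        vertebra_labels=labels,
    )


def write_results_table(records: pd.DataFrame, path) -> None:
    """Write the per-animal morphometry table as CSV with stable column order.

    Rejects empty tables and duplicate (subject_id, day) rows.
    """
    if records is None or len(records) == 0:
        raise ValueError("results table is empty; refusing to write an empty file")
    missing = [c for c in RESULT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    dup = records.duplicated(subset=["subject_id", "day"])
    if dup.any():
        first = records.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (subject_id, day) row: ({first['subject_id']!r}, {first['day']!r})"
        )
    records.loc[:, list(RESULT_COLUMNS)].to_csv(path, index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results_table`."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table at {path} missing columns: {missing}")
    return df
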