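"""Cardiothoracic-ratio geometry from binary lung/heart segmentation masks.

The cardiothoracic ratio (CTR) on a frontal chest radiograph is

    CTR = (MLD + MRD) / GT

where MLD and MRD are the maximum horizontal distances from the body
midline to the left and right cardiac borders (patient orientation:
patient-left is image-right), and GT is the greatest transverse dimension
of the thoracic cavity.  This module computes those quantities from a pair
of binary rasters, one for the lung fields and one for the cardiac
silhouette.

Conventions
-----------
* rows run top to bottom, columns left to right, 0-based;
* widths are inclusive pixel counts (rightmost - leftmost + 1);
* the midline is derived from the lung-field horizontal extremes (the
  column ``floor((leftmost + rightmost) / 2)``), because a vertebral
  midline is not recoverable from lung/heart masks alone;
* MLD and MRD are per-row maxima and may come from different rows;
* every foreground component counts (a split lung field still contributes
  to the thoracic extent).

The ratio is dimensionless, so an optional isotropic pixel spacing never
changes it; lengths are reported in pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .errors import EmptyMaskError

__all__ = [
    "MaskPair",
    "CtrMeasurement",
    "estimate_midline",
    "max_horizontal_extent",
    "measure_case",
    "load_mask",
    "iter_mask_pairs",
    "measure_directory",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = ["case_id", "mld_px", "mrd_px", "gt_px", "ctr", "midline_col"]


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} mask must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} mask must be strictly binary (0/1), got values {uniq[:5]}")
    return arr.astype(bool)


@dataclass(frozen=True)
class MaskPair:
    """A lung mask and a heart mask on a shared pixel grid.

    Parameters
    ----------
    lung, heart
        Binary 2-D arrays of identical shape; any truthy pixel is
        foreground.  The lung mask may contain two (or more) connected
        components.
    pixel_spacing
        Optional isotropic physical size of one pixel.  Only carried as
        metadata: the CTR is spacing-invariant.
    """

    lung: np.ndarray
    heart: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        lung = _as_binary(self.lung, "lung")
        heart = _as_binary(self.heart, "heart")
        if lung.shape != heart.shape:
            raise ValueError(
                f"lung and heart masks must share a grid: {lung.shape} != {heart.shape}"
            )
        object.__setattr__(self, "lung", lung)
        object.__setattr__(self, "heart", heart)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lung.shape


@dataclass(frozen=True)
class CtrMeasurement:
    """MLD/MRD/GT/CTR for one case from one measurement source.

    ``ctr`` always equals ``(mld + mrd) / gt`` exactly; there is no upper
    clamp, so pathological masks may legitimately yield CTR > 1.
    """

    mld: int
    mrd: int
    gt: int
    ctr: float
    midline_col: int

    def __post_init__(self) -> None:
        if self.mld < 0 or self.mrd < 0:
            raise ValueError("MLD and MRD must be non-negative")
        if self.gt <= 0:
            raise ValueError("GT must be positive")
        if not math.isclose(self.ctr, (self.mld + self.mrd) / self.gt, rel_tol=0, abs_tol=0):
            raise ValueError("ctr must equal (mld + mrd) / gt exactly")


def _column_range(mask: np.ndarray) -> tuple[int, int]:
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise EmptyMaskError("empty-mask: no foreground pixels")
    return int(cols[0]), int(cols[-1])


def estimate_midline(masks: MaskPair) -> int:
    """Column index of the body midline, from the lung-field extremes.

    Returns ``floor((leftmost + rightmost) / 2)`` over the foreground
    columns of the lung mask, i.e. the midpoint rounded half toward the
    image left.
    """
    c_min, c_max = _column_range(masks.lung)
    return (c_min + c_max) // 2


def max_horizontal_extent(mask: np.ndarray) -> tuple[int, int]:
    """Maximum per-row horizontal width of a binary mask.

    Width in a row is ``rightmost - leftmost + 1`` over that row's
    foreground pixels.  Returns ``(max_width, row)`` where ``row`` is the
    topmost row attaining the maximum.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixels.
    """
    arr = _as_binary(np.asarray(mask), "input")
    any_row = arr.any(axis=1)
    if not any_row.any():
        raise EmptyMaskError("empty-mask: no foreground pixels")
    n_cols = arr.shape[1]
    left = arr.argmax(axis=1)
    right = n_cols - 1 - arr[:, ::-1].argmax(axis=1)
    widths = np.where(any_row, right - left + 1, 0)
    row = int(np.argmax(widths))  # argmax ties break to the topmost row
    return int(widths[row]), row


def measure_case(masks: MaskPair) -> CtrMeasurement:
    """Measure MLD, MRD, GT and CTR for one lung/heart mask pair.

    MRD is the maximum over rows of (midline - leftmost heart column) and
    MLD the maximum of (rightmost heart column - midline); both are clamped
    at zero, and they may come from different rows.  GT is taken from the
    global column range of the lung mask.

    A heart that lies outside the column range bracketed by the lungs is
    unusual but measurable; it triggers a warning, not an error.
    """
    midline = estimate_midline(masks)
    heart = masks.heart
    rows = heart.any(axis=1)
    if not rows.any():
        raise EmptyMaskError("empty-mask: heart mask has no foreground pixels")
    n_cols = heart.shape[1]
    left = heart.argmax(axis=1)[rows]
    right = (n_cols - 1 - heart[:, ::-1].argmax(axis=1))[rows]
    mrd = max(0, int((midline - left).max()))
    mld = max(0, int((right - midline).max()))

    lung_cmin, lung_cmax = _column_range(masks.lung)
    gt = lung_cmax - lung_cmin + 1
    h_cmin, h_cmax = _column_range(heart)
    if h_cmax < lung_cmin or h_cmin > lung_cmax:
        warnings.warn(
            "heart mask lies entirely outside the lung column range",
            stacklevel=2,
        )
    ctr = (mld + mrd) / gt
    return CtrMeasurement(mld=mld, mrd=mrd, gt=gt, ctr=ctr, midline_col=midline)


# ---------------------------------------------------------------------------
# File I/O: 8-bit grayscale PNG masks, foreground = any value > 0.
# ---------------------------------------------------------------------------

def load_mask(path: str | Path) -> np.ndarray:
    """Read a PNG mask; any pixel value > 0 is foreground."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr > 0


def iter_mask_pairs(directory: str | Path) -> Iterator[tuple[str, MaskPair]]:
    """Yield ``(case_id, MaskPair)`` for ``<case>_lung.png`` / ``<case>_heart.png`` files.

    Raises
    ------
    FileNotFoundError
        If a lung mask has no matching heart mask (the message names the case).
    """
    directory = Path(directory)
    lung_files = sorted(directory.glob("*_lung.png"))
    for lung_path in lung_files:
        case_id = lung_path.name[: -len("_lung.png")]
        heart_path = directory / f"{case_id}_heart.png"
        if not heart_path.exists():
            raise FileNotFoundError(f"missing heart mask for case '{case_id}': {heart_path}")
        yield case_id, MaskPair(lung=load_mask(lung_path), heart=load_mask(heart_path))


def measure_directory(directory: str | Path) -> pd.DataFrame:
    """Measure every mask pair found in ``directory``.

    Returns a frame with columns
    ``case_id, mld_px, mrd_px, gt_px, ctr, midline_col``.
    """
    records = []
    for case_id, pair in iter_mask_pairs(directory):
        m = measure_case(pair)
        records.append((case_id, m.mld, m.mrd, m.gt, m.ctr, m.midline_col))
    return pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
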