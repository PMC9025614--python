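"""Measurement of A, B and epidermal thickness from label images.

Replaces interactive on-screen measurement with a defined algorithm:

* **B** — horizontal scale length: distance between the centers of two
  adjacent hair-follicle column intervals, converted to µm.
* **A** — horizontal extent of the continuous granular layer: the
  longest contiguous run of columns containing granular-class pixels
  inside the scale window (a total-coverage ``sum`` mode exists for
  sensitivity analysis).
* **thickness** — viable-epidermis pixel count per sampled column
  (stratum corneum excluded), at equally spaced columns inside the
  window.

Coordinates are 0-based; column windows are half-open ``[left, right)``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import LabelImage, ScaleMeasurement, ScaleWindow, ValidationError

logger = logging.getLogger(__name__)


class NoScaleError(ValueError):
    """Raised when an image has fewer than two follicles (no measurable scale)."""


def longest_run(flags: Sequence[bool]) -> int:
    """Length of the longest contiguous block of True values (0 if none)."""
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        if cur > best:
            best = cur
    return best


def detect_follicles(image: LabelImage) -> list[tuple[int, int, int]]:
    """Maximal contiguous follicle column intervals, left to right.

    Returns ``(left, right, center)`` triples with half-open column
    intervals; the center is the interval midpoint, ties resolved
    downward.  Raises :class:`NoScaleError` with fewer than two
    intervals.
    """
    code = image.class_codes["follicle"]
    cols = np.flatnonzero((image.grid == code).any(axis=0))
    intervals: list[tuple[int, int, int]] = []
    if cols.size:
        breaks = np.flatnonzero(np.diff(cols) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [cols.size - 1]))
        for s, e in zip(starts, ends):
            left, last = int(cols[s]), int(cols[e])
            intervals.append((left, last + 1, (left + last) // 2))
    if len(intervals) < 2:
        raise NoScaleError(
            f"no scale: need >=2 follicles, found {len(intervals)}"
        )
    return intervals


def scale_windows(follicles: Sequence[tuple[int, int, int]]) -> list[ScaleWindow]:
    """One center-to-center window per adjacent follicle pair."""
    wins = []
    for (_, _, c1), (_, _, c2) in zip(follicles, follicles[1:]):
        wins.append(
            ScaleWindow(
                left_px=c1,
                right_px=c2,
                follicle_left_center_px=c1,
                follicle_right_center_px=c2,
            )
        )
    return wins


def measure_scale(
    image: LabelImage,
    window: ScaleWindow,
    measurements_per_scale: int = 5,
    run_mode: str = "longest",
    min_granular_px: int = 1,
    group: str = "image",
    animal: int = 0,
    scale: int = 0,
) -> ScaleMeasurement:
    """Measure A, B and the thickness readings of one scale window.

    A column counts toward the granular layer if it contains at least
    ``min_granular_px`` granular-class pixels.  ``run_mode='longest'``
    takes the longest contiguous run of such columns as A;
    ``run_mode='sum'`` takes their total count.  Thickness is sampled at
    ``measurements_per_scale`` columns at fractions 1/(m+1) ... m/(m+1)
    of the window; a sampled column without epidermis pixels is excluded
    and logged rather than reported as zero.
    """
    if run_mode not in ("longest", "sum"):
        raise ValidationError(f"run_mode must be 'longest' or 'sum', got {run_mode}")
    grid = image.grid
    if not (0 <= window.left_px < window.right_px <= grid.shape[1]):
        raise ValidationError("window out of image bounds")
    um = image.um_per_px

    b_px = window.follicle_right_center_px - window.follicle_left_center_px
    b_um = b_px * um

    gran = image.class_codes["granular"]
    sub = grid[:, window.left_px: window.right_px]
    flags = (sub == gran).sum(axis=0) >= min_granular_px
    a_px = longest_run(flags) if run_mode == "longest" else int(flags.sum())
    a_um = min(a_px * um, b_um)

    epi = image.class_codes["epidermis"]
    width = window.right_px - window.left_px
    m = int(measurements_per_scale)
    readings: list[float] = []
    for i in range(1, m + 1):
        col = window.left_px + int(np.floor(i / (m + 1) * width))
        t_px = int((grid[:, col] == epi).sum())
        if t_px == 0:
            logger.warning(
                "invalid thickness column %d (no epidermis pixels) in group=%s "
                "animal=%s scale=%s; excluded", col, group, animal, scale,
            )
            continue
        readings.append(t_px * um)
    if not readings:
        raise ValidationError("no valid thickness column in scale window")

    return ScaleMeasurement(
        group=group, animal=animal, scale=scale,
        A_um=a_um, B_um=b_um, thickness_um=tuple(readings),
    )


def measure_image(image: LabelImage, scale: int | None = None, **kwargs) -> list[ScaleMeasurement]:
    """Measure every scale (adjacent follicle pair) in one image.

    With a single scale per image, ``scale`` sets its id; multi-scale
    images number their scales 0, 1, ... left to right.
    """
    follicles = detect_follicles(image)
    windows = scale_windows(follicles)
    out = []
    for i, win in enumerate(windows):
        sid = scale if (scale is not None and len(windows) == 1) else i
        out.append(measure_scale(image, win, scale=sid, **kwargs))
    return out


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O and batch mode

def read_label_image(path) -> tuple[LabelImage, dict | None]:
    """Read a label TIFF and its ``.truth.json`` sidecar if present."""
    import tifffile

    path = Path(path)
    grid = tifffile.imread(path)
    sidecar = path.with_suffix(".truth.json")
    truth = json.loads(sidecar.read_text()) if sidecar.exists() else None
    um = truth.get("um_per_px") if truth else None
    if um is None:
        raise ValidationError(
            f"{path.name}: no um_per_px calibration (missing sidecar); pass it explicitly"
        )
    return LabelImage(grid=grid, um_per_px=float(um)), truth


def measure_directory(
    directory,
    um_per_px: float | None = None,
    run_mode: str = "longest",
    measurements_per_scale: int = 5,
) -> pd.DataFrame:
    """Measure every label TIFF in a directory into the standard table.

    Group/animal/scale labels come from the sidecar when present,
    otherwise from the file name.  ``um_per_px`` overrides the sidecar
    calibration.
    """
    from .synthetic import measurements_to_frame

    directory = Path(directory)
    paths = sorted(list(directory.glob("*.tif")) + list(directory.glob("*.tiff")))
    if not paths:
        raise FileNotFoundError(f"no images found in {directory}")
    records: list[ScaleMeasurement] = []
    for idx, path in enumerate(paths):
        import tifffile

        grid = tifffile.imread(path)
        sidecar = path.with_suffix(".truth.json")
        truth = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        um = um_per_px if um_per_px is not None else truth.get("um_per_px")
        if um is None:
            raise ValidationError(f"{path.name}: um_per_px not given and not in sidecar")
        image = LabelImage(grid=grid, um_per_px=float(um))
        records.extend(
            measure_image(
                image,
                run_mode=run_mode,
                measurements_per_scale=measurements_per_scale,
                group=str(truth.get("group", path.stem)),
                animal=int(truth.get("animal", 0)),
                scale=int(truth.get("scale", idx)),
            )
        )
        logger.info("measured %s: %d scale(s)", path.name, 1)
    return measurements_to_frame(records)
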