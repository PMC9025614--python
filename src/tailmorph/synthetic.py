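"""Synthetic per-scale measurements and labeled pseudo-histology images.

Emulates the mouse-tail study design: 7 treatment groups, 6 animals per
group, 10 scales per animal and 5 epidermal-thickness readings per scale,
with group means/SDs set to the study's reported values.  Per-scale
orthokeratosis degrees and thickness readings are drawn from a normal
model whose variance is split between an animal-level random effect and a
scale-level residual by ``animal_icc``, then truncated to the parameter's
valid range.

Reproducibility: one master seed; every (group, animal, scale) gets its
own substream derived by stable hashing, so regenerating any subset of
the design reproduces the same numbers.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CLASS_CODES, GroupSpec, LabelImage, ScaleMeasurement, ValidationError

# Group parameterization of the seven study arms, in table order:
# (name, ok_mean %, ok_sd %, thick_mean µm, thick_sd µm)
DEFAULT_GROUP_PARAMS: tuple[tuple[str, float, float, float, float], ...] = (
    ("untreated", 17.7, 1.81, 24.77, 2.43),
    ("white soft paraffin", 19.64, 3.2, 29.76, 2.02),
    ("tretinoin 0.05%", 48.72, 6.09, 33.22, 2.61),
    ("diclofenac 1%", 42.24, 13.73, 28.42, 2.62),
    ("diclofenac 2%", 41.42, 8.17, 27.38, 2.75),
    ("celecoxib 1%", 42.15, 7.28, 28.07, 2.37),
    ("celecoxib 2%", 56.48, 11.33, 32.28, 6.18),
)

#: Default scale-length (B) model: normal(500, 50) µm truncated at 100 µm.
B_MEAN_UM = 500.0
B_SD_UM = 50.0
B_MIN_UM = 100.0

#: Strictly-positive floor applied when truncating thickness draws.
_POSITIVE_FLOOR = 1e-6


def default_study_specs(animal_icc: float = 0.3) -> list[GroupSpec]:
    """The seven study arms at their reported means/SDs, in table order.

    Each spec carries the default design counts (6 animals x 10 scales x
    5 readings -> 60 scales and 300 thickness measurements per group).
    """
    return [
        GroupSpec(name=name, ok_mean=om, ok_sd=osd, thick_mean=tm, thick_sd=tsd,
                  animal_icc=animal_icc)
        for name, om, osd, tm, tsd in DEFAULT_GROUP_PARAMS
    ]


def _substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic RNG substream keyed by (seed, *keys) via sha256."""
    tag = "|".join(str(k) for k in keys).encode()
    digest = int.from_bytes(hashlib.sha256(tag).digest()[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), digest]))


def generate_measurements(
    spec: GroupSpec,
    seed: int,
    b_mean_um: float = B_MEAN_UM,
    b_sd_um: float = B_SD_UM,
    b_min_um: float = B_MIN_UM,
) -> list[ScaleMeasurement]:
    """Draw one group's per-scale measurements from its GroupSpec.

    The per-scale orthokeratosis degree is ``ok_mean + animal effect +
    scale residual`` with the two components' SDs set by ``animal_icc``,
    truncated to [0, 100]; A is then ``degree/100 x B`` with B drawn from
    a truncated normal.  Thickness readings are drawn analogously from
    ``(thick_mean, thick_sd)`` and truncated positive.  Deterministic
    given (spec, seed).
    """
    if b_mean_um <= 0 or b_min_um <= 0:
        raise ValidationError("scale-length parameters must be positive")
    sd_animal_ok = spec.ok_sd * np.sqrt(spec.animal_icc)
    sd_scale_ok = spec.ok_sd * np.sqrt(1.0 - spec.animal_icc)
    sd_animal_t = spec.thick_sd * np.sqrt(spec.animal_icc)
    sd_scale_t = spec.thick_sd * np.sqrt(1.0 - spec.animal_icc)

    out: list[ScaleMeasurement] = []
    for animal in range(1, spec.n_animals + 1):
        rng_a = _substream(seed, spec.name, "animal", animal)
        eff_ok = rng_a.normal(0.0, sd_animal_ok) if sd_animal_ok > 0 else 0.0
        eff_t = rng_a.normal(0.0, sd_animal_t) if sd_animal_t > 0 else 0.0
        for scale in range(1, spec.scales_per_animal + 1):
            rng_s = _substream(seed, spec.name, "scale", animal, scale)
            degree = spec.ok_mean + eff_ok + (
                rng_s.normal(0.0, sd_scale_ok) if sd_scale_ok > 0 else 0.0
            )
            degree = float(np.clip(degree, 0.0, 100.0))
            b_um = float(max(rng_s.normal(b_mean_um, b_sd_um), b_min_um))
            a_um = degree / 100.0 * b_um
            resid = (
                rng_s.normal(0.0, sd_scale_t, size=spec.measurements_per_scale)
                if sd_scale_t > 0
                else np.zeros(spec.measurements_per_scale)
            )
            thick = np.maximum(spec.thick_mean + eff_t + resid, _POSITIVE_FLOOR)
            out.append(
                ScaleMeasurement(
                    group=spec.name,
                    animal=animal,
                    scale=scale,
                    A_um=a_um,
                    B_um=b_um,
                    thickness_um=tuple(float(t) for t in thick),
                )
            )
    return out


def generate_study(specs: Sequence[GroupSpec], seed: int, **kwargs) -> pd.DataFrame:
    """Generate measurements for every group and return the wide table."""
    records: list[ScaleMeasurement] = []
    for spec in specs:
        records.extend(generate_measurements(spec, seed, **kwargs))
    return measurements_to_frame(records)


# ---------------------------------------------------------------------------
# measurement table I/O

def measurements_to_frame(records: Sequence[ScaleMeasurement]) -> pd.DataFrame:
    """Wide table: group, animal, scale, A_um, B_um, t1_um, t2_um, ..."""
    if not records:
        raise ValidationError("no measurements to tabulate")
    m = len(records[0].thickness_um)
    if any(len(r.thickness_um) != m for r in records):
        raise ValidationError("all records must carry the same number of readings")
    rows = []
    for r in records:
        row = {"group": r.group, "animal": r.animal, "scale": r.scale,
               "A_um": r.A_um, "B_um": r.B_um}
        for i, t in enumerate(r.thickness_um, start=1):
            row[f"t{i}_um"] = t
        rows.append(row)
    return pd.DataFrame(rows)


def thickness_columns(frame: pd.DataFrame) -> list[str]:
    """The tN_um columns of a measurement table, in reading order."""
    cols = [c for c in frame.columns if c.startswith("t") and c.endswith("_um")]
    return sorted(cols, key=lambda c: int(c[1:-3]))


def frame_to_measurements(frame: pd.DataFrame) -> list[ScaleMeasurement]:
    """Inverse of :func:`measurements_to_frame` (validates every record)."""
    tcols = thickness_columns(frame)
    return [
        ScaleMeasurement(
            group=str(row["group"]),
            animal=int(row["animal"]),
            scale=int(row["scale"]),
            A_um=float(row["A_um"]),
            B_um=float(row["B_um"]),
            thickness_um=tuple(float(row[c]) for c in tcols),
        )
        for _, row in frame.iterrows()
    ]


def write_measurements_csv(frame: pd.DataFrame, path) -> None:
    """Write the standard measurement CSV with a fixed float format.

    The fixed format makes output byte-identical across runs and
    platforms for identical inputs.
    """
    frame.to_csv(path, index=False, float_format="%.6f")


def read_measurements_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"group", "animal", "scale", "A_um", "B_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"measurement CSV lacks columns: {sorted(missing)}")
    return frame


def frame_to_csv_text(frame: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_measurements_csv(frame, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# labeled pseudo-histology images

def generate_label_image(
    B_um: float,
    degree: float,
    thickness_um: Sequence[float],
    um_per_px: float,
    seed: int,
    *,
    follicle_width_px: int = 5,
    granular_px: int = 2,
    corneum_px: int = 4,
    margin_px: int = 5,
    height_px: int | None = None,
    width_px: int | None = None,
) -> tuple[LabelImage, dict]:
    """Rasterize one scale as a labeled image plus its ground truth.

    Left to right: two follicle columns bounding one scale; between them
    an epidermis band following the requested thickness profile, a
    stratum-corneum band above, and a single contiguous granular-layer
    run whose horizontal extent is ``degree/100 x B``, placed at a random
    offset within the follicle-center-to-center interval.

    Returns the image and a ground-truth record (the exact generated A,
    B, degree and thickness values) suitable for the ``.truth.json``
    sidecar.
    """
    if um_per_px <= 0:
        raise ValidationError("um_per_px must be > 0")
    if not 0.0 <= degree <= 100.0:
        raise ValidationError(f"degree must be in [0, 100], got {degree}")
    if B_um <= 0:
        raise ValidationError("B_um must be > 0")
    if not thickness_um or any(t <= 0 for t in thickness_um):
        raise ValidationError("thickness profile must be non-empty and positive")

    b_px = int(round(B_um / um_per_px))
    fw = int(follicle_width_px)
    if b_px <= fw + len(thickness_um):
        raise ValidationError("scale too short for the requested geometry")
    t_px = [max(1, int(round(t / um_per_px))) for t in thickness_um]
    tmax = max(t_px)
    stack = tmax + granular_px + corneum_px

    need_h = stack + 2 * margin_px
    # left follicle occupies [margin, margin+fw); its center is at margin + (fw-1)//2
    cl = margin_px + (fw - 1) // 2
    cr = cl + b_px
    need_w = cr + (fw - (fw - 1) // 2) + margin_px
    H = need_h if height_px is None else int(height_px)
    W = need_w if width_px is None else int(width_px)
    if H < need_h or W < need_w:
        raise ValidationError(
            f"geometry needs at least {need_h}x{need_w} px, got {H}x{W}"
        )

    grid = np.zeros((H, W), dtype=np.uint8)
    base = H - margin_px  # dermo-epidermal junction row (exclusive bottom of epidermis)
    win_l = margin_px + fw          # inner edge of left follicle
    win_r = cr - (fw - 1) // 2      # left edge of right follicle

    # epidermis band: the inter-follicular window split into len(profile)
    # equal horizontal segments, each of constant thickness
    n_seg = len(t_px)
    seg_edges = [win_l + round(i * (win_r - win_l) / n_seg) for i in range(n_seg + 1)]
    for i in range(n_seg):
        grid[base - t_px[i]: base, seg_edges[i]: seg_edges[i + 1]] = CLASS_CODES["epidermis"]

    # stratum corneum: fixed band above the granular slot
    sc_top = base - tmax - granular_px - corneum_px
    grid[sc_top: sc_top + corneum_px, win_l: win_r] = CLASS_CODES["stratum_corneum"]

    # follicles: full-depth columns at both ends of the scale
    grid[base - stack: base, margin_px: margin_px + fw] = CLASS_CODES["follicle"]
    grid[base - stack: base, cr - (fw - 1) // 2: cr - (fw - 1) // 2 + fw] = CLASS_CODES["follicle"]

    # granular layer: one contiguous run inside [cl, cr), random offset
    a_px = int(round(degree / 100.0 * b_px))
    rng = _substream(seed, "granular_offset", round(B_um, 6), round(degree, 6))
    offset = int(rng.integers(0, b_px - a_px + 1)) if a_px < b_px else 0
    if a_px > 0:
        grid[base - tmax - granular_px: base - tmax, cl + offset: cl + offset + a_px] = (
            CLASS_CODES["granular"]
        )

    image = LabelImage(grid=grid, um_per_px=float(um_per_px))
    truth = {
        "A_um": degree / 100.0 * B_um,
        "B_um": float(B_um),
        "degree": float(degree),
        "thickness_um": [float(t) for t in thickness_um],
        "um_per_px": float(um_per_px),
        "follicle_centers_px": [cl, cr],
        "granular_run_px": [cl + offset, cl + offset + a_px],
    }
    return image, truth


def write_label_image(image: LabelImage, truth: dict, path) -> None:
    """Write a single-channel TIFF plus its ``.truth.json`` sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.grid.astype(np.uint8))
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=1, sort_keys=True))
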