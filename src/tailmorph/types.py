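"""Core value objects shared across the pipeline.

All lengths are in micrometers (µm) unless a name says otherwise
(``*_px`` fields are pixel counts / column indices).  Validation lives in
``__post_init__`` so that an instance, once constructed, satisfies its
invariants everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Integer class codes used in label images.  0 doubles as dermis and
#: background; only the classes named here are ever written or read.
CLASS_CODES: Mapping[str, int] = {
    "background": 0,
    "epidermis": 1,
    "granular": 2,
    "stratum_corneum": 3,
    "follicle": 4,
}


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class GroupSpec:
    """Distributional parameters and design counts for one treatment group.

    Parameters
    ----------
    name
        Group label (one of the seven study arms, or user-defined).
    ok_mean, ok_sd
        Mean and SD of the per-scale orthokeratosis degree, in percent.
    thick_mean, thick_sd
        Mean and SD of single epidermal-thickness readings, in µm.
    n_animals, scales_per_animal, measurements_per_scale
        Design counts; defaults reproduce the study design of 6 animals,
        10 scales each, 5 thickness readings per scale.
    animal_icc
        Fraction of the total variance attributed to animal-level effects,
        in [0, 1).  Splits the reported group-level SD into an animal
        component and a residual scale component.
    """

    name: str
    ok_mean: float
    ok_sd: float
    thick_mean: float
    thick_sd: float
    n_animals: int = 6
    scales_per_animal: int = 10
    measurements_per_scale: int = 5
    animal_icc: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.ok_mean <= 100.0:
            raise ValidationError(f"ok_mean must be in [0, 100], got {self.ok_mean}")
        if self.ok_sd < 0:
            raise ValidationError(f"ok_sd must be >= 0, got {self.ok_sd}")
        if self.thick_mean <= 0:
            raise ValidationError(f"thick_mean must be > 0, got {self.thick_mean}")
        if self.thick_sd < 0:
            raise ValidationError(f"thick_sd must be >= 0, got {self.thick_sd}")
        for attr in ("n_animals", "scales_per_animal", "measurements_per_scale"):
            if int(getattr(self, attr)) <= 0:
                raise ValidationError(f"{attr} must be a positive count")
        if not 0.0 <= self.animal_icc < 1.0:
            raise ValidationError(
                f"animal_icc must be in [0, 1), got {self.animal_icc}"
            )

    @property
    def n_scales(self) -> int:
        """Scales per group (default 60)."""
        return self.n_animals * self.scales_per_animal

    @property
    def n_thickness(self) -> int:
        """Thickness readings per group (default 300)."""
        return self.n_scales * self.measurements_per_scale


@dataclass(frozen=True)
class ScaleMeasurement:
    """Primary measurements of one tail scale.

    ``A_um`` is the horizontal length of the continuous granular layer,
    ``B_um`` the horizontal scale length between the two bounding
    follicles, and ``thickness_um`` the individual viable-epidermis
    thickness readings taken inside the scale (stratum corneum excluded).
    """

    group: str
    animal: int
    scale: int
    A_um: float
    B_um: float
    thickness_um: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "thickness_um", tuple(float(t) for t in self.thickness_um))
        if self.B_um <= 0:
            raise ValidationError(f"B_um must be > 0, got {self.B_um}")
        if not 0.0 <= self.A_um <= self.B_um:
            raise ValidationError(
                f"A_um must satisfy 0 <= A <= B, got A={self.A_um}, B={self.B_um}"
            )
        if len(self.thickness_um) < 1:
            raise ValidationError("at least one thickness reading is required")
        if any(t <= 0 for t in self.thickness_um):
            raise ValidationError("all thickness readings must be > 0")

    @property
    def degree(self) -> float:
        """Orthokeratosis degree of this scale, percent."""
        # A <= B is guaranteed; the min guards the A == B case against
        # floating-point round-up past 100
        return min(100.0 * self.A_um / self.B_um, 100.0)


@dataclass
class LabelImage:
    """2D integer class map with isotropic µm-per-pixel calibration.

    Rows are the vertical (depth) axis, columns run horizontally along
    the tail.
    """

    grid: np.ndarray
    um_per_px: float
    class_codes: Mapping[str, int] = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValidationError("label grid must be 2D")
        if self.um_per_px <= 0:
            raise ValidationError(f"um_per_px must be > 0, got {self.um_per_px}")
        allowed = set(int(v) for v in self.class_codes.values())
        present = set(int(v) for v in np.unique(self.grid))
        if not present <= allowed:
            raise ValidationError(f"grid contains unknown class codes: {present - allowed}")


@dataclass(frozen=True)
class ScaleWindow:
    """Column interval [left_px, right_px) bounding one scale.

    The window spans the centers of the two bounding follicles; the
    follicle-center columns define the scale length B.
    """

    left_px: int
    right_px: int
    follicle_left_center_px: int
    follicle_right_center_px: int

    def __post_init__(self) -> None:
        if not self.left_px < self.right_px:
            raise ValidationError("window must satisfy left_px < right_px")
        if not (
            self.follicle_left_center_px <= self.left_px
            and self.right_px <= self.follicle_right_center_px + 1
        ):
            raise ValidationError("window must lie between the two follicle centers")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary: orthokeratosis degree, thickness, drug activity.

    ``drug_activity`` is ``None`` for groups excluded from the
    normalization (e.g. the untreated arm) and exactly 0 for the control
    group itself.
    """

    group: str
    ok_mean: float
    ok_sd: float
    thick_mean: float
    thick_sd: float
    drug_activity: float | None
    n_scales: int
    n_thickness: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ok_mean <= 100.0:
            raise ValidationError("ok_mean must be in [0, 100]")
        if self.n_scales <= 0:
            raise ValidationError("n_scales must be > 0")


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of pairwise p-values with significance flags.

    ``flags[i, j]`` is ``"S"`` iff ``p[i, j] <= alpha``, ``"N"``
    otherwise; the diagonal is NaN / blank.
    """

    labels: list[str]
    p: np.ndarray
    flags: np.ndarray
    alpha: float
    endpoint: str
    unit: str

    def to_long_frame(self):
        """Long-format table with one row per unordered group pair."""
        import pandas as pd

        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "group_a": self.labels[i],
                        "group_b": self.labels[j],
                        "p": self.p[i, j],
                        "flag": self.flags[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        """Render the matrix with S/N verdicts and 3-decimal p-values."""
        header = "| Groups | " + " | ".join(self.labels) + " |"
        sep = "|" + " --- |" * (len(self.labels) + 1)
        lines = [header, sep]
        for i, lab in enumerate(self.labels):
            cells = []
            for j in range(len(self.labels)):
                if i == j:
                    cells.append("")
                else:
                    cells.append(f"{self.flags[i, j]} ({self.p[i, j]:.3f})")
            lines.append("| " + lab + " | " + " | ".join(cells) + " |")
        lines.append("")
        lines.append(
            f"S = statistically significant; N = non-significant; p <= {self.alpha:g}."
        )
        return "\n".join(lines)


@dataclass
class RunConfig:
    """Configuration for one end-to-end pipeline run.

    Exactly one input source must be set: ``specs`` (simulate),
    ``measurements_csv`` (pre-measured table) or ``image_dir``
    (label images to be measured).
    """

    specs: Sequence[GroupSpec] | None = None
    measurements_csv: str | None = None
    image_dir: str | None = None
    control_group: str = "white soft paraffin"
    activity_excluded: tuple[str, ...] = ("untreated",)
    seed: int = 0
    unit: str = "animal"
    alpha: float = 0.05
    output_dir: str = "tailmorph_out"
    um_per_px: float | None = None
    run_mode: str = "longest"

    def __post_init__(self) -> None:
        sources = [self.specs is not None, self.measurements_csv is not None, self.image_dir is not None]
        if sum(sources) != 1:
            raise ValidationError(
                "exactly one of specs, measurements_csv, image_dir must be set"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.run_mode not in ("longest", "sum"):
            raise ValidationError(f"run_mode must be 'longest' or 'sum', got {self.run_mode}")
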