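"""Derived parameters: orthokeratosis degree, thickness, drug activity.

The orthokeratosis degree of a scale is ``100 x A/B`` where A is the
horizontal extent of the continuous granular layer and B the scale
length.  Percentual drug activity normalizes a test group's mean degree
(Oks) against the vehicle-control group's mean (Okc):

    activity = (Oks - Okc) / (100 - Okc) x 100

It is 0 for the control itself, 100 at complete orthokeratosis, and may
be negative for a compound performing worse than the vehicle (reported
as computed, never clipped).

Standard deviations use the sample convention (n - 1 denominator);
reports round half-away-from-zero to 2 decimals, internal values keep
full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import thickness_columns
from .types import GroupSummary, ValidationError


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def orthokeratosis_degree(A_um: float, B_um: float) -> float:
    """Per-scale orthokeratosis degree, percent: 100 x A/B."""
    if B_um <= 0:
        raise ValidationError(f"B_um must be > 0, got {B_um}")
    if not 0.0 <= A_um <= B_um:
        raise ValidationError(f"need 0 <= A <= B, got A={A_um}, B={B_um}")
    return min(100.0 * A_um / B_um, 100.0)


def mean_epidermal_thickness(values: Sequence[float]) -> float:
    """Arithmetic mean of thickness readings, µm."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("mean thickness of zero readings is undefined")
    return float(values.mean())


def drug_activity(oks: float, okc: float) -> float:
    """Percentual drug activity: (Oks - Okc) / (100 - Okc) x 100."""
    if not 0.0 <= oks <= 100.0:
        raise ValidationError(f"Oks must be in [0, 100], got {oks}")
    if not 0.0 <= okc < 100.0:
        raise ValidationError(f"Okc must be in [0, 100), got {okc}")
    return (oks - okc) / (100.0 - okc) * 100.0


def _degrees(frame: pd.DataFrame) -> pd.Series:
    # min() guards A == B against floating-point round-up past 100
    return (100.0 * frame["A_um"] / frame["B_um"]).clip(upper=100.0)


def summarize_groups(
    frame: pd.DataFrame,
    control_group: str,
    activity_excluded: Iterable[str] = (),
    thickness_unit: str = "reading",
    sd_unit: str = "scale",
) -> list[GroupSummary]:
    """Per-group mean +/- SD of degree and thickness, plus drug activity.

    Parameters
    ----------
    frame
        Standard measurement table (group, animal, scale, A_um, B_um,
        t1_um...).
    control_group
        Label of the vehicle-control group; drug activity normalizes
        against its mean degree and is exactly 0 for the control itself.
    activity_excluded
        Groups reported without a drug activity (e.g. the untreated arm).
    thickness_unit
        ``"reading"`` pools all individual readings per group (default);
        ``"animal"`` averages per-animal means.
    sd_unit
        ``"scale"`` computes the degree SD over scales (default);
        ``"animal"`` over per-animal mean degrees.

    Groups are reported in first-appearance order; summaries are
    invariant to record order otherwise.
    """
    if thickness_unit not in ("reading", "animal"):
        raise ValidationError(f"unknown thickness_unit {thickness_unit!r}")
    if sd_unit not in ("scale", "animal"):
        raise ValidationError(f"unknown sd_unit {sd_unit!r}")
    groups = list(dict.fromkeys(frame["group"]))
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} not in table")
    excluded = set(activity_excluded)
    tcols = thickness_columns(frame)
    if not tcols:
        raise ValidationError("measurement table has no thickness columns")

    work = frame.copy()
    work["degree"] = _degrees(work)
    bad = (work["degree"] < 0) | (work["degree"] > 100) | (work["B_um"] <= 0)
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} record(s) violate 0 <= A <= B")

    def group_stats(g: pd.DataFrame) -> tuple[float, float, float, float, int, int]:
        if sd_unit == "scale":
            ok = g["degree"]
        else:
            ok = g.groupby("animal")["degree"].mean()
        readings = g[tcols].to_numpy(dtype=float).ravel()
        readings = readings[~np.isnan(readings)]
        if thickness_unit == "reading":
            th = pd.Series(readings)
        else:
            th = g.melt(id_vars=["animal"], value_vars=tcols, value_name="t").groupby(
                "animal"
            )["t"].mean()
        return (
            float(g["degree"].mean()),
            float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
            float(th.mean()),
            float(th.std(ddof=1)) if len(th) > 1 else 0.0,
            len(g),
            readings.size,
        )

    stats = {name: group_stats(frame_g) for name, frame_g in work.groupby("group", sort=False)}
    for name, (_, _, _, _, n_scales, _) in stats.items():
        if n_scales == 0:
            raise ValidationError(f"group {name!r} is empty")
    okc = stats[control_group][0]

    out = []
    for name in groups:
        ok_mean, ok_sd, th_mean, th_sd, n_scales, n_th = stats[name]
        if name in excluded:
            act = None
        elif name == control_group:
            act = 0.0
        else:
            act = drug_activity(ok_mean, okc)
        out.append(
            GroupSummary(
                group=name, ok_mean=ok_mean, ok_sd=ok_sd,
                thick_mean=th_mean, thick_sd=th_sd,
                drug_activity=act, n_scales=n_scales, n_thickness=n_th,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Tabular form with the standard summary columns."""
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "ok_mean": s.ok_mean,
                "ok_sd": s.ok_sd,
                "thick_mean": s.thick_mean,
                "thick_sd": s.thick_sd,
                "drug_activity": np.nan if s.drug_activity is None else s.drug_activity,
                "n_scales": s.n_scales,
                "n_thickness": s.n_thickness,
            }
            for s in summaries
        ]
    )


def summaries_to_markdown(summaries: Sequence[GroupSummary]) -> str:
    """Render a mean +/- SD report table (2-decimal rounding)."""
    lines = [
        "| Group | Orthokeratosis degree (%) | Mean epidermal thickness (µm) | Percentual drug activity (%) |",
        "| --- | --- | --- | --- |",
    ]
    for s in summaries:
        act = "" if s.drug_activity is None else f"{round_half_away(s.drug_activity):.2f}"
        lines.append(
            f"| {s.group} | {round_half_away(s.ok_mean):.2f} ± {round_half_away(s.ok_sd):.2f}"
            f" | {round_half_away(s.thick_mean):.2f} ± {round_half_away(s.thick_sd):.2f}"
            f" | {act} |"
        )
    return "\n".join(lines)
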