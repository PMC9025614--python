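"""Pipeline orchestration: generate/measure -> score -> stats -> report.

``run_pipeline`` executes the applicable stages for a :class:`RunConfig`
and writes, under ``output_dir``:

* ``measurements.csv`` — the standard per-scale table,
* ``summary.csv`` and ``summary.md`` — group summaries (mean ± SD,
  drug activity),
* ``pairwise_orthokeratosis.csv`` / ``pairwise_thickness.csv`` plus
  rendered ``.md`` matrices,
* ``fig_orthokeratosis.png``, ``fig_drug_activity.png``,
  ``fig_thickness.png`` — bar charts with SD error bars,
* ``manifest.json`` — config, seed, package version and per-stage row
  counts.

Re-running with the same config reproduces identical CSV bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .morphometry import measure_directory
from .scoring import round_half_away, summaries_to_frame, summaries_to_markdown, summarize_groups
from .stats import pairwise_comparisons
from .synthetic import generate_study, read_measurements_csv, write_measurements_csv
from .types import GroupSummary, RunConfig, ValidationError

logger = logging.getLogger(__name__)

_RANK_FIELDS = {"ok_mean", "thick_mean", "drug_activity"}


def rank_groups(summaries: Sequence[GroupSummary], by: str = "ok_mean") -> list[str]:
    """Group labels in descending order of the chosen parameter.

    Groups without a value for the parameter (e.g. no drug activity)
    sort last; ties break by label for determinism.
    """
    if by not in _RANK_FIELDS:
        raise ValidationError(f"unknown ranking parameter {by!r}")
    if not summaries:
        raise ValidationError("empty summary")

    def key(s: GroupSummary):
        v = getattr(s, by)
        return (v is None, -(v if v is not None else 0.0), s.group)

    return [s.group for s in sorted(summaries, key=key)]


def _bar_chart(path: Path, labels, values, errors, ylabel: str, title: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(len(labels)), values, yerr=errors, capsize=4, color="#4878a8")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_figures(summaries: Sequence[GroupSummary], outdir: Path) -> list[Path]:
    """Bar charts of degree, drug activity and thickness (SD error bars)."""
    labels = [s.group for s in summaries]
    paths = []
    p = outdir / "fig_orthokeratosis.png"
    _bar_chart(p, labels, [s.ok_mean for s in summaries], [s.ok_sd for s in summaries],
               "Orthokeratosis degree (%)", "Orthokeratosis degree")
    paths.append(p)
    act = [(s.group, s.drug_activity) for s in summaries if s.drug_activity is not None]
    p = outdir / "fig_drug_activity.png"
    _bar_chart(p, [a for a, _ in act], [v for _, v in act], None,
               "Percentual drug activity (%)", "Percentual drug activity")
    paths.append(p)
    p = outdir / "fig_thickness.png"
    _bar_chart(p, labels, [s.thick_mean for s in summaries], [s.thick_sd for s in summaries],
               "Mean epidermal thickness (µm)", "Mean epidermal thickness")
    paths.append(p)
    return paths


def _config_to_jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.specs is not None:
        d["specs"] = [dataclasses.asdict(s) for s in config.specs]
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run all applicable stages and return the manifest dictionary.

    Stage failures propagate with the failing stage named; outputs from
    a failed run are removed so no partial result can be mistaken for a
    complete one.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "input"
    try:
        if config.specs is not None:
            frame = generate_study(config.specs, config.seed)
        elif config.measurements_csv is not None:
            frame = read_measurements_csv(config.measurements_csv)
        else:
            frame = measure_directory(config.image_dir, um_per_px=config.um_per_px,
                                      run_mode=config.run_mode)
        logger.info("stage=input rows=%d groups=%d", len(frame), frame["group"].nunique())
        mpath = outdir / "measurements.csv"
        write_measurements_csv(frame, mpath)
        written.append(mpath)

        stage = "score"
        summaries = summarize_groups(
            frame, control_group=config.control_group,
            activity_excluded=config.activity_excluded,
        )
        sframe = summaries_to_frame(summaries)
        spath = outdir / "summary.csv"
        sframe.to_csv(spath, index=False, float_format="%.6f")
        (outdir / "summary.md").write_text(summaries_to_markdown(summaries) + "\n")
        written += [spath, outdir / "summary.md"]
        logger.info("stage=score groups=%d", len(summaries))

        stage = "stats"
        counts = {}
        for endpoint in ("orthokeratosis", "thickness"):
            matrix = pairwise_comparisons(
                frame, endpoint=endpoint, unit=config.unit, alpha=config.alpha,
                seed=config.seed,
            )
            long = matrix.to_long_frame()
            ppath = outdir / f"pairwise_{endpoint}.csv"
            long.to_csv(ppath, index=False, float_format="%.6f")
            (outdir / f"pairwise_{endpoint}.md").write_text(matrix.to_markdown() + "\n")
            written += [ppath, outdir / f"pairwise_{endpoint}.md"]
            counts[endpoint] = len(long)
            logger.info("stage=stats endpoint=%s pairs=%d", endpoint, len(long))

        stage = "figures"
        written += make_figures(summaries, outdir)

        stage = "manifest"
        manifest = {
            "config": _config_to_jsonable(config),
            "seed": config.seed,
            "version": __version__,
            "stages": {
                "input_rows": len(frame),
                "groups": int(frame["group"].nunique()),
                "pairwise": counts,
            },
            "ranking_by_ok_mean": rank_groups(summaries, "ok_mean"),
            "outputs": [p.name for p in written],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
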