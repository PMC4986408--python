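"""End-to-end orchestration: simulate -> segment -> texture -> ANOVA -> report.

A run is fully determined by a cohort configuration and a master seed:
per-subject seeds are derived from the master seed by a counter-based
scheme, so outputs are byte-identical across reruns and adding subjects
never perturbs earlier ones.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import group_summary, one_way_anova
from .phantom import CohortSpec, default_cohort_spec, iter_cohort
from .segmentation import bilateral_average, fibrous_muscle_ratio, segment_image
from .texture import UndefinedCorrelationError, texture_profile

logger = logging.getLogger("fibroquant")


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    cohort: CohortSpec = field(default_factory=default_cohort_spec)
    master_seed: int = 0
    out_dir: Path = Path("fibroquant_run")
    levels: int = 64
    glcm_distance: int = 1
    compute_texture: bool = True
    write_images: bool = False
    image_format: str = "tiff"
    log_level: str = "INFO"


def analyze_cohort(
    spec: CohortSpec,
    seed: int,
    groups: Sequence[str] | None = None,
    compartments: Sequence[str] | None = None,
    levels: int = 64,
    glcm_distance: int = 1,
    compute_texture: bool = False,
    collect_warnings: list[str] | None = None,
) -> pd.DataFrame:
    """Generate phantoms and run the measurement pipeline on each subject.

    Returns one row per subject and compartment with left/right and
    bilateral-averaged fibrous-to-muscle ratios, the planted ground truth,
    and (optionally) bilaterally averaged texture features.
    """
    rows = []
    for subj in iter_cohort(spec, seed=seed, groups=groups, compartments=compartments):
        side_ratio = {}
        side_feats = {}
        for side, out in (("left", subj.left), ("right", subj.right)):
            roi = spec.phantom.roi_mask()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mask, _ = segment_image(out.image, roi=roi, levels=levels)
            for w in caught:
                msg = (
                    f"{subj.subject_id}/{subj.compartment}/{side}: "
                    f"{w.category.__name__}: {w.message}"
                )
                logger.warning(msg)
                if collect_warnings is not None:
                    collect_warnings.append(msg)
            side_ratio[side] = fibrous_muscle_ratio(mask)
            if compute_texture:
                try:
                    side_feats[side] = texture_profile(
                        out.image, roi=roi, levels=levels, distance=glcm_distance
                    )
                except UndefinedCorrelationError:
                    side_feats[side] = None
        row = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "compartment": subj.compartment,
            "ratio_left": side_ratio["left"],
            "ratio_right": side_ratio["right"],
            "ratio": bilateral_average(side_ratio["left"], side_ratio["right"]),
            "planted_left": subj.planted_left,
            "planted_right": subj.planted_right,
            "planted": subj.planted_bilateral,
            "true_left": subj.left.true_ratio,
            "true_right": subj.right.true_ratio,
        }
        if compute_texture:
            fl, fr = side_feats["left"], side_feats["right"]
            if fl is None or fr is None:
                row.update(correlation=np.nan, entropy_bits=np.nan, asm=np.nan)
            else:
                row.update(
                    correlation=bilateral_average(fl.correlation, fr.correlation),
                    entropy_bits=bilateral_average(fl.entropy, fr.entropy),
                    asm=bilateral_average(fl.asm, fr.asm),
                )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for all subjects and compartments.

    Writes ``cohort.csv`` (per-subject bilateral measurements),
    ``ratios.csv`` (per-side ratios), ``anova.json`` (one ANOVA per
    compartment and measure) and ``manifest.json``; returns the manifest.
    Identical config and master seed reproduce identical CSV bytes.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    run_warnings: list[str] = []

    df = analyze_cohort(
        config.cohort,
        seed=config.master_seed,
        levels=config.levels,
        glcm_distance=config.glcm_distance,
        compute_texture=config.compute_texture,
        collect_warnings=run_warnings,
    )
    if config.write_images:
        from .io import write_image, write_mask

        img_dir = out_dir / "images"
        sfx = {"tiff": ".tif", "png": ".png", "nifti": ".nii.gz"}[config.image_format]
        for subj in iter_cohort(config.cohort, seed=config.master_seed):
            for side, out in (("left", subj.left), ("right", subj.right)):
                stem = f"{subj.subject_id}_{subj.compartment}_{side}"
                write_image(img_dir / f"{stem}{sfx}", out.image)
                write_mask(img_dir / f"{stem}_truth{sfx}", out.truth_mask)

    cohort_csv = out_dir / "cohort.csv"
    measures = ["ratio"] + (
        ["correlation", "entropy_bits", "asm"] if config.compute_texture else []
    )
    df[["subject_id", "group", "compartment", "planted"] + measures].to_csv(
        cohort_csv, index=False
    )
    ratios_long = df.melt(
        id_vars=["subject_id", "group", "compartment"],
        value_vars=["ratio_left", "ratio_right"],
        var_name="side",
        value_name="side_ratio",
    )
    ratios_long["side"] = ratios_long["side"].str.removeprefix("ratio_")
    ratios_long = ratios_long.rename(columns={"side_ratio": "ratio"})
    ratios_csv = out_dir / "ratios.csv"
    ratios_long.to_csv(ratios_csv, index=False)

    anova_results: dict[str, dict] = {}
    for comp, sub in df.groupby("compartment", sort=False):
        anova_results[comp] = {}
        for measure in measures:
            vals = sub.dropna(subset=[measure])
            table = one_way_anova(vals, value_col=measure)
            anova_results[comp][measure] = table.to_dict()
    anova_json = out_dir / "anova.json"
    anova_json.write_text(json.dumps(anova_results, indent=2))

    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "levels": config.levels,
        "glcm_distance": config.glcm_distance,
        "compute_texture": config.compute_texture,
        "multiple_testing_correction": "none (per-compartment ANOVAs reported unadjusted)",
        "cohort_spec": config.cohort.to_dict(),
        "outputs": {
            "cohort_csv": str(cohort_csv),
            "ratios_csv": str(ratios_csv),
            "anova_json": str(anova_json),
        },
        "warnings": run_warnings,
        "runtime_seconds": round(time.perf_counter() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def render_report(manifest: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Bar histograms (group mean +/- SEM) and a markdown summary of a run.

    Produces one ratio panel per compartment plus one panel per texture
    feature present in the run outputs; deterministic given the inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    cohort_csv = Path(manifest["outputs"]["cohort_csv"])
    if not cohort_csv.exists():
        raise FileNotFoundError(f"missing run output: {cohort_csv}")
    df = pd.read_csv(cohort_csv)
    if df.empty:
        raise ValueError("empty cohort table; nothing to report")
    out_dir = Path(out_dir) if out_dir is not None else cohort_csv.parent
    out_dir.mkdir(parents=True, exist_ok=True)

    figures: list[str] = []
    group_order = [g for g in manifest["cohort_spec"]["ratio_mean"][df["compartment"].iloc[0]]]

    def _bar_panel(sub: pd.DataFrame, measure: str, title: str, fname: str) -> None:
        summ = group_summary(sub.dropna(subset=[measure]), value_col=measure)
        summ = summ.reindex([g for g in group_order if g in summ.index])
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.bar(
            summ.index,
            summ["mean"],
            yerr=summ["sem"],
            capsize=4,
            color="#888888",
            edgecolor="black",
        )
        ax.set_ylabel(measure)
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(str(path))

    for comp, sub in df.groupby("compartment", sort=False):
        _bar_panel(sub, "ratio", f"Fibrous/muscle ratio — {comp}", f"ratio_{comp}.png")
    for measure in ("correlation", "entropy_bits"):
        if measure in df.columns:
            _bar_panel(df, measure, f"GLCM {measure} (all compartments)", f"texture_{measure}.png")

    lines = ["# Run summary", ""]
    for comp, sub in df.groupby("compartment", sort=False):
        summ = group_summary(sub, value_col="ratio")
        lines.append(f"## {comp}")
        lines.append("")
        lines.append("```\n" + summ.to_string(float_format=lambda v: f"{v:.4f}") + "\n```")
        lines.append("")
    summary_md = out_dir / "summary.md"
    summary_md.write_text("\n".join(lines))
    return {"figures": figures, "summary": str(summary_md)}
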