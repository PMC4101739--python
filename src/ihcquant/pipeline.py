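"""End-to-end pipeline: simulate -> quantify -> compare, with a run manifest.

Each stage writes its artifacts under the configured output directory;
every CSV carries the global seed and config hash in ``#`` header
comments, and ``run_manifest.json`` records the config echo, seed,
package versions, and per-stage row counts.  Identical config + seed
gives byte-identical metrics and contrasts CSVs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import aggregate, chart, compare_groups, contrasts_frame, surface_plot
from .config import RunConfig
from .io import read_image, write_image, write_mask, write_metrics_csv
from .quantify import quantify_image
from .stains import StainMatrix, default_hdab_matrix
from .synthetic import generate_cohort

logger = logging.getLogger("ihcquant")

__all__ = ["simulate_stage", "quantify_stage", "compare_stage", "run_pipeline"]


def _stain_matrix(config: RunConfig) -> StainMatrix:
    if config.stain_matrix_csv:
        return StainMatrix.from_csv(config.stain_matrix_csv)
    return default_hdab_matrix()


def simulate_stage(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Generate the synthetic cohort to disk; returns the manifest."""
    images_dir = out_dir / "images"
    truth_dir = out_dir / "truth"
    images_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort
    samples = generate_cohort(
        cohort.normal, cohort.tumor, cohort.n_normal, cohort.n_tumor,
        list(cohort.tissues), seed=config.seed,
    )
    rows = []
    for s in samples:
        img_path = images_dir / f"{s.sample_id}.png"
        write_image(img_path, s.image)
        write_mask(truth_dir / f"{s.sample_id}_dab_mask.png", s.truth.dab_mask)
        write_mask(truth_dir / f"{s.sample_id}_tissue_mask.png", s.truth.tissue_mask)
        rows.append(
            {
                "sample_id": s.sample_id,
                "tissue": s.tissue,
                "group": s.group,
                "path": str(img_path),
                "true_dab_fraction": s.truth.true_dab_fraction,
                "seed": s.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    write_metrics_csv(
        out_dir / "manifest.csv", manifest,
        header_lines=[f"seed={config.seed}", f"config_hash={config.config_hash()}"],
    )
    logger.info("[simulate] wrote %d samples to %s", len(manifest), images_dir)
    return manifest


def quantify_stage(
    config: RunConfig, manifest: pd.DataFrame, out_dir: Path
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Quantify every manifest image; returns (and writes) the metrics table
    together with the per-sample DAB concentration planes (manifest order)."""
    stains = _stain_matrix(config)
    records, planes = [], []
    for row in manifest.itertuples(index=False):
        image = read_image(row.path)
        metrics, dab, _ = quantify_image(
            image,
            stains=stains,
            threshold_mode=config.threshold_mode,
            fixed_threshold=config.fixed_threshold,
            min_threshold=config.min_threshold,
            min_particle_size=config.min_particle_size,
            connectivity=config.connectivity,
            od_sum_threshold=config.tissue_od_threshold,
            sample_id=row.sample_id,
            tissue=row.tissue,
            group=row.group,
        )
        records.append(metrics.__dict__)
        planes.append(dab)
    metrics_df = pd.DataFrame(records)
    write_metrics_csv(
        out_dir / "metrics.csv", metrics_df,
        header_lines=[f"seed={config.seed}", f"config_hash={config.config_hash()}"],
    )
    logger.info("[quantify] wrote %d metric rows", len(metrics_df))
    return metrics_df, planes


def compare_stage(
    config: RunConfig,
    metrics_df: pd.DataFrame,
    out_dir: Path,
    planes: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Aggregate metrics, contrast the groups, and render the figures."""
    table = aggregate(metrics_df)
    contrasts = contrasts_frame(compare_groups(table, metric=config.comparison_metric))
    write_metrics_csv(
        out_dir / "contrasts.csv", contrasts,
        header_lines=[f"seed={config.seed}", f"config_hash={config.config_hash()}"],
    )
    fmt = config.plot_format
    chart(
        table, out_dir / f"chart.{fmt}",
        metric=config.comparison_metric, csv_path=out_dir / "chart_values.csv",
    )
    if planes is not None:
        # planes arrive in manifest order; reorder to the montage row order
        order = {sid: i for i, sid in enumerate(metrics_df["sample_id"])}
        grid = [planes[order[sid]] for sid in table.rows["sample_id"]]
        surface_plot(table, grid, out_dir / f"surface.{fmt}")
    logger.info("[compare] wrote %d tissue contrasts", len(contrasts))
    return contrasts


def run_pipeline(config: RunConfig, simulate: bool = True) -> dict:
    """Run all stages in order; returns the run manifest dictionary.

    With ``simulate=False`` an existing ``manifest.csv`` in the output
    directory (e.g. describing real images) is quantified instead.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate:
        manifest = simulate_stage(config, out_dir)
    else:
        manifest_path = out_dir / "manifest.csv"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest at {manifest_path}")
        manifest = pd.read_csv(manifest_path, comment="#")
    metrics, planes = quantify_stage(config, manifest, out_dir)
    contrasts = compare_stage(config, metrics, out_dir, planes=planes)
    run_manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": {
            "ihcquant": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {
            "manifest": len(manifest),
            "metrics": len(metrics),
            "contrasts": len(contrasts),
        },
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, default=str))
    return run_manifest
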