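"""Normal-versus-tumor cohort aggregation, contrasts, and figures.

Collects per-sample DAB metrics into a validated table ordered like a
tissue-microarray montage (normal sample first within each tissue),
computes per-tissue group contrasts of the DAB area fraction, and
renders the two summary figures: a surface plot of extracted DAB signal
over the montage grid and a per-sample chart in which each within-tissue
peak is, for the expected biology, the normal sample.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "TissueContrast",
    "aggregate",
    "compare_groups",
    "contrasts_frame",
    "surface_plot",
    "chart",
]

METRIC_COLUMNS = [
    "sample_id",
    "tissue",
    "group",
    "particle_count",
    "dab_area_fraction",
    "mean_dab_od",
    "integrated_dab_od",
    "tissue_area",
    "threshold_used",
]

VALID_GROUPS = ("normal", "tumor")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortTable:
    """Validated per-sample metrics with an explicit montage tissue order."""

    rows: pd.DataFrame
    tissue_order: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class TissueContrast:
    """Normal-versus-tumor summary for one tissue.

    ``rank_p`` is a descriptive two-sided rank-sum p-value; no multiple
    testing correction or significance threshold is applied.
    ``ratio`` is NaN when the normal mean is 0.
    """

    tissue: str
    normal_mean: float
    tumor_mean: float
    difference: float
    ratio: float
    n_normal: int
    n_tumor: int
    rank_p: float


def aggregate(metrics: "pd.DataFrame | str | io.IOBase") -> CohortTable:
    """Parse and validate a metrics table (CSV path, file object, or frame).

    Rows keep file order; the tissue order is first appearance, with normal
    samples sorted before tumor samples within each tissue (montage layout).
    Lines starting with ``#`` are treated as header comments.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:
        df = pd.read_csv(metrics, comment="#")
    if df.empty:
        raise CohortValidationError("no samples: metrics table is empty")
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"metrics table missing columns: {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise CohortValidationError(f"duplicate sample ids: {dupes}")
    bad = sorted(set(df["group"]) - set(VALID_GROUPS))
    if bad:
        raise CohortValidationError(
            f"unknown group labels {bad}; accepted labels are {list(VALID_GROUPS)}"
        )
    frac = df["dab_area_fraction"].astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise CohortValidationError("dab_area_fraction outside [0, 1]")
    tissue_order = tuple(dict.fromkeys(df["tissue"]))
    group_rank = df["group"].map({"normal": 0, "tumor": 1})
    tissue_rank = df["tissue"].map({t: i for i, t in enumerate(tissue_order)})
    order = np.lexsort((np.arange(len(df)), group_rank.to_numpy(), tissue_rank.to_numpy()))
    return CohortTable(rows=df.iloc[order].reset_index(drop=True), tissue_order=tissue_order)


def compare_groups(
    table: CohortTable, metric: str = "dab_area_fraction"
) -> list[TissueContrast]:
    """Per-tissue normal-versus-tumor contrast of the chosen metric.

    Means are arithmetic; the rank-sum test is exact when the smaller group
    has at most 8 samples, otherwise the normal approximation is used.
    """
    contrasts = []
    for tissue in table.tissue_order:
        sub = table.rows[table.rows["tissue"] == tissue]
        normal = sub.loc[sub["group"] == "normal", metric].to_numpy(dtype=float)
        tumor = sub.loc[sub["group"] == "tumor", metric].to_numpy(dtype=float)
        if normal.size == 0 or tumor.size == 0:
            raise CohortValidationError(
                f"tissue {tissue!r} lacks a "
                f"{'normal' if normal.size == 0 else 'tumor'} group"
            )
        method = "exact" if min(normal.size, tumor.size) <= 8 else "asymptotic"
        rank_p = float(
            stats.mannwhitneyu(normal, tumor, alternative="two-sided", method=method).pvalue
        )
        nm, tm = float(normal.mean()), float(tumor.mean())
        contrasts.append(
            TissueContrast(
                tissue=tissue,
                normal_mean=nm,
                tumor_mean=tm,
                difference=nm - tm,
                ratio=tm / nm if nm > 0 else float("nan"),
                n_normal=int(normal.size),
                n_tumor=int(tumor.size),
                rank_p=rank_p,
            )
        )
    return contrasts


def contrasts_frame(contrasts: list[TissueContrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


def _montage_heightmap(
    table: CohortTable, planes: list[np.ndarray], cell: int = 32
) -> np.ndarray:
    """Downsample each sample's DAB plane onto one montage grid cell.

    Rows follow the tissue order; columns follow within-tissue sample order
    (normal first).  Block means preserve integrated signal structure.
    """
    if len(planes) != len(table.rows):
        raise CohortValidationError(
            f"grid mismatch: {len(planes)} planes for {len(table.rows)} samples"
        )
    per_tissue = table.rows.groupby("tissue", sort=False).size()
    n_cols = int(per_tissue.max())
    if (per_tissue != n_cols).any():
        raise CohortValidationError("tissues have unequal sample counts; grid undefined")
    n_rows = len(table.tissue_order)
    height = np.zeros((n_rows * cell, n_cols * cell))
    for k, plane in enumerate(planes):
        r, c = divmod(k, n_cols)
        p = np.maximum(np.asarray(plane, dtype=float), 0.0)
        h, w = p.shape
        ry = np.minimum((np.arange(cell + 1) * h) // cell, h)
        rx = np.minimum((np.arange(cell + 1) * w) // cell, w)
        block = np.empty((cell, cell))
        for i in range(cell):
            for j in range(cell):
                sub = p[ry[i] : max(ry[i + 1], ry[i] + 1), rx[j] : max(rx[j + 1], rx[j] + 1)]
                block[i, j] = sub.mean()
        height[r * cell : (r + 1) * cell, c * cell : (c + 1) * cell] = block
    return height


def surface_plot(
    table: CohortTable,
    planes: list[np.ndarray],
    path,
    cell: int = 32,
) -> np.ndarray:
    """Render the montage-wide DAB signal as a 3-D surface; returns the
    plotted heightmap (deterministic for fixed input)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    height = _montage_heightmap(table, planes, cell=cell)
    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    yy, xx = np.mgrid[: height.shape[0], : height.shape[1]]
    ax.plot_surface(xx, yy, height, cmap="viridis", linewidth=0, antialiased=False)
    ax.set_xlabel("montage column (px)")
    ax.set_ylabel("montage row (px)")
    ax.set_zlabel("DAB OD")
    ax.invert_yaxis()
    fig.savefig(path, dpi=100, metadata=_no_date_metadata(path))
    plt.close(fig)
    return height


def chart(
    table: CohortTable,
    path,
    metric: str = "dab_area_fraction",
    csv_path=None,
) -> pd.DataFrame:
    """Bar chart of the per-sample metric in montage order plus a tidy CSV.

    With the expected normal-versus-tumor biology every within-tissue maximum
    (peak) is the normal sample.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table.rows) == 0:
        raise CohortValidationError("no samples to chart")
    plotted = table.rows[["sample_id", "tissue", "group", metric]].copy()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(plotted)), 4))
    colors = plotted["group"].map({"normal": "#2a6fbb", "tumor": "#c4452c"})
    ax.bar(np.arange(len(plotted)), plotted[metric], color=colors)
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_xticks(np.arange(len(plotted)))
    ax.set_xticklabels(plotted["sample_id"], rotation=90, fontsize=6)
    ax.set_title("per-sample DAB signal (normal first within each tissue)")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata=_no_date_metadata(path))
    plt.close(fig)
    if csv_path is not None:
        plotted.to_csv(csv_path, index=False)
    return plotted


def _no_date_metadata(path) -> dict | None:
    # strip timestamps so identical inputs give identical figure bytes
    p = str(path).lower()
    if p.endswith(".png"):
        return {"Software": "ihcquant"}
    if p.endswith(".svg"):
        return {"Date": None}
    return None
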