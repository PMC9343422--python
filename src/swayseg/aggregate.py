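"""Trial/subject aggregation, similarity categories, cluster runs and heatmaps.

Group means of AC (AAC) and of the signed synchronization index (APLV) are
banded into four similarity categories and scanned along the cranio-caudal
adjacent-pair chain for coherent runs (every internal pair at or above a high
threshold) and link sites (pairs below a low threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("VS", "S", "M", "W")

#: Default thresholds for the coherent-run / link-site scan.
HIGH_THRESHOLD = 0.6
LOW_THRESHOLD = 0.4

# anatomical spans along the 22-sensor chain: (first, last) sensors -> region
_REGION_SPANS = (
    ((1, 2), "head and upper neck"),
    ((2, 4), "upper neck"),
    ((4, 6), "lower neck"),
    ((6, 9), "upper thorax"),
    ((9, 12), "middle thorax"),
    ((12, 15), "lower thorax"),
    ((15, 18), "upper lumbar"),
    ((18, 21), "lower lumbar"),
    ((21, 22), "lower lumbar and pelvis"),
)


class InsufficientDataError(ValueError):
    pass


def categorize(value: float) -> str:
    """Band a mean similarity/synchronization value into VS/S/M/W.

    Bands are closed at the lower edge: value >= 0.8 -> VS, [0.6, 0.8) -> S,
    [0.4, 0.6) -> M, < 0.4 (including all negative values) -> W.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"value {value} outside [-1, 1]")
    if value >= 0.8:
        return "VS"
    if value >= 0.6:
        return "S"
    if value >= 0.4:
        return "M"
    return "W"


def average_over_trials(table: pd.DataFrame, metrics=("ac", "V", "plv")) -> pd.DataFrame:
    """Average per-trial pairwise statistics within subject x condition x
    direction x pair (arithmetic mean across trials)."""
    if len(table) == 0:
        raise InsufficientDataError("no trials to average")
    keys = ["subject", "condition", "direction", "sensor_n", "sensor_m"]
    metrics = [m for m in metrics if m in table.columns]
    out = table.groupby(keys, as_index=False)[list(metrics)].mean()
    out["n_trials"] = table.groupby(keys).size().to_numpy()
    return out


def group_mean_sd(subject_stats: pd.DataFrame, metric: str = "V") -> pd.DataFrame:
    """Across-subject mean and sample SD (ddof=1) per condition x direction x
    pair, with the similarity category of the mean attached."""
    keys = ["condition", "direction", "sensor_n", "sensor_m"]
    grouped = subject_stats.groupby(keys)[metric]
    counts = grouped.size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"need >= 2 subjects per cell; short cells: {bad}")
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n_subjects="size")
    out = out.reset_index()
    out["category"] = [categorize(v) for v in out["mean"]]
    out["region"] = [
        region_label((n, m)) if m == n + 1 else ""
        for n, m in zip(out["sensor_n"], out["sensor_m"])
    ]
    return out


@dataclass
class SegmentationProfile:
    """Coherent runs and link sites along the adjacent-pair chain.

    `values[i]` belongs to the adjacent pair (i+1, i+2) (1-based sensors).
    `coherent_runs` are maximal (first_sensor, last_sensor) ranges whose every
    internal adjacent pair has value >= high; `link_sites` are the pairs with
    value < low. Pairs in [low, high) belong to neither.
    """

    values: np.ndarray
    high: float
    low: float
    coherent_runs: list[tuple[int, int]]
    link_sites: list[tuple[int, int]]
    region_labels: dict[tuple[int, int], str] = field(default_factory=dict)


def find_clusters(
    adjacent_values,
    high: float = HIGH_THRESHOLD,
    low: float = LOW_THRESHOLD,
    n_sensors: int | None = None,
) -> SegmentationProfile:
    """Scan ordered adjacent-pair values for coherent runs and link sites.

    `adjacent_values` must hold exactly n_sensors - 1 values in cranio-caudal
    order. A single qualifying pair is reported as a length-2 sensor run.
    """
    values = np.asarray(adjacent_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("adjacent_values must be 1-D")
    if n_sensors is None:
        n_sensors = values.size + 1
    if values.size != n_sensors - 1:
        raise ValueError(f"expected {n_sensors - 1} values, got {values.size}")
    if low > high:
        raise ValueError("low threshold exceeds high threshold")

    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(values):
        if v >= high:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i + 1))
            start = None
    if start is not None:
        runs.append((start + 1, values.size + 1))

    links = [(i + 1, i + 2) for i, v in enumerate(values) if v < low]
    labels = {}
    if n_sensors == 22:
        labels = {(n, n + 1): region_label((n, n + 1)) for n in range(1, 22)}
    return SegmentationProfile(
        values=values,
        high=high,
        low=low,
        coherent_runs=runs,
        link_sites=links,
        region_labels=labels,
    )


def region_label(pair: tuple[int, int]) -> str:
    """Anatomical region of an adjacent sensor pair on the 22-sensor chain."""
    n, m = pair
    if m != n + 1:
        raise ValueError(f"region lookup is restricted to adjacent pairs; got {pair}")
    if not 1 <= n < m <= 22:
        raise ValueError(f"pair {pair} outside sensors 1..22")
    for (first, last), name in _REGION_SPANS:
        if first <= n and m <= last:
            return name
    raise ValueError(f"pair {pair} not covered by the region map")  # pragma: no cover


def pair_matrix(group_stats: pd.DataFrame, condition: str, direction: str,
                column: str = "mean", n_sensors: int = 22) -> np.ndarray:
    """Symmetric n x n matrix of a group statistic (NaN off the given pairs)."""
    mat = np.full((n_sensors, n_sensors), np.nan)
    np.fill_diagonal(mat, 1.0 if column == "mean" else 0.0)
    sel = group_stats[
        (group_stats["condition"] == condition) & (group_stats["direction"] == direction)
    ]
    for _, row in sel.iterrows():
        i, j = int(row["sensor_n"]) - 1, int(row["sensor_m"]) - 1
        mat[i, j] = mat[j, i] = row[column]
    return mat


def render_heatmaps(group_stats: pd.DataFrame, out_dir, n_sensors: int = 22,
                    cmap: str = "viridis") -> list[str]:
    """Write one mean map and one SD map per condition x direction.

    Deterministic given identical input (fixed style, no timestamps); missing
    cells are rendered masked. Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    combos = group_stats[["condition", "direction"]].drop_duplicates().itertuples(index=False)
    for condition, direction in combos:
        for column, vmin, vmax in (("mean", -1.0, 1.0), ("sd", 0.0, 1.0)):
            mat = pair_matrix(group_stats, condition, direction, column, n_sensors)
            if np.isnan(mat).any():
                import warnings

                warnings.warn(
                    f"missing cells in {condition}/{direction}/{column}; rendered masked"
                )
            fig, ax = plt.subplots(figsize=(6, 5))
            masked = np.ma.masked_invalid(mat)
            im = ax.imshow(masked, vmin=vmin, vmax=vmax, cmap=cmap, origin="upper")
            ax.set_xticks(range(0, n_sensors, 3), [str(i + 1) for i in range(0, n_sensors, 3)])
            ax.set_yticks(range(0, n_sensors, 3), [str(i + 1) for i in range(0, n_sensors, 3)])
            ax.set_xlabel("sensor")
            ax.set_ylabel("sensor")
            ax.set_title(f"{column} | {condition} {direction}")
            fig.colorbar(im, ax=ax)
            path = out_dir / f"heatmap_{column}_{condition}_{direction}.png"
            fig.savefig(path, dpi=100, metadata={"Software": None})
            plt.close(fig)
            written.append(str(path))
    return written


def adjacent_profile(
    group_stats: pd.DataFrame,
    condition: str,
    direction: str,
    high: float = HIGH_THRESHOLD,
    low: float = LOW_THRESHOLD,
) -> SegmentationProfile:
    """Build the SegmentationProfile for one condition x direction from a
    group-stats table restricted to adjacent pairs."""
    sel = group_stats[
        (group_stats["condition"] == condition)
        & (group_stats["direction"] == direction)
        & (group_stats["sensor_m"] == group_stats["sensor_n"] + 1)
    ].sort_values("sensor_n")
    return find_clusters(sel["mean"].to_numpy(), high=high, low=low)
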