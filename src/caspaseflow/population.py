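"""Population-level statistics over per-cell cascade profiles.

Builds the cells × indices table, the all-pairs correlation matrix in the
R-lower / R²-upper layout (positive correlations red, negative blue), the
paired between-caspase comparisons, and mean ± error time-course summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import INDEX_COLUMNS

__all__ = [
    "PopulationTable",
    "CorrelationMatrix",
    "build_population_table",
    "correlation_heatmap",
    "plot_heatmap",
    "compare_caspases",
    "average_time_course",
]


@dataclass
class CorrelationMatrix:
    """Square index-by-index matrix: Pearson R below the diagonal, R² above.

    ``r`` keeps the full symmetric R matrix; ``matrix`` is the display
    layout. ``undefined`` lists zero-variance columns whose correlations are
    undefined (reported as NaN, never silently zero).
    """

    labels: tuple
    r: np.ndarray
    matrix: np.ndarray
    undefined: tuple = ()

    def color_values(self) -> np.ndarray:
        """Signed values driving the heatmap colors: R in the lower triangle,
        sign(R)·R² in the upper, 1 on the diagonal (red = positive,
        blue = negative)."""
        out = self.matrix.copy()
        upper = np.triu_indices(len(self.labels), k=1)
        out[upper] = np.sign(self.r[upper]) * self.matrix[upper]
        return out

    def entry(self, a: str, b: str) -> float:
        """Pearson R between two named indices."""
        return float(self.r[self.labels.index(a), self.labels.index(b)])


def build_population_table(cascades) -> pd.DataFrame:
    """One row per accepted cell, columns in the controlled index vocabulary."""
    cascades = list(cascades)
    if not cascades:
        raise ValueError("no accepted cells: cannot build a population table")
    rows = []
    for c in cascades:
        if not c.responded:
            raise ValueError(
                f"cell {c.cell_id} did not respond on both sensors; "
                "run filter_responders first"
            )
        row = {"cell_id": c.cell_id}
        for tag, prof in (("c9", c.profile9), ("c3", c.profile3)):
            row[f"initiation_{tag}"] = prof.initiation
            row[f"saturation_{tag}"] = prof.saturation
            row[f"duration_{tag}"] = prof.duration
            row[f"response_scale_{tag}"] = prof.response_scale
            row[f"maximum_ratio_{tag}"] = prof.maximum_ratio
            row[f"slope_{tag}"] = prof.slope
            row[f"integration_{tag}"] = prof.integration
            row[f"time_at_max_{tag}"] = prof.time_at_max
        row["promotion_interval"] = c.promotion_interval
        row["activation_interval"] = c.activation_interval
        row["completion_interval"] = c.completion_interval
        rows.append(row)
    table = pd.DataFrame(rows, columns=["cell_id", *INDEX_COLUMNS]).set_index("cell_id")
    if table.isna().any().any():
        raise ValueError("accepted rows must not contain missing values")
    table.attrs["n_cells"] = len(table)
    return table


def correlation_heatmap(table: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """All-pairs correlations of the index columns in the R/R² layout."""
    if len(table) < 3:
        raise ValueError("need at least 3 cells for a correlation heatmap")
    cols = [c for c in INDEX_COLUMNS if c in table.columns]
    sub = table[cols]
    zero_var = tuple(c for c in cols if np.isclose(sub[c].std(ddof=0), 0.0))
    if zero_var:
        warnings.warn(
            f"zero-variance column(s) {zero_var}: their correlations are undefined",
            stacklevel=2,
        )
    r = sub.corr(method=method).to_numpy()
    display = r.copy()
    iu = np.triu_indices(len(cols), k=1)
    display[iu] = r[iu] ** 2
    np.fill_diagonal(display, 1.0)
    return CorrelationMatrix(labels=tuple(cols), r=r, matrix=display, undefined=zero_var)


def plot_heatmap(corr: CorrelationMatrix, path=None, ax=None):
    """Render the R-lower/R²-upper heatmap, positive red / negative blue."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = corr.color_values()
    n = len(corr.labels)
    if ax is None:
        fig, ax = plt.subplots(figsize=(0.55 * n + 2, 0.55 * n + 1.5))
    else:
        fig = ax.figure
    im = ax.imshow(values, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(n), corr.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), corr.labels, fontsize=7)
    ax.set_title("Pearson R (lower) / R$^2$ (upper)", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def compare_caspases(table: pd.DataFrame, index: str = "time_at_max", paired: bool = True) -> dict:
    """Between-caspase comparison of one index (t-test, two-sided).

    Degenerate guards: identical columns give t=0, p=1; a constant nonzero
    paired shift gives t=±inf, p=0 (the limiting behavior of the paired
    test at zero within-pair variance).
    """
    c9, c3 = f"{index}_c9", f"{index}_c3"
    for col in (c9, c3):
        if col not in table.columns:
            raise ValueError(f"population table has no column {col!r}")
    x9 = table[c9].to_numpy(dtype=float)
    x3 = table[c3].to_numpy(dtype=float)
    n = len(x9)
    if n < 2:
        raise ValueError("need at least 2 cells for a t-test")
    diff = x3 - x9
    if paired and np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = float(np.sign(diff.mean()) * np.inf)
            p_value = 0.0
    elif paired:
        t_stat, p_value = stats.ttest_rel(x3, x9)
    else:
        t_stat, p_value = stats.ttest_ind(x3, x9)
    return {
        "index": index,
        "paired": paired,
        "n": n,
        "mean_c9": float(x9.mean()),
        "mean_c3": float(x3.mean()),
        "sd_c9": float(x9.std(ddof=1)),
        "sd_c3": float(x3.std(ddof=1)),
        "t": float(t_stat),
        "p": float(p_value),
        "direction": "c3_greater" if x3.mean() > x9.mean() else "c9_greater_or_equal",
    }


def average_time_course(traces, error_mode: str = "sem"):
    """Per-frame mean and dispersion band across cells.

    ``traces`` is an ``(n_cells, n_frames)`` array (or list of equal-length
    1-D traces). Returns ``(mean, err, n)`` with ``err`` the per-frame SEM
    (default) or SD.
    """
    try:
        arr = np.asarray(traces, dtype=float)
    except ValueError as exc:
        raise ValueError("traces must share one time grid") from exc
    if arr.ndim != 2:
        raise ValueError("traces must share one time grid: expected a 2-D array")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
    if error_mode == "sd":
        err = sd
    elif error_mode == "sem":
        err = sd / np.sqrt(n)
    else:
        raise ValueError(f"unknown error mode {error_mode!r}")
    return mean, err, n
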