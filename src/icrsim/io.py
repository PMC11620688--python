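"""Deterministic result output: CSV tables, VTK snapshots, analysis reports.

Every data file starts with a comment header carrying the configuration
hash, so outputs are reproducible byte-for-byte from the configuration
alone (no timestamps or hostnames).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .mesh import AxisymMesh, write_vtk

__all__ = ["write_campaign_table", "read_campaign_table", "write_run_snapshot",
           "write_analysis_report"]


def _header(config_hash: str) -> str:
    return f"# icrsim config={config_hash}\n"


def write_campaign_table(table: pd.DataFrame, path, config_hash: str = "") -> None:
    with open(path, "w") as f:
        f.write(_header(config_hash))
        table.to_csv(f, index=False, lineterminator="\n", float_format="%.10g")


def read_campaign_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_run_snapshot(out_dir, name: str, mesh: AxisymMesh, u: np.ndarray,
                       x_ref: np.ndarray | None = None) -> str:
    """VTK snapshot of a converged stage (displacement as point data)."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"{name}.vtk")
    disp = u.reshape(-1, 2)
    write_vtk(path, mesh, point_data={"displacement": disp})
    return path


def write_analysis_report(out_dir, correlations: pd.DataFrame,
                          comparisons: pd.DataFrame,
                          contributions: pd.DataFrame,
                          config_hash: str = "", figure=None) -> dict:
    """Write the statistics bundle (correlation, pairwise comparison and
    variance-contribution CSVs plus the stacked-bar contribution figure)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (("correlations", correlations),
                     ("comparisons", comparisons),
                     ("contributions", contributions)):
        path = os.path.join(out_dir, f"{name}.csv")
        with open(path, "w") as f:
            f.write(_header(config_hash))
            df.to_csv(f, index=False, lineterminator="\n", float_format="%.10g")
        paths[name] = path
    if figure is not None:
        path = os.path.join(out_dir, "contributions.png")
        figure.savefig(path, dpi=150)
        paths["figure"] = path
    return paths


def contribution_figure(contributions: pd.DataFrame):
    """Stacked-bar chart of variance shares per outcome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    pivot = contributions.pivot(index="outcome", columns="component",
                                values="share")
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(pivot))
    for comp in pivot.columns:
        ax.bar(pivot.index, pivot[comp], bottom=bottom, label=comp)
        bottom += pivot[comp].to_numpy()
    ax.set_ylabel("share of outcome variance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
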