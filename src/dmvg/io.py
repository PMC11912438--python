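"""Panel readers and writers (delimited text) and edge-list export.

Panel files hold one column per variable and one row per time point, with a
header row of variable names; comma- and tab-delimited files are both
accepted. A directory convention ``<participant>/<trial>.csv`` supplies the
participant and trial labels.
"""

from __future__ import annotations

import glob
import os
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import TimeSeriesPanel
from .visibility import DirectedMultiplexVisibilityGraph

__all__ = ["read_panel", "read_panels", "write_panel", "export_edge_list"]


class PanelInputError(ValueError):
    """Input file failed validation; the message names the file and location."""


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_panel(path: str) -> TimeSeriesPanel:
    """Read one delimited panel file (columns = variables, rows = time points)."""
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed text
        raise PanelInputError(f"{path}: cannot parse ({exc})") from exc
    if df.shape[0] < 3:
        raise PanelInputError(f"{path}: needs at least 3 time points, got {df.shape[0]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise PanelInputError(
            f"{path}: non-numeric or missing value at row {row + 2} "
            f"(column {col!r}, counting the header as row 1)"
        )
    parent = os.path.basename(os.path.dirname(os.path.abspath(path)))
    stem = os.path.splitext(os.path.basename(path))[0]
    return TimeSeriesPanel(
        values=numeric.to_numpy().T,
        sample_id=f"{parent}/{stem}",
        participant_id=parent,
        variable_names=[str(c) for c in df.columns],
    )


def read_panels(path_pattern: str) -> List[TimeSeriesPanel]:
    """Read every file matching a glob pattern; variable columns must agree."""
    paths = sorted(glob.glob(path_pattern, recursive=True))
    if not paths:
        raise PanelInputError(f"no files match {path_pattern!r}")
    panels = [read_panel(p) for p in paths]
    names = panels[0].variable_names
    for p, panel in zip(paths, panels):
        if panel.variable_names != names:
            raise PanelInputError(
                f"{p}: variable columns {panel.variable_names} differ from "
                f"{paths[0]}'s {names}"
            )
    return panels


def write_panel(panel: TimeSeriesPanel, path: str, sep: str = ",") -> None:
    """Write a panel in the same format the readers consume (full precision)."""
    df = pd.DataFrame(panel.values.T, columns=panel.variable_names)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def export_edge_list(
    g: DirectedMultiplexVisibilityGraph, layer: int, path: str, sep: str = "\t"
) -> None:
    """Write one layer as a two-column edge list (1-based ids, source first)."""
    edges = g.layer_edges[layer] + 1
    np.savetxt(path, edges, fmt="%d", delimiter=sep)
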