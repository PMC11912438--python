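"""Multivariate time-series panels.

A panel is one sample (e.g. one trial of one participant): ``N`` variables
observed at ``T`` strictly increasing time points. Panels are the input to
visibility-graph construction; many panels are pooled when estimating degree
distributions at the cohort level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["TimeSeriesPanel", "reverse_panel"]


@dataclass
class TimeSeriesPanel:
    """One sample of a multivariate time series.

    Parameters
    ----------
    values : ndarray of shape (n_variables, n_times)
        Real-valued observations, one row per variable. No missing values.
    time_indices : ndarray of shape (n_times,), optional
        Strictly increasing observation times. Defaults to ``1..T``
        (equispaced unit sampling).
    sample_id : str
        Opaque sample (trial) label.
    participant_id : str, optional
        Opaque participant label, used for per-participant pooling.
    variable_names : sequence of str, optional
        One name per variable; defaults to ``x1..xN``.
    """

    values: np.ndarray
    time_indices: Optional[np.ndarray] = None
    sample_id: str = ""
    participant_id: Optional[str] = None
    variable_names: Optional[Sequence[str]] = field(default=None)

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (n_variables, n_times) array")
        n_var, n_time = values.shape
        if n_var < 1:
            raise ValueError("panel needs at least one variable")
        if n_time < 3:
            raise ValueError(f"panel needs at least 3 time points, got {n_time}")
        if not np.isfinite(values).all():
            raise ValueError("panel contains missing or non-finite values")
        self.values = values

        if self.time_indices is None:
            times = np.arange(1, n_time + 1, dtype=float)
        else:
            times = np.asarray(self.time_indices, dtype=float)
            if times.shape != (n_time,):
                raise ValueError(
                    f"time_indices has length {times.size}, expected {n_time}"
                )
            if not np.all(np.diff(times) > 0):
                raise ValueError("time_indices must be strictly increasing")
        self.time_indices = times

        if self.variable_names is None:
            names = [f"x{i + 1}" for i in range(n_var)]
        else:
            names = [str(n) for n in self.variable_names]
            if len(names) != n_var:
                raise ValueError(
                    f"{len(names)} variable names for {n_var} variables"
                )
        self.variable_names = names

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


def reverse_panel(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Time-reverse a panel.

    Values are reversed along the time axis; time indices are remapped so the
    gap structure is preserved in reverse order (equispaced panels keep their
    grid exactly). Reversing twice restores the original panel.
    """
    t = panel.time_indices
    new_times = t[0] + (t[-1] - t[::-1])
    return TimeSeriesPanel(
        values=panel.values[:, ::-1].copy(),
        time_indices=new_times,
        sample_id=panel.sample_id,
        participant_id=panel.participant_id,
        variable_names=list(panel.variable_names),
    )
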