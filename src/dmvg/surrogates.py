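"""Shuffled-surrogate null models and subsampling error bars.

Finite series produce nonzero divergence estimates even for perfectly
reversible dynamics (finite-size bias). To decide whether a measured sigma
reflects genuine nonequilibrium structure, the analysis is re-run on
time-shuffled surrogates: permuting the time order destroys temporal
structure while preserving each variable's value distribution, so the
surrogate sigmas form a null distribution for "no irreversibility beyond
finite-size effects". Subsampling the trial pool quantifies the estimation
error of sigma itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .distributions import effective_dmax
from .divergence import korder_irreversibility
from .panel import TimeSeriesPanel
from .visibility import DegreeTable, degree_table

__all__ = [
    "shuffle_panel",
    "surrogate_null_test",
    "surrogate_null_sweep",
    "subsample_error",
    "SurrogateNullResult",
    "SubsampleErrorResult",
]


@dataclass
class SurrogateNullResult:
    tuple_layers: Tuple[int, ...]
    observed_sigma: float
    null_sigma: List[float]
    percentile_rank: float
    n_surrogates: int
    shuffle_mode: str
    seed: int

    def null_percentile(self, q: float) -> float:
        return float(np.percentile(self.null_sigma, q))


@dataclass
class SubsampleErrorResult:
    tuple_layers: Tuple[int, ...]
    mean_sigma: float
    sd_sigma: float
    subsample_fraction: float
    n_repeats: int
    seed: int


def shuffle_panel(
    panel: TimeSeriesPanel, mode: str = "joint", seed: int = 0
) -> TimeSeriesPanel:
    """Randomly permute a panel's time order.

    ``joint`` applies one permutation to all variables, preserving
    instantaneous cross-variable coupling (the equal-time correlation matrix
    is untouched) while destroying temporal order; ``per_layer`` permutes each
    variable independently, destroying cross-variable coupling too.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    T = panel.n_times
    if mode == "joint":
        perm = rng.permutation(T)
        values = panel.values[:, perm]
    elif mode == "per_layer":
        values = np.empty_like(panel.values)
        for l in range(panel.n_variables):
            values[l] = panel.values[l, rng.permutation(T)]
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return TimeSeriesPanel(
        values=values.copy(),
        time_indices=panel.time_indices.copy(),
        sample_id=panel.sample_id,
        participant_id=panel.participant_id,
        variable_names=list(panel.variable_names),
    )


def _surrogate_seed(seed: int, draw: int, sample: int) -> np.random.SeedSequence:
    # deterministic in (seed, draw, sample) so surrogates are reproducible
    # regardless of execution order
    return np.random.SeedSequence([int(seed), int(draw), int(sample)])


def _shuffled_tables(
    panels: Sequence[TimeSeriesPanel], draw: int, mode: str, seed: int
) -> List[DegreeTable]:
    tables = []
    for s, panel in enumerate(panels):
        sub = _surrogate_seed(seed, draw, s)
        tables.append(degree_table(shuffle_panel(panel, mode=mode, seed=sub)))
    return tables


def surrogate_null_sweep(
    panels: Sequence[TimeSeriesPanel],
    tuples: Sequence[Tuple[int, ...]],
    n_surrogates: int = 99,
    mode: str = "joint",
    seed: int = 0,
    dmax: Optional[int] = None,
    dmax_cap: Optional[int] = 75,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> Dict[Tuple[int, ...], SurrogateNullResult]:
    """Surrogate null test for several tuples sharing the same shuffled draws.

    The shuffle for draw r depends only on (seed, r, sample), never on the
    tuple, so results are bit-identical to running each tuple separately.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a meaningful rank")
    if not panels:
        raise ValueError("need at least one panel")
    tuples = [tuple(int(l) for l in t) for t in tuples]

    observed_tables = [degree_table(p) for p in panels]
    if dmax is None:
        dmax = effective_dmax(observed_tables, cap=dmax_cap,
                              exclude_boundary=exclude_boundary)

    observed = {
        t: korder_irreversibility(observed_tables, t, dmax=dmax,
                                  smoothing=smoothing,
                                  exclude_boundary=exclude_boundary)
        for t in tuples
    }
    nulls: Dict[Tuple[int, ...], List[float]] = {t: [] for t in tuples}
    for r in range(n_surrogates):
        tables = _shuffled_tables(panels, r, mode, seed)
        for t in tuples:
            nulls[t].append(
                korder_irreversibility(tables, t, dmax=dmax,
                                       smoothing=smoothing,
                                       exclude_boundary=exclude_boundary)
            )

    results = {}
    for t in tuples:
        below = sum(1 for v in nulls[t] if v < observed[t])
        results[t] = SurrogateNullResult(
            tuple_layers=t,
            observed_sigma=observed[t],
            null_sigma=nulls[t],
            percentile_rank=100.0 * below / n_surrogates,
            n_surrogates=n_surrogates,
            shuffle_mode=mode,
            seed=int(seed),
        )
    return results


def surrogate_null_test(
    panels: Sequence[TimeSeriesPanel],
    tuple_layers: Sequence[int],
    n_surrogates: int = 99,
    mode: str = "joint",
    seed: int = 0,
    dmax: Optional[int] = None,
    dmax_cap: Optional[int] = 75,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> SurrogateNullResult:
    """Rank a tuple's observed sigma against shuffled surrogates.

    Every sample panel is shuffled afresh for each surrogate draw, the full
    pipeline (graphs, degrees, distributions, JSD) is re-run, and the observed
    sigma is ranked by the fraction of null draws strictly below it (ties
    count as not-below — a conservative rank). The observed panels' dmax
    (capped) is reused for every null draw so all sigmas share one support.
    """
    t = tuple(int(l) for l in tuple_layers)
    return surrogate_null_sweep(
        panels, [t], n_surrogates=n_surrogates, mode=mode, seed=seed,
        dmax=dmax, dmax_cap=dmax_cap, smoothing=smoothing,
        exclude_boundary=exclude_boundary,
    )[t]


def subsample_error(
    panels: Sequence[TimeSeriesPanel],
    tuple_layers: Sequence[int],
    fraction: float = 0.5,
    n_repeats: int = 20,
    seed: int = 0,
    dmax: Optional[int] = None,
    dmax_cap: Optional[int] = 75,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> SubsampleErrorResult:
    """Spread of sigma under subsampling of the trial pool.

    Each repeat draws ``floor(fraction * n_samples)`` panels without
    replacement and recomputes sigma; the SD over repeats estimates the
    sampling error of the pooled estimate. Degree tables are built once and
    reused across repeats (the subsample only changes which tables are pooled).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    n = len(panels)
    m = math.floor(fraction * n)
    if m < 1:
        raise ValueError(f"subsample of {n} panels at fraction {fraction} is empty")

    tables = [degree_table(p) for p in panels]
    if dmax is None:
        dmax = effective_dmax(tables, cap=dmax_cap,
                              exclude_boundary=exclude_boundary)
    t = tuple(int(l) for l in tuple_layers)
    rng = np.random.default_rng(seed)
    sigmas = []
    for _ in range(n_repeats):
        idx = rng.choice(n, size=m, replace=False)
        subset = [tables[i] for i in idx]
        sigmas.append(
            korder_irreversibility(subset, t, dmax=dmax, smoothing=smoothing,
                                   exclude_boundary=exclude_boundary)
        )
    return SubsampleErrorResult(
        tuple_layers=t,
        mean_sigma=float(np.mean(sigmas)),
        sd_sigma=float(np.std(sigmas, ddof=0)),
        subsample_fraction=float(fraction),
        n_repeats=int(n_repeats),
        seed=int(seed),
    )
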