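"""scikit-learn style estimator running the full irreversibility analysis.

``MultiplexIrreversibility`` is fit to a collection of sample panels (trials).
Fitting builds each panel's directed multiplex visibility graph, pools the
degree tables, and computes the per-tuple irreversibility sigma at every
requested level; fitted attributes expose the reports, the shared degree cap,
and the sigma table. Surrogate nulls, subsampling error bars and the unique-
contribution decomposition are methods on the fitted estimator.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import surrogates as _surr
from .distributions import effective_dmax
from .divergence import (
    IrreversibilityReport,
    UniqueContributionTable,
    sweep_level,
    unique_contributions,
)
from .panel import TimeSeriesPanel
from .visibility import degree_table

__all__ = ["MultiplexIrreversibility"]

PanelLike = Union[TimeSeriesPanel, np.ndarray]


def _as_panel(x: PanelLike, i: int) -> TimeSeriesPanel:
    if isinstance(x, TimeSeriesPanel):
        return x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"sample {i}: expected a 2-D (n_variables, T) array")
    return TimeSeriesPanel(values=arr, sample_id=f"sample{i}")


class MultiplexIrreversibility(BaseEstimator):
    """Per-tuple time-irreversibility of a multivariate time-series cohort.

    Parameters
    ----------
    levels : sequence of int, default (1, 2)
        Interaction orders k to sweep; each level reports all C(N, k) tuples.
    dmax : int, optional
        Fixed degree-support cap. By default the observed maximum directed
        degree, capped at ``dmax_cap``, is used.
    dmax_cap : int, default 75
        Upper bound on the inferred dmax (keeps high-order joint supports
        tractable).
    smoothing : bool, default True
        Average empirical degree distributions with a uniform prior so every
        support bin is positive (required for finite divergences).
    exclude_boundary : bool, default True
        Drop the first and last node of each sample from the degree pools
        (they have in- resp. out-degree zero by construction).

    Attributes
    ----------
    n_variables_ : int
    variable_names_ : list of str
    n_samples_ : int
    degree_tables_ : list of DegreeTable
    dmax_used_ : int
    reports_ : dict  {k: IrreversibilityReport}
    sigma_ : dict  {tuple of layer indices: float}

    Examples
    --------
    >>> from dmvg.synthdata import CohortSpec, gen_cohort
    >>> panels = gen_cohort(CohortSpec(n_variables=3, n_participants=2,
    ...                                n_trials=2, trial_length=200, seed=7))
    >>> est = MultiplexIrreversibility(levels=(1, 2)).fit(panels)
    >>> sorted(est.sigma_)  # doctest: +NORMALIZE_WHITESPACE
    [(0,), (0, 1), (0, 2), (1,), (1, 2), (2,)]
    """

    def __init__(
        self,
        levels: Sequence[int] = (1, 2),
        dmax: Optional[int] = None,
        dmax_cap: int = 75,
        smoothing: bool = True,
        exclude_boundary: bool = True,
    ):
        self.levels = levels
        self.dmax = dmax
        self.dmax_cap = dmax_cap
        self.smoothing = smoothing
        self.exclude_boundary = exclude_boundary

    # ------------------------------------------------------------------
    def fit(self, X: Sequence[PanelLike], y=None) -> "MultiplexIrreversibility":
        """Fit to a list of panels (or 2-D (n_variables, T) arrays)."""
        if len(X) == 0:
            raise ValueError("need at least one sample panel")
        panels = [_as_panel(x, i) for i, x in enumerate(X)]
        n_var = panels[0].n_variables
        for p in panels:
            if p.n_variables != n_var:
                raise ValueError("panels disagree on the number of variables")
        levels = sorted(set(int(k) for k in self.levels))
        if not levels or levels[0] < 1 or levels[-1] > n_var:
            raise ValueError(f"levels {levels} out of range for {n_var} variables")

        self.panels_ = panels
        self.n_variables_ = n_var
        self.variable_names_ = list(panels[0].variable_names)
        self.n_samples_ = len(panels)
        self.degree_tables_ = [degree_table(p) for p in panels]
        if self.dmax is not None:
            self.dmax_used_ = int(self.dmax)
        else:
            self.dmax_used_ = effective_dmax(
                self.degree_tables_, cap=self.dmax_cap,
                exclude_boundary=self.exclude_boundary,
            )
        self.reports_: Dict[int, IrreversibilityReport] = {}
        self.sigma_: Dict[Tuple[int, ...], float] = {}
        for k in levels:
            rep = sweep_level(
                self.degree_tables_, k, dmax=self.dmax_used_,
                smoothing=self.smoothing,
                exclude_boundary=self.exclude_boundary,
                layer_names=self.variable_names_,
            )
            self.reports_[k] = rep
            self.sigma_.update(dict(rep.entries))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "sigma_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # ------------------------------------------------------------------
    def report(self, k: int) -> IrreversibilityReport:
        self._check_fitted()
        return self.reports_[k]

    def unique_contributions(self) -> UniqueContributionTable:
        """Recursive decomposition eta from the fitted sigma table.

        Requires the fitted levels to be contiguous from 1 (every sub-tuple's
        sigma must be available).
        """
        self._check_fitted()
        ks = sorted(self.reports_)
        if ks != list(range(1, ks[-1] + 1)):
            raise ValueError(
                f"unique contributions need levels 1..{ks[-1]}, fitted {ks}"
            )
        return unique_contributions(self.sigma_)

    def surrogate_null(
        self,
        tuple_layers: Sequence[int],
        n_surrogates: int = 99,
        mode: str = "joint",
        seed: int = 0,
    ) -> _surr.SurrogateNullResult:
        self._check_fitted()
        return _surr.surrogate_null_test(
            self.panels_, tuple_layers, n_surrogates=n_surrogates, mode=mode,
            seed=seed, dmax=self.dmax_used_, smoothing=self.smoothing,
            exclude_boundary=self.exclude_boundary,
        )

    def subsample_error(
        self,
        tuple_layers: Sequence[int],
        fraction: float = 0.5,
        n_repeats: int = 20,
        seed: int = 0,
    ) -> _surr.SubsampleErrorResult:
        self._check_fitted()
        return _surr.subsample_error(
            self.panels_, tuple_layers, fraction=fraction, n_repeats=n_repeats,
            seed=seed, dmax=self.dmax_used_, smoothing=self.smoothing,
            exclude_boundary=self.exclude_boundary,
        )
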