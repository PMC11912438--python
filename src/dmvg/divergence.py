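"""k-order irreversibility: divergence between in- and out-degree distributions.

A stationary process is time-reversible when a trajectory and its reversal
are equally probable; for a reversible process the in- and out-degree
distributions of the time-directed visibility graph converge. The k-order
irreversibility of a layer tuple is therefore the Jensen-Shannon divergence

    sigma(n_1..n_k) = JSD( P_in || P_out )

between the smoothed joint degree distributions of the tuple, in nats, so
0 <= sigma <= ln 2. Sweeping all C(N, k) tuples at a level and annotating each
tuple by how many standard deviations its sigma lies above (stars) or below
(daggers) the level mean ranks interactions within a level.

The recursive unique-contribution decomposition

    eta(S) = sigma(S) - sum_{nonempty proper subsets W of S} eta(W)

isolates the part of a tuple's irreversibility not attributable to any of its
sub-tuples; summing eta over all nonempty subsets of S reconstructs sigma(S).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .distributions import (
    JointDegreeDistribution,
    effective_dmax,
    estimate_joint_distribution,
)
from .visibility import DegreeTable

__all__ = [
    "kld",
    "jsd",
    "korder_irreversibility",
    "sweep_level",
    "annotate_significance",
    "unique_contributions",
    "sigma_table",
    "IrreversibilityReport",
    "UniqueContributionTable",
    "LN2",
]

LN2 = math.log(2.0)

Distribution = Union[JointDegreeDistribution, Sequence[float], np.ndarray]


# ---------------------------------------------------------------------------
# divergences
# ---------------------------------------------------------------------------

def _check_same_support(p: JointDegreeDistribution, q: JointDegreeDistribution) -> None:
    if (p.k, p.dmax, p.support_min) != (q.k, q.dmax, q.support_min):
        raise ValueError(
            "distributions have mismatched supports: "
            f"(k={p.k}, dmax={p.dmax}, min={p.support_min}) vs "
            f"(k={q.k}, dmax={q.dmax}, min={q.support_min})"
        )


def _kld_dense(p: np.ndarray, q: np.ndarray) -> float:
    if p.shape != q.shape:
        raise ValueError(f"mismatched supports: shapes {p.shape} vs {q.shape}")
    bad = (p > 0) & (q == 0)
    if bad.any():
        idx = tuple(int(v) for v in np.argwhere(bad)[0])
        raise ValueError(f"Q is zero at bin {idx} where P is positive")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kld(p: Distribution, q: Distribution) -> float:
    """Kullback-Leibler divergence sum_x P(x) log(P(x)/Q(x)), in nats.

    Accepts a pair of :class:`JointDegreeDistribution` on the same truncated
    support (sparse path, implicit smoothing floors handled analytically) or a
    pair of dense probability arrays. ``0 * log(0/q)`` is taken as 0; a zero
    ``Q`` bin with positive ``P`` is a domain error naming the bin.
    """
    if isinstance(p, JointDegreeDistribution) and isinstance(q, JointDegreeDistribution):
        _check_same_support(p, q)
        total = 0.0
        union = set(p.counts) | set(q.counts)
        for b in union:
            pb = p.mass(b)
            if pb == 0.0:
                continue
            qb = q.mass(b)
            if qb == 0.0:
                raise ValueError(f"Q is zero at bin {b} where P is positive")
            total += pb * math.log(pb / qb)
        rest = p.n_support_bins - len(union)
        pf, qf = p.floor, q.floor
        if rest and pf > 0.0:
            if qf == 0.0:
                raise ValueError("Q is zero on unoccupied support where P has smoothing mass")
            total += rest * pf * math.log(pf / qf)
        return total
    if isinstance(p, JointDegreeDistribution) or isinstance(q, JointDegreeDistribution):
        raise TypeError("cannot mix a degree distribution with a dense array")
    return _kld_dense(np.asarray(p, dtype=float), np.asarray(q, dtype=float))


def jsd(p: Distribution, q: Distribution) -> float:
    """Jensen-Shannon divergence 0.5*KLD(P||M) + 0.5*KLD(Q||M), M = (P+Q)/2.

    Symmetric, zero iff the distributions coincide, bounded by ln 2 (nats).
    Sparse degree distributions are evaluated over occupied bins only: bins
    empty in both distributions carry equal smoothing floors and contribute
    nothing to either KLD term.
    """
    if isinstance(p, JointDegreeDistribution) and isinstance(q, JointDegreeDistribution):
        _check_same_support(p, q)
        t = 0.0
        for b in set(p.counts) | set(q.counts):
            pb, qb = p.mass(b), q.mass(b)
            m = 0.5 * (pb + qb)
            if pb > 0.0:
                t += pb * math.log(pb / m)
            if qb > 0.0:
                t += qb * math.log(qb / m)
        rest = p.n_support_bins - (len(set(p.counts) | set(q.counts)))
        pf, qf = p.floor, q.floor
        if rest and (pf > 0.0 or qf > 0.0):
            mf = 0.5 * (pf + qf)
            if pf > 0.0:
                t += rest * pf * math.log(pf / mf)
            if qf > 0.0:
                t += rest * qf * math.log(qf / mf)
        return max(0.5 * t, 0.0)
    pa, qa = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError(f"mismatched supports: shapes {pa.shape} vs {qa.shape}")
    m = 0.5 * (pa + qa)
    return max(0.5 * _kld_dense(pa, m) + 0.5 * _kld_dense(qa, m), 0.0)


# ---------------------------------------------------------------------------
# k-order irreversibility
# ---------------------------------------------------------------------------

def korder_irreversibility(
    degree_tables: Sequence[DegreeTable],
    tuple_layers: Sequence[int],
    dmax: Optional[int] = None,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> float:
    """JSD between the pooled in- and out-degree distributions of a tuple."""
    p_in = estimate_joint_distribution(
        degree_tables, tuple_layers, "in", dmax=dmax,
        smoothing=smoothing, exclude_boundary=exclude_boundary,
    )
    p_out = estimate_joint_distribution(
        degree_tables, tuple_layers, "out", dmax=dmax,
        smoothing=smoothing, exclude_boundary=exclude_boundary,
    )
    return jsd(p_in, p_out)


# ---------------------------------------------------------------------------
# level sweeps & annotation
# ---------------------------------------------------------------------------

@dataclass
class IrreversibilityReport:
    """All C(N, k) tuple irreversibilities at one level, with annotations.

    ``annotations`` maps each tuple to a signed integer: +m means the tuple
    sits at least m standard deviations above the level mean (printed as m
    stars), -m at least m below (m daggers), 0 within one SD.
    """

    level_k: int
    entries: List[Tuple[Tuple[int, ...], float]]
    level_mean: float
    level_sd: float
    annotations: Dict[Tuple[int, ...], int]
    dmax_used: int
    n_samples: int
    sd_is_zero: bool = False
    layer_names: Optional[List[str]] = None

    def sigma(self, tuple_layers: Sequence[int]) -> float:
        key = tuple(sorted(int(l) for l in tuple_layers))
        for t, s in self.entries:
            if t == key:
                return s
        raise KeyError(f"tuple {key} not in level-{self.level_k} report")

    def to_frame(self):
        import pandas as pd

        names = self.layer_names
        rows = []
        for t, s in self.entries:
            label = "|".join(names[l] for l in t) if names else "|".join(map(str, t))
            z = 0.0 if self.sd_is_zero else (s - self.level_mean) / self.level_sd
            a = self.annotations.get(t, 0)
            symbol = "*" * a if a > 0 else "†" * (-a)
            rows.append({"tuple": label, "k": self.level_k, "sigma_nats": s,
                         "z": z, "annotation": symbol})
        return pd.DataFrame(rows)

    def export(self, path, sep: str = ",") -> None:
        """Delimited report table plus a JSON sidecar with run metadata."""
        self.to_frame().to_csv(path, sep=sep, index=False)
        meta = {
            "level_k": self.level_k,
            "level_mean": self.level_mean,
            "level_sd": self.level_sd,
            "dmax_used": self.dmax_used,
            "n_samples": self.n_samples,
            "sd_is_zero": self.sd_is_zero,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def annotate_significance(report: IrreversibilityReport) -> IrreversibilityReport:
    """Attach star/dagger counts: floor(|z|) at |z| >= 1, z from the population
    SD of sigma across tuples at the level. A zero SD yields no annotations and
    sets ``sd_is_zero``."""
    sigmas = np.array([s for _, s in report.entries])
    mean = float(sigmas.mean())
    sd = float(sigmas.std(ddof=0))
    ann: Dict[Tuple[int, ...], int] = {}
    if sd == 0.0:
        ann = {t: 0 for t, _ in report.entries}
        return replace(report, level_mean=mean, level_sd=sd,
                       annotations=ann, sd_is_zero=True)
    for t, s in report.entries:
        z = (s - mean) / sd
        if z >= 1.0:
            ann[t] = int(math.floor(z))
        elif z <= -1.0:
            ann[t] = -int(math.floor(-z))
        else:
            ann[t] = 0
    return replace(report, level_mean=mean, level_sd=sd,
                   annotations=ann, sd_is_zero=False)


def sweep_level(
    degree_tables: Sequence[DegreeTable],
    k: int,
    dmax: Optional[int] = None,
    dmax_cap: Optional[int] = 75,
    smoothing: bool = True,
    exclude_boundary: bool = True,
    layer_names: Optional[List[str]] = None,
) -> IrreversibilityReport:
    """sigma for every k-tuple of layers, with level statistics and annotations.

    A single dmax (observed maximum directed degree, capped at ``dmax_cap``)
    is shared by every tuple at the level so their divergences are directly
    comparable.
    """
    if not degree_tables:
        raise ValueError("need at least one degree table")
    n_layers = degree_tables[0].n_layers
    if not 1 <= k <= n_layers:
        raise ValueError(f"level k={k} out of range for {n_layers} layers")
    if dmax is None:
        dmax = effective_dmax(degree_tables, cap=dmax_cap,
                              exclude_boundary=exclude_boundary)
    entries = []
    for combo in combinations(range(n_layers), k):
        s = korder_irreversibility(
            degree_tables, combo, dmax=dmax,
            smoothing=smoothing, exclude_boundary=exclude_boundary,
        )
        entries.append((combo, s))
    report = IrreversibilityReport(
        level_k=k,
        entries=entries,
        level_mean=float(np.mean([s for _, s in entries])),
        level_sd=float(np.std([s for _, s in entries], ddof=0)),
        annotations={},
        dmax_used=int(dmax),
        n_samples=len(degree_tables),
        layer_names=layer_names,
    )
    return annotate_significance(report)


def sigma_table(
    degree_tables: Sequence[DegreeTable],
    levels: Sequence[int],
    dmax: Optional[int] = None,
    dmax_cap: Optional[int] = 75,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> Dict[Tuple[int, ...], float]:
    """sigma for every tuple at each requested level, under one shared dmax."""
    if dmax is None:
        dmax = effective_dmax(degree_tables, cap=dmax_cap,
                              exclude_boundary=exclude_boundary)
    out: Dict[Tuple[int, ...], float] = {}
    n_layers = degree_tables[0].n_layers
    for k in levels:
        for combo in combinations(range(n_layers), k):
            out[combo] = korder_irreversibility(
                degree_tables, combo, dmax=dmax,
                smoothing=smoothing, exclude_boundary=exclude_boundary,
            )
    return out


# ---------------------------------------------------------------------------
# unique contributions
# ---------------------------------------------------------------------------

@dataclass
class UniqueContributionTable:
    """Recursive decomposition eta of per-tuple irreversibility.

    eta of a singleton equals its sigma; higher-order eta subtracts every
    proper nonempty sub-tuple's eta and may be negative.
    """

    eta: Dict[Tuple[int, ...], float]
    max_level: int

    def reconstruct(self, tuple_layers: Sequence[int]) -> float:
        """Sum of eta over all nonempty subsets — recovers sigma of the tuple."""
        key = tuple(sorted(int(l) for l in tuple_layers))
        total = 0.0
        for r in range(1, len(key) + 1):
            for sub in combinations(key, r):
                total += self.eta[sub]
        return total


def unique_contributions(
    sigma_by_tuple: Mapping[Tuple[int, ...], float],
) -> UniqueContributionTable:
    """Compute eta bottom-up by level from a complete sigma table.

    Requires sigma for every nonempty subset of every tuple present; a missing
    subset is a domain error naming it.
    """
    table = {tuple(sorted(t)): float(s) for t, s in sigma_by_tuple.items()}
    eta: Dict[Tuple[int, ...], float] = {}
    for key in sorted(table, key=len):
        acc = 0.0
        for r in range(1, len(key)):
            for sub in combinations(key, r):
                if sub not in table:
                    raise ValueError(
                        f"sigma missing for subset {sub} of tuple {key}"
                    )
                acc += eta[sub]
        eta[key] = table[key] - acc
    max_level = max((len(t) for t in eta), default=0)
    return UniqueContributionTable(eta=eta, max_level=max_level)
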