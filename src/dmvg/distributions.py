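"""Joint in/out degree distributions of layer tuples, pooled across samples.

For a k-tuple of layers the empirical joint distribution assigns to each
degree vector ``(d_1, .., d_k)`` the fraction of pooled nodes whose directed
degree in layer ``n_l`` equals ``d_l`` for every ``l`` simultaneously. Each
sample's DMVG contributes its nodes to the pool (cohort-level estimation).

Finite pooling leaves empty bins, which break Kullback-Leibler terms; the
estimator therefore averages the empirical distribution with a uniform prior
over the truncated support ``{1..dmax}^k``:

    P(d_1..d_k) = 1/2 * N/M + 1/2 * dmax^{-k},

where ``N`` counts matching nodes and ``M`` is the pooled node count. Degrees
above ``dmax`` are clipped into the top bin so normalisation over the
truncated support is preserved.

Distributions are stored sparsely: only occupied bins carry explicit counts,
the smoothing floor on the remaining support is implicit. Downstream
divergence code handles the implicit floor analytically, which is what makes
5-tuples at dmax = 75 tractable (75^5 bins are never materialised).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .visibility import DegreeTable

__all__ = [
    "JointDegreeDistribution",
    "estimate_joint_distribution",
    "marginalize",
    "effective_dmax",
]

DegreeVector = Tuple[int, ...]


@dataclass
class JointDegreeDistribution:
    """Sparse probability mass over k-dimensional degree vectors.

    ``counts`` maps occupied degree vectors to pooled node counts; the
    probability of a bin follows from the smoothing rule. ``support_min`` is 1
    on the standard (boundary-excluded) support and 0 when boundary nodes with
    zero degree are pooled in.
    """

    tuple_layers: Tuple[int, ...]
    direction: str  # "in" or "out"
    dmax: int
    counts: Dict[DegreeVector, int]
    smoothed: bool
    n_nodes_pooled: int
    n_samples: int
    support_min: int = 1

    def __post_init__(self) -> None:
        self.tuple_layers = tuple(int(l) for l in self.tuple_layers)
        if self.direction not in ("in", "out"):
            raise ValueError(f"direction must be 'in' or 'out', got {self.direction!r}")
        if len(set(self.tuple_layers)) != len(self.tuple_layers):
            raise ValueError("duplicate layer in tuple")
        if self.dmax < 1:
            raise ValueError("dmax must be >= 1")

    @property
    def k(self) -> int:
        return len(self.tuple_layers)

    @property
    def n_support_bins(self) -> int:
        return (self.dmax - self.support_min + 1) ** self.k

    @property
    def floor(self) -> float:
        """Implicit uniform-prior mass on every support bin (0 if unsmoothed)."""
        return 0.5 / self.n_support_bins if self.smoothed else 0.0

    def mass(self, bin_: Sequence[int]) -> float:
        """Probability of one degree vector (including the smoothing floor)."""
        c = self.counts.get(tuple(int(d) for d in bin_), 0)
        empirical = c / self.n_nodes_pooled
        return 0.5 * empirical + self.floor if self.smoothed else empirical

    def occupied(self) -> Iterable[DegreeVector]:
        return self.counts.keys()

    def total_mass(self) -> float:
        """Total probability over the full truncated support."""
        occ = sum(self.mass(b) for b in self.counts)
        rest = self.n_support_bins - len(self.counts)
        return occ + rest * self.floor

    def to_frame(self):
        """Occupied bins as a DataFrame: one degree column per layer + probability."""
        import pandas as pd

        rows = sorted(self.counts)
        cols = {f"d{l}": [r[i] for r in rows] for i, l in enumerate(self.tuple_layers)}
        cols["probability"] = [self.mass(r) for r in rows]
        return pd.DataFrame(cols)

    def metadata(self) -> dict:
        return {
            "tuple_layers": list(self.tuple_layers),
            "direction": self.direction,
            "dmax": int(self.dmax),
            "support_min": int(self.support_min),
            "smoothed": bool(self.smoothed),
            "n_nodes_pooled": int(self.n_nodes_pooled),
            "n_samples": int(self.n_samples),
        }

    def export(self, path, sep: str = ",") -> None:
        """Write occupied bins as delimited text with a JSON metadata sidecar."""
        self.to_frame().to_csv(path, sep=sep, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _check_tables(degree_tables: Sequence[DegreeTable]) -> int:
    if not degree_tables:
        raise ValueError("need at least one degree table")
    n_layers = degree_tables[0].n_layers
    for t in degree_tables:
        if t.n_layers != n_layers:
            raise ValueError("degree tables disagree on the number of layers")
    return n_layers


def _pooled_degrees(
    degree_tables: Sequence[DegreeTable],
    layers: Sequence[int],
    direction: str,
    exclude_boundary: bool,
) -> np.ndarray:
    """Stack the (node, k) degree matrix pooled over samples."""
    idx = np.asarray(layers, dtype=int)
    blocks = []
    for t in degree_tables:
        mat = t.din if direction == "in" else t.dout
        sel = mat[idx, 1:-1] if exclude_boundary else mat[idx, :]
        blocks.append(sel.T)
    return np.concatenate(blocks, axis=0)


def effective_dmax(
    degree_tables: Sequence[DegreeTable],
    cap: Optional[int] = None,
    exclude_boundary: bool = True,
) -> int:
    """Maximum observed directed degree across layers, nodes, samples and both
    directions, optionally capped.

    A single dmax shared by the in- and out-distributions (and across tuples)
    keeps all supports identical, which a well-defined JSD requires.
    """
    _check_tables(degree_tables)
    observed = 0
    for t in degree_tables:
        sl = slice(1, -1) if exclude_boundary else slice(None)
        observed = max(observed, int(t.din[:, sl].max()), int(t.dout[:, sl].max()))
    return min(observed, cap) if cap is not None else observed


def estimate_joint_distribution(
    degree_tables: Sequence[DegreeTable],
    tuple_layers: Sequence[int],
    direction: str,
    dmax: Optional[int] = None,
    smoothing: bool = True,
    exclude_boundary: bool = True,
) -> JointDegreeDistribution:
    """Estimate the joint degree distribution of a layer tuple by node counting.

    Nodes are pooled over all samples; by default the first and last node of
    each sample are excluded from both directions so every pooled degree is at
    least 1 and the in/out distributions share the same pool size M. Degrees
    above ``dmax`` are clipped into the top bin. With ``smoothing`` the
    empirical distribution is averaged with the uniform prior on the support.
    """
    n_layers = _check_tables(degree_tables)
    layers = tuple(int(l) for l in tuple_layers)
    if not layers:
        raise ValueError("tuple_layers must be nonempty")
    if len(set(layers)) != len(layers):
        raise ValueError(f"duplicate layer in tuple {layers}")
    if any(l < 0 or l >= n_layers for l in layers):
        raise ValueError(f"layer index out of range in {layers}")
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")

    if dmax is None:
        dmax = effective_dmax(degree_tables, exclude_boundary=exclude_boundary)
        if dmax < 1:
            raise ValueError("cannot infer dmax: no positive degrees observed")
    if dmax < 1:
        raise ValueError("dmax must be >= 1")

    support_min = 1 if exclude_boundary else 0
    mat = _pooled_degrees(degree_tables, layers, direction, exclude_boundary)
    m_pooled = mat.shape[0]
    if m_pooled == 0:
        raise ValueError("no nodes left after boundary exclusion")
    clipped = np.clip(mat, support_min, dmax)
    # radix-encode degree vectors to 1-D codes: much faster to count than
    # row-wise unique, and lossless for dmax^k up to ~2^63
    k = len(layers)
    radix = dmax + 1
    weights = radix ** np.arange(k, dtype=np.int64)
    codes = clipped.astype(np.int64) @ weights
    uniq, cnt = np.unique(codes, return_counts=True)
    counts = {}
    for code, c in zip(uniq.tolist(), cnt.tolist()):
        counts[tuple(int(code // radix**i) % radix for i in range(k))] = int(c)

    return JointDegreeDistribution(
        tuple_layers=layers,
        direction=direction,
        dmax=int(dmax),
        counts=counts,
        smoothed=bool(smoothing),
        n_nodes_pooled=int(m_pooled),
        n_samples=len(degree_tables),
        support_min=support_min,
    )


def marginalize(
    dist: JointDegreeDistribution, keep_layers: Sequence[int]
) -> JointDegreeDistribution:
    """Marginal distribution over a sublist of the tuple's layers.

    Sums counts over the dropped coordinates. Because the uniform prior
    marginalises to the uniform prior on the smaller support, marginalising a
    smoothed joint agrees exactly with directly estimating the smoothed
    marginal; for unsmoothed distributions the agreement is exact by counting.
    """
    keep = tuple(int(l) for l in keep_layers)
    if not keep:
        raise ValueError("keep_layers must be nonempty")
    if not set(keep) <= set(dist.tuple_layers):
        raise ValueError(
            f"keep_layers {keep} not a subset of tuple {dist.tuple_layers}"
        )
    pos = [dist.tuple_layers.index(l) for l in keep]
    new_counts: Dict[DegreeVector, int] = {}
    for bin_, c in dist.counts.items():
        key = tuple(bin_[p] for p in pos)
        new_counts[key] = new_counts.get(key, 0) + c
    return JointDegreeDistribution(
        tuple_layers=keep,
        direction=dist.direction,
        dmax=dist.dmax,
        counts=new_counts,
        smoothed=dist.smoothed,
        n_nodes_pooled=dist.n_nodes_pooled,
        n_samples=dist.n_samples,
        support_min=dist.support_min,
    )
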