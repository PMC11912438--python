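"""Synthetic multivariate panels with known reversibility structure.

Real use targets source-localised neural recordings (many participants, many
trials, a handful of regions), but validating an irreversibility estimator
needs ground truth. Three generator families span the reversible-to-
irreversible axis:

* iid Gaussian noise — exactly time-reversible (exchangeable), the null
  baseline;
* multivariate Ornstein-Uhlenbeck — a linear Gaussian diffusion that is
  reversible when the drift is symmetric (equilibrium, detailed balance) and
  irreversible when it is not; an antisymmetric drift perturbation of
  strength epsilon gives a one-parameter family of increasingly
  nonequilibrium dynamics with cross-channel coupling;
* logistic map — deterministic dissipative chaos, strongly irreversible, the
  classic positive control in visibility-graph irreversibility work.

``gen_cohort`` emulates a pooled study: participants x trials panels with
deterministic per-trial seed streams. The default cohort mirrors a 6-region,
51-participant, 15-trial recording with trials of a few thousand equispaced
points, mixing near-reversible reciprocally coupled channels with strongly
driven ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .panel import TimeSeriesPanel

__all__ = [
    "CohortSpec",
    "gen_iid_gaussian",
    "gen_asymmetric_ou",
    "gen_logistic_map_panel",
    "gen_cohort",
    "rotational_drift",
    "hierarchical_drift",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_iid_gaussian(n_variables: int, T: int, seed=0) -> TimeSeriesPanel:
    """Independent standard-normal values: a stationary, exactly reversible panel."""
    if T < 3:
        raise ValueError("T must be >= 3")
    values = _rng(seed).standard_normal((n_variables, T))
    return TimeSeriesPanel(values=values, sample_id="iid")


def rotational_drift(n_variables: int, epsilon: float) -> np.ndarray:
    """Drift -I + epsilon*K with K antisymmetric (nearest-neighbour rotation).

    K couples consecutive variables as a solenoidal flow: K[i, i+1] = 1,
    K[i+1, i] = -1. At epsilon = 0 the process is in equilibrium (reversible);
    increasing epsilon strengthens the probability current without ever
    destabilising the drift (the antisymmetric part only shifts eigenvalues
    along the imaginary axis).
    """
    A = -np.eye(n_variables)
    for i in range(n_variables - 1):
        A[i, i + 1] += epsilon
        A[i + 1, i] -= epsilon
    return A


def hierarchical_drift(n_variables: int = 6, strength: float = 0.8) -> np.ndarray:
    """Asymmetric feed-forward drift emulating a hierarchy of driven channels.

    The first two channels relax independently apart from a weak reciprocal
    (reversible) coupling; later channels are driven one-way by earlier ones,
    so the cross-channel coupling is strongly asymmetric and the stationary
    dynamics are far from equilibrium in the driven channels.
    """
    A = -np.eye(n_variables)
    if n_variables >= 2:
        A[0, 1] += 0.2
        A[1, 0] += 0.2
    for i in range(2, n_variables):
        A[i, i - 2] += strength
        if i - 1 >= 2:
            A[i, i - 1] += 0.5 * strength
    return A


def gen_asymmetric_ou(
    n_variables: int,
    T: int,
    dt: float = 0.05,
    coupling: Optional[np.ndarray] = None,
    noise: float = 1.0,
    seed=0,
) -> TimeSeriesPanel:
    """Euler-Maruyama sample of a multivariate Ornstein-Uhlenbeck process.

    dX = A X dt + noise dW with drift matrix ``A`` (``coupling``; default -I).
    The drift must be stable (all eigenvalue real parts negative). A burn-in
    of ten relaxation times is discarded so sampling starts near stationarity.
    The process is time-reversible iff the stationary dynamics satisfy
    detailed balance, which for isotropic noise holds exactly when ``A`` is
    symmetric; any asymmetric part drives a stationary probability current.
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = -np.eye(n_variables) if coupling is None else np.asarray(coupling, dtype=float)
    if A.shape != (n_variables, n_variables):
        raise ValueError(f"coupling must be {n_variables}x{n_variables}")
    eig = np.linalg.eigvals(A)
    max_re = float(np.max(eig.real))
    if max_re >= 0:
        raise ValueError(f"unstable drift: max eigenvalue real part {max_re:.3g} >= 0")

    relax = 1.0 / abs(max_re)
    burn = int(np.ceil(10.0 * relax / dt))
    rng = _rng(seed)
    x = np.zeros(n_variables)
    sq = noise * np.sqrt(dt)
    out = np.empty((n_variables, T))
    for step in range(burn + T):
        x = x + dt * (A @ x) + sq * rng.standard_normal(n_variables)
        if step >= burn:
            out[:, step - burn] = x
    return TimeSeriesPanel(values=out, sample_id="ou")


def gen_logistic_map_panel(
    n_variables: int, T: int, r: float = 4.0, seed=0
) -> TimeSeriesPanel:
    """Independent logistic-map trajectories x <- r x (1 - x).

    For r in the chaotic band the map is dissipative and strongly
    time-irreversible, making it the standard positive control. Initial
    conditions are uniform on (0.1, 0.9); a 1000-step transient is discarded.
    """
    if not 3.57 < r <= 4.0:
        raise ValueError("r must lie in the chaotic band (3.57, 4]")
    if T < 3:
        raise ValueError("T must be >= 3")
    rng = _rng(seed)
    x = rng.uniform(0.1, 0.9, size=n_variables)
    for _ in range(1000):
        x = r * x * (1.0 - x)
    out = np.empty((n_variables, T))
    for i in range(T):
        x = r * x * (1.0 - x)
        out[:, i] = x
    return TimeSeriesPanel(values=out, sample_id="logistic")


_PROCESSES = {
    "iid_gaussian": gen_iid_gaussian,
    "asymmetric_ou": gen_asymmetric_ou,
    "logistic_map": gen_logistic_map_panel,
}


@dataclass
class CohortSpec:
    """Shape and dynamics of a synthetic cohort.

    Defaults emulate a 6-region, 51-participant, 15-trial recording with
    trials of 4500 equispaced points, generated by the hierarchical
    asymmetric OU process (a mix of near-reversible and strongly driven
    channels).
    """

    n_variables: int = 6
    n_participants: int = 51
    n_trials: int = 15
    trial_length: int = 4500
    process: str = "asymmetric_ou"
    params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_variables, self.n_participants, self.n_trials) < 1:
            raise ValueError("all cohort counts must be >= 1")
        if self.trial_length < 3:
            raise ValueError("trial_length must be >= 3")
        if self.process not in _PROCESSES:
            raise ValueError(
                f"unknown process {self.process!r}; choose from {sorted(_PROCESSES)}"
            )


def gen_cohort(spec: CohortSpec) -> List[TimeSeriesPanel]:
    """Generate participant x trial panels with independent per-trial streams.

    Trial (p, t) uses the seed stream SeedSequence([seed, p, t]), so any
    subset of the cohort is reproducible independently of generation order.
    """
    params = dict(spec.params)
    if spec.process == "asymmetric_ou" and "coupling" not in params:
        params["coupling"] = hierarchical_drift(spec.n_variables)
    gen = _PROCESSES[spec.process]
    panels = []
    for p in range(spec.n_participants):
        for t in range(spec.n_trials):
            seed = np.random.SeedSequence([int(spec.seed), p, t])
            panel = gen(spec.n_variables, spec.trial_length, seed=seed, **params)
            panel.sample_id = f"p{p:03d}/t{t:03d}"
            panel.participant_id = f"p{p:03d}"
            panels.append(panel)
    return panels
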