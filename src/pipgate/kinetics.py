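"""Ligand-dependent aggregated Markov gating schemes and their exact properties.

A channel is modelled as a continuous-time Markov chain over a small set of
conductance states, each labelled ``closed`` or ``open``.  Transition rates are
either concentration-independent (order 0, units 1/ms) or proportional to the
ligand concentration L (order 1, units 1/ms/uM), so the effective rate at
concentration L is ``coefficient * L**ligand_order``.

Two canonical schemes are provided:

* a two-state pseudo-first-order scheme  C <-> O  in which binding of a single
  ligand opens the channel (opening rate k_on*L, closing rate k_off), and
* a sequential three-state chain  C <-> O1 <-> O2  in which a second ligand
  binding stabilises the open channel; both forward rates scale with L.

All stationary quantities (open probability, mean open/closed class sojourn
times, dose-response curves, local Hill slopes) are computed exactly from the
generator matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CLOSED = "closed"
OPEN = "open"

__all__ = [
    "LigandRate",
    "GatingScheme",
    "SojournStats",
    "two_state_scheme",
    "sequential_open_scheme",
    "generator_matrix",
    "stationary_distribution",
    "stationary_open_probability",
    "mean_sojourn_times",
    "dose_response_curve",
    "effective_hill_slope",
]


@dataclass(frozen=True)
class LigandRate:
    """A transition rate, optionally first order in ligand concentration.

    coefficient : rate in 1/ms (order 0) or 1/ms/uM (order 1).
    ligand_order : 0 for concentration-independent rates, 1 for binding steps.
    """

    coefficient: float
    ligand_order: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient) or self.coefficient < 0:
            raise ValueError(f"rate coefficient must be >= 0, got {self.coefficient}")
        if self.ligand_order not in (0, 1):
            raise ValueError(f"ligand_order must be 0 or 1, got {self.ligand_order}")

    def at(self, L: float) -> float:
        """Effective rate (1/ms) at ligand concentration ``L`` (uM)."""
        if L < 0:
            raise ValueError(f"ligand concentration must be >= 0, got {L}")
        return self.coefficient * (L if self.ligand_order == 1 else 1.0)


@dataclass(frozen=True)
class SojournStats:
    """Mean dwell times (ms) in the aggregated open and closed classes."""

    mean_open: float
    mean_closed: float


@dataclass
class GatingScheme:
    """A small CTMC gating scheme with open/closed state classes.

    states : ordered list of (label, conductance_class) pairs.
    transitions : mapping (i, j) of state indices -> LigandRate, i != j.
    """

    states: list[tuple[str, str]]
    transitions: dict[tuple[int, int], LigandRate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        classes = {c for _, c in self.states}
        for _, c in self.states:
            if c not in (CLOSED, OPEN):
                raise ValueError(f"conductance class must be 'closed' or 'open', got {c!r}")
        if CLOSED not in classes or OPEN not in classes:
            raise ValueError("scheme needs at least one closed and one open state")
        n = len(self.states)
        for (i, j), rate in self.transitions.items():
            if i == j:
                raise ValueError("self-transitions are not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"transition ({i},{j}) references unknown state")
            if not isinstance(rate, LigandRate):
                raise TypeError("transition rates must be LigandRate instances")
        if not self._connected():
            raise ValueError("transition graph must be connected")

    def _connected(self) -> bool:
        n = len(self.states)
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in self.transitions:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_mask(self) -> np.ndarray:
        return np.array([c == OPEN for _, c in self.states])

    # --- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "states": [{"label": lab, "class": cls} for lab, cls in self.states],
            "transitions": [
                {"from": i, "to": j, "coefficient": r.coefficient, "ligand_order": r.ligand_order}
                for (i, j), r in sorted(self.transitions.items())
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GatingScheme":
        doc = json.loads(text)
        states = [(s["label"], s["class"]) for s in doc["states"]]
        transitions = {
            (t["from"], t["to"]): LigandRate(t["coefficient"], t["ligand_order"])
            for t in doc["transitions"]
        }
        return cls(states=states, transitions=transitions)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def two_state_scheme(k_on: float, k_off: float) -> GatingScheme:
    """Pseudo-first-order two-state scheme C <-> O.

    Opening rate is ``k_on * L`` (k_on in 1/ms/uM); closing rate ``k_off``
    (1/ms) is concentration independent.
    """
    _require_positive(k_on=k_on, k_off=k_off)
    return GatingScheme(
        states=[("C", CLOSED), ("O", OPEN)],
        transitions={
            (0, 1): LigandRate(k_on, 1),
            (1, 0): LigandRate(k_off, 0),
        },
    )


def sequential_open_scheme(k_on1: float, k_off1: float, k_on2: float, k_off2: float) -> GatingScheme:
    """Sequential binding chain C <-> O1 <-> O2 with two open states.

    Both forward rates are first order in ligand (``k_on1*L``, ``k_on2*L``);
    a second bound ligand stabilises the open channel in O2.  Backward rates
    ``k_off1`` (O1 -> C) and ``k_off2`` (O2 -> O1) are fixed.
    """
    _require_positive(k_on1=k_on1, k_off1=k_off1, k_on2=k_on2, k_off2=k_off2)
    return GatingScheme(
        states=[("C", CLOSED), ("O1", OPEN), ("O2", OPEN)],
        transitions={
            (0, 1): LigandRate(k_on1, 1),
            (1, 0): LigandRate(k_off1, 0),
            (1, 2): LigandRate(k_on2, 1),
            (2, 1): LigandRate(k_off2, 0),
        },
    )


def generator_matrix(scheme: GatingScheme, L: float) -> np.ndarray:
    """Infinitesimal generator Q (1/ms) at ligand concentration L (uM).

    Off-diagonal entries are the effective rates; rows sum to zero.
    """
    if L < 0:
        raise ValueError(f"ligand concentration must be >= 0, got {L}")
    n = scheme.n_states
    Q = np.zeros((n, n))
    for (i, j), rate in scheme.transitions.items():
        Q[i, j] = rate.at(L)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(scheme: GatingScheme, L: float) -> np.ndarray:
    """Stationary probability vector pi with pi @ Q = 0, sum(pi) = 1."""
    Q = generator_matrix(scheme, L)
    n = scheme.n_states
    # replace one balance equation with the normalisation constraint
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_open_probability(scheme: GatingScheme, L: float) -> float:
    """Equilibrium open probability Po at concentration L.

    L = 0 is a defined degenerate case: with all binding steps first order in
    ligand the closed state is absorbing and Po = 0.
    """
    if L < 0:
        raise ValueError(f"ligand concentration must be >= 0, got {L}")
    if L == 0:
        return 0.0
    pi = stationary_distribution(scheme, L)
    return float(pi[scheme.open_mask].sum())


def mean_sojourn_times(scheme: GatingScheme, L: float) -> SojournStats:
    """Mean aggregated open- and closed-class dwell times (ms) at L > 0.

    Absorption analysis: a class sojourn starts in an entry state drawn from
    the stationary entry flux and ends on the first jump out of the class, so
    the mean is the entry-weighted solution of the class sub-generator system
    -Q_AA t = 1.  (Equivalent to the alternating-renewal identity
    mean = occupancy / exit flux, but numerically stable when the occupancies
    are very lopsided.)
    """
    if L <= 0:
        raise ValueError("sojourn means require L > 0 (closed sojourn diverges at L = 0)")
    Q = generator_matrix(scheme, L)
    pi = stationary_distribution(scheme, L)

    def class_mean(mask: np.ndarray) -> float:
        inside = np.nonzero(mask)[0]
        outside = np.nonzero(~mask)[0]
        entry = np.array([pi[outside] @ Q[np.ix_(outside, [j])].ravel() for j in inside])
        if entry.sum() <= 0:
            raise ValueError("class is unreachable; scheme not irreducible at this L")
        entry = entry / entry.sum()
        t = np.linalg.solve(-Q[np.ix_(inside, inside)], np.ones(inside.size))
        return float(entry @ t)

    return SojournStats(
        mean_open=class_mean(scheme.open_mask),
        mean_closed=class_mean(~scheme.open_mask),
    )


def dose_response_curve(scheme: GatingScheme, L_grid) -> list[tuple[float, float]]:
    """Exact (L, Po) pairs over a concentration grid (uM)."""
    L_grid = np.asarray(L_grid, dtype=float)
    if L_grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    return [(float(L), stationary_open_probability(scheme, float(L))) for L in L_grid]


def effective_hill_slope(scheme: GatingScheme, L: float, rel_step: float = 1e-3) -> float:
    """Local logistic slope d ln(Po/(1-Po)) / d ln L at concentration L.

    Computed by central difference on a log-spaced step.  For the sequential
    two-binding-site chain this slope lies strictly between 1 and 2 for all
    finite L, so a fitted Hill coefficient above 2 cannot be produced by that
    scheme.
    """
    po = stationary_open_probability(scheme, L)
    if po <= 0.0 or po >= 1.0:
        raise ValueError("effective Hill slope undefined where Po is 0 or 1")
    h = 1.0 + rel_step

    def log_odds(x: float) -> float:
        p = stationary_open_probability(scheme, x)
        return np.log(p / (1.0 - p))

    return float((log_odds(L * h) - log_odds(L / h)) / (2.0 * np.log(h)))
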