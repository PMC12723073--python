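"""Weighted network parameters of a dense connectivity graph.

Three scalars summarize a symmetric, nonnegative, zero-diagonal weight matrix
W of N nodes:

* connectivity strength  CS  = mean off-diagonal weight,
  ``sum_{i<j} w_ij / (N (N-1) / 2)`` -- overall coupling level;
* clustering coefficient ClC = ``(1/N) sum_i 2 t_i / (s_i (s_i - 1))`` with
  ``t_i = (1/2) sum_{j != i} sum_{h != i,j} (w_ij w_ih w_jh)^(1/3)`` the
  geometric-mean triangle intensity and ``s_i = sum_j w_ij`` the node
  strength -- segregation;
* characteristic path length PL = mean shortest-path distance over ordered
  node pairs with edge distance ``d_ij = 1 / w_ij`` -- integration.

The strength-normalized ClC can exceed 1 and its denominator degenerates when
any ``s_i <= 1``; dense many-channel phase-locking graphs (the intended
regime) sit far from that boundary, but small or weakly coupled graphs can
hit it, so the guard raises by default and can be relaxed to NaN for batch
pipelines.  A degree-based denominator ``(N-1)(N-2)`` is available as an
alternative convention, as is the ``1 - w`` distance map for PL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphMetrics",
    "DegenerateStrengthError",
    "connectivity_strength",
    "clustering_coefficient",
    "characteristic_path_length",
    "metrics_for",
]


class DegenerateStrengthError(ValueError):
    """A node strength <= 1 makes the strength-normalized ClC undefined."""

    def __init__(self, node: int, strength: float):
        super().__init__(
            f"node {node} has strength {strength:.4g} <= 1: "
            "strength-normalized clustering coefficient is degenerate"
        )
        self.node = node
        self.strength = strength


@dataclass(frozen=True)
class GraphMetrics:
    cs: float
    clc: float
    pl: float
    n_nodes: int


def _validate(w: np.ndarray, min_nodes: int = 2) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    n = w.shape[0]
    if n < min_nodes:
        raise ValueError(f"need at least {min_nodes} nodes")
    if not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero")
    return w


def connectivity_strength(weights) -> float:
    """Mean off-diagonal weight."""
    w = _validate(weights)
    n = w.shape[0]
    return float(w.sum() / (n * (n - 1)))


def clustering_coefficient(
    weights, denominator: str = "strength", strength_policy: str = "error"
) -> float:
    """Weighted clustering coefficient with geometric-mean triangle intensity.

    ``denominator='strength'`` normalizes node i by ``s_i (s_i - 1)`` (node
    strength); ``'degree'`` uses the dense-graph degree ``(N-1)(N-2)``.
    ``strength_policy`` controls the ``s_i <= 1`` guard: ``'error'`` raises
    :class:`DegenerateStrengthError`, ``'nan'`` returns NaN.
    """
    w = _validate(weights, min_nodes=3)
    n = w.shape[0]
    w3 = np.cbrt(w)
    t = np.einsum("ij,jh,hi->i", w3, w3, w3) / 2.0
    if denominator == "degree":
        denom = float((n - 1) * (n - 2))
        return float(np.mean(2.0 * t / denom))
    if denominator != "strength":
        raise ValueError("denominator must be 'strength' or 'degree'")
    s = w.sum(axis=1)
    bad = np.flatnonzero(s <= 1.0)
    if bad.size:
        if strength_policy == "nan":
            return float("nan")
        raise DegenerateStrengthError(int(bad[0]), float(s[bad[0]]))
    return float(np.mean(2.0 * t / (s * (s - 1.0))))


def characteristic_path_length(
    weights, distance: str = "inverse", weight_floor: float = 0.0
) -> float:
    """Mean shortest-path distance over ordered node pairs.

    Edge distances are ``1/w`` (default) or ``1 - w``; zero weights yield no
    edge and raise on disconnection unless ``weight_floor > 0`` replaces them.
    """
    w = _validate(weights)
    if weight_floor > 0:
        w = np.where((w > 0) | np.eye(w.shape[0], dtype=bool), w, weight_floor)
    off = ~np.eye(w.shape[0], dtype=bool)
    with np.errstate(divide="ignore"):
        if distance == "inverse":
            d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif distance == "one_minus":
            # clamp so a full weight (w=1) keeps a real zero-cost edge rather
            # than being read as "no edge" by the dense csgraph convention
            d = np.where(w > 0, np.maximum(1.0 - w, 1e-12), np.inf)
        else:
            raise ValueError("distance must be 'inverse' or 'one_minus'")
    d[~off] = 0.0
    lengths = shortest_path(d, method="D", directed=False)
    vals = lengths[off]
    if not np.isfinite(vals).all():
        raise ValueError("graph is disconnected: some shortest paths are infinite")
    return float(vals.mean())


def metrics_for(
    weights,
    distance: str = "inverse",
    clc_denominator: str = "strength",
    clc_policy: str = "error",
) -> GraphMetrics:
    """Bundle CS, ClC and PL for one connectivity matrix."""
    w = _validate(weights, min_nodes=3)
    return GraphMetrics(
        cs=connectivity_strength(w),
        clc=clustering_coefficient(w, clc_denominator, clc_policy),
        pl=characteristic_path_length(w, distance),
        n_nodes=w.shape[0],
    )
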