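"""Bezier curve evaluation: Bernstein form and the De Casteljau recursion.

A degree-n Bezier curve over control points P0..Pn is

    B(t) = sum_i C(n, i) t^i (1-t)^(n-i) P_i,      t in [0, 1].

De Casteljau evaluates the same point by repeated linear interpolation
(for the quadratic case: Q0 = (1-t)P0 + tP1, Q1 = (1-t)P1 + tP2,
B(t) = (1-t)Q0 + tQ1), which is numerically stable and cheap; it is the
production evaluator here, with the Bernstein form kept as an independent
formulation.  The posture pipeline uses the quadratic curve through the three
root/head keypoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = [
    "CurveSamples",
    "bernstein_point",
    "de_casteljau_point",
    "sample_curve",
]


@dataclass(frozen=True)
class CurveSamples:
    """Curve points evaluated on a strictly increasing t-grid in [0, 1]."""

    t_values: np.ndarray  # (n,)
    points: np.ndarray  # (n, 2) of (x, y)

    def __len__(self) -> int:
        return len(self.t_values)


def _as_ctrl(ctrl) -> np.ndarray:
    arr = np.asarray(ctrl, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("control points must be an (n+1, 2) array with n >= 1")
    return arr


def _check_t(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    return t


def bernstein_point(ctrl, t: float) -> tuple[float, float]:
    """Evaluate B(t) directly from the Bernstein polynomial form."""
    pts = _as_ctrl(ctrl)
    t = _check_t(t)
    n = pts.shape[0] - 1
    i = np.arange(n + 1)
    weights = comb(n, i) * t**i * (1.0 - t) ** (n - i)
    x, y = weights @ pts
    return float(x), float(y)


def de_casteljau_point(ctrl, t: float) -> tuple[float, float]:
    """Evaluate B(t) by the De Casteljau linear-interpolation recursion."""
    pts = _as_ctrl(ctrl).copy()
    t = _check_t(t)
    while pts.shape[0] > 1:
        pts = (1.0 - t) * pts[:-1] + t * pts[1:]
    return float(pts[0, 0]), float(pts[0, 1])


def sample_curve(ctrl, n_samples: int = 200) -> CurveSamples:
    """Sample the curve on a uniform t-grid (inclusive of both endpoints).

    Evaluation goes through De Casteljau, vectorised over the grid.
    """
    pts = _as_ctrl(ctrl)
    n_samples = int(n_samples)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t = np.linspace(0.0, 1.0, n_samples)
    layers = np.broadcast_to(pts[None, :, :], (n_samples, *pts.shape)).copy()
    while layers.shape[1] > 1:
        layers = (1.0 - t)[:, None, None] * layers[:, :-1] + t[:, None, None] * layers[:, 1:]
    return CurveSamples(t_values=t, points=layers[:, 0, :])
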