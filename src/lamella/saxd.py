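"""Bragg-peak indexing and lamellar repeat distances from SAXD peak positions.

A lamellar phase produces equidistant Bragg peaks q_n = 2*pi*n/d; the
repeat distance follows as d = 2*n*pi/q_n, fitted over all assigned
orders.  Peaks not matching the series (e.g. phase-separated crystalline
cholesterol at q = 1.8 nm^-1) are reported unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LamellarAssignment", "q_to_spacing", "repeat_distance_lsq", "assign_orders"]


@dataclass
class LamellarAssignment:
    """Assignment of observed peak positions to a lamellar order series."""

    d: float
    orders: np.ndarray
    q_obs: np.ndarray
    q_pred: np.ndarray
    unassigned: np.ndarray
    ambiguous: list = field(default_factory=list)  # (q, [candidate orders])
    d_se: float = float("nan")

    def residuals(self) -> np.ndarray:
        return self.q_obs - self.q_pred


def q_to_spacing(q: float) -> float:
    """Spacing 2*pi/q (nm) of a single reflection at q (nm^-1)."""
    q = float(q)
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * np.pi / q


def repeat_distance_lsq(q_obs, orders) -> LamellarAssignment:
    """Least-squares lamellar repeat distance from (q_n, n) pairs.

    Minimising sum (q_n - 2*pi*n/d)^2 is linear in 1/d and has the closed
    form d = 2*pi * sum(n^2) / sum(n*q_n).
    """
    q = np.asarray(q_obs, dtype=float)
    n = np.asarray(orders, dtype=int)
    if q.shape != n.shape or q.ndim != 1 or q.size == 0:
        raise ValueError("q_obs and orders must be equal-length non-empty 1D")
    if np.any(n <= 0):
        raise ValueError("diffraction orders must be positive integers")
    if np.any(q <= 0):
        raise ValueError("q values must be positive")
    d = 2.0 * np.pi * float(np.sum(n.astype(float) ** 2)) / float(np.sum(n * q))
    q_pred = 2.0 * np.pi * n / d
    resid = q - q_pred
    if q.size > 1:
        # propagate residual scatter on the slope 1/d to d
        s2 = float(np.sum(resid**2)) / (q.size - 1)
        slope_se = np.sqrt(s2 / float(np.sum(n.astype(float) ** 2)))
        d_se = d**2 / (2.0 * np.pi) * slope_se
    else:
        d_se = float("nan")
    order = np.argsort(n)
    return LamellarAssignment(d, n[order], q[order], q_pred[order],
                              np.empty(0), d_se=float(d_se))


def assign_orders(q_obs, d_guess: float, tol: float = 0.1) -> LamellarAssignment:
    """Match observed peaks to integer orders of a d_guess series.

    A peak q is assigned order n = round(q*d_guess/(2*pi)) when
    |q - 2*pi*n/d_guess| < tol * 2*pi/d_guess; otherwise it is listed
    unassigned.  When two orders are exactly equidistant the lower order
    is chosen.  A peak whose position is consistent with more than one
    order within tolerance (possible for overlapping phases, e.g. the
    even orders of a 10.8 nm series on a 5.4 nm series) is recorded in
    ``ambiguous`` as well.  The repeat distance is then refined by least
    squares over the assigned peaks.
    """
    if d_guess <= 0:
        raise ValueError("d_guess must be positive")
    # tol = 0.5 (inclusive) admits the boundary case of a peak exactly
    # between two orders, resolved in favour of the lower order
    if not (0 < tol <= 0.5):
        raise ValueError("tol must lie in (0, 0.5]")
    q = np.atleast_1d(np.asarray(q_obs, dtype=float))
    if q.size == 0:
        return LamellarAssignment(d_guess, np.empty(0, int), np.empty(0),
                                  np.empty(0), np.empty(0))
    q1 = 2.0 * np.pi / d_guess
    frac = q / q1
    n_lo = np.floor(frac).astype(int)
    assigned_q, assigned_n, unassigned, ambiguous = [], [], [], []
    for qi, nl in zip(q, n_lo):
        cands = [n for n in (nl, nl + 1) if n >= 1
                 and abs(qi - n * q1) <= tol * q1 + 1e-12 * q1]
        if not cands:
            unassigned.append(qi)
            continue
        # tie-break: lower order (sorted candidates, equal distances keep nl)
        best = min(cands, key=lambda n: (round(abs(qi - n * q1), 12), n))
        assigned_q.append(qi)
        assigned_n.append(best)
        if len(cands) > 1:
            ambiguous.append((float(qi), cands))
    if not assigned_q:
        return LamellarAssignment(d_guess, np.empty(0, int), np.empty(0),
                                  np.empty(0), np.asarray(unassigned),
                                  ambiguous=ambiguous)
    fit = repeat_distance_lsq(assigned_q, assigned_n)
    fit.unassigned = np.asarray(unassigned)
    fit.ambiguous = ambiguous
    return fit
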