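"""Microstate heterogeneity and apparent cooperativity.

A residue exchanging slowly between conformers with distinct pKa has an
ensemble titration curve that is a weighted mixture of Henderson–
Hasselbalch sigmoids.  Such a mixture is always *shallower* than a single
sigmoid, so a Hill fit reports an apparent coefficient n < 1 — apparent
negative cooperativity with no site–site interaction behind it.  This
module quantifies that mechanism: mixture fits of titration curves, the
mapping from conformer pKa separation to apparent n, persistent
single-state intervals in λ-trajectories, and correlation between
protonation and conformational traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError
from .io_formats import LambdaTrajectory
from .synthetic import TitrationModel, theta_true
from .titration_fit import HillParameters, fit_hill, hh_theta, interpolate_pka
from .method_compare import pearson

__all__ = [
    "MixtureFit",
    "StateInterval",
    "fit_mixture",
    "apparent_hill_vs_separation",
    "persistent_intervals",
    "state_trace_correlation",
]


@dataclass
class MixtureFit:
    """Weighted mixture of HH sigmoids fitted to one titration curve.

    ``conformers`` is a list of (weight, pKa); ``rss`` the residual sum of
    squares; ``apparent_hill`` the Hill fit of the same curve for
    comparison.  ``k`` may be smaller than requested when the parsimony
    guard keeps the single-sigmoid description.
    """

    conformers: list[tuple[float, float]]
    rss: float
    apparent_hill: HillParameters

    @property
    def k(self) -> int:
        return len(self.conformers)


def _curve_arrays(curve):
    if hasattr(curve, "pH") and hasattr(curve, "theta"):
        return np.asarray(curve.pH, float), np.asarray(curve.theta, float)
    pH, theta = curve
    return np.asarray(pH, float), np.asarray(theta, float)


def _mixture_theta(pH, weights, pkas):
    w = np.asarray(weights, float)[:, None]
    pk = np.asarray(pkas, float)[:, None]
    return np.sum(w / (1.0 + 10.0 ** (pH[None, :] - pk)), axis=0)


def _fit_k(pH, theta, k, starts):
    lo, hi = pH.min() - 5.0, pH.max() + 5.0

    def unpack(params):
        # stick-breaking weights keep the simplex constraint inside box bounds
        sticks = params[: k - 1]
        weights = []
        rest = 1.0
        for s in sticks:
            weights.append(rest * s)
            rest *= 1.0 - s
        weights.append(rest)
        return np.array(weights), params[k - 1:]

    def resid(params):
        w, pk = unpack(params)
        return _mixture_theta(pH, w, pk) - theta

    best = None
    for start in starts:
        try:
            sol = least_squares(
                resid, start,
                bounds=([1e-3] * (k - 1) + [lo] * k,
                        [1 - 1e-3] * (k - 1) + [hi] * k),
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DataError("mixture fit failed to converge from all starts")
    w, pk = unpack(best.x)
    order = np.argsort(pk)
    return list(zip(w[order].tolist(), pk[order].tolist())), float(2 * best.cost)


def fit_mixture(curve, k: int = 2, rss_ratio: float = 4.0) -> MixtureFit:
    """Fit theta(pH) = Σ w_j · HH(pH; pKa_j) with simplex weights.

    Multistart from quantile crossings of the curve.  A parsimony guard
    keeps the k = 1 description unless the k-component fit reduces the
    residual sum of squares by at least ``rss_ratio``.
    """
    pH, theta = _curve_arrays(curve)
    if pH.size < 2 * k:
        raise DataError(f"need at least {2 * k} grid points for a {k}-conformer fit")
    apparent = fit_hill((pH, theta), force=True)

    def crossing(level):
        # pH at which the (monotone-interpolated) curve passes `level`
        order = np.argsort(-theta)
        return float(np.interp(-level, -theta[order], pH[order]))

    interp = interpolate_pka((pH, theta))
    center = interp.censor.limit if interp.is_censored else interp.value
    rss1 = None
    fit1, rss1 = _fit_k(pH, theta, 1, [np.array([center])])
    if k == 1:
        return MixtureFit(conformers=fit1, rss=rss1, apparent_hill=apparent)
    starts = []
    if k == 2:
        for qa, qb in [(0.75, 0.25), (0.8, 0.2), (0.9, 0.1)]:
            starts.append(np.array([0.5, crossing(qa), crossing(qb)]))
        starts.append(np.array([0.5, center - 1.0, center + 1.0]))
    else:
        qs = np.linspace(0.9, 0.1, k)
        starts.append(np.concatenate([np.full(k - 1, 1.0 / k),
                                      [crossing(q) for q in qs]]))
    fitk, rssk = _fit_k(pH, theta, k, starts)
    if rssk > 0 and rss1 / max(rssk, 1e-30) < rss_ratio:
        return MixtureFit(conformers=fit1, rss=rss1, apparent_hill=apparent)
    return MixtureFit(conformers=fitk, rss=rssk, apparent_hill=apparent)


def apparent_hill_vs_separation(
    weights, delta_pka_list, pH_grid=None, center: float = 4.5
) -> pd.DataFrame:
    """Apparent Hill coefficient of a conformer mixture vs pKa separation.

    For each ΔpKa the mixture curve is built from the closed-form occupancy
    with conformer pKas spread symmetrically around ``center`` and fitted to
    the Hill form.  Returns a frame with columns ``delta_pka``, ``pKa`` and
    ``n``; n = 1 at ΔpKa = 0 and decreases as the conformers separate.
    """
    weights = np.asarray(weights, float)
    if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise DataError("weights must be positive and sum to 1")
    if pH_grid is None:
        pH_grid = np.linspace(center - 3.5, center + 3.5, 29)
    pH_grid = np.asarray(pH_grid, float)
    rows = []
    for delta in delta_pka_list:
        offsets = np.linspace(-0.5, 0.5, weights.size) if weights.size > 1 else [0.0]
        conformers = tuple(
            (float(w), float(center + off * delta)) for w, off in zip(weights, offsets)
        )
        model = TitrationModel(conformers=conformers)
        theta = theta_true(pH_grid, model)
        hill = fit_hill((pH_grid, theta), force=True)
        rows.append({"delta_pka": float(delta), "pKa": hill.pKa, "n": hill.n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StateInterval:
    """A maximal single-state run: [start, end] ns in one protonation state."""

    start: float
    end: float
    state: str  # "protonated" | "deprotonated"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise DataError("interval end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def persistent_intervals(
    traj: LambdaTrajectory,
    lo: float = 0.2,
    hi: float = 0.8,
    min_duration: float = 10.0,
) -> list[StateInterval]:
    """Maximal runs of one assigned protonation state lasting >= min_duration.

    Frames inside the excluded λ band do not break a run; a run of exactly
    ``min_duration`` is included.
    """
    if min_duration <= 0:
        raise DataError("min_duration must be positive")
    lam = traj.lam
    state = np.where(lam < lo, 1, np.where(lam > hi, 0, -1))
    assigned = state >= 0
    out: list[StateInterval] = []
    times = traj.time[assigned]
    vals = state[assigned]
    if vals.size == 0:
        return out
    run_start = 0
    for i in range(1, vals.size + 1):
        if i == vals.size or vals[i] != vals[run_start]:
            start_t = float(times[run_start])
            end_t = float(times[i - 1])
            if end_t - start_t >= min_duration - 1e-12 and end_t > start_t:
                out.append(
                    StateInterval(
                        start=start_t,
                        end=end_t,
                        state="protonated" if vals[run_start] == 1 else "deprotonated",
                    )
                )
            run_start = i
    return out


def state_trace_correlation(x, y) -> float:
    """Pearson correlation of two aligned time series.

    Typical uses: protonation indicator vs hidden/assigned conformer trace,
    or an RMSD-like structural observable vs a sidechain dihedral trace.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise DataError("traces must have equal length")
    if x.size < 3:
        raise DataError("traces must have length >= 3")
    return pearson(x, y)
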