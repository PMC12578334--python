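"""pKa estimation from titration curves: linear interpolation at half
protonation, Henderson–Hasselbalch least squares, and Hill fits, plus the
censor-aware classification of residues that never titrate inside the
scanned pH window.

Sign convention.  The protonated fraction of a monoprotic site is written

    theta(pH) = 1 / (1 + 10**(n * (pH - pKa)))

so that theta -> 1 at low pH, theta(pKa) = 1/2, and theta decreases with
pH.  The Hill exponent n measures the steepness of the transition: n = 1 is
the ideal single-site (HH) curve, n < 1 a shallower transition —
conventionally read as negative cooperativity, but equally the signature of
an ensemble average over microstates with distinct pKa (see the
``microstate`` module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, isotonic_regression

from .errors import DataError
from .io_formats import Censor, PkaEstimate
from .protonation import TitrationCurve

__all__ = [
    "HillParameters",
    "ResidueCall",
    "hh_theta",
    "interpolate_pka",
    "fit_hh",
    "fit_hill",
    "classify_residue",
]


@dataclass(frozen=True)
class HillParameters:
    """Midpoint and steepness of a generalized (Hill) titration curve."""

    pKa: float
    n: float
    rss: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DataError("Hill coefficient must be positive")


def hh_theta(pH, pKa: float, n: float = 1.0):
    """Protonated fraction theta = 1/(1 + 10**(n*(pH - pKa)))."""
    if n <= 0:
        raise DataError("Hill coefficient must be positive")
    pH = np.asarray(pH, dtype=float)
    th = 1.0 / (1.0 + 10.0 ** (n * (pH - pKa)))
    return float(th) if th.ndim == 0 else th


def _curve_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, TitrationCurve):
        return curve.pH, curve.theta
    pH, theta = curve
    return np.asarray(pH, dtype=float), np.asarray(theta, dtype=float)


def _monotone_theta(theta: np.ndarray) -> np.ndarray:
    # pooled-adjacent-violators, non-increasing: guarantees a unique 0.5 crossing
    return -isotonic_regression(-theta, increasing=True).x


def interpolate_pka(curve) -> PkaEstimate:
    """pKa as the pH where the protonation fraction crosses 0.5.

    The curve is first regularized to be non-increasing (pooled adjacent
    violators), then the crossing is located by linear interpolation between
    the bracketing grid points.  Curves that stay on one side of 0.5 return
    a censored estimate at the corresponding grid endpoint: ``above(max pH)``
    when always more than half protonated, ``below(min pH)`` when always
    less.  Grid points landing exactly on 0.5 resolve to that grid pH.
    """
    pH, theta = _curve_arrays(curve)
    if pH.size < 2:
        raise DataError("interpolation needs at least two grid points")
    th = _monotone_theta(theta)
    if np.all(th > 0.5):
        return PkaEstimate(censor=Censor("above", float(pH.max())))
    if np.all(th < 0.5):
        return PkaEstimate(censor=Censor("below", float(pH.min())))
    exact = np.isclose(th, 0.5, atol=1e-12)
    if exact.any():
        return PkaEstimate(value=float(np.mean(pH[exact])))
    i = int(np.nonzero(th > 0.5)[0][-1])  # last point above the midpoint
    p0, p1 = pH[i], pH[i + 1]
    t0, t1 = th[i], th[i + 1]
    return PkaEstimate(value=float(p0 + (t0 - 0.5) * (p1 - p0) / (t0 - t1)))


def fit_hh(curve, force: bool = False) -> PkaEstimate:
    """Least-squares Henderson–Hasselbalch fit (n fixed at 1).

    Initialization is the interpolated pKa; a censored curve is refused
    unless ``force`` is set (the fit then starts from the censor limit).
    The residual sum of squares is attached as ``rss``.
    """
    pH, theta = _curve_arrays(curve)
    interp = interpolate_pka(curve)
    if interp.is_censored:
        if not force:
            raise DataError(
                "curve does not cross theta = 0.5; censored as "
                f"{interp.censor.kind}({interp.censor.limit}) — pass force=True to fit anyway"
            )
        p0 = interp.censor.limit
    else:
        p0 = interp.value
    popt, _ = curve_fit(lambda x, pka: hh_theta(x, pka, 1.0), pH, theta, p0=[p0])
    rss = float(np.sum((theta - hh_theta(pH, popt[0], 1.0)) ** 2))
    return PkaEstimate(value=float(popt[0]), hill_n=1.0, rss=rss)


def fit_hill(curve, force: bool = False) -> HillParameters:
    """Least-squares Hill fit with pKa and n free.

    Bounds: n in [0.05, 5], pKa within 5 units of the grid; initialization
    at (interpolated pKa, n = 1).
    """
    pH, theta = _curve_arrays(curve)
    interp = interpolate_pka(curve)
    if interp.is_censored and not force:
        raise DataError("curve does not cross theta = 0.5 — pass force=True to fit anyway")
    p0 = interp.censor.limit if interp.is_censored else interp.value
    lo, hi = float(pH.min()) - 5.0, float(pH.max()) + 5.0
    popt, _ = curve_fit(
        hh_theta, pH, theta,
        p0=[np.clip(p0, lo, hi), 1.0],
        bounds=([lo, 0.05], [hi, 5.0]),
        maxfev=10000,
    )
    rss = float(np.sum((theta - hh_theta(pH, *popt)) ** 2))
    return HillParameters(pKa=float(popt[0]), n=float(popt[1]), rss=rss)


@dataclass
class ResidueCall:
    """Classification of one residue over the scanned pH window."""

    label: str  # "titrating" | "always_protonated" | "always_deprotonated"
    pka_interp: PkaEstimate
    pka_hh: PkaEstimate | None = None
    hill: HillParameters | None = None


def classify_residue(curve: TitrationCurve, pH_range=None) -> ResidueCall:
    """Classify a residue from its averaged curve and attach pKa estimates.

    A residue whose regularized curve never crosses 0.5 within the grid is
    called ``always_protonated`` (reported "> max pH") or
    ``always_deprotonated`` ("< min pH").  For titrating residues the HH and
    Hill fits are attached, and the replica scatter of the interpolated pKa
    is reported as ``sd`` (replicas that individually fail to cross 0.5 are
    left out of the scatter).
    """
    if pH_range is not None:
        lo, hi = pH_range
        if curve.pH.min() > lo or curve.pH.max() < hi:
            raise DataError("curve grid does not span the requested pH range")
    interp = interpolate_pka(curve)
    if interp.is_censored:
        label = (
            "always_protonated" if interp.censor.kind == "above" else "always_deprotonated"
        )
        return ResidueCall(label=label, pka_interp=interp)
    rep_pkas = []
    for rep in curve.theta_by_replica.index:
        est = interpolate_pka((curve.pH, curve.theta_by_replica.loc[rep].to_numpy()))
        if not est.is_censored:
            rep_pkas.append(est.value)
    sd = float(np.std(rep_pkas, ddof=1)) if len(rep_pkas) > 1 else None
    interp = PkaEstimate(value=interp.value, sd=sd)
    pka_hh = fit_hh(curve)
    try:
        hill = fit_hill(curve)
    except RuntimeError as exc:  # non-convergence: keep the HH answer
        warnings.warn(f"Hill fit failed for {curve.residue_id!r}: {exc}")
        hill = None
    return ResidueCall(label="titrating", pka_interp=interp, pka_hh=pka_hh, hill=hill)
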